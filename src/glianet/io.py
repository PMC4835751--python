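"""Delimited-text tables and JSON reports.

Cell tables: tab-separated with columns
``cell_id, marker, x_um, y_um, z_um, plaque_id, origin`` (marker labels
are case-normalized on read).  Plaque tables: ``plaque_id, class, cx,
cy, cz, volume_um3``.  Both round-trip exactly, so downstream stages are
agnostic to whether records came from the generator or from detection.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CellRecord, Cohort, MARKERS, PLAQUE_CLASSES, \
    PlaqueRecord

__all__ = [
    "SchemaError",
    "cells_to_frame",
    "plaques_to_frame",
    "write_cell_table",
    "read_cell_table",
    "write_plaque_table",
    "read_plaque_table",
    "write_cohort",
    "profiles_to_frame",
    "write_report",
    "read_report",
]

CELL_COLUMNS = ("cell_id", "marker", "x_um", "y_um", "z_um", "plaque_id",
                "origin")
PLAQUE_COLUMNS = ("plaque_id", "class", "cx", "cy", "cz", "volume_um3")


class SchemaError(ValueError):
    """A table does not conform to the documented column schema."""


def cells_to_frame(cells) -> pd.DataFrame:
    rows = [(c.cell_id, c.marker, *c.position_um, c.plaque_id or "",
             c.origin) for c in cells]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def plaques_to_frame(plaques) -> pd.DataFrame:
    rows = [(p.plaque_id, p.plaque_class, *p.center_um, p.volume_um3)
            for p in plaques]
    return pd.DataFrame(rows, columns=PLAQUE_COLUMNS)


def write_cell_table(cells, path) -> None:
    cells_to_frame(cells).to_csv(path, sep="\t", index=False)


def write_plaque_table(plaques, path) -> None:
    plaques_to_frame(plaques).to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _require_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(df.index[df[col].isna()])
        if len(bad):
            # +2: header line plus 1-based numbering
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line "
                f"{int(bad[0]) + 2}")
        df[col] = coerced
    return df


def read_cell_table(path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str,
                                            "plaque_id": str})
    _require_columns(df, CELL_COLUMNS[:5], path)
    df = _require_numeric(df, ("x_um", "y_um", "z_um"), path)
    markers = df["marker"].astype(str).str.strip().str.lower()
    bad = df.index[~markers.isin(MARKERS)]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown marker {df['marker'][bad[0]]!r} at line "
            f"{int(bad[0]) + 2} (expected one of {', '.join(MARKERS)})")
    has_pid = "plaque_id" in df.columns
    has_origin = "origin" in df.columns
    cells = []
    for i, row in df.iterrows():
        pid = row["plaque_id"] if has_pid else None
        if isinstance(pid, float) and math.isnan(pid):
            pid = None
        cells.append(CellRecord(
            cell_id=str(row["cell_id"]), marker=markers[i],
            position_um=(float(row["x_um"]), float(row["y_um"]),
                         float(row["z_um"])),
            origin=str(row["origin"]) if has_origin else "detected",
            plaque_id=(pid or None)))
    return cells


def read_plaque_table(path) -> list[PlaqueRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"plaque_id": str})
    _require_columns(df, PLAQUE_COLUMNS, path)
    df = _require_numeric(df, ("cx", "cy", "cz", "volume_um3"), path)
    classes = df["class"].astype(str).str.strip().str.lower()
    bad = df.index[~classes.isin(PLAQUE_CLASSES)]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown plaque class {df['class'][bad[0]]!r} at line "
            f"{int(bad[0]) + 2}")
    return [PlaqueRecord(plaque_id=str(row["plaque_id"]),
                         plaque_class=classes[i],
                         center_um=(float(row["cx"]), float(row["cy"]),
                                    float(row["cz"])),
                         volume_um3=float(row["volume_um3"]))
            for i, row in df.iterrows()]


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write cells.tsv, plaques.tsv and ground_truth.json; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"cells": str(outdir / "cells.tsv"),
             "plaques": str(outdir / "plaques.tsv"),
             "ground_truth": str(outdir / "ground_truth.json")}
    write_cell_table(cohort.cells, paths["cells"])
    write_plaque_table(cohort.plaques, paths["plaques"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1)
    return paths


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        lo, hi = p.interval_max_gfap_um or (float("nan"), float("nan"))
        rows.append((p.plaque_id, p.plaque_class, p.volume_um3, lo, hi,
                     p.rgn_boundary_um if p.rgn_defined else float("nan"),
                     p.n_iba1_total, p.n_iba1_intra_rgn, p.n_gfap,
                     p.rgn_defined))
    return pd.DataFrame(rows, columns=(
        "plaque_id", "plaque_class", "volume_um3", "interval_lo_um",
        "interval_hi_um", "rgn_boundary_um", "n_iba1_total",
        "n_iba1_intra_rgn", "n_gfap", "rgn_defined"))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Serialize a (possibly dataclass-laden) report dict to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
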