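"""Per-plaque radial profiling of glia and cohort recruitment statistics.

The central measurement: for each plaque, compute 3D Euclidean distances
from glial somata to the plaque center, histogram them in fixed radial
bins, locate the bin holding the maximum number of GFAP+ astrocytes (the
"Interval Max GFAP+"), take that bin's outer edge as the boundary of the
reactive glial net (RGN), classify microglia inside the boundary as
Intra-RGN, and correlate per-plaque counts with plaque volume across a
cohort.

Distances are measured to the plaque CENTER (not its surface), in 3D.
Plaques with no GFAP+ cell inside the analysis radius have an undefined
RGN and are excluded from cohort statistics (never silently zeroed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stats import pearson_r
from .synthetic import CellRecord, MARKERS, PlaqueRecord

__all__ = [
    "RGNUndefinedError",
    "RadialHistogram",
    "RGNProfile",
    "RecruitmentResult",
    "radial_distances",
    "radial_histogram",
    "interval_max_gfap",
    "count_intra_rgn",
    "profile_plaque",
    "profile_cohort",
    "recruitment_correlations",
]

#: Radial bin width, μm.  Every interval reported for these structures
#: (20–30, 30–50, ~40, 60, 80 μm) lies on a 10 μm grid.
DEFAULT_BIN_WIDTH_UM = 10.0

#: Analysis radius, μm: beyond the 80 μm completion of astrocyte
#: reactivity with margin; anything farther is background by definition.
DEFAULT_MAX_RADIUS_UM = 100.0


class RGNUndefinedError(ValueError):
    """Raised when a plaque has no GFAP+ cells, so the RGN has no limit."""


@dataclass
class RadialHistogram:
    """Half-open radial bins [k·w, (k+1)·w) with per-marker counts."""

    bin_width_um: float
    bin_edges_um: np.ndarray  # increasing, starts at 0
    counts_per_marker: dict[str, np.ndarray]
    truncated_last_bin: bool = False

    def counts(self, marker: str) -> np.ndarray:
        return self.counts_per_marker[marker]


@dataclass
class RGNProfile:
    """Everything measured around one plaque."""

    plaque_id: str
    plaque_class: str
    volume_um3: float
    interval_max_gfap_um: tuple[float, float] | None
    rgn_boundary_um: float | None
    n_iba1_total: int
    n_iba1_intra_rgn: int
    n_gfap: int
    distances_per_marker: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def rgn_defined(self) -> bool:
        return self.interval_max_gfap_um is not None


@dataclass
class RecruitmentResult:
    """Pearson correlations of per-plaque glial counts with plaque volume."""

    r_iba1_total: float
    r_iba1_intra_rgn: float
    r_gfap: float
    n_plaques: int


def radial_distances(cells: Iterable[CellRecord],
                     center_um: Sequence[float], marker: str,
                     max_radius_um: float = DEFAULT_MAX_RADIUS_UM,
                     ) -> np.ndarray:
    """Sorted 3D distances (μm) of the marker's cells within the radius."""
    if max_radius_um <= 0:
        raise ValueError("max_radius_um must be > 0")
    center = np.asarray(center_um, dtype=float)
    pos = np.array([c.position_um for c in cells if c.marker == marker],
                   dtype=float).reshape(-1, 3)
    if pos.size == 0:
        return np.empty(0)
    d = np.linalg.norm(pos - center, axis=1)
    return np.sort(d[d <= max_radius_um])


def radial_histogram(distances_per_marker: dict[str, np.ndarray],
                     bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
                     max_radius_um: float = DEFAULT_MAX_RADIUS_UM,
                     ) -> RadialHistogram:
    """Count cells per half-open radial bin, per marker.

    If the bin width does not divide the max radius, the last (partial)
    bin is truncated at the max radius and the histogram is flagged.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    n_full = int(np.floor(max_radius_um / bin_width_um + 1e-9))
    edges = np.arange(n_full + 1) * bin_width_um
    truncated = edges[-1] < max_radius_um - 1e-9
    if truncated:
        warnings.warn("bin width does not divide max radius; last bin "
                      "truncated", stacklevel=2)
        edges = np.append(edges, max_radius_um)
    counts = {}
    for marker, d in distances_per_marker.items():
        d = np.asarray(d, dtype=float)
        d = d[d <= max_radius_um]
        # half-open [lo, hi) bins; np.histogram closes the last bin, so
        # count bin membership directly
        idx = np.minimum((d // bin_width_um).astype(int), len(edges) - 2)
        counts[marker] = np.bincount(idx, minlength=len(edges) - 1)
    return RadialHistogram(bin_width_um=bin_width_um, bin_edges_um=edges,
                           counts_per_marker=counts,
                           truncated_last_bin=bool(truncated))


def interval_max_gfap(hist: RadialHistogram) -> tuple[float, float]:
    """The radial bin holding the maximum GFAP+ count (ties → innermost).

    The outer edge of this interval is the limit of the RGN.
    """
    counts = hist.counts_per_marker.get("gfap")
    if counts is None or counts.sum() == 0:
        raise RGNUndefinedError(
            "no GFAP+ cells within the analysis radius: RGN undefined")
    k = int(np.argmax(counts))  # argmax returns the first (innermost) max
    return (float(hist.bin_edges_um[k]), float(hist.bin_edges_um[k + 1]))


def count_intra_rgn(iba1_distances: np.ndarray, boundary_um: float) -> int:
    """Number of microglia at distance ≤ the RGN boundary."""
    if boundary_um <= 0:
        raise ValueError("boundary_um must be > 0")
    d = np.asarray(iba1_distances, dtype=float)
    return int(np.count_nonzero(d <= boundary_um))


def profile_plaque(plaque: PlaqueRecord, cells: Iterable[CellRecord],
                   bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
                   max_radius_um: float = DEFAULT_MAX_RADIUS_UM,
                   ) -> RGNProfile:
    """Full per-plaque measurement bundle.

    A plaque with zero GFAP+ cells gets a profile flagged undefined
    (``interval_max_gfap_um is None``) rather than raising, so cohort
    runs can proceed and report the exclusion.
    """
    cells = list(cells)
    dists = {m: radial_distances(cells, plaque.center_um, m, max_radius_um)
             for m in MARKERS}
    hist = radial_histogram(dists, bin_width_um, max_radius_um)
    try:
        interval = interval_max_gfap(hist)
        boundary = interval[1]
        n_intra = count_intra_rgn(dists["iba1"], boundary)
    except RGNUndefinedError:
        interval, boundary, n_intra = None, None, 0
    return RGNProfile(
        plaque_id=plaque.plaque_id, plaque_class=plaque.plaque_class,
        volume_um3=plaque.volume_um3, interval_max_gfap_um=interval,
        rgn_boundary_um=boundary, n_iba1_total=len(dists["iba1"]),
        n_iba1_intra_rgn=n_intra, n_gfap=len(dists["gfap"]),
        distances_per_marker=dists)


def profile_cohort(plaques: Sequence[PlaqueRecord],
                   cells: Sequence[CellRecord],
                   bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
                   max_radius_um: float = DEFAULT_MAX_RADIUS_UM,
                   ) -> list[RGNProfile]:
    """Profile every plaque against its own cells (matched by plaque_id)."""
    by_plaque: dict[str | None, list[CellRecord]] = {}
    for c in cells:
        by_plaque.setdefault(c.plaque_id, []).append(c)
    return [profile_plaque(p, by_plaque.get(p.plaque_id, []),
                           bin_width_um, max_radius_um)
            for p in plaques]


def recruitment_correlations(profiles: Sequence[RGNProfile],
                             ) -> RecruitmentResult:
    """Pearson r of (count, volume) across plaques, per count type.

    Plaques with an undefined RGN are excluded.  Zero-variance counts
    yield NaN (undefined), never a silent 0.
    """
    valid = [p for p in profiles if p.rgn_defined]
    if len(valid) < 3:
        raise ValueError(
            f"need >= 3 plaques with a defined RGN, got {len(valid)}")
    vol = np.array([p.volume_um3 for p in valid])

    def _r(counts: np.ndarray) -> float:
        if np.ptp(counts) == 0 or np.ptp(vol) == 0:
            return float("nan")
        return pearson_r(counts, vol)

    return RecruitmentResult(
        r_iba1_total=_r(np.array([p.n_iba1_total for p in valid])),
        r_iba1_intra_rgn=_r(np.array([p.n_iba1_intra_rgn for p in valid])),
        r_gfap=_r(np.array([p.n_gfap for p in valid])),
        n_plaques=len(valid))
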