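"""Synthetic plaque/glia generators for reactive glial net (RGN) analysis.

A reactive glial net is the stereotyped 3D arrangement of glia around an
amyloid plaque: an inner shell of activated (Iba1+) microglia and an outer
corona of reactive (GFAP+) astrocytes.  This module generates seeded 3D
point patterns of plaques with surrounding glia, cohorts of such plaques,
2D microglial landscapes for Voronoi analysis, and voxel renderings that
emulate confocal stacks — with ground truth recorded for every parameter
the analysis pipeline is expected to recover.

Geometry model
--------------
Shell cells sit at a radial distance drawn from a marker-specific normal
distribution, truncated below at the plaque core radius and (for
astrocytes) above at a hard outer limit; directions are uniform on the
sphere.  Per-plaque shell counts are linear in plaque volume with additive
Gaussian noise whose standard deviation is solved in closed form so that,
across a cohort, the sample Pearson correlation between measured count and
volume matches a preset population value.  Background (non-RGN) glia are a
homogeneous Poisson process over the field of view.

All coordinates are physical micrometres, right-handed, origin at the
field corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats as _st

__all__ = [
    "MARKERS",
    "PLAQUE_CLASSES",
    "RGNPreset",
    "PlaqueRecord",
    "CellRecord",
    "Cohort",
    "LandscapeSpec",
    "Landscape",
    "PRESET_NAMES",
    "make_preset",
    "equivalent_radius",
    "loguniform_moments",
    "calibrated_count_noise_sd",
    "sample_plaque",
    "sample_glia",
    "generate_cohort",
    "generate_landscape",
    "render_stack",
]

MARKERS = ("iba1", "gfap")
PLAQUE_CLASSES = ("dense_core", "fibrillar", "phf_nft")

#: Default per-plaque field of view in μm (x, y, z); the plaque sits at its
#: center, so a 100 μm analysis radius is fully contained.
DEFAULT_FIELD_UM = (200.0, 200.0, 200.0)

#: Default plaque-volume range (μm³) for cohorts, log-uniform: equivalent
#: radii ~5–23 μm, the span seen across dense-core and fibrillar deposits.
DEFAULT_VOLUME_RANGE_UM3 = (500.0, 5.0e4)

#: Radius (μm) of the analysis sphere whose background-cell Poisson count
#: enters the count-noise calibration (matches the profiling max radius).
CALIBRATION_RADIUS_UM = 100.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RGNPreset:
    """Generative parameters for one plaque class / disease condition.

    Lengths in μm, volumes in μm³, densities in cells per mm³.  The shell
    ordering invariant (microglia inner, astrocytes outer) is enforced.
    """

    name: str
    plaque_class: str
    core_radius_um: float
    microglia_shell_mean_um: float
    microglia_shell_sd_um: float
    astro_shell_mean_um: float
    astro_shell_sd_um: float
    astro_max_um: float
    microglia_base_count: float
    gfap_base_count: float
    microglia_slope_per_um3: float
    gfap_slope_per_um3: float
    microglia_population_r: float
    gfap_population_r: float
    background_iba1_per_mm3: float
    background_gfap_per_mm3: float
    field_um: tuple[float, float, float] = DEFAULT_FIELD_UM
    volume_range_um3: tuple[float, float] = DEFAULT_VOLUME_RANGE_UM3

    def __post_init__(self) -> None:
        if self.plaque_class not in PLAQUE_CLASSES:
            raise ValueError(f"unknown plaque class {self.plaque_class!r}")
        for f_ in ("core_radius_um", "microglia_shell_mean_um",
                   "microglia_shell_sd_um", "astro_shell_mean_um",
                   "astro_shell_sd_um", "astro_max_um"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be > 0")
        if not (self.astro_max_um >= self.astro_shell_mean_um
                >= self.microglia_shell_mean_um):
            raise ValueError(
                "shell ordering violated: need astro_max >= astro mean "
                ">= microglia mean (microglia inner, astrocytes outer)")
        for f_ in ("microglia_base_count", "gfap_base_count",
                   "microglia_slope_per_um3", "gfap_slope_per_um3",
                   "background_iba1_per_mm3", "background_gfap_per_mm3"):
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")
        for f_ in ("microglia_population_r", "gfap_population_r"):
            if abs(getattr(self, f_)) > 1:
                raise ValueError(f"|{f_}| must be <= 1")

    def shell_params(self, marker: str) -> tuple[float, float, float]:
        """(mean, sd, upper truncation) of the radial law for ``marker``."""
        half = min(self.field_um) / 2.0
        if marker == "iba1":
            return (self.microglia_shell_mean_um,
                    self.microglia_shell_sd_um, half)
        if marker == "gfap":
            return (self.astro_shell_mean_um, self.astro_shell_sd_um,
                    min(self.astro_max_um, half))
        raise ValueError(f"unknown marker {marker!r}")

    def count_params(self, marker: str) -> tuple[float, float, float]:
        """(base count, slope per μm³, target population r) for ``marker``."""
        if marker == "iba1":
            return (self.microglia_base_count, self.microglia_slope_per_um3,
                    self.microglia_population_r)
        if marker == "gfap":
            return (self.gfap_base_count, self.gfap_slope_per_um3,
                    self.gfap_population_r)
        raise ValueError(f"unknown marker {marker!r}")

    def background_density(self, marker: str) -> float:
        if marker == "iba1":
            return self.background_iba1_per_mm3
        if marker == "gfap":
            return self.background_gfap_per_mm3
        raise ValueError(f"unknown marker {marker!r}")


@dataclass(frozen=True)
class PlaqueRecord:
    """One plaque or PHF/NFT aggregate: class, center (μm), volume (μm³)."""

    plaque_id: str
    plaque_class: str
    center_um: tuple[float, float, float]
    volume_um3: float
    equivalent_radius_um: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError("volume_um3 must be > 0")
        if self.equivalent_radius_um == 0.0:
            object.__setattr__(self, "equivalent_radius_um",
                               equivalent_radius(self.volume_um3))


@dataclass(frozen=True)
class CellRecord:
    """One soma: marker class and 3D position in μm.

    ``origin`` ("shell" or "background") is generator ground truth only;
    detected cells carry origin "detected".
    """

    cell_id: str
    marker: str
    position_um: tuple[float, float, float]
    origin: str = "detected"
    plaque_id: str | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"marker must be one of {MARKERS}, "
                             f"got {self.marker!r}")


@dataclass
class Cohort:
    """A generated set of plaques with their glia and full ground truth."""

    preset: RGNPreset
    plaques: list[PlaqueRecord]
    cells: list[CellRecord]
    ground_truth: dict

    def cells_for(self, plaque_id: str) -> list[CellRecord]:
        return [c for c in self.cells if c.plaque_id == plaque_id]


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a 2D microglial landscape (1 mm² by default).

    ``plaque_perturbed`` mode relocates ``aggregation_fraction`` of the
    cells into discs of ``aggregation_radius_um`` around plaque centers,
    preferentially thinning the surrounding annulus out to
    ``depletion_outer_um`` — the aggregation/depletion signature of AD
    tissue versus the homogeneous control distribution.
    """

    roi_um: tuple[float, float] = (1000.0, 1000.0)
    mode: str = "homogeneous"
    n_microglia: int = 100
    plaque_centers: tuple[tuple[float, float], ...] = ()
    aggregation_radius_um: float = 50.0
    depletion_outer_um: float = 150.0
    aggregation_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "plaque_perturbed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_microglia < 3:
            raise ValueError("n_microglia must be >= 3 "
                             "(Voronoi tessellation needs >= 3 seeds)")
        if self.depletion_outer_um <= self.aggregation_radius_um:
            raise ValueError("depletion_outer_um must exceed "
                             "aggregation_radius_um")
        if not 0.0 <= self.aggregation_fraction <= 1.0:
            raise ValueError("aggregation_fraction must be in [0, 1]")
        if self.mode == "plaque_perturbed" and not self.plaque_centers:
            raise ValueError("plaque_perturbed mode needs plaque_centers")


@dataclass
class Landscape:
    spec: LandscapeSpec
    points_um: np.ndarray  # (n, 2)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _base_preset(**overrides) -> dict:
    d = dict(
        core_radius_um=8.0,
        microglia_shell_mean_um=25.0, microglia_shell_sd_um=4.0,
        astro_shell_mean_um=40.0, astro_shell_sd_um=6.0, astro_max_um=80.0,
        background_iba1_per_mm3=3000.0, background_gfap_per_mm3=1000.0,
    )
    d.update(overrides)
    return d


# Human dense-core: microglial capsule centered 25 μm (20–30 μm band) from
# the plaque center; astrocyte somata 40 μm (30–50 μm band), hard outer
# truncation at 80 μm.  Counts/correlations for fibrillar come from the
# ~2× microglial recruitment and the published r of the fibrillar cohort;
# the astrocytic geometry is shared between the two plaque classes.
_PRESETS: dict[str, dict] = {
    "human-dense-core": _base_preset(
        plaque_class="dense_core",
        microglia_base_count=21.0, microglia_slope_per_um3=5.0e-4,
        gfap_base_count=25.0, gfap_slope_per_um3=5.0e-4,
        microglia_population_r=0.5, gfap_population_r=0.479,
    ),
    "human-fibrillar": _base_preset(
        plaque_class="fibrillar",
        microglia_base_count=42.0, microglia_slope_per_um3=1.0e-3,
        gfap_base_count=25.0, gfap_slope_per_um3=5.0e-4,
        microglia_population_r=0.561, gfap_population_r=0.479,
    ),
    # PHF/NFT aggregates: microglia do not cluster (no recruitment with
    # aggregate volume: slope 0, target r 0 → |r| small by construction);
    # astrocytes sometimes form a corona, weakly correlated with volume.
    "human-phf-nft": _base_preset(
        plaque_class="phf_nft",
        microglia_shell_mean_um=35.0, microglia_shell_sd_um=10.0,
        microglia_base_count=5.0, microglia_slope_per_um3=0.0,
        gfap_base_count=18.0, gfap_slope_per_um3=1.4e-4,
        microglia_population_r=0.0, gfap_population_r=0.281,
    ),
    # Mouse (CRND8) mid-stage: astrocyte shell centered 40 μm from the
    # dense core; late-stage: shell widens to 60 μm with more glia.
    "mouse-mid": _base_preset(
        plaque_class="dense_core",
        astro_shell_mean_um=40.0, astro_shell_sd_um=6.0, astro_max_um=80.0,
        microglia_base_count=14.0, microglia_slope_per_um3=1.0e-4,
        gfap_base_count=20.0, gfap_slope_per_um3=4.0e-4,
        microglia_population_r=0.264, gfap_population_r=0.561,
    ),
    "mouse-late": _base_preset(
        plaque_class="dense_core",
        astro_shell_mean_um=60.0, astro_shell_sd_um=8.0, astro_max_um=100.0,
        microglia_base_count=20.0, microglia_slope_per_um3=2.0e-4,
        gfap_base_count=24.0, gfap_slope_per_um3=4.0e-4,
        microglia_population_r=0.264, gfap_population_r=0.561,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str, **overrides) -> RGNPreset:
    """Return the named condition preset, optionally with field overrides.

    Valid names: ``human-dense-core``, ``human-fibrillar``,
    ``human-phf-nft``, ``mouse-mid``, ``mouse-late``.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return RGNPreset(name=name, **params)


# ---------------------------------------------------------------------------
# Count-noise calibration
# ---------------------------------------------------------------------------

def equivalent_radius(volume_um3: float) -> float:
    """Radius (μm) of the sphere with the given volume: (3V/4π)^(1/3)."""
    return float((3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0))


def loguniform_moments(lo: float, hi: float) -> tuple[float, float]:
    """Mean and variance of a log-uniform variable on [lo, hi]."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    span = math.log(hi / lo)
    mean = (hi - lo) / span
    second = (hi * hi - lo * lo) / (2.0 * span)
    return mean, second - mean * mean


def calibrated_count_noise_sd(preset: RGNPreset, marker: str,
                              volume_range_um3: tuple[float, float] | None = None,
                              ) -> float:
    """Per-plaque count-noise sd realizing the preset's population r.

    With counts N = base + slope·V + ε and volumes log-uniform over the
    range, corr(N_measured, V) = slope·sd(V) / sqrt(slope²·var(V) + σ²_tot)
    where σ²_tot collects the Gaussian noise, the Poisson variance of
    background cells inside the 100 μm analysis sphere, and the rounding
    variance 1/12.  Solving for the Gaussian part gives the sd returned
    here (floored at 0).  A target r of 0 goes with slope 0, in which case
    a nominal sd of 1 is returned (the correlation is 0 regardless).
    """
    base, slope, rho = preset.count_params(marker)
    if rho == 0.0 or slope == 0.0:
        if rho != 0.0:
            raise ValueError(
                f"{marker}: nonzero target r requires a nonzero slope")
        return 1.0
    if (rho > 0) != (slope > 0):
        raise ValueError(f"{marker}: sign of target r must match slope")
    vrange = volume_range_um3 or preset.volume_range_um3
    _, var_v = loguniform_moments(*vrange)
    lam = (preset.background_density(marker) * 1e-9
           * 4.0 / 3.0 * math.pi * CALIBRATION_RADIUS_UM ** 3)
    var_needed = slope * slope * var_v * (1.0 / rho ** 2 - 1.0)
    var_eps = var_needed - lam - 1.0 / 12.0
    return math.sqrt(max(var_eps, 0.0))


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _rng(seed) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


def sample_plaque(preset: RGNPreset, volume_um3: float, seed=0,
                  plaque_id: str = "p0") -> PlaqueRecord:
    """A plaque of the given volume, centered in the field of view."""
    if volume_um3 <= 0:
        raise ValueError("volume_um3 must be > 0")
    center = tuple(s / 2.0 for s in preset.field_um)
    return PlaqueRecord(plaque_id=plaque_id,
                        plaque_class=preset.plaque_class,
                        center_um=center, volume_um3=float(volume_um3))


def _truncnorm_radii(rng: Generator, n: int, mean: float, sd: float,
                     lo: float, hi: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return _st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                             random_state=rng)


def _uniform_sphere_dirs(rng: Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def sample_glia(plaque: PlaqueRecord, preset: RGNPreset, seed=0,
                count_noise_sd: dict[str, float] | None = None,
                ) -> list[CellRecord]:
    """Shell and background glia around one plaque.

    Shell radii follow the preset's truncated-normal radial law (lower
    truncation at the preset core radius; astrocytes also truncated at
    ``astro_max_um``); directions are uniform on the sphere.  Shell counts
    are ``round(base + slope·V + ε)`` clamped at 0, with ε ~ N(0, sd) and
    sd taken from ``count_noise_sd`` (per marker) or calibrated from the
    preset (see :func:`calibrated_count_noise_sd`).  Background cells are
    a homogeneous Poisson process over the field.
    """
    if plaque.plaque_class != preset.plaque_class:
        raise ValueError("preset and plaque disagree on plaque_class")
    rng = _rng(seed)
    center = np.asarray(plaque.center_um)
    field = np.asarray(preset.field_um)
    cells: list[CellRecord] = []
    i = 0
    for marker in MARKERS:
        base, slope, _ = preset.count_params(marker)
        if count_noise_sd is not None and marker in count_noise_sd:
            sd = count_noise_sd[marker]
        else:
            sd = calibrated_count_noise_sd(preset, marker)
        eps = rng.normal(0.0, sd) if sd > 0 else 0.0
        n = int(round(base + slope * plaque.volume_um3 + eps))
        n = max(n, 0)
        mean, ssd, hi = preset.shell_params(marker)
        radii = _truncnorm_radii(rng, n, mean, ssd, preset.core_radius_um, hi)
        dirs = _uniform_sphere_dirs(rng, n)
        pos = center + radii[:, None] * dirs
        np.clip(pos, 0.0, field, out=pos)
        for p in pos:
            cells.append(CellRecord(f"{plaque.plaque_id}-c{i}", marker,
                                    tuple(p), "shell", plaque.plaque_id))
            i += 1
    field_mm3 = float(np.prod(field)) * 1e-9
    for marker in MARKERS:
        lam = preset.background_density(marker) * field_mm3
        n_bg = int(rng.poisson(lam)) if lam > 0 else 0
        pos = rng.uniform(0.0, 1.0, (n_bg, 3)) * field
        for p in pos:
            cells.append(CellRecord(f"{plaque.plaque_id}-c{i}", marker,
                                    tuple(p), "background",
                                    plaque.plaque_id))
            i += 1
    return cells


def generate_cohort(preset: RGNPreset, n_plaques: int,
                    volume_range_um3: tuple[float, float] | None = None,
                    seed=0) -> Cohort:
    """A seeded cohort of plaques with glia and embedded ground truth.

    Plaque volumes are log-uniform over the range; per-plaque random
    streams are spawned from the cohort seed via ``SeedSequence`` so the
    cohort is reproducible element-wise.
    """
    if n_plaques < 1:
        raise ValueError("n_plaques must be >= 1")
    vrange = volume_range_um3 or preset.volume_range_um3
    lo, hi = vrange
    if not (0 < lo < hi):
        raise ValueError("volume range must satisfy 0 < lo < hi")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    vol_ss, *cell_ss = ss.spawn(n_plaques + 1)
    vol_rng = default_rng(vol_ss)
    volumes = np.exp(vol_rng.uniform(math.log(lo), math.log(hi), n_plaques))
    noise_sd = {m: calibrated_count_noise_sd(preset, m, vrange)
                for m in MARKERS}
    plaques: list[PlaqueRecord] = []
    cells: list[CellRecord] = []
    for k, (v, css) in enumerate(zip(volumes, cell_ss)):
        plaque = sample_plaque(preset, float(v), plaque_id=f"p{k}")
        plaques.append(plaque)
        cells.extend(sample_glia(plaque, preset, default_rng(css),
                                 count_noise_sd=noise_sd))
    truth = {
        "preset": preset.name,
        "plaque_class": preset.plaque_class,
        "n_plaques": n_plaques,
        "volume_range_um3": list(vrange),
        "count_noise_sd": noise_sd,
        "shell": {m: dict(zip(("mean_um", "sd_um", "max_um"),
                              preset.shell_params(m))) for m in MARKERS},
        "counts": {m: dict(zip(("base", "slope_per_um3", "target_r"),
                               preset.count_params(m))) for m in MARKERS},
        "background_per_mm3": {m: preset.background_density(m)
                               for m in MARKERS},
    }
    return Cohort(preset=preset, plaques=plaques, cells=cells,
                  ground_truth=truth)


# ---------------------------------------------------------------------------
# 2D landscapes (Voronoi substrate)
# ---------------------------------------------------------------------------

def generate_landscape(spec: LandscapeSpec, seed=0) -> Landscape:
    """Seeded 2D microglial point pattern over the ROI.

    Homogeneous mode: uniform points.  Plaque-perturbed mode: starting
    from the same uniform draw (so a zero aggregation fraction reproduces
    the homogeneous pattern under the same seed), a fraction of the points
    — taken preferentially from the depletion annuli — is relocated
    uniformly into the aggregation discs around the plaque centers.
    """
    rng = _rng(seed)
    roi = np.asarray(spec.roi_um)
    pts = rng.uniform(0.0, 1.0, (spec.n_microglia, 2)) * roi
    if spec.mode == "homogeneous":
        return Landscape(spec=spec, points_um=pts)

    centers = np.asarray(spec.plaque_centers, dtype=float)
    n_move = int(round(spec.aggregation_fraction * spec.n_microglia))
    if n_move == 0:
        return Landscape(spec=spec, points_um=pts)
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    dmin = d.min(axis=1)
    in_disc = dmin <= spec.aggregation_radius_um
    in_annulus = (~in_disc) & (dmin <= spec.depletion_outer_um)
    annulus_idx = np.flatnonzero(in_annulus)
    outside_idx = np.flatnonzero(~in_disc & ~in_annulus)
    rng.shuffle(annulus_idx)
    rng.shuffle(outside_idx)
    move = np.concatenate([annulus_idx, outside_idx])[:n_move]
    which = rng.integers(0, len(centers), len(move))
    # uniform in the disc, rejection-free via sqrt radius; re-draw any
    # relocation that would leave the ROI
    for idx, c in zip(move, which):
        while True:
            r = spec.aggregation_radius_um * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            p = centers[c] + r * np.array([math.cos(th), math.sin(th)])
            if 0.0 <= p[0] <= roi[0] and 0.0 <= p[1] <= roi[1]:
                pts[idx] = p
                break
    return Landscape(spec=spec, points_um=pts)


# ---------------------------------------------------------------------------
# Voxel rendering (synthetic confocal stacks)
# ---------------------------------------------------------------------------

#: Default voxel size (dx, dy, dz) in μm — lateral 0.5 μm, 1 μm z-step.
DEFAULT_VOXEL_UM = (0.5, 0.5, 1.0)

CHANNELS = ("iba1", "gfap", "plaque")


def _voxel_centers(n: int, delta: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * delta


def render_stack(cells: Sequence[CellRecord],
                 plaques: Sequence[PlaqueRecord] = (),
                 field_um: tuple[float, float, float] = DEFAULT_FIELD_UM,
                 voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_UM,
                 blob_sigma_um: float = 2.0,
                 noise_sd: float = 0.0,
                 seed=0):
    """Render somata and plaques into a 3-channel voxel stack.

    Channels are (iba1, gfap, plaque); array axes (channel, z, y, x);
    voxel (0, 0, 0) spans [0, Δ) on each axis with voxel centers at
    (i + 0.5)·Δ.  Each soma is an isotropic Gaussian blob of the given
    sigma and unit peak amplitude.  A dense-core plaque renders as a
    filled sphere of its equivalent radius; a fibrillar plaque as a
    spherical fibril annulus (inner half-radius hollow); a PHF/NFT
    aggregate as a diffuse Gaussian of sigma = r_eq/2.  Additive Gaussian
    noise of the given sd is applied to every channel.
    """
    from .detection import VoxelStack  # deferred: detection consumes stacks

    dx, dy, dz = voxel_size_um
    if min(voxel_size_um) <= 0:
        raise ValueError("voxel sizes must be > 0")
    if blob_sigma_um < max(voxel_size_um):
        import warnings
        warnings.warn("blob sigma finer than voxel size; blobs will alias",
                      stacklevel=2)
    nx = max(int(round(field_um[0] / dx)), 1)
    ny = max(int(round(field_um[1] / dy)), 1)
    nz = max(int(round(field_um[2] / dz)), 1)
    data = np.zeros((len(CHANNELS), nz, ny, nx), dtype=np.float32)

    cx = _voxel_centers(nx, dx)
    cy = _voxel_centers(ny, dy)
    cz = _voxel_centers(nz, dz)

    def _add_gaussian(ch: int, pos, sigma: float, amp: float = 1.0) -> None:
        x0, y0, z0 = pos
        ext = 4.0 * sigma
        ix = np.searchsorted(cx, [x0 - ext, x0 + ext])
        iy = np.searchsorted(cy, [y0 - ext, y0 + ext])
        iz = np.searchsorted(cz, [z0 - ext, z0 + ext])
        sx = slice(max(ix[0] - 1, 0), min(ix[1] + 1, nx))
        sy = slice(max(iy[0] - 1, 0), min(iy[1] + 1, ny))
        sz = slice(max(iz[0] - 1, 0), min(iz[1] + 1, nz))
        gx = np.exp(-0.5 * ((cx[sx] - x0) / sigma) ** 2)
        gy = np.exp(-0.5 * ((cy[sy] - y0) / sigma) ** 2)
        gz = np.exp(-0.5 * ((cz[sz] - z0) / sigma) ** 2)
        data[ch, sz, sy, sx] += amp * (gz[:, None, None]
                                       * gy[None, :, None]
                                       * gx[None, None, :])

    chan_index = {m: i for i, m in enumerate(CHANNELS)}
    for cell in cells:
        _add_gaussian(chan_index[cell.marker], cell.position_um,
                      blob_sigma_um)

    for plaque in plaques:
        x0, y0, z0 = plaque.center_um
        r = plaque.equivalent_radius_um
        if plaque.plaque_class == "phf_nft":
            _add_gaussian(chan_index["plaque"], plaque.center_um, r / 2.0)
            continue
        ext = r + max(voxel_size_um)
        sx = slice(*np.searchsorted(cx, [x0 - ext, x0 + ext]))
        sy = slice(*np.searchsorted(cy, [y0 - ext, y0 + ext]))
        sz = slice(*np.searchsorted(cz, [z0 - ext, z0 + ext]))
        d2 = ((cx[sx] - x0)[None, None, :] ** 2
              + (cy[sy] - y0)[None, :, None] ** 2
              + (cz[sz] - z0)[:, None, None] ** 2)
        if plaque.plaque_class == "dense_core":
            mask = d2 <= r * r
        else:  # fibrillar: hollow fibril annulus
            mask = (d2 <= r * r) & (d2 >= (0.5 * r) ** 2)
        data[chan_index["plaque"], sz, sy, sx] = np.maximum(
            data[chan_index["plaque"], sz, sy, sx], mask.astype(np.float32))

    if noise_sd > 0:
        rng = _rng(seed)
        data += rng.normal(0.0, noise_sd, data.shape).astype(np.float32)

    return VoxelStack(data=data, channel_names=CHANNELS,
                      voxel_size_um=(dx, dy, dz))
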