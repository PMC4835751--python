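# Methods

## The measurement model

A reactive glial net (RGN) is quantified per plaque from soma centroids
alone. All distances are 3D Euclidean distances to the plaque **center**
(not its surface), in μm, because the source measurements are made
between cell centers and plaque centers; the generator's core-radius
truncation keeps center distances meaningful for plaques of realistic
size. Distances beyond a 100 μm analysis radius are ignored: astrocyte
reactivity around a dense-core plaque is complete by ~80 μm, so 100 μm
covers the structure with margin and everything farther out is
background by definition.

Radial histograms use half-open bins [k·w, (k+1)·w) with default width
w = 10 μm — every interval reported for these structures (20–30 μm
microglial capsule, 30–50 μm astrocyte somata, shells at 40, 60, 80 μm)
lies on a 10 μm grid. The **Interval Max GFAP+** is the bin holding the
most GFAP+ somata; ties break toward the innermost bin (conservative:
the smaller RGN), and the bin's **outer** edge is taken as the RGN
boundary (the inclusive reading of "the interval defines the limit").
Both choices are deterministic and configurable. Microglia at distance
≤ the boundary are **Intra-RGN**. A plaque with zero GFAP+ cells inside
the analysis radius has an undefined RGN: its profile is flagged and
excluded from cohort statistics rather than scored as a silent zero,
which would bias the count–volume correlations.

The per-plaque argmax is computed first and interval midpoints are
averaged across plaques afterwards (per-plaque argmax, then average),
matching a per-plaque definition of the statistic; averaging the
histograms first and taking one cohort argmax is a different estimator
and is not used.

## Synthetic data: what it emulates

The generator produces the geometry the pipeline must recover, with
ground truth embedded:

- **Shell radii** are truncated normal: lower truncation at the preset
  core radius (8 μm), upper truncation for astrocytes at `astro_max_um`
  (80 μm for human/mouse-mid presets, 100 μm for mouse-late). A
  two-parameter location/scale family is the simplest law consistent
  with "shell centered at X μm" statements; nothing heavier-tailed is
  implied by the available summaries. Directions are uniform on the
  sphere, so shells are isotropic.
- **Counts** are N = round(base + slope·V + ε) clamped at 0, ε Gaussian.
  The noise sd is solved in closed form so that the *measured*
  per-plaque count (shell + Poisson background inside the 100 μm
  analysis sphere, plus rounding) has the preset's population Pearson
  correlation with volume: with volumes log-uniform on [a, b],
  σ²_ε = slope²·Var(V)·(1/ρ² − 1) − λ_bg − 1/12, floored at 0. Clamping
  at zero is kept rare by construction (base counts ≥ ~3 total sd), so
  the realized correlation stays within a few hundredths of ρ.
- **Plaque volumes** are log-uniform over [500, 5·10⁴] μm³ (equivalent
  radii ~5–23 μm): plaque sizes span orders of magnitude and no
  parametric size distribution is assumed.
- **Background glia** are homogeneous Poisson over the 200³ μm field.
  Densities are this package's own defaults, not literature values for
  any specific cohort: 3000 Iba1+ cells/mm³ (microglia tile cortex at
  thousands per mm³) and 1000 GFAP+ cells/mm³ (GFAP immunoreactivity is
  sparse outside reactive zones).
- **2D landscapes** for Voronoi analysis are uniform points over 1 mm²,
  optionally perturbed by relocating a fraction of cells into discs
  around plaque positions while thinning the surrounding annulus — the
  aggregation/depletion pattern of plaque-bearing tissue. The
  homogeneous draw happens first in the same stream, so a zero
  aggregation fraction reproduces the control pattern bit-for-bit under
  the same seed.
- **Rendering** emulates confocal stacks at 0.5 × 0.5 × 1.0 μm voxels
  (1 μm z-step, lateral/axial anisotropy typical of such stacks): somata
  as isotropic Gaussian blobs (σ = 2 μm, unit peak), dense-core plaques
  as filled spheres of the volume-equivalent radius, fibrillar plaques
  as a hollow fibril annulus (inner half-radius empty), PHF/NFT
  aggregates as a diffuse Gaussian. Voxel (0,0,0) spans [0, Δ); voxel
  centers sit at (i + 0.5)·Δ.

### Preset parameter choices

Shell geometry per preset is fixed by the condition it encodes:
microglia 25 ± 4 μm (the 20–30 μm capsule) and astrocytes 40 ± 6 μm for
human dense-core and fibrillar plaques (fibrillar plaques recruit about
twice the microglia but their astrocyte shell geometry is unchanged);
mouse mid-stage astrocytes 40 ± 6 μm, late-stage 60 ± 8 μm. The PHF/NFT
preset keeps a diffuse, wide microglial placement (35 ± 10 μm) with zero
recruitment slope — microglia do not cluster around these aggregates —
and a weak astrocyte correlation (target r = 0.281).

Base counts and slopes are chosen so mean totals are in the tens of
cells per RGN and so the closed-form calibration has headroom (negative
draws before clamping ≤ ~1%): dense-core 21 + 5·10⁻⁴·V microglia and
25 + 5·10⁻⁴·V astrocytes; fibrillar doubles both microglial terms
(42 + 10⁻³·V) so the Intra-RGN count ratio is 2 across the whole volume
range, not only at V → 0. Target population correlations: fibrillar
r = 0.561 (Iba1 total) and 0.479 (GFAP); dense-core 0.5/0.479; mouse
0.264/0.561, reused for mouse-late where no separate value is available.

**On the 80 μm corona extent.** With the documented astrocyte law
(40 ± 6 μm truncated at 80 μm), the expected per-plaque *maximum* soma
distance for cohorts of ~30–60 astrocytes per plaque is ≈ 52–56 μm: the
maximum of ~30–60 draws of N(40, 6) sits near +2σ, and reaching 70+ μm
would require astronomically many somata or a sd incompatible with the
30–50 μm soma band. The 80 μm completion describes astrocyte
*reactivity* — dominated by processes — rather than soma positions, so
`astro_max_um = 80` acts as a hard cap on rare outliers, and the
measured corona extent stays safely below it. The acceptance script
reports the computed value as measured.

### What passing tests do and do not show

The generator realizes isotropic shells, independent plaques, exact
marker identity and Poisson background. Real tissue has anisotropic
fields, touching somata that a binary centroid detector merges,
marker-expression gradients, irregular plaque shapes, and RGNs that can
overlap between neighboring plaques. Tests passing on synthetic cohorts
therefore validate the *estimators* (that the pipeline recovers known
shell centers, correlations and geometry), not the biology of any
particular tissue sample.

## Detection

Segmentation is deliberately simple and fully deterministic: Otsu or
fixed thresholding, 26-connected components in 3D (8-connected in 2D
logic), size filter at 8 μm³ (well below soma volume, removes specks),
binary (unweighted) centroids — the closest reproducible analogue of
manually marked somata, and trivially flipped to intensity-weighted if
needed. The plaque is the largest component of the plaque channel;
volume is voxel count × voxel volume. No deconvolution, no watershed
splitting of touching somata: clumped cells merge, an acknowledged
limitation. Detection thresholds and size rules are this module's own
parameters, surfaced in the configuration.

## Voronoi analysis

Tessellation runs in 2D on maximum-intensity projections only. Seeds
are reflected across the four ROI edges and scipy's Voronoi diagram of
the augmented set is computed; each original seed's region is then
bounded and its intersection with the ROI tiles the ROI exactly, giving
area conservation to floating-point precision (asserted at 1e-6
relative). A cell is *complete* when its territory keeps a positive
distance from the ROI boundary — border cells are clipped for
conservation but excluded from area statistics. Duplicate seeds (e.g.
clumped detections at identical centroids) are merged with a warning,
since they would otherwise degenerate the tessellation. Nearest-neighbor
distances come from a k-d tree and agree exactly with the O(n²) brute
force.

## Statistics

All tests are two-sided; significance is declared at α = 0.05. The
two-sample t test uses the pooled-variance Student form (not Welch).
Tukey–Kramer uses q = |m_i − m_j| / √((MSW/2)(1/n_i + 1/n_j)), which
reduces to the classic Tukey statistic for equal sizes, with p-values
from scipy's studentized range distribution. The post hoc runs when the
ANOVA is significant and there are more than two groups (a convention,
stated as such). Statistic values are computed from the explicit
formulas in `glianet.stats`; scipy/statsmodels equivalents serve as
independent cross-checks in the test suite. Zero-variance degenerate
inputs return NaN ("undefined"), never a fabricated 0 or p.

## Reproducibility and problem sizes

Every stochastic operation takes a seed; cohorts spawn per-plaque
streams from the master seed via `numpy.random.SeedSequence`, so any
plaque can be regenerated in isolation and full runs are reproducible
file-for-file. The shipped verification uses cohorts of 100 plaques for
shell-recovery checks (sampling error of the mean midpoint ≪ half a
bin), 200 per class for the fibrillar/dense-core contrast, 2000 for
correlation calibration (sampling sd of r ≈ 0.015 at ρ ≈ 0.56), 10 000
null replicates for type-I-error calibration of ANOVA/t (binomial sd
≈ 0.002), and 100 random instances for each brute-force equivalence
suite — sizes at which the checked tolerances are comfortably resolved.

## Known limitations

- Single-marker, single-soma model: no morphology, no processes, so
  process-based definitions of reactivity cannot be emulated.
- Plaques are generated one per field; overlapping RGNs of plaque
  clusters are untested territory.
- The count model is linear with Gaussian noise; real recruitment may
  saturate at large volumes.
- Tukey–Kramer p-values assume the studentized range under equal
  variances; strong heteroscedasticity is not handled.
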