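# glianet

Quantification of **reactive glial nets (RGNs)** — the stereotyped 3D
structures that microglia and astrocytes assemble around amyloid plaques in
Alzheimer disease tissue — together with a seeded synthetic-data generator
that makes every stage of the pipeline testable without patient material.

## The problem and the measurement

In AD cortex, activated Iba1+ microglia form an inner capsule around a
dense-core amyloid plaque, concentrated ~20–30 μm from the plaque center,
and reactive GFAP+ astrocytes form an outer corona with somata ~30–50 μm
out, astrocyte reactivity being complete by ~80 μm. The package measures
this architecture from cell-centroid tables (or from 3D image stacks):

- **Radial profiling.** For each plaque, 3D Euclidean distances from every
  soma to the plaque center, histogrammed in half-open 10 μm bins
  [k·w, (k+1)·w).
- **Interval Max GFAP+.** The radial bin containing the maximum number of
  GFAP+ somata. Its outer edge defines the limit (boundary) of the RGN.
- **Intra-RGN microglia.** Iba1+ cells at distance ≤ the RGN boundary.
- **Recruitment correlations.** Pearson r of (count, plaque volume) across
  a cohort, for total Iba1+, Intra-RGN Iba1+, and GFAP+ counts — the
  signature that distinguishes dense-core plaques, fibrillar plaques
  (≈2× microglial recruitment) and PHF/NFT aggregates (no microglial
  recruitment, r ≈ 0).
- **Voronoi territories & nearest neighbors.** Delaunay–Voronoi
  tessellation of microglial somata in 2D maximum-intensity projections,
  complete-cell areas and nearest-neighbor distances — the
  aggregation-near-plaques / depletion-around-them signature.
- **Statistics.** Pearson r, one-way ANOVA on plaque factor, Tukey–Kramer
  post hoc comparisons, and Student t tests (pooled two-sample and
  one-sample), two-sided at α = 0.05.

The synthetic generator draws shell radii from truncated normal laws,
per-plaque counts linear in plaque volume with closed-form-calibrated
noise (so cohort count–volume correlations hit preset population values),
and homogeneous Poisson background glia. Presets encode the conditions
above: `human-dense-core`, `human-fibrillar`, `human-phf-nft`,
`mouse-mid` (astrocyte shell at 40 μm), `mouse-late` (60 μm).

## Worked example

```python
import numpy as np
import glianet as g
from glianet.metrics import profile_cohort

preset = g.make_preset("human-fibrillar")
cohort = g.generate_cohort(preset, n_plaques=200, seed=42)
profiles = profile_cohort(cohort.plaques, cohort.cells)
rec = g.recruitment_correlations(profiles)

mids = [0.5 * sum(p.interval_max_gfap_um) for p in profiles if p.rgn_defined]
print(f"plaques profiled: {rec.n_plaques}")
print(f"mean Interval-Max-GFAP+ midpoint: {np.mean(mids):.1f} um")
print(f"r(total Iba1+, volume)    = {rec.r_iba1_total:.3f}")
print(f"r(Intra-RGN Iba1+, volume) = {rec.r_iba1_intra_rgn:.3f}")
print(f"r(GFAP+, volume)          = {rec.r_gfap:.3f}")
```

prints

```
plaques profiled: 200
mean Interval-Max-GFAP+ midpoint: 40.5 um
r(total Iba1+, volume)    = 0.624
r(Intra-RGN Iba1+, volume) = 0.628
r(GFAP+, volume)          = 0.472
```

The astrocyte corona of this fibrillar cohort is centered near 40 μm (the
boundary bins straddle the 40 μm shell), and counts of both glial types
rise with plaque volume — microglia more steeply, as expected for
fibrillar plaques. On a `human-phf-nft` cohort the same call returns
`r(total Iba1+, volume) ≈ 0`, because microglia do not cluster around
PHF/NFT aggregates.

A command-line interface wraps the same library:

```sh
glianet simulate --preset mouse-mid --n-plaques 100 --seed 1 --outdir out
glianet profile out/mouse-mid --outdir out/profiled
glianet full --seed 1 --outdir out/full     # two-class cohorts + report
```

`glianet render` / `glianet detect` round-trip tables through synthetic
3-channel confocal stacks (TIFF) via thresholding, 26-connected
component labeling and binary centroids.

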