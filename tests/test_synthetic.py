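"""Generator behavior: presets, shell geometry, counts, landscapes, rendering."""

import math

import numpy as np
import pytest
from scipy import stats as st

from glianet import (
    LandscapeSpec,
    generate_cohort,
    generate_landscape,
    make_preset,
    render_stack,
    sample_glia,
    sample_plaque,
)
from glianet.synthetic import equivalent_radius, loguniform_moments


class TestPresets:
    def test_known_names_and_shell_geometry(self):
        mid = make_preset("mouse-mid")
        late = make_preset("mouse-late")
        dense = make_preset("human-dense-core")
        assert mid.astro_shell_mean_um == 40.0
        assert late.astro_shell_mean_um == 60.0
        assert dense.microglia_shell_mean_um == 25.0
        assert dense.astro_shell_mean_um == 40.0
        assert dense.astro_max_um == 80.0

    def test_fibrillar_doubles_microglial_recruitment(self):
        dense = make_preset("human-dense-core")
        fib = make_preset("human-fibrillar")
        assert fib.microglia_base_count == 2 * dense.microglia_base_count
        assert fib.microglia_slope_per_um3 == 2 * dense.microglia_slope_per_um3
        assert fib.microglia_population_r == 0.561
        # astrocytic geometry is shared between the two plaque classes
        assert fib.astro_shell_mean_um == dense.astro_shell_mean_um
        assert fib.astro_shell_sd_um == dense.astro_shell_sd_um

    def test_phf_nft_has_no_microglial_recruitment(self):
        phf = make_preset("human-phf-nft")
        assert phf.microglia_slope_per_um3 == 0.0
        assert phf.microglia_population_r == 0.0

    def test_unknown_name_names_valid_presets(self):
        with pytest.raises(ValueError, match="mouse-mid"):
            make_preset("human-diffuse")

    def test_shell_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="shell ordering"):
            make_preset("human-dense-core", astro_shell_mean_um=20.0)

    @pytest.mark.parametrize("name", ["human-dense-core", "human-fibrillar",
                                      "human-phf-nft", "mouse-mid",
                                      "mouse-late"])
    def test_all_presets_order_shells_inward_microglia(self, name):
        p = make_preset(name)
        assert (p.astro_max_um >= p.astro_shell_mean_um
                >= p.microglia_shell_mean_um > 0)


class TestSamplePlaque:
    @pytest.mark.parametrize("volume, radius", [
        (4.18879e3, 10.0),     # V = 4π/3 · 10³
        (33510.3, 20.0),       # sphere formula
    ])
    def test_equivalent_radius(self, volume, radius):
        p = sample_plaque(make_preset("human-dense-core"), volume)
        assert p.equivalent_radius_um == pytest.approx(radius, rel=1e-4)
        assert equivalent_radius(volume) == pytest.approx(radius, rel=1e-4)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            sample_plaque(make_preset("human-dense-core"), 0.0)

    def test_centered_in_field(self):
        preset = make_preset("mouse-mid")
        p = sample_plaque(preset, 1000.0)
        assert p.center_um == tuple(s / 2 for s in preset.field_um)


class TestSampleGlia:
    def test_deterministic_counts_without_noise(self):
        preset = make_preset("human-dense-core",
                             microglia_base_count=10.0, gfap_base_count=8.0,
                             microglia_slope_per_um3=0.0,
                             gfap_slope_per_um3=0.0,
                             microglia_population_r=0.0,
                             gfap_population_r=0.0,
                             background_iba1_per_mm3=0.0,
                             background_gfap_per_mm3=0.0)
        plaque = sample_plaque(preset, 2000.0)
        cells = sample_glia(plaque, preset, seed=5,
                            count_noise_sd={"iba1": 0.0, "gfap": 0.0})
        shell = [c for c in cells if c.origin == "shell"]
        assert sum(c.marker == "iba1" for c in shell) == 10
        assert sum(c.marker == "gfap" for c in shell) == 8
        assert len(cells) == 18  # no background

    def test_same_seed_is_reproducible(self):
        preset = make_preset("mouse-mid")
        plaque = sample_plaque(preset, 5000.0)
        a = sample_glia(plaque, preset, seed=9)
        b = sample_glia(plaque, preset, seed=9)
        assert [c.position_um for c in a] == [c.position_um for c in b]
        assert [c.marker for c in a] == [c.marker for c in b]

    def test_pooled_microglia_shell_distance_matches_truncated_normal(self):
        # oracle: direct Monte-Carlo of the truncated normal mean
        preset = make_preset("human-dense-core",
                             background_iba1_per_mm3=0.0,
                             background_gfap_per_mm3=0.0)
        mean, sd, hi = preset.shell_params("iba1")
        a = (preset.core_radius_um - mean) / sd
        b = (hi - mean) / sd
        oracle = st.truncnorm.mean(a, b, loc=mean, scale=sd)
        plaque = sample_plaque(preset, 2000.0)
        rng = np.random.default_rng(31)
        dists = []
        for _ in range(400):  # ~8000 pooled shell microglia
            cells = sample_glia(plaque, preset, rng,
                                count_noise_sd={"iba1": 0.0, "gfap": 0.0})
            pos = np.array([c.position_um for c in cells
                            if c.marker == "iba1" and c.origin == "shell"])
            dists.append(np.linalg.norm(pos - plaque.center_um, axis=1))
        pooled = np.concatenate(dists)
        assert pooled.mean() == pytest.approx(oracle, abs=0.5)
        assert abs(oracle - 25.0) < 0.1  # truncation barely shifts the mean

    def test_astrocyte_distances_truncated_at_astro_max(self,
                                                        dense_core_cohort):
        coh = dense_core_cohort
        centers = {p.plaque_id: np.array(p.center_um) for p in coh.plaques}
        hi = coh.preset.astro_max_um
        lo = coh.preset.core_radius_um
        for c in coh.cells:
            if c.origin != "shell":
                continue
            d = np.linalg.norm(np.array(c.position_um)
                               - centers[c.plaque_id])
            assert d <= (hi + 1e-9 if c.marker == "gfap" else np.inf)
            assert d >= lo - 1e-9

    def test_mismatched_plaque_class_rejected(self):
        fib = make_preset("human-fibrillar")
        plaque = sample_plaque(make_preset("mouse-mid"), 1000.0)
        with pytest.raises(ValueError, match="plaque_class"):
            sample_glia(plaque, fib)


class TestGenerateCohort:
    def test_cohort_size_matches_request(self):
        coh = generate_cohort(make_preset("human-dense-core"), 39, seed=1)
        assert len(coh.plaques) == 39

    def test_single_plaque_cohort_runs(self):
        coh = generate_cohort(make_preset("mouse-mid"), 1, seed=1)
        assert len(coh.plaques) == 1
        assert any(c.origin == "shell" for c in coh.cells)

    def test_identical_seed_identical_cohort(self):
        p = make_preset("mouse-late")
        a = generate_cohort(p, 5, seed=77)
        b = generate_cohort(p, 5, seed=77)
        assert [pl.volume_um3 for pl in a.plaques] \
            == [pl.volume_um3 for pl in b.plaques]
        assert [c.position_um for c in a.cells] \
            == [c.position_um for c in b.cells]
        assert a.ground_truth == b.ground_truth

    def test_empty_volume_range_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(make_preset("mouse-mid"), 3,
                            volume_range_um3=(100.0, 100.0), seed=0)

    def test_shell_ordering_across_cohort(self, dense_core_cohort):
        # mean astrocyte shell distance exceeds mean microglial shell
        # distance: inner microglial sphere, outer astrocyte sphere
        coh = dense_core_cohort
        centers = {p.plaque_id: np.array(p.center_um) for p in coh.plaques}
        d = {"iba1": [], "gfap": []}
        for c in coh.cells:
            if c.origin == "shell":
                d[c.marker].append(np.linalg.norm(
                    np.array(c.position_um) - centers[c.plaque_id]))
        assert np.mean(d["gfap"]) > np.mean(d["iba1"])

    def test_loguniform_moments_closed_form(self):
        # oracle: Monte-Carlo moments of exp(U), U ~ Uniform(ln a, ln b)
        rng = np.random.default_rng(5)
        v = np.exp(rng.uniform(math.log(500.0), math.log(5e4), 200_000))
        mean, var = loguniform_moments(500.0, 5e4)
        assert mean == pytest.approx(v.mean(), rel=0.01)
        assert var == pytest.approx(v.var(), rel=0.05)


class TestLandscape:
    def test_homogeneous_points_inside_roi(self):
        spec = LandscapeSpec(mode="homogeneous", n_microglia=100)
        land = generate_landscape(spec, seed=4)
        assert land.points_um.shape == (100, 2)
        assert (land.points_um >= 0).all()
        assert (land.points_um <= spec.roi_um).all()

    def test_zero_aggregation_fraction_is_null_perturbation(self):
        base = LandscapeSpec(mode="homogeneous", n_microglia=200)
        pert = LandscapeSpec(mode="plaque_perturbed", n_microglia=200,
                             plaque_centers=((500.0, 500.0),),
                             aggregation_fraction=0.0)
        a = generate_landscape(base, seed=11).points_um
        b = generate_landscape(pert, seed=11).points_um
        np.testing.assert_array_equal(a, b)

    def test_aggregation_raises_disc_density_above_annulus(self):
        spec = LandscapeSpec(mode="plaque_perturbed", n_microglia=1500,
                             plaque_centers=((300.0, 300.0), (700.0, 650.0)),
                             aggregation_fraction=0.3)
        land = generate_landscape(spec, seed=13)
        centers = np.asarray(spec.plaque_centers)
        d = np.linalg.norm(land.points_um[:, None] - centers[None],
                           axis=2).min(axis=1)
        r, r_out = spec.aggregation_radius_um, spec.depletion_outer_um
        disc_density = (d <= r).sum() / (len(centers) * math.pi * r ** 2)
        ann_density = (((d > r) & (d <= r_out)).sum()
                       / (len(centers) * math.pi * (r_out ** 2 - r ** 2)))
        assert disc_density > ann_density

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            LandscapeSpec(mode="homogeneous", n_microglia=2)


class TestRenderStack:
    def test_single_cell_peak_at_center_voxel(self):
        from glianet.synthetic import CellRecord
        cell = CellRecord("c0", "iba1", (25.0, 25.0, 25.0), "shell")
        stack = render_stack([cell], field_um=(50, 50, 50),
                             voxel_size_um=(1.0, 1.0, 1.0),
                             blob_sigma_um=2.0)
        ch = stack.channel("iba1")
        z, y, x = np.unravel_index(np.argmax(ch), ch.shape)
        assert (z, y, x) == (25, 25, 25) or ch[25, 25, 25] == ch[z, y, x]

    def test_empty_input_gives_zero_channels(self):
        stack = render_stack([], field_um=(20, 20, 10),
                             voxel_size_um=(1.0, 1.0, 1.0),
                             blob_sigma_um=2.0)
        assert not stack.data.any()

    def test_rendered_sphere_volume_matches_analytic(self):
        # voxelized-sphere oracle: suprathreshold count ≈ 4/3 π 10³ voxels
        preset = make_preset("human-dense-core", field_um=(50.0, 50.0, 50.0))
        plaque = sample_plaque(preset, 4.18879e3)
        stack = render_stack([], [plaque], field_um=preset.field_um,
                             voxel_size_um=(1.0, 1.0, 1.0),
                             blob_sigma_um=2.0)
        count = int((stack.channel("plaque") > 0.5).sum())
        assert count == pytest.approx(4189, rel=0.10)

    def test_fine_blob_warns(self):
        with pytest.warns(UserWarning, match="sigma"):
            render_stack([], field_um=(10, 10, 10),
                         voxel_size_um=(1.0, 1.0, 2.0), blob_sigma_um=0.5)
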