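"""Generator contracts: geometry honesty, planted truth, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from jawstrain import morphometrics, synthgen
from jawstrain.afm import dmt_force
from jawstrain.errors import ConvergenceError, SizingError, ValidationError
from jawstrain.volume import BACKGROUND, EXOSTOSIS, MC_LEFT, MC_RIGHT, PQ_LEFT, PQ_RIGHT


class TestShapeParams:
    def test_presets_encode_mutant_phenotype_directions(self):
        wt = synthgen.shape_preset("wt")
        mut = synthgen.shape_preset("mutant")
        assert mut.neck_width > wt.neck_width
        assert mut.head_width > wt.head_width
        assert mut.joint_space < wt.joint_space

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"joint_space": -1.0},
            {"element_length": 0.0},
            {"neck_width": 12.0, "head_width": 10.0},
            {"voxel_size": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            synthgen.ShapeParams(**kwargs)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            synthgen.shape_preset("heterozygote")


class TestBuildParametricJaw:
    @pytest.mark.parametrize("preset", ["wt", "mutant"])
    def test_shape_parameters_recoverable_within_half_voxel(self, preset):
        """Geometry honesty: measured dims match requested within h/2."""
        p = synthgen.shape_preset(preset)
        vol = synthgen.build_parametric_jaw(p)
        m = morphometrics.measure_joint(vol)
        tol = 0.5 * p.voxel_size
        assert abs(m.neck_width - p.neck_width) <= tol
        assert abs(m.head_width - p.head_width) <= tol
        assert abs(m.joint_space - p.joint_space) <= tol

    def test_zero_joint_space_fuses_elements(self):
        """Gap closure: each MC fuses with its PQ into one 26-component."""
        p = synthgen.ShapeParams(joint_space=0.0)
        vol = synthgen.build_parametric_jaw(p)
        mcpq = vol.mask(MC_LEFT, PQ_LEFT)
        _, n = ndimage.label(mcpq, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_nonzero_joint_space_separates_elements(self, wt_volume):
        mcpq = wt_volume.mask(MC_LEFT, PQ_LEFT)
        _, n = ndimage.label(mcpq, structure=np.ones((3, 3, 3)))
        assert n == 2  # MC and PQ are disjoint across the open joint

    def test_too_small_domain_names_dimension(self):
        p = synthgen.shape_preset("wt")
        with pytest.raises(SizingError, match="along x"):
            synthgen.build_parametric_jaw(p, domain_shape=(10, 70, 16))

    def test_geometry_jitter_is_deterministic(self):
        p = synthgen.shape_preset("wt")
        a = synthgen.build_parametric_jaw(p, seed=11)
        b = synthgen.build_parametric_jaw(p, seed=11)
        c = synthgen.build_parametric_jaw(p, seed=12)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)

    def test_jitter_preserves_measured_dimensions(self):
        p = synthgen.shape_preset("wt")
        for seed in range(3):
            vol = synthgen.build_parametric_jaw(p, seed=seed)
            m = morphometrics.measure_joint(vol)
            assert abs(m.joint_space - p.joint_space) <= 0.5
            assert abs(m.neck_width - p.neck_width) <= 0.5


class TestRenderStack:
    def test_zero_noise_gives_exactly_two_grey_values(self, wt_volume):
        stack = synthgen.render_stack(wt_volume, synthgen.NoiseModel(sd=0.0))
        assert np.unique(stack.intensities).size == 2

    def test_same_seed_bit_identical(self, wt_volume):
        n = synthgen.NoiseModel(sd=10.0, seed=3)
        a = synthgen.render_stack(wt_volume, n)
        b = synthgen.render_stack(wt_volume, n)
        assert np.array_equal(a.intensities, b.intensities)

    def test_histogram_bimodal_at_generator_means(self):
        """Histogram modes sit within +/-3 grey levels of the set means."""
        vol = synthgen.build_parametric_jaw(
            synthgen.ShapeParams(element_length=24.0, ceratohyal_length=28.0)
        )
        for seed in range(100):
            noise = synthgen.NoiseModel(
                background_mean=30, foreground_mean=200, sd=10, seed=seed
            )
            img = synthgen.render_stack(vol, noise).intensities
            hist, edges = np.histogram(img, bins=256, range=(0, 256))
            # 5-bin moving average stabilizes the empirical mode location
            hist = np.convolve(hist, np.ones(5) / 5, mode="same")
            centers = 0.5 * (edges[:-1] + edges[1:])
            lo = centers[np.argmax(np.where(centers < 115, hist, 0))]
            hi = centers[np.argmax(np.where(centers >= 115, hist, 0))]
            assert abs(lo - 30) <= 3
            assert abs(hi - 200) <= 3

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            synthgen.NoiseModel(sd=-1.0)


class TestPlantExostoses:
    def test_zero_blobs_leaves_volume_unchanged(self, wt_volume):
        out = synthgen.plant_exostoses(wt_volume, 0, seed=1)
        assert np.array_equal(out.labels, wt_volume.labels)

    @pytest.mark.parametrize("k", [1, 4])
    def test_planted_count_recovered(self, wt_volume, k):
        out = synthgen.plant_exostoses(wt_volume, k, blob_radius=2.0, seed=5)
        assert morphometrics.count_protrusions(out) == k

    def test_blob_touching_main_element_not_counted(self, wt_volume):
        """A blob merged with the main body is part of it, not a protrusion."""
        out = wt_volume.copy()
        # stamp a blob directly adjacent to an MC voxel
        idx = np.argwhere(out.labels == MC_LEFT)[0]
        sl = tuple(slice(i, i + 3) for i in idx)
        patch = out.labels[sl]
        patch[patch == BACKGROUND] = EXOSTOSIS
        assert morphometrics.count_protrusions(out) == 0

    def test_planting_is_deterministic(self, wt_volume):
        a = synthgen.plant_exostoses(wt_volume, 3, seed=9)
        b = synthgen.plant_exostoses(wt_volume, 3, seed=9)
        assert np.array_equal(a.labels, b.labels)


class TestSynthCellOutline:
    def test_near_circular_target(self):
        poly = synthgen.synth_cell_outline(1.0, n_vertices=256)
        assert poly.circularity >= 0.98

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.8])
    def test_target_circularity_hit_within_tolerance(self, target):
        poly = synthgen.synth_cell_outline(target, n_vertices=128, seed=2)
        assert poly.is_simple
        assert abs(poly.circularity - target) <= 0.02

    def test_degenerate_vertex_count_rejected(self):
        with pytest.raises(ValidationError):
            synthgen.synth_cell_outline(0.5, n_vertices=2)

    def test_unreachable_target_raises(self):
        # a triangle tops out at circularity ~0.6
        with pytest.raises(ConvergenceError):
            synthgen.synth_cell_outline(0.99, n_vertices=3)


class TestSynthForceCurve:
    def test_zero_indentation_force_is_minus_adhesion(self):
        c = synthgen.synth_force_curve(E=2.5, F_adh=0.7, noise_sd=0.0)
        assert c.force[0] == pytest.approx(-0.7, abs=1e-12)

    def test_noiseless_curve_matches_closed_form(self):
        E, nu, R, F_adh = 2.5, 0.3, 5.0, 0.5
        c = synthgen.synth_force_curve(E=E, nu=nu, R=R, F_adh=F_adh, noise_sd=0.0)
        expected = dmt_force(c.delta, E / (1 - nu**2), R, F_adh)
        np.testing.assert_allclose(c.force, expected, rtol=0, atol=0)

    def test_doubling_modulus_doubles_adhesion_corrected_force(self):
        kw = dict(nu=0.3, R=5.0, F_adh=0.5, noise_sd=0.0)
        c1 = synthgen.synth_force_curve(E=2.5, **kw)
        c2 = synthgen.synth_force_curve(E=5.0, **kw)
        np.testing.assert_allclose(c2.force + 0.5, 2 * (c1.force + 0.5), atol=1e-12)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValidationError):
            synthgen.synth_force_curve(E=1.0, nu=0.6)
        with pytest.raises(ValidationError):
            synthgen.synth_force_curve(E=1.0, R=-5.0)
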