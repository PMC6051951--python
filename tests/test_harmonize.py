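import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petharm import (
    ActivityVolume,
    Grid,
    HarmonizationTarget,
    LesionSpec,
    ScannerModel,
    build_ground_truth,
    gaussian_smooth,
    harmonize_volume,
    matched_filter_fwhm,
    pgc_correct,
    resample_to_grid,
    simulate_scan,
)


class TestMatchedFilter:
    @pytest.mark.parametrize(
        "current,target,expected",
        [
            (7.0, 7.0, 0.0),
            (0.0, 7.0, 7.0),
            (6.3, 7.0, np.sqrt(49.0 - 39.69)),
            (6.6, 7.0, np.sqrt(49.0 - 43.56)),
        ],
    )
    def test_quadrature_closed_form(self, current, target, expected):
        assert matched_filter_fwhm(current, target) == pytest.approx(expected)

    def test_cannot_sharpen_by_smoothing(self):
        with pytest.raises(ValueError, match="sharpen"):
            matched_filter_fwhm(7.0, 6.3)

    @given(
        current=st.floats(0.0, 10.0),
        extra=st.floats(0.01, 10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_quadrature_inverts_composition(self, current, extra):
        target = np.sqrt(current**2 + extra**2)
        assert matched_filter_fwhm(current, target) == pytest.approx(extra, abs=1e-9)


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self, random_volume):
        out = gaussian_smooth(random_volume, 0.0)
        np.testing.assert_array_equal(out.values, random_volume.values)

    def test_uniform_volume_unchanged_in_interior(self):
        g = Grid((40, 40, 40), (1.0, 1.0, 1.0))
        vol = ActivityVolume(g, np.full(g.shape, 7.3))
        out = gaussian_smooth(vol, 5.0)
        np.testing.assert_allclose(out.values[14:-14, 14:-14, 14:-14], 7.3, atol=1e-6)

    def test_negative_fwhm_rejected(self, random_volume):
        with pytest.raises(ValueError):
            gaussian_smooth(random_volume, -1.0)

    def test_semigroup_two_stage_equals_single_quadrature_fwhm(self):
        # point source: the hardest field for kernel-composition errors
        g = Grid((61, 61, 61), (1.0, 1.0, 1.0))
        vals = np.zeros(g.shape)
        vals[30, 30, 30] = 1000.0
        vol = ActivityVolume(g, vals)
        f1, f2 = 4.0, 5.0
        two_stage = gaussian_smooth(gaussian_smooth(vol, f1), f2)
        single = gaussian_smooth(vol, np.sqrt(f1**2 + f2**2))
        peak = single.values.max()
        assert np.abs(two_stage.values - single.values).max() < 1e-4 * peak

    def test_anisotropic_spacing_uses_physical_mm(self):
        # same physical field sampled on two grids must smooth identically
        g_fine = Grid((40, 40, 80), (1.0, 1.0, 0.5))
        g_iso = Grid((40, 40, 40), (1.0, 1.0, 1.0))
        x = np.arange(40)
        bump = np.exp(-((x - 20) ** 2) / 30.0)
        field_iso = bump[:, None, None] * np.ones((40, 40, 40))
        field_fine = bump[:, None, None] * np.ones((40, 40, 80))
        out_iso = gaussian_smooth(ActivityVolume(g_iso, field_iso), 6.0)
        out_fine = gaussian_smooth(ActivityVolume(g_fine, field_fine), 6.0)
        np.testing.assert_allclose(
            out_fine.values[:, 20, 40], out_iso.values[:, 20, 20], atol=1e-9
        )


class TestResample:
    def test_same_grid_is_identity(self, random_volume):
        out = resample_to_grid(random_volume, random_volume.grid)
        np.testing.assert_allclose(out.values, random_volume.values, atol=1e-12)

    def test_reproduces_linear_ramp_exactly(self):
        src = Grid((20, 20, 20), (1.0, 1.0, 1.0))
        xs, ys, zs = np.meshgrid(*src.axis_coordinates(), indexing="ij")
        vol = ActivityVolume(src, 2.0 + 0.5 * xs + 0.25 * ys - 0.1 * zs)
        tgt = Grid((8, 8, 8), (2.1, 2.1, 2.3), (0.3, 0.4, 0.5))
        out = resample_to_grid(vol, tgt)
        tx, ty, tz = np.meshgrid(*tgt.axis_coordinates(), indexing="ij")
        np.testing.assert_allclose(out.values, 2.0 + 0.5 * tx + 0.25 * ty - 0.1 * tz, atol=1e-9)

    def test_matches_hand_rolled_trilinear_oracle(self, random_volume):
        # one off-lattice query point, 8-corner weighted sum by hand
        q = np.array([3.3, 4.7, 2.2])  # world == index for the unit grid
        tgt = Grid((1, 1, 1), (1.0, 1.0, 1.0), tuple(q))
        out = resample_to_grid(random_volume, tgt)
        i0, j0, k0 = int(q[0]), int(q[1]), int(q[2])
        fx, fy, fz = q - np.array([i0, j0, k0])
        v = random_volume.values
        expected = 0.0
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    expected += wx * wy * wz * v[i0 + di, j0 + dj, k0 + dk]
        assert out.values[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_target_grid_rejected(self, random_volume):
        with pytest.raises(ValueError):
            resample_to_grid(random_volume, Grid((4, 4, 0), (1, 1, 1)))


class TestPgcCorrect:
    @pytest.mark.parametrize("value,factor,expected", [(8.0, 0.8, 10.0), (9.0, 0.9, 10.0), (5.0, 1.0, 5.0)])
    def test_divides_imaged_ac_by_recovery_factor(self, value, factor, expected):
        assert pgc_correct(value, factor) == pytest.approx(expected)

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.2])
    def test_factor_outside_unit_interval_rejected(self, factor):
        with pytest.raises(ValueError):
            pgc_correct(1.0, factor)

    def test_volume_input_scales_all_voxels(self, random_volume):
        out = pgc_correct(random_volume, 0.8)
        np.testing.assert_allclose(out.values, random_volume.values / 0.8)


class TestHarmonizeVolume:
    def test_identity_when_already_at_target(self, random_volume):
        scanner = ScannerModel("s", random_volume.grid.spacing, 7.0, 1.0, 0.0)
        target = HarmonizationTarget(7.0, random_volume.grid.spacing)
        out = harmonize_volume(random_volume, scanner, target, common_grid=random_volume.grid)
        np.testing.assert_allclose(out.values, random_volume.values, atol=1e-12)

    def test_two_scanners_uniform_truth_both_recover_10(self):
        g = Grid((80, 80, 80), (1.0, 1.0, 1.0))
        truth = ActivityVolume(g, np.full(g.shape, 10.0))
        target = HarmonizationTarget(7.0, (2.1, 2.1, 2.4))
        for fwhm, pgc, spacing in ((6.6, 0.8, (1.73, 1.73, 2.43)), (6.3, 0.9, (2.09, 2.09, 2.03))):
            scanner = ScannerModel("s", spacing, fwhm, pgc, 0.0)
            obs = simulate_scan(truth, scanner, 0)
            harm = harmonize_volume(obs, scanner, target)
            c = tuple(s // 2 for s in harm.grid.shape)
            interior = harm.values[c[0] - 3 : c[0] + 4, c[1] - 3 : c[1] + 4, c[2] - 3 : c[2] + 4]
            np.testing.assert_allclose(interior, 10.0, atol=1e-6)

    def test_pgc_scaling_commutes_with_smoothing_and_resampling(self, random_volume):
        scanner = ScannerModel("s", random_volume.grid.spacing, 5.0, 0.8, 0.0)
        target = HarmonizationTarget(7.0, (1.5, 1.5, 1.5))
        after = harmonize_volume(random_volume, scanner, target)
        pre_scaled = pgc_correct(random_volume, scanner.pgc_factor)
        before = harmonize_volume(pre_scaled, scanner, target, apply_pgc=False)
        assert np.abs(after.values - before.values).max() < 1e-9

    def test_linear_in_input_values(self, random_volume):
        scanner = ScannerModel("s", random_volume.grid.spacing, 6.0, 0.9, 0.0)
        target = HarmonizationTarget(7.0, (1.5, 1.5, 1.5))
        a = harmonize_volume(random_volume, scanner, target)
        doubled = ActivityVolume(random_volume.grid, 2.0 * random_volume.values)
        b = harmonize_volume(doubled, scanner, target)
        np.testing.assert_allclose(b.values, 2.0 * a.values, rtol=1e-12)

    def test_quadrature_equivalence_of_native_resolutions(self):
        # a lesion imaged at 6.3 mm then matched to 7.0 mm must agree with the
        # same lesion imaged directly at 7.0 mm by an otherwise identical scanner
        g = Grid((80, 80, 80), (1.0, 1.0, 1.0))
        les = LesionSpec("L", (40.0, 40.0, 40.0), 12.0, 100.0, 1.0)
        truth = build_ground_truth([les], 0.0, g)
        target = HarmonizationTarget(7.0, (2.1, 2.1, 2.4))
        spacing = (2.0, 2.0, 2.0)
        sharp = simulate_scan(truth, ScannerModel("a", spacing, 6.3, 1.0, 0.0), 0)
        at_target = simulate_scan(truth, ScannerModel("b", spacing, 7.0, 1.0, 0.0), 0)
        harm_sharp = harmonize_volume(sharp, ScannerModel("a", spacing, 6.3, 1.0, 0.0), target)
        harm_direct = harmonize_volume(at_target, ScannerModel("b", spacing, 7.0, 1.0, 0.0), target)
        assert np.abs(harm_sharp.values - harm_direct.values).max() < 0.01 * les.ac
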