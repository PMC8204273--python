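import numpy as np
import pytest

import msirepi as m


class TestFitBaMap:
    def test_exact_recovery_from_affine_model(self, brain_phantom):
        fas = [0.0, 30.0, 40.0, 50.0, 60.0, 70.0]
        r1_int = np.where(brain_phantom.support, 1000.0 / np.where(
            brain_phantom.support, brain_phantom.t1_ms, 1.0), np.nan)
        maps = [m.apparent_r1(r1_int, 0.0045, fa, brain_phantom.b1_scale) for fa in fas]
        fit = m.fit_ba_map(maps, fas, brain_phantom.b1_scale)
        ok = fit.valid & brain_phantom.support
        assert ok.sum() > 100
        np.testing.assert_allclose(fit.ba_per_deg[ok], 0.0045, atol=1e-10)
        np.testing.assert_allclose(fit.fit_r2[ok], 1.0, atol=1e-9)

    def test_two_fa_subset_matches_full_set_noiseless(self, fa_sweep_r1_maps):
        fas, maps, ok = fa_sweep_r1_maps
        full = m.fit_ba_map(maps, fas)
        idx = [fas.index(40.0), fas.index(70.0)]
        two = m.fit_ba_map([maps[i] for i in idx], [40.0, 70.0])
        both = ok & full.valid & two.valid
        np.testing.assert_allclose(
            two.ba_per_deg[both], full.ba_per_deg[both], rtol=1e-6
        )

    def test_halved_b1_doubles_slope_and_ba(self):
        shape = (6, 6, 2)
        r1_int = np.full(shape, 0.7)
        fas = [0.0, 35.0, 70.0]
        x = np.full(shape, 1.0)
        maps = [m.apparent_r1(r1_int, 0.004, fa, x) for fa in fas]
        fit_full = m.fit_ba_map(maps, fas, x)
        fit_half = m.fit_ba_map(maps, fas, 0.5 * x)
        np.testing.assert_allclose(
            fit_half.beta_per_s_deg, 2 * fit_full.beta_per_s_deg, rtol=1e-9
        )
        np.testing.assert_allclose(
            fit_half.ba_per_deg, 2 * fit_full.ba_per_deg, rtol=1e-9
        )
        np.testing.assert_allclose(fit_half.alpha_per_s, fit_full.alpha_per_s, rtol=1e-9)

    def test_single_fa_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            m.fit_ba_map([np.ones((2, 2, 2))], [70.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.fit_ba_map([np.ones((2, 2, 2)), np.ones((3, 2, 2))], [0.0, 70.0])


class TestSmoothBaMap:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        ba = rng.normal(0.0045, 0.0005, (8, 8, 4))
        out = m.smooth_ba_map(ba, 0.0, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out, ba)

    def test_constant_map_unchanged(self):
        ba = np.full((10, 10, 6), 0.0045)
        out = m.smooth_ba_map(ba, 2.0, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out, 0.0045, rtol=1e-12)

    def test_impulse_mass_preserved(self):
        ba = np.zeros((21, 21, 21))
        ba[10, 10, 10] = 1.0
        out = m.smooth_ba_map(ba, 2.0, (1.0, 1.0, 1.0))
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_mask_normalisation_avoids_edge_shrinkage(self):
        ba = np.full((12, 12, 4), 0.0045)
        ba[6:, :, :] = np.nan  # invalid half
        out = m.smooth_ba_map(ba, 3.0, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out[:6], 0.0045, rtol=1e-9)


class TestGlobalBa:
    def test_unimodal_gaussian(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.0045, 0.0002, 100_000)
        est, mix = m.global_ba(vals)
        assert est == pytest.approx(0.0045, abs=1e-4)

    def test_bimodal_returns_dominant_component(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([
            rng.normal(0.0045, 0.0003, 70_000),
            rng.normal(0.002, 0.0003, 30_000),
        ])
        est, mix = m.global_ba(vals)
        assert est == pytest.approx(0.0045, abs=2e-4)
        assert len(mix["means"]) == 2

    def test_identical_values_exact_fallback(self):
        vals = np.full(500, 0.004)
        est, mix = m.global_ba(vals)
        assert est == 0.004
        assert "fallback" in mix

    def test_empty_and_small_masks_rejected(self):
        with pytest.raises(ValueError):
            m.global_ba(np.array([]))
        with pytest.raises(ValueError):
            m.global_ba(np.full(50, 0.004))


class TestCorrectR1:
    def test_exact_inverse_of_apparent_r1(self):
        r1_corr, valid = m.correct_r1_map(0.81, 0.005, 70.0)
        assert valid
        assert float(r1_corr) == pytest.approx(0.6)

    def test_zero_fa_identity(self):
        r1 = np.random.default_rng(0).uniform(0.3, 1.2, (4, 4, 2))
        out, valid = m.correct_r1_map(r1, 0.0045, 0.0)
        np.testing.assert_allclose(out, r1)
        assert valid.all()

    def test_correction_inverts_loading_for_random_draws(self):
        # Eq-style inverse: correct(apparent(r1)) == r1 for any positive inputs
        rng = np.random.default_rng(5)
        r1 = rng.uniform(0.2, 2.0, 500)
        ba = rng.uniform(0.0, 0.01, 500)
        fa = 70.0
        x = rng.uniform(0.6, 1.4, 500)
        loaded = m.apparent_r1(r1, ba, fa, x)
        out, valid = m.correct_r1_map(loaded, ba, fa, x)
        assert valid.all()
        np.testing.assert_allclose(out, r1, rtol=1e-12)

    def test_nonpositive_denominator_flagged(self):
        out, valid = m.correct_r1_map(np.array([0.8]), -0.1, 70.0, np.array([1.0]))
        assert not valid[0]
        assert np.isnan(out[0])


class TestHalfRate:
    def test_closed_form_example(self):
        ba, r1_0, valid = m.ba_from_half_rate(
            np.array([0.81]), np.array([0.705]), 70.0, np.array([1.0])
        )
        assert valid[0]
        assert ba[0] == pytest.approx(0.005)
        assert r1_0[0] == pytest.approx(0.6)

    def test_no_mt_gives_zero_ba(self):
        ba, r1_0, valid = m.ba_from_half_rate(
            np.array([0.7]), np.array([0.7]), 90.0
        )
        assert ba[0] == pytest.approx(0.0)
        assert r1_0[0] == pytest.approx(0.7)

    def test_halved_b1_doubles_ba(self):
        rf, rh = np.array([0.81]), np.array([0.705])
        ba1, _, _ = m.ba_from_half_rate(rf, rh, 70.0, np.array([1.0]))
        ba2, _, _ = m.ba_from_half_rate(rf, rh, 70.0, np.array([0.5]))
        assert ba2[0] == pytest.approx(2 * ba1[0])

    def test_monotonicity_violation_flagged(self):
        ba, r1_0, valid = m.ba_from_half_rate(
            np.array([0.7]), np.array([0.8]), 90.0
        )
        assert not valid[0]
        assert np.isnan(ba[0])

    def test_exact_recovery_on_simulated_pair(self, brain_phantom):
        sup = brain_phantom.support
        r1_int = 1000.0 / brain_phantom.t1_ms[sup]
        x = brain_phantom.b1_scale[sup]
        rf = m.apparent_r1(r1_int, 0.0045, 90.0, x, 1.0)
        rh = m.apparent_r1(r1_int, 0.0045, 90.0, x, 0.5)
        ba, r1_0, valid = m.ba_from_half_rate(rf, rh, 90.0, x)
        assert valid.all()
        np.testing.assert_allclose(ba, 0.0045, rtol=1e-9)
        np.testing.assert_allclose(r1_0, r1_int, rtol=1e-9)


class TestEndToEnd:
    def test_corrected_histograms_collapse_across_fa(
        self, brain_phantom, fa_sweep_r1_maps
    ):
        # corrected R1 distributions coincide with the no-FS distribution
        # when the transmit field enters both the regression and Eq-2
        fas, maps, ok = fa_sweep_r1_maps
        x = brain_phantom.b1_scale
        fit = m.fit_ba_map(maps, fas, x)
        gba, _ = m.global_ba(fit.ba_per_deg, ok & fit.valid)
        reference = maps[0][ok]
        for fa, r1_map in zip(fas[1:], maps[1:]):
            corr, _ = m.correct_r1_map(r1_map, gba, fa, x)
            np.testing.assert_allclose(corr[ok], reference, rtol=1e-4)

    def test_global_correction_less_variance_than_voxelwise_under_noise(
        self, brain_phantom
    ):
        # noise in the voxel-wise ba map propagates into the corrected map
        rng = np.random.default_rng(8)
        sup = brain_phantom.support
        r1_int = 1000.0 / np.where(sup, brain_phantom.t1_ms, 1000.0)
        fas = [0.0, 30.0, 40.0, 50.0, 60.0, 70.0]
        noisy = [
            m.apparent_r1(r1_int, 0.0045, fa, brain_phantom.b1_scale)
            + rng.normal(0, 0.01, r1_int.shape)
            for fa in fas
        ]
        fit = m.fit_ba_map(noisy, fas, brain_phantom.b1_scale)
        ok = fit.valid & sup
        gba, _ = m.global_ba(fit.ba_per_deg, ok)
        vox, _ = m.correct_r1_map(noisy[-1], fit.ba_per_deg, 70.0, brain_phantom.b1_scale)
        glob, _ = m.correct_r1_map(noisy[-1], gba, 70.0, brain_phantom.b1_scale)
        gm = brain_phantom.labels == 1
        assert np.nanstd(glob[gm & ok]) < np.nanstd(vox[gm & ok])

    def test_apparent_r1_vs_fa_regression_is_linear(self, fa_sweep_r1_maps):
        fas, maps, ok = fa_sweep_r1_maps
        fit = m.fit_ba_map(maps, fas)
        assert np.nanmin(fit.fit_r2[ok & fit.valid]) > 1 - 1e-6
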