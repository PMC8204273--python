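import numpy as np
import pytest
from scipy.optimize import curve_fit

import msirepi as m
from msirepi.fitting import restore_polarity_curves


def ms1_tis(n=8, tr=5000.0):
    return 44.5 + (tr / n) * np.arange(n)


class TestRestorePolarity:
    def test_antiphase_is_negative_in_phase_positive(self):
        tis = ms1_tis(4)
        sched = m.TISchedule(ti_ms=tis[None, :], slot_duration_ms=1250.0,
                             min_ti_ms=44.5, tr_ms=5000.0)
        phi = 0.7
        data = np.array([[[
            [0.5 * np.exp(1j * (phi + np.pi)),   # antiphase before the null
             0.2 * np.exp(1j * phi),
             0.6 * np.exp(1j * phi),
             0.9 * np.exp(1j * phi)],
        ]]])
        signed, zero_mask = m.restore_polarity(data, sched)
        np.testing.assert_allclose(signed[0, 0, 0], [-0.5, 0.2, 0.6, 0.9])
        assert not zero_mask.any()

    def test_signs_match_analytic_signal(self):
        tis = ms1_tis(8)
        clean = m.ir_signal(tis, 5000.0, 1000.0, 1.0, 1.0)
        data = (clean * np.exp(1j * 1.1))[None, :]
        signed, _ = restore_polarity_curves(data, ref_index=7)
        np.testing.assert_allclose(np.sign(signed[0]), np.sign(clean))

    def test_all_zero_voxel_flagged(self):
        tis = ms1_tis(4)
        sched = m.TISchedule(ti_ms=tis[None, :], slot_duration_ms=1250.0,
                             min_ti_ms=44.5, tr_ms=5000.0)
        data = np.zeros((1, 1, 1, 4), dtype=complex)
        signed, zero_mask = m.restore_polarity(data, sched)
        assert zero_mask.all()
        np.testing.assert_array_equal(signed, 0.0)

    def test_requires_two_acquisitions(self):
        sched = m.TISchedule(ti_ms=np.array([[44.5]]), slot_duration_ms=5000.0,
                             min_ti_ms=44.5, tr_ms=5000.0)
        with pytest.raises(ValueError):
            m.restore_polarity(np.zeros((1, 1, 1, 1), dtype=complex), sched)


class TestFitExactness:
    @pytest.mark.parametrize("t1", [500.0, 1000.0, 1800.0, 3000.0])
    def test_noiseless_recovery_any_t1(self, t1):
        tis = ms1_tis(8)
        y = m.ir_signal(tis, 5000.0, t1, 1.3, 1.0)
        s0, t1_fit, rss, valid = m.fit_t1_curves(y, tis, 5000.0)
        assert valid[0]
        assert t1_fit[0] == pytest.approx(t1, rel=1e-6)
        assert s0[0] == pytest.approx(1.3, rel=1e-6)

    def test_accuracy_independent_of_ti_count_noiseless(self):
        tr = 5000.0
        full = ms1_tis(8, tr)
        sub = full[:4]
        y_full = m.ir_signal(full, tr, 1800.0, 1.0, 1.0)
        y_sub = m.ir_signal(sub, tr, 1800.0, 1.0, 1.0)
        _, t1_a, _, _ = m.fit_t1_curves(y_full, full, tr)
        _, t1_b, _, _ = m.fit_t1_curves(y_sub, sub, tr)
        assert t1_a[0] == pytest.approx(t1_b[0], abs=1e-3)
        assert t1_a[0] == pytest.approx(1800.0, abs=1e-3)

    def test_matches_scipy_curve_fit(self):
        # independent optimizer route on the same model
        tis = ms1_tis(6)
        rng = np.random.default_rng(3)
        y = m.ir_signal(tis, 5000.0, 1400.0, 1.0, 1.0) + rng.normal(0, 0.02, 6)

        def model(ti, s0, t1):
            return s0 * (1 - 2 * np.exp(-ti / t1) + np.exp(-5000.0 / t1))

        popt, _ = curve_fit(model, tis, y, p0=[1.0, 1000.0])
        s0, t1_fit, _, valid = m.fit_t1_curves(y, tis, 5000.0, refit_null=False)
        assert valid[0]
        assert t1_fit[0] == pytest.approx(popt[1], rel=1e-5)
        assert s0[0] == pytest.approx(popt[0], rel=1e-5)

    def test_log_linear_slope_equals_minus_inverse_t1(self):
        # ln(S_plateau - S(TI)) is linear in TI with slope -1/T1
        tr, t1 = 5000.0, 1600.0
        tis = ms1_tis(8, tr)
        y = m.ir_signal(tis, tr, t1, 1.0, 1.0)
        s_plateau = 1.0 * (1 + np.exp(-tr / t1))  # S0 * (1 + exp(-TR/T1))
        logs = np.log(s_plateau - y)
        slope = np.polyfit(tis, logs, 1)[0]
        assert slope == pytest.approx(-1.0 / t1, rel=1e-12)
        r = np.corrcoef(tis, logs)[0, 1]
        assert r**2 > 0.999999

    def test_polarity_restored_equals_true_signed_fit(self):
        tis = ms1_tis(8)
        clean = m.ir_signal(tis, 5000.0, 1200.0, 1.0, 1.0)
        complex_data = (clean * np.exp(1j * 0.4))[None, :]
        signed, _ = restore_polarity_curves(complex_data, ref_index=7)
        _, t1_a, _, _ = m.fit_t1_curves(signed, tis, 5000.0)
        _, t1_b, _, _ = m.fit_t1_curves(clean, tis, 5000.0)
        assert t1_a[0] == pytest.approx(t1_b[0], abs=1e-6)

    def test_all_zero_voxel_invalid_nan(self):
        tis = ms1_tis(6)
        s0, t1, rss, valid = m.fit_t1_curves(np.zeros(6), tis, 5000.0)
        assert not valid[0]
        assert np.isnan(t1[0]) and np.isnan(s0[0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            m.fit_t1_curves(np.array([1.0, 2.0]), np.array([100.0, 200.0]), 5000.0)


class TestParameterRecovery:
    @pytest.mark.parametrize("t1", [500.0, 1000.0, 1800.0, 3000.0])
    @pytest.mark.parametrize("snr", [10.0, 25.0])
    def test_mean_recovery_under_noise(self, t1, snr):
        # mean fitted T1 across noise draws stays within a few percent of
        # truth (Rician modulus bias bounds the residual offset)
        tr, n_draws = 5000.0, 512
        tis = ms1_tis(8, tr)
        clean = m.ir_signal(tis, tr, t1, 1.0, 1.0)
        rng = np.random.default_rng(11)
        noise = rng.normal(0, 1 / snr, (n_draws, 8, 2))
        data = clean[None, :] + noise[..., 0] + 1j * noise[..., 1]
        signed, _ = restore_polarity_curves(data, ref_index=7)
        _, t1_fit, _, valid = m.fit_t1_curves(signed, tis, tr, noise_floor=1 / snr)
        mean = t1_fit[valid].mean()
        assert valid.mean() > 0.95
        assert mean == pytest.approx(t1, rel=0.05)

    def test_median_noiseless_grid(self):
        tr = 5000.0
        tis = ms1_tis(8, tr)
        for t1 in (500.0, 1000.0, 1800.0, 3000.0):
            y = m.ir_signal(tis, tr, t1, 1.0, 1.0)
            _, t1_fit, _, _ = m.fit_t1_curves(y, tis, tr)
            assert abs(t1_fit[0] - t1) / t1 < 1e-4


class TestVolumeFit:
    def test_brain_phantom_round_trip(self, brain_phantom, protocol_8ti):
        series = m.simulate_series(brain_phantom, protocol_8ti, snr=None)
        res = m.fit_t1_volume(series)
        sup = brain_phantom.support
        assert res.valid[sup].all()
        rel = np.abs(res.t1_ms[sup] - brain_phantom.t1_ms[sup]) / brain_phantom.t1_ms[sup]
        assert rel.max() < 1e-6
        # background voxels are invalid with NaN outputs
        assert not res.valid[~sup].any()
        assert np.isnan(res.t1_ms[~sup]).all()
        # goodness of fit is perfect on noiseless data
        assert np.nanmin(res.r_squared[sup]) > 1 - 1e-9

    def test_mask_restricts_fit(self, brain_phantom, protocol_8ti):
        series = m.simulate_series(brain_phantom, protocol_8ti, snr=None)
        mask = brain_phantom.labels == 2
        res = m.fit_t1_map(
            m.restore_polarity(series)[0], series.schedule, 5000.0, mask=mask
        )
        assert res.valid[mask].all()
        assert not res.valid[brain_phantom.labels == 1].any()


class TestLookupFit:
    def test_lut_matches_nls_on_grid_values(self):
        tis = ms1_tis(8)
        grid = np.geomspace(200.0, 5000.0, 1024)
        t1_true = grid[400]
        y = m.ir_signal(tis, 5000.0, t1_true, 0.8, 1.0)
        s0, t1_fit, rss = m.lut_fit_t1(y, tis, 5000.0, t1_grid_ms=grid)
        assert t1_fit[0] == pytest.approx(t1_true, abs=1e-9)
        assert s0[0] == pytest.approx(0.8, rel=1e-9)

    def test_lut_within_one_grid_step_off_grid(self):
        tis = ms1_tis(8)
        grid = np.geomspace(200.0, 5000.0, 2048)
        y = m.ir_signal(tis, 5000.0, 1234.5, 1.0, 1.0)
        _, t1_fit, _ = m.lut_fit_t1(y, tis, 5000.0, t1_grid_ms=grid)
        step = np.diff(grid)[np.searchsorted(grid, 1234.5)]
        assert abs(t1_fit[0] - 1234.5) <= step
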