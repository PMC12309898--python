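"""Estimators: sqBOLD linear system, hyperoxia-BOLD DBV, OEF, and TRUST."""

import numpy as np
import pytest

from hqbold import estimators as est
from hqbold.forward_models import TrustProtocol, ase_signal_analytic
from hqbold.physiology import PhysiologicalState

TAUS = np.arange(0.0, 67.0, 3.0)


def two_regime_signal(taus, dbv, r2p, offset):
    tau_s = taus * 1e-3
    ln_s = np.full_like(tau_s, offset)
    long_t = taus > 15
    ln_s[long_t] += dbv - r2p * tau_s[long_t]
    short = (taus > 0) & ~long_t
    if dbv > 0:
        ln_s[short] -= 0.3 * dbv * (r2p / dbv * tau_s[short]) ** 2
    return np.exp(ln_s)


class TestSqboldFit:
    def test_closed_form_example(self):
        # S(0) = 100, S(tau) = 100 exp(0.05 - 4.0 tau[s]) for long tau:
        # the two-point closed-form solution of the model is exact.
        sig = np.where(TAUS == 0, 100.0, 100.0 * np.exp(0.05 - 4.0 * TAUS * 1e-3))
        fit = est.sqbold_fit(TAUS, sig)
        assert fit.dbv == pytest.approx(0.05, abs=1e-10)
        assert fit.r2p == pytest.approx(4.0, abs=1e-8)
        assert fit.ln_s0_minus_te_r2 == pytest.approx(np.log(100.0), abs=1e-10)

    def test_constant_signal(self):
        fit = est.sqbold_fit(TAUS, np.full_like(TAUS, 100.0))
        assert fit.dbv == pytest.approx(0.0, abs=1e-12)
        assert fit.r2p == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_over_random_draws(self, rng):
        # Generator/estimator consistency across 100 random parameter sets.
        for _ in range(100):
            dbv = rng.uniform(0.001, 0.06)
            r2p = rng.uniform(0.5, 6.0)
            offset = rng.uniform(3.0, 6.0)
            sig = two_regime_signal(TAUS, dbv, r2p, offset)
            fit = est.sqbold_fit(TAUS, sig)
            assert abs(fit.dbv - dbv) < 1e-8
            assert abs(fit.r2p - r2p) < 1e-8
            assert abs(fit.ln_s0_minus_te_r2 - offset) < 1e-8

    def test_transition_points_ignored(self):
        sig = two_regime_signal(TAUS, 0.03, 3.0, 0.0)
        corrupted = sig.copy()
        corrupted[(TAUS > 0) & (TAUS <= 15)] *= 5.0  # garbage in excluded range
        a = est.sqbold_fit(TAUS, sig)
        b = est.sqbold_fit(TAUS, corrupted)
        assert a.r2p == b.r2p and a.dbv == b.dbv

    def test_insufficient_data(self):
        with pytest.raises(est.InsufficientDataError):
            est.sqbold_fit(np.array([3.0, 30.0, 40.0, 50.0]), np.ones(4))
        with pytest.raises(est.InsufficientDataError):
            est.sqbold_fit(np.array([0.0, 30.0, 40.0]), np.ones(3))

    def test_nonpositive_signal(self):
        sig = np.ones_like(TAUS)
        sig[5] = -1.0
        with pytest.raises(ValueError):
            est.sqbold_fit(TAUS, sig)


class TestLongTauFit:
    def test_matches_sqbold_r2p_on_analytic_data(self):
        curve = ase_signal_analytic(PhysiologicalState(dbv=0.03, oef=0.5))
        fit = est.sqbold_fit(curve.abscissa, curve.attenuation)
        r2p, _ = est.r2p_longtau_fit(curve.abscissa, curve.attenuation)
        assert r2p == pytest.approx(fit.r2p, abs=1e-12)

    def test_pure_exponential(self):
        sig = np.exp(-5.0 * TAUS * 1e-3)
        r2p, intercept = est.r2p_longtau_fit(TAUS, sig)
        assert r2p == pytest.approx(5.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact(self):
        taus = np.array([20.0, 60.0])
        sig = np.exp(1.0 - 2.5 * taus * 1e-3)
        r2p, intercept = est.r2p_longtau_fit(taus, sig)
        assert r2p == pytest.approx(2.5) and intercept == pytest.approx(1.0)


class TestOefInversion:
    def test_standard_state(self):
        assert est.oef_from_r2p_dbv(2.8, 0.023) == pytest.approx(0.40, abs=0.01)

    def test_round_trip_with_forward(self):
        from hqbold.forward_models import r2p_static_dephasing

        for oef in (0.1, 0.4, 0.9):
            r2p = r2p_static_dephasing(oef, 0.34, 0.03)
            assert est.oef_from_r2p_dbv(r2p, 0.03) == pytest.approx(oef, rel=1e-12)

    def test_direct_value(self):
        # constant gamma (4/3) pi dchi0 Hct B0 ~ 301.7 s^-1 at Hct 0.34, 3 T
        assert est.oef_from_r2p_dbv(3.0, 0.03) == pytest.approx(
            3.0 / (301.73 * 0.03), abs=2e-3
        )

    def test_negative_dbv_handling(self):
        assert np.isnan(est.oef_from_r2p_dbv(3.0, 0.0))
        assert np.isnan(est.oef_from_r2p_dbv(3.0, -0.01))
        assert est.oef_from_r2p_dbv(3.0, -0.01, negative_dbv="propagate") < 0


class TestPeto2Regressor:
    def test_constant_trace(self):
        t = np.arange(0.0, 700.0)
        reg, centered = est.peto2_regressor(t, np.full_like(t, 110.0))
        assert np.allclose(reg, 110.0)
        assert np.allclose(centered, 0.0)

    def test_smoothing_preserves_mean(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 600.0)
        trace = 110.0 + rng.normal(0, 5, t.size)
        reg, _ = est.peto2_regressor(t, trace, smooth_width=10.0)
        assert reg.mean() == pytest.approx(np.interp(np.arange(600), t, trace).mean(),
                                           rel=1e-3)

    def test_step_smoothed_to_ramp(self):
        # Sliding-window oracle: midpoint of the ramp sits at the step.
        t = np.arange(0.0, 600.0)
        trace = np.where(t < 300, 110.0, 405.0)
        width = 11.0
        reg, _ = est.peto2_regressor(t, trace, smooth_width=width)
        padded = np.pad(np.where(np.arange(600) < 300, 110.0, 405.0),
                        5, mode="reflect")
        oracle = np.convolve(padded, np.ones(11) / 11, mode="valid")
        assert np.allclose(reg, oracle)
        midpoint = (110.0 + 405.0) / 2.0
        cross = np.argmin(np.abs(reg - midpoint))
        assert abs(cross - 300) <= width / 2

    def test_short_trace_errors(self):
        with pytest.raises(ValueError):
            est.peto2_regressor(np.arange(0.0, 500.0), np.ones(500), n_volumes=600)


class TestDeltaBoldGlm:
    @staticmethod
    def boxcar():
        reg = np.zeros(600)
        for lo, hi in ((120, 240), (360, 480)):
            reg[lo:hi] = 1.0
        return reg

    def test_exact_on_generating_model(self):
        reg = self.boxcar()
        series = 100.0 + 1.0 * reg
        assert est.delta_bold_glm(series, reg) == pytest.approx(1.0, rel=1e-10)

    def test_uncorrelated_series(self):
        assert est.delta_bold_glm(np.full(600, 50.0), self.boxcar()) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_variance_regressor(self):
        with pytest.raises(ValueError):
            est.delta_bold_glm(np.ones(600), np.ones(600))

    def test_noisy_recovery(self, rng):
        # SNR 200, n = 600: the 0.5% response is recovered within 0.05%.
        reg = self.boxcar()
        series = 100.0 * (1 + 0.005 * reg) + rng.normal(0, 0.5, 600)
        assert est.delta_bold_glm(series, reg) == pytest.approx(0.5, abs=0.05)

    def test_voxelwise_broadcasting(self):
        reg = self.boxcar()
        series = np.stack([100.0 + 2.0 * reg, 50.0 + 0.5 * reg])
        out = est.delta_bold_glm(series, reg)
        assert out == pytest.approx([2.0, 1.0], rel=1e-10)


class TestDeltaPeto2:
    def test_constant_trace(self):
        assert est.delta_peto2(np.full(600, 110.0)) == 0.0

    def test_window_means(self):
        trace = np.full(600, 110.0)
        for lo, hi in est.HYPEROXIA_WINDOWS:
            trace[lo - 1 : hi] = 405.0
        assert est.delta_peto2(trace) == pytest.approx(295.0)

    def test_short_trace(self):
        with pytest.raises(ValueError):
            est.delta_peto2(np.ones(400))


class TestDbvHeuristic:
    def test_worked_example(self):
        # (27/35 + 0.2)(245.1/294.7 + 0.1) * 1.00
        assert est.dbv_heuristic(1.0, 35.0, 294.7) == pytest.approx(0.905, abs=5e-4)

    def test_coefficient_arithmetic(self):
        c = est.HeuristicCoefficients()
        val = est.dbv_heuristic(1.0, c.a, 10.0 * c.c)
        assert val == pytest.approx(1.2 * 0.2)

    def test_proportional_in_delta_bold(self):
        assert est.dbv_heuristic(0.0, 35.0, 300.0) == 0.0
        assert est.dbv_heuristic(2.0, 35.0, 300.0) == pytest.approx(
            2 * est.dbv_heuristic(1.0, 35.0, 300.0)
        )

    def test_strictly_decreasing_in_te_and_dpao2(self):
        assert est.dbv_heuristic(1.0, 30.0, 300.0) > est.dbv_heuristic(1.0, 40.0, 300.0)
        assert est.dbv_heuristic(1.0, 35.0, 250.0) > est.dbv_heuristic(1.0, 35.0, 350.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            est.dbv_heuristic(1.0, 0.0, 300.0)
        with pytest.raises(ValueError):
            est.dbv_heuristic(1.0, 35.0, -10.0)


class TestTrust:
    def test_exact_exponential_recovery(self):
        etes = np.array([0.0, 40.0, 80.0, 160.0])
        c_true = 1.0 / 1624.0 - 1.0 / 60.0
        ds = 100.0 * np.exp(etes * c_true)
        res = est.trust_t2b_fit(etes, ds)
        assert res.t2b == pytest.approx(60.0, abs=1e-9)
        assert res.c_exponent == pytest.approx(c_true)
        assert res.s0 == pytest.approx(100.0)

    def test_zero_exponent_gives_t1b(self):
        res = est.trust_t2b_fit([0.0, 40.0, 80.0, 160.0], np.full(4, 10.0))
        assert res.t2b == pytest.approx(1624.0)

    def test_calibration_round_trip(self):
        calib = est.CalibrationModel.for_hct(0.42)
        for y in np.linspace(0.4, 0.9, 11):
            assert calib.invert(calib.t2b(y)) == pytest.approx(y, abs=1e-6)

    def test_calibration_monotone(self):
        calib = est.CalibrationModel.for_hct(0.42)
        y = np.linspace(0.3, 1.0, 100)
        assert np.all(np.diff(calib.rate(y)) < 0)  # rate falls as Y rises

    def test_nonpositive_ds_errors(self):
        with pytest.raises(ValueError):
            est.trust_t2b_fit([0.0, 40.0, 80.0, 160.0], [5.0, 1.0, -0.1, 0.2])

    def test_preprocess_selects_blob_and_ties(self):
        shape = (8, 8, 2)
        protocol = TrustProtocol()
        n_vol = 4 * 4 * 2
        series = np.full(shape + (n_vol,), 10.0)
        blob = np.zeros(shape, dtype=bool)
        blob[2:4, 2:4, 0] = True  # 4 voxels, equal signal: tie-break by index
        v = 0
        for ete in protocol.etes:
            for _ in range(4):
                series[..., v] = np.where(blob, 10.0 + 50.0 * np.exp(-ete / 60.0), 10.0)
                series[..., v + 1] = 10.0
                v += 2
        prep = est.trust_preprocess(series, protocol)
        assert prep.roi.sum() == 4
        assert np.array_equal(prep.roi, blob)
        assert prep.ds[0] == pytest.approx(50.0)

    def test_preprocess_degenerate_warns(self):
        series = np.full((4, 4, 2, 32), 7.0)
        with pytest.warns(UserWarning):
            est.trust_preprocess(series)

    def test_preprocess_shape_validation(self):
        with pytest.raises(ValueError):
            est.trust_preprocess(np.zeros((4, 4, 2, 30)))


class TestImageFits:
    def test_image_fit_matches_scalar_fit(self):
        sig = two_regime_signal(TAUS, 0.03, 3.0, np.log(100.0))
        data = np.tile(sig, (2, 2, 1, 1))
        maps = est.sqbold_fit_image(data, TAUS)
        assert maps["dbv"] == pytest.approx(np.full((2, 2, 1), 0.03), abs=1e-10)
        assert maps["r2p"] == pytest.approx(np.full((2, 2, 1), 3.0), abs=1e-8)
        long_maps = est.r2p_longtau_image(data, TAUS)
        assert long_maps["r2p"] == pytest.approx(maps["r2p"], abs=1e-10)

    def test_masked_voxels_nan(self):
        sig = two_regime_signal(TAUS, 0.03, 3.0, np.log(100.0))
        data = np.tile(sig, (2, 1, 1, 1))
        mask = np.zeros((2, 1, 1))
        mask[0] = 1
        maps = est.sqbold_fit_image(data, TAUS, mask=mask)
        assert np.isfinite(maps["r2p"][0, 0, 0])
        assert np.isnan(maps["r2p"][1, 0, 0])
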