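"""Forward models: analytic static dephasing and the Monte Carlo simulator."""

import numpy as np
import pytest

from hqbold import estimators, forward_models as fm
from hqbold.physiology import PhysiologicalState


class TestStaticDephasingRate:
    def test_standard_state_value(self):
        # gamma (4/3) pi dchi0 Hct OEF B0 DBV at the standard tissue state
        assert fm.r2p_static_dephasing(0.40, 0.34, 0.023, 3.0) == pytest.approx(
            2.776, abs=2e-3
        )

    def test_linearity(self):
        base = fm.r2p_static_dephasing(0.3, 0.34, 0.02)
        assert fm.r2p_static_dephasing(0.6, 0.34, 0.02) == pytest.approx(2 * base)
        assert fm.r2p_static_dephasing(0.3, 0.34, 0.04) == pytest.approx(2 * base)
        assert fm.r2p_static_dephasing(0.3, 0.34, 0.0) == 0.0


class TestFcFunction:
    def test_quadratic_small_argument(self):
        u = 0.05
        assert fm.static_dephasing_fc(u) / (0.3 * u**2) == pytest.approx(1.0, rel=1e-3)

    def test_linear_large_argument(self):
        assert fm.static_dephasing_fc(20.0) == pytest.approx(19.0, rel=0.01)

    def test_monotone(self):
        u = np.linspace(0.0, 15.0, 200)
        assert np.all(np.diff(fm.static_dephasing_fc(u)) > 0)


class TestAnalyticAse:
    def test_estimator_recovers_generator(self):
        state = PhysiologicalState(dbv=0.03, oef=0.5)
        offset = np.log(100.0)
        curve = fm.ase_signal_analytic(state, ln_s0_minus_te_r2=offset)
        fit = estimators.sqbold_fit(curve.abscissa, curve.attenuation)
        r2p = fm.r2p_static_dephasing(state.oef, state.hct, state.dbv)
        assert fit.dbv == pytest.approx(state.dbv, abs=1e-12)
        assert fit.r2p == pytest.approx(r2p, abs=1e-9)
        assert fit.ln_s0_minus_te_r2 == pytest.approx(offset, abs=1e-12)

    def test_zero_oef_flat_long_tau(self):
        curve = fm.ase_signal_analytic(PhysiologicalState(oef=0.0))
        long_t = curve.abscissa > 15
        assert np.ptp(curve.attenuation[long_t]) == 0.0

    def test_dbv_from_extrapolated_intercept(self):
        state = PhysiologicalState(dbv=0.04)
        curve = fm.ase_signal_analytic(state)
        r2p, intercept = estimators.r2p_longtau_fit(curve.abscissa, curve.attenuation)
        ln_s0 = np.log(curve.attenuation[curve.abscissa == 0][0])
        assert intercept - ln_s0 == pytest.approx(state.dbv, abs=1e-12)


class TestMcSingleRadius:
    def test_full_saturation_no_dephasing(self):
        c = fm.mc_single_radius(10.0, 1.0, 0.34, n_protons=500, seed=3)
        assert np.allclose(c.attenuation, 1.0)

    def test_attenuation_monotone_in_tau(self):
        c = fm.mc_single_radius(30.0, 0.6, 0.34, n_protons=2000, seed=3)
        att = dict(zip(c.abscissa, c.attenuation))
        assert att[0.0] >= att[40.0]
        assert np.all((c.attenuation > 0) & (c.attenuation <= 1.0))

    def test_deterministic_under_seed(self):
        a = fm.mc_single_radius(3.0, 0.7, 0.34, n_protons=400, seed=9)
        b = fm.mc_single_radius(3.0, 0.7, 0.34, n_protons=400, seed=9)
        assert np.array_equal(a.attenuation, b.attenuation)

    def test_static_dephasing_limit(self):
        # Large radius, no diffusion: the long-tau log-slope approaches the
        # analytic static-dephasing R2' of the compartment.
        c = fm.mc_single_radius(
            100.0, 0.6, 0.34, n_protons=3000, seed=7, diffusion_coeff=0.0
        )
        long_t = c.abscissa > 16
        slope = -np.polyfit(
            c.abscissa[long_t] * 1e-3, np.log(c.attenuation[long_t]), 1
        )[0]
        analytic = c.meta["vf_ref"] * fm.characteristic_frequency(0.4, 0.34)
        assert slope == pytest.approx(analytic, rel=0.10)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            fm.mc_single_radius(10.0, 0.6, 0.34, grid=[0.0, 3.0], n_protons=200)
        with pytest.raises(ValueError):
            fm.mc_single_radius(10.0, 0.6, 0.34, kind="GE", grid=[35.0], n_protons=200)

    def test_too_few_protons(self):
        with pytest.raises(ValueError):
            fm.mc_single_radius(10.0, 0.6, 0.34, n_protons=50)


@pytest.fixture(scope="module")
def curve():
    return fm.mc_single_radius(10.0, 0.6, 0.34, n_protons=1500, seed=5)


class TestMcCombine:
    def test_zero_fraction_noop(self, curve):
        combined = fm.mc_combine([curve, curve], [0.02, 0.0], curve.abscissa)
        alone = fm.mc_combine([curve], [0.02], curve.abscissa)
        assert np.allclose(combined.attenuation, alone.attenuation)

    def test_grid_point_exact(self, curve):
        combined = fm.mc_combine([curve], [curve.meta["vf_ref"]], [8.0])
        assert combined.attenuation[0] == pytest.approx(
            curve.attenuation[curve.abscissa == 8.0][0]
        )

    def test_log_additivity(self, curve):
        halves = fm.mc_combine([curve, curve], [0.01, 0.01], curve.abscissa)
        full = fm.mc_combine([curve], [0.02], curve.abscissa)
        assert np.allclose(halves.attenuation, full.attenuation)

    def test_extrapolation_error(self, curve):
        with pytest.raises(ValueError):
            fm.mc_combine([curve], [0.02], [100.0])

    def test_tsv_round_trip(self, curve, tmp_path):
        path = tmp_path / "curve.tsv"
        curve.to_tsv(path)
        back = fm.SignalCurve.from_tsv(path)
        assert np.allclose(back.abscissa, curve.abscissa)
        assert np.allclose(back.attenuation, curve.attenuation, rtol=1e-10)
        assert back.meta["radius"] == curve.meta["radius"]
        assert back.meta["vf_ref"] == curve.meta["vf_ref"]


class TestDeltaBold:
    def test_zero_without_hyperoxia(self):
        state = PhysiologicalState(pao2_hyper=110.0)
        assert fm.delta_bold_forward(state) == 0.0

    def test_monotone_in_dbv(self):
        vals = [
            fm.delta_bold_forward(PhysiologicalState(dbv=d / 100.0))
            for d in (1.0, 2.0, 3.0, 4.0)
        ]
        assert vals == sorted(vals)
        assert vals[0] > 0

    def test_matches_long_regime_closed_form(self):
        # In the no-diffusion limit with both compartments in the linear
        # regime, deltaBOLD ~ 100 TE [R2'(norm) - R2'(hyper)] summed over
        # compartments.
        from hqbold.physiology import hyperoxia_pair

        state = PhysiologicalState()
        norm, hyper = hyperoxia_pair(state)
        te_s = 35e-3
        dr2p = fm.characteristic_frequency(
            hyper.svo2 - norm.svo2, state.hct
        ) * state.dbv + fm.characteristic_frequency(
            hyper.sco2 - norm.sco2, state.hct
        ) * (state.cbv_total - state.dbv)
        expected = 100.0 * te_s * dr2p
        assert fm.delta_bold_forward(state) == pytest.approx(expected, rel=0.05)

    def test_mc_route_positive_and_deterministic(self, mc_forward):
        state = PhysiologicalState()
        a = fm.delta_bold_forward(state, model="mc", mc=mc_forward)
        b = fm.delta_bold_forward(state, model="mc", mc=mc_forward)
        assert a == b
        assert a > 0


class TestProtocols:
    def test_ase_protocol_invariants(self):
        with pytest.raises(ValueError):
            fm.AseProtocol(te=50.0)  # te below max tau
        with pytest.raises(ValueError):
            fm.AseProtocol(taus=(0.0, 3.0, 3.0))

    def test_vessel_population_invariants(self):
        with pytest.raises(ValueError):
            fm.VesselPopulation(compartments=((3.0, 0.6, 0.6), (30.0, 0.6, 0.6)))
        with pytest.raises(ValueError):
            fm.VesselPopulation(compartments=((-1.0, 0.1, 0.6),))


class TestMcVsAnalyticConsistency:
    def test_long_tau_slope_agreement_in_static_limit(self):
        # Venous-size vessels with diffusion on still sit close to the
        # static-dephasing regime at these time scales.
        c = fm.mc_single_radius(30.0, 0.6, 0.34, n_protons=3000, seed=13)
        long_t = c.abscissa > 16
        slope = -np.polyfit(
            c.abscissa[long_t] * 1e-3, np.log(c.attenuation[long_t]), 1
        )[0]
        analytic = c.meta["vf_ref"] * fm.characteristic_frequency(0.4, 0.34)
        assert slope == pytest.approx(analytic, rel=0.15)
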