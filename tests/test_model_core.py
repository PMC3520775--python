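"""Structural model: covariate algebra, exact simulation, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from petpop import model_core as mc

TQ3 = mc.TariquidarEvent(dose_group=3.0, start=60.0, duration=1.0)


def make_effects(**kw):
    defaults = dict(
        eff_tariquidar={3.0: 0.161, 15.0: 0.135}, eff_scan=1.33, eff_se=1.84,
        placement=mc.Placement.ON_QOUT,
    )
    defaults.update(kw)
    return mc.CovariateEffects(**defaults)


class TestCovariateAlgebra:
    def test_no_tariquidar_gives_unity(self):
        effs = make_effects()
        assert mc.effect_d([], 1, 30.0, effs) == 1.0
        assert mc.effect_d([], 2, 30.0, effs) == 1.0

    def test_dose_effect_applies_from_administration(self):
        effs = make_effects()
        assert mc.effect_d([TQ3], 1, 30.0, effs) == 1.0
        assert mc.effect_d([TQ3], 1, 90.0, effs) == pytest.approx(0.161)

    def test_scan_effect_multiplies_in_second_scan(self):
        effs = make_effects()
        assert mc.effect_d([TQ3], 2, 30.0, effs) == pytest.approx(0.161 * 1.33)

    def test_unknown_dose_group_raises(self):
        effs = make_effects(eff_tariquidar={3.0: 0.161})
        with pytest.raises(mc.ModelError):
            mc.effect_d([mc.TariquidarEvent(15.0, 60.0, 1.0)], 1, 90.0, effs)

    @given(theta=st.floats(0.01, 1e4), eta=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_lognormal_individual_parameter(self, theta, eta):
        assert mc.individual_from_population(theta, eta) == pytest.approx(
            theta * np.exp(eta)
        )

    def test_lognormal_examples(self):
        assert mc.individual_from_population(16.4, 0.0) == pytest.approx(16.4)
        assert mc.individual_from_population(16.4, np.log(2)) == pytest.approx(32.8)
        with pytest.raises(mc.ModelError):
            mc.individual_from_population(-1.0, 0.0)

    def test_lognormal_median_equals_typical_value(self):
        rng = np.random.default_rng(7)
        draws = 16.4 * np.exp(rng.normal(0.0, 0.162, size=100_000))
        assert np.median(draws) == pytest.approx(16.4, rel=5e-3)

    def test_se_covariate(self):
        assert mc.apply_se_covariate(0.132, 1.84, "control") == pytest.approx(0.132)
        assert mc.apply_se_covariate(0.132, 1.84, "post_SE") == pytest.approx(0.24288)
        assert mc.apply_se_covariate(0.132, 1.0, "post_SE") == pytest.approx(0.132)
        with pytest.raises(mc.ModelError):
            mc.apply_se_covariate(0.132, 1.84, "unknown")


@pytest.fixture
def dose():
    return mc.DoseEvent(amount_kbq=91_000.0, start=0.0, duration=0.4)


class TestPlasmaSimulation:
    def test_zero_dose_gives_zero_curve(self, rat_plasma):
        tac = mc.simulate_plasma(
            rat_plasma, [mc.DoseEvent(0.0, 0.0, 0.4)], np.linspace(0.1, 140, 50)
        )
        assert np.all(tac.values == 0.0)

    def test_auc_equals_dose_over_clearance(self, rat_plasma, dose):
        t = np.linspace(0.0, 10_000.0, 50_001)
        tac = mc.simulate_plasma(rat_plasma, [dose], t)
        auc = np.trapezoid(tac.values, t)
        assert auc == pytest.approx(91_000.0 / 16.4, rel=1e-3)

    def test_linearity_in_dose(self, rat_plasma, dose):
        t = np.linspace(0.1, 140, 60)
        single = mc.simulate_plasma(rat_plasma, [dose], t).values
        double = mc.simulate_plasma(
            rat_plasma, [mc.DoseEvent(2 * dose.amount_kbq, 0.0, dose.duration)], t
        ).values
        np.testing.assert_allclose(double, 2 * single, rtol=1e-12)

    def test_mass_balance_without_elimination(self, dose):
        params = mc.PlasmaParams(vc=38.8, vp1=141, vp2=1580, cl=0.0, q1=29.1, q2=22.3)
        t = np.array([1.0, 10.0, 100.0, 1000.0])
        segs = mc._infusion_segments([dose], 1000.0)
        states = mc.lti_solve(
            params.rate_matrix(), np.array([1.0, 0, 0]), segs, np.zeros(3), t
        )
        totals = states.sum(axis=1)
        np.testing.assert_allclose(totals, dose.amount_kbq, rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ode_oracle(self, seed, dose):
        rng = np.random.default_rng(seed)
        p = mc.PlasmaParams(*np.exp(rng.uniform(np.log(0.5), np.log(500.0), size=6)))
        t = np.linspace(0.05, 140, 120)
        tac = mc.simulate_plasma(p, [dose], t)
        M = p.rate_matrix()

        def rhs(time, y):
            r = dose.amount_kbq / dose.duration if time < dose.duration else 0.0
            return M @ y + np.array([r, 0.0, 0.0])

        sol = solve_ivp(rhs, (0, 140), np.zeros(3), t_eval=t, rtol=1e-11,
                        atol=1e-6, method="LSODA", max_step=0.1)
        oracle = sol.y[0] / p.vc
        np.testing.assert_allclose(tac.values, oracle, rtol=1e-6, atol=1e-9 * oracle.max())

    def test_modes_agree_with_direct_solution(self, rat_plasma, dose):
        t = np.linspace(0.05, 140, 200)
        direct = mc.simulate_plasma(rat_plasma, [dose], t).values
        modes = mc.plasma_modes(rat_plasma, [dose], 140.0)
        np.testing.assert_allclose(mc.eval_modes(modes, t), direct, rtol=1e-10)


class TestBrainSimulation:
    def test_zero_influx_gives_zero_brain(self, rat_plasma, rat_brain_wb, dose):
        bp = mc.BrainParams(vbr1=0.132, vbr2=2.0, qin=1e-12, qout=3.6, qbr=0.115)
        modes = mc.plasma_modes(rat_plasma, [dose], 140.0)
        tac = mc.simulate_brain(
            bp, make_effects(), modes, [TQ3], 1, np.linspace(0.5, 140, 50)
        )
        assert np.all(np.abs(tac.values) < 1e-9)

    def test_matches_ode_oracle_exponential_forcing(self, rat_plasma, rat_brain_wb, dose):
        effs = make_effects()
        modes = mc.plasma_modes(rat_plasma, [dose], 140.0)
        t = np.linspace(0.5, 140, 120)
        ours = mc.simulate_brain(rat_brain_wb, effs, modes, [TQ3], 1, t)
        bp = rat_brain_wb

        def cc(time):
            return mc.eval_modes(modes, np.array([time]))[0]

        def rhs(time, y):
            d = 1.0 if time < 60.0 else 0.161
            c1, c2 = y[0] / bp.vbr1, y[1] / bp.vbr2
            return [bp.qin * cc(time) - d * bp.qout * c1 - bp.qbr * (c1 - c2),
                    bp.qbr * (c1 - c2)]

        sol = solve_ivp(rhs, (0, 140), [0, 0], t_eval=t, rtol=1e-11, atol=1e-12,
                        method="LSODA", max_step=0.25)
        oracle = sol.y.sum(axis=0) / (bp.vbr1 + bp.vbr2)
        np.testing.assert_allclose(ours.values, oracle, rtol=1e-6)

    def test_matches_ode_oracle_piecewise_linear_forcing(self, rat_plasma, rat_brain_wb, dose):
        effs = make_effects(placement=mc.Placement.ON_QIN)
        grid = np.linspace(0.0, 140.0, 1401)
        plasma = mc.simulate_plasma(rat_plasma, [dose], grid)
        t = np.linspace(0.5, 139.5, 80)
        ours = mc.simulate_brain(rat_brain_wb, effs, plasma, [TQ3], 1, t)
        bp = rat_brain_wb

        def rhs(time, y):
            d = 1.0 if time < 60.0 else 0.161
            cc = np.interp(time, plasma.times, plasma.values)
            c1, c2 = y[0] / bp.vbr1, y[1] / bp.vbr2
            return [d * bp.qin * cc - bp.qout * c1 - bp.qbr * (c1 - c2),
                    bp.qbr * (c1 - c2)]

        sol = solve_ivp(rhs, (0, 140), [0, 0], t_eval=t, rtol=1e-11, atol=1e-12,
                        method="LSODA", max_step=0.1)
        oracle = sol.y.sum(axis=0) / (bp.vbr1 + bp.vbr2)
        np.testing.assert_allclose(ours.values, oracle, rtol=1e-6)

    def test_steady_state_ratio(self, rat_brain_wb):
        # constant plasma level; D = 0.5 active from t = 0
        effs = make_effects(eff_tariquidar={3.0: 0.5})
        const = [mc.ExpModeSegment(0.0, 1e5, np.array([-1.0]), np.array([0.0]), 5.0)]
        event = mc.TariquidarEvent(3.0, 0.0, 1.0)
        tac = mc.simulate_brain(rat_brain_wb, effs, const, [event], 1, np.array([5e4]))
        expected = rat_brain_wb.qin / (0.5 * rat_brain_wb.qout)
        assert tac.values[0] / 5.0 == pytest.approx(expected, rel=1e-3)

    def test_brain_auc_monotone_in_inhibition(self, rat_plasma, rat_brain_wb, dose):
        modes = mc.plasma_modes(rat_plasma, [dose], 140.0)
        t = np.linspace(0.5, 140, 200)
        aucs = []
        for d in (1.0, 0.5, 0.25, 0.1):
            effs = make_effects(eff_tariquidar={3.0: d})
            tac = mc.simulate_brain(rat_brain_wb, effs, modes, [TQ3], 1, t)
            aucs.append(np.trapezoid(tac.values, t))
        assert np.all(np.diff(aucs) > 0)

    def test_linearity_in_forcing(self, rat_plasma, rat_brain_wb, dose):
        t = np.linspace(0.5, 140, 60)
        effs = make_effects()
        m1 = mc.plasma_modes(rat_plasma, [dose], 140.0)
        m2 = mc.plasma_modes(
            rat_plasma, [mc.DoseEvent(2 * dose.amount_kbq, 0.0, dose.duration)], 140.0
        )
        b1 = mc.simulate_brain(rat_brain_wb, effs, m1, [TQ3], 1, t).values
        b2 = mc.simulate_brain(rat_brain_wb, effs, m2, [TQ3], 1, t).values
        np.testing.assert_allclose(b2, 2 * b1, rtol=1e-10)


class TestSuv:
    def test_definition(self):
        tac = mc.TimeActivityCurve("plasma", [1.0, 2.0], [500.0, 500.0])
        suv = mc.suv_normalize(tac, injected_kbq=91_000.0, body_weight_g=260.0)
        assert suv.unit is mc.Unit.SUV
        np.testing.assert_allclose(suv.values, 500.0 * 260.0 / 91_000.0)
        assert suv.values[0] == pytest.approx(1.4286, abs=1e-4)

    def test_unity_when_concentration_matches_dose_density(self):
        tac = mc.TimeActivityCurve("b", [1.0], [91_000.0 / 260.0])
        suv = mc.suv_normalize(tac, 91_000.0, 260.0)
        assert suv.values[0] == pytest.approx(1.0)

    def test_already_normalized_rejected(self):
        tac = mc.TimeActivityCurve("b", [1.0], [1.0], unit=mc.Unit.SUV)
        with pytest.raises(mc.ModelError):
            mc.suv_normalize(tac, 1.0, 1.0)

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, scale):
        tac = mc.TimeActivityCurve("b", [1.0, 2.0], [3.0, 4.0])
        suv = mc.suv_normalize(tac, 1000.0, 250.0)
        scaled = mc.TimeActivityCurve("b", [1.0, 2.0], [3.0 * scale, 4.0 * scale])
        suv2 = mc.suv_normalize(scaled, 1000.0, 250.0)
        np.testing.assert_allclose(suv2.values, scale * suv.values, rtol=1e-12)
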