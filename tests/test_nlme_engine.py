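"""Estimation engine: OFV correctness, empirical Bayes, diagnostics, fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from petpop import model_core as mc
from petpop import nlme_engine as ne


# ---------------------------------------------------------------------------
# A minimal mono-exponential toy model: f(t) = a * exp(-k t)
# ---------------------------------------------------------------------------


class ExpDecayStructure:
    param_names = ("a", "k")

    def mask(self, subj):
        return np.ones(subj.n_obs, dtype=bool)

    def predict(self, params, subj):
        return params["a"] * np.exp(-params["k"] * subj.times)


def toy_subject(sid, times, y):
    times = np.asarray(times, dtype=float)
    return ne.SubjectData(
        subject_id=sid, group="control", tq_dose=None, body_weight_g=250.0,
        scans={}, times=times, scan_idx=np.ones(len(times), dtype=int),
        obs_type=np.asarray(["conc"] * len(times), dtype=object),
        y=np.asarray(y, dtype=float),
    )


def toy_model(a=10.0, k=0.2, omega=0.3, sigma=0.1, iiv_on=("a",)):
    iiv = [ne.IIVBlock(tuple(iiv_on), omega)] if omega > 0 else []
    return ne.PopulationModel(
        structure=ExpDecayStructure(), theta={"a": a, "k": k},
        iiv=iiv, sigma={"conc": sigma},
    )


def simulate_toy(rng, n_subj, a=10.0, k=0.2, omega=0.3, sigma=0.1, n_obs=8):
    subjects, etas = [], []
    times = np.linspace(0.5, 12.0, n_obs)
    for i in range(n_subj):
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0
        f = a * math.exp(eta) * np.exp(-k * times)
        y = f * (1.0 + rng.normal(0.0, sigma, size=n_obs))
        subjects.append(toy_subject(f"s{i}", times, np.clip(y, 1e-9, None)))
        etas.append(eta)
    return subjects, np.asarray(etas)


def gauss_hermite_ofv(subjects, model, n_nodes=64):
    """Independent oracle: adaptive Gauss-Hermite marginal likelihood."""
    import scipy.optimize

    omega = model.iiv[0].omega
    sigma = model.sigma["conc"]
    structure = model.structure
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for subj in subjects:
        def neg_log_joint(eta):
            f = structure.predict(
                {k: v * math.exp(eta) if k in model.iiv[0].names else v
                 for k, v in model.theta.items()},
                subj,
            )
            v = (sigma * f) ** 2
            ll = -0.5 * np.sum(np.log(2 * np.pi * v) + (subj.y - f) ** 2 / v)
            lp = -0.5 * eta**2 / omega**2 - 0.5 * math.log(2 * np.pi * omega**2)
            return -(ll + lp)

        res = scipy.optimize.minimize_scalar(
            neg_log_joint, bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        mode = res.x
        h = 1e-4
        curv = (neg_log_joint(mode + h) - 2 * neg_log_joint(mode) + neg_log_joint(mode - h)) / h**2
        s = 1.0 / math.sqrt(max(curv, 1e-12))
        z = mode + math.sqrt(2.0) * s * nodes
        vals = np.array([-neg_log_joint(zi) for zi in z])
        log_terms = vals + nodes**2 + math.log(math.sqrt(2.0) * s)
        m = log_terms.max()
        log_lik = m + math.log(np.sum(weights * np.exp(log_terms - m)))
        total += -2.0 * log_lik
    return total


class TestOfv:
    def test_no_random_effects_closed_form(self):
        rng = np.random.default_rng(0)
        subjects, _ = simulate_toy(rng, 3, omega=0.0)
        model = toy_model(omega=0.0)
        got = ne.ofv(subjects, model)
        expected = 0.0
        for s in subjects:
            f = 10.0 * np.exp(-0.2 * s.times)
            v = (0.1 * f) ** 2
            expected += float(np.sum(np.log(2 * np.pi * v) + (s.y - f) ** 2 / v))
        assert got == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("objective", ["laplace", "focei"])
    def test_matches_gauss_hermite_quadrature(self, objective):
        rng = np.random.default_rng(1)
        subjects, _ = simulate_toy(rng, 3)
        model = toy_model()
        approx = ne.ofv(subjects, model, objective=objective)
        oracle = gauss_hermite_ofv(subjects, model)
        assert approx == pytest.approx(oracle, abs=0.1)

    def test_additive_over_subjects(self):
        rng = np.random.default_rng(2)
        subjects, _ = simulate_toy(rng, 4)
        model = toy_model()
        total = ne.ofv(subjects, model)
        parts = sum(ne.ofv([s], model) for s in subjects)
        assert total == pytest.approx(parts, abs=1e-8)

    def test_subject_with_no_observations_contributes_zero(self):
        model = toy_model()
        empty = toy_subject("e", [], [])
        assert ne.ofv([empty], model) == pytest.approx(0.0, abs=1e-12)


class TestFit:
    def test_recovers_truth_from_noise_free_data(self):
        times = np.linspace(0.5, 12.0, 10)
        f = 10.0 * np.exp(-0.2 * times)
        subjects = [toy_subject("s0", times, f), toy_subject("s1", times, f)]
        # sigma is fixed small: the proportional-error likelihood is exactly
        # centred on the data only in the sigma -> 0 limit
        model = ne.PopulationModel(
            structure=ExpDecayStructure(), theta={"a": 5.0, "k": 0.5},
            iiv=[], sigma={"conc": 0.005}, sigma_fixed={"conc"},
        )
        fit = ne.fit_population(subjects, model, maxiter=300)
        assert fit.theta["a"] == pytest.approx(10.0, rel=1e-3)
        assert fit.theta["k"] == pytest.approx(0.2, rel=1e-3)

    def test_fixed_parameters_never_move(self):
        rng = np.random.default_rng(3)
        subjects, _ = simulate_toy(rng, 4)
        model = toy_model(k=0.37)
        model.fixed = {"k"}
        fit = ne.fit_population(subjects, model, maxiter=60)
        assert fit.theta["k"] == 0.37

    def test_final_ofv_not_worse_than_initial(self):
        rng = np.random.default_rng(4)
        subjects, _ = simulate_toy(rng, 4)
        model = toy_model(a=6.0, k=0.4)
        initial = ne.ofv(subjects, model)
        fit = ne.fit_population(subjects, model, maxiter=80)
        assert fit.ofv <= initial + 1e-6

    def test_population_fit_recovers_toy_truth(self):
        rng = np.random.default_rng(5)
        subjects, _ = simulate_toy(rng, 30, a=10.0, k=0.2, omega=0.3, sigma=0.1)
        model = toy_model(a=5.0, k=0.35, omega=0.15, sigma=0.2)
        fit = ne.fit_population(subjects, model, maxiter=200)
        assert fit.theta["a"] == pytest.approx(10.0, rel=0.15)
        assert fit.theta["k"] == pytest.approx(0.2, rel=0.1)
        assert fit.iiv[0].omega == pytest.approx(0.3, rel=0.4)
        assert fit.sigma["conc"] == pytest.approx(0.1, rel=0.25)

    def test_init_invariance_on_well_conditioned_data(self):
        rng = np.random.default_rng(6)
        subjects, _ = simulate_toy(rng, 12)
        ofvs = []
        for a0, k0 in [(5.0, 0.1), (20.0, 0.4), (8.0, 0.25)]:
            fit = ne.fit_population(subjects, toy_model(a=a0, k=k0), maxiter=300)
            ofvs.append(fit.ofv)
        assert max(ofvs) - min(ofvs) < 0.5


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self):
        model = toy_model()
        eta = ne.empirical_bayes(toy_subject("e", [], []), model)
        assert np.all(eta == 0.0)

    def test_shrinks_to_zero_as_omega_vanishes(self):
        rng = np.random.default_rng(7)
        subjects, _ = simulate_toy(rng, 1, omega=0.4)
        model = toy_model(omega=1e-6)
        eta = ne.empirical_bayes(subjects[0], model)
        assert abs(eta[0]) < 1e-3

    def test_tracks_true_eta_with_rich_data(self):
        rng = np.random.default_rng(8)
        subjects, etas = simulate_toy(rng, 10, sigma=0.02, n_obs=20)
        model = toy_model(sigma=0.02)
        for subj, true_eta in zip(subjects, etas):
            est = ne.empirical_bayes(subj, model)[0]
            assert est == pytest.approx(true_eta, abs=0.05)


class TestDiagnostics:
    def test_noise_free_data_gives_zero_iwres(self):
        times = np.linspace(0.5, 12.0, 10)
        f = 10.0 * np.exp(-0.2 * times)
        subjects = [toy_subject("s0", times, f)]
        model = toy_model(omega=0.0)
        fit = ne.FitResult(
            model=model, theta=model.theta, iiv=[], sigma=model.sigma,
            ofv=0.0, etas={"s0": np.zeros(0)}, rse=None,
            convergence={"success": True},
        )
        table = ne.diagnostics_table(fit, subjects)
        np.testing.assert_allclose(table["iwres"], 0.0, atol=1e-10)
        np.testing.assert_allclose(table["pred"], table["ipred"])

    def test_iwres_standardized_under_true_model(self):
        rng = np.random.default_rng(9)
        subjects, _ = simulate_toy(rng, 40, omega=0.0, sigma=0.1, n_obs=15)
        model = toy_model(omega=0.0)
        fit = ne.FitResult(
            model=model, theta=model.theta, iiv=[], sigma=model.sigma,
            ofv=0.0, etas={s.subject_id: np.zeros(0) for s in subjects},
            rse=None, convergence={"success": True},
        )
        table = ne.diagnostics_table(fit, subjects)
        assert table["iwres"].std() == pytest.approx(1.0, abs=0.08)


class TestBrainStructure:
    def test_fast_path_matches_reference_simulation(
        self, small_rat_subjects, small_rat_forcings, rat_true_model
    ):
        structure = ne.BrainStructure(small_rat_forcings)
        params = {
            "vbr1": 0.132, "vbr2": 2.0, "qin": 5.62, "qout": 3.60, "qbr": 0.115,
            "eff_tq_3": 0.161, "eff_tq_15": 0.135, "eff_scan": 1.33, "eff_se": 1.84,
        }
        for subj in small_rat_subjects[:4]:
            fast = structure.predict(params, subj)
            m = structure.mask(subj)
            slow = np.empty(int(m.sum()))
            times, scans = subj.times[m], subj.scan_idx[m]
            vbr1 = params["vbr1"] * (params["eff_se"] if subj.group == "post_SE" else 1.0)
            for scan in subj.scans:
                sel = scans == scan
                slow[sel] = structure._predict_reference(
                    params, subj, scan, times[sel], vbr1
                )
            np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-12)

    def test_placement_changes_predictions_only_after_inhibition(
        self, small_rat_subjects, small_rat_forcings
    ):
        params = {
            "vbr1": 0.132, "vbr2": 2.0, "qin": 5.62, "qout": 3.60, "qbr": 0.115,
            "eff_tq_3": 0.3, "eff_tq_15": 0.3, "eff_scan": 1.0,
        }
        subj = small_rat_subjects[0]
        out_q = ne.BrainStructure(small_rat_forcings, placement=mc.Placement.ON_QOUT)
        in_q = ne.BrainStructure(small_rat_forcings, placement=mc.Placement.ON_QIN)
        f_out = out_q.predict(params, subj)
        f_in = in_q.predict(params, subj)
        m = out_q.mask(subj)
        scan1 = subj.scan_idx[m] == 1
        pre_tq = scan1 & (subj.times[m] < 60.0)
        np.testing.assert_allclose(f_out[pre_tq], f_in[pre_tq], rtol=1e-9)
        assert not np.allclose(f_out[~pre_tq], f_in[~pre_tq], rtol=1e-3)


class TestSubjectsFromDataset:
    def test_roundtrip_preserves_counts_and_design(self, small_rat_study, small_rat_subjects):
        _, ds, _ = small_rat_study
        assert len(small_rat_subjects) == len(ds.subject_ids)
        subj = small_rat_subjects[0]
        assert set(subj.scans) == {1, 2}
        assert subj.scans[1].tariquidar[0].start == 60.0
        assert subj.scans[1].duration == 140.0
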