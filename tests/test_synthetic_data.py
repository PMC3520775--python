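"""Study generator: designs, rosters, noise structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from petpop import model_core as mc
from petpop import nlme_engine as ne
from petpop import synthetic_data as sd


class TestStudyFactories:
    def test_default_rat_roster_has_21_subjects(self):
        tpl = sd.make_rat_study(seed=0)
        assert tpl.n_subjects == 21
        counts = {}
        for s in tpl.subjects:
            counts[(s.group, s.tq_dose)] = counts.get((s.group, s.tq_dose), 0) + 1
        assert counts == {
            ("control", 3.0): 7, ("control", 15.0): 4,
            ("post_SE", 3.0): 5, ("post_SE", 15.0): 5,
        }

    def test_rat_scan_windows_and_tariquidar_timing(self):
        tpl = sd.make_rat_study(seed=0)
        scan1, scan2 = tpl.scans
        assert scan1.duration == 140.0 and scan2.duration == 60.0
        assert scan1.tq_start == 60.0 and scan1.tq_duration == 1.0
        assert tpl.inter_scan_gap_min == 120.0
        assert scan1.frames[0] > 0 and scan1.frames[-1] < 140.0

    def test_default_human_roster(self):
        tpl = sd.make_human_study(seed=0)
        assert tpl.n_subjects == 5
        scan1, scan2 = tpl.scans
        assert (scan1.duration, scan2.duration) == (120.0, 40.0)
        assert scan1.tq_start == 40.0 and scan1.tq_duration == 30.0

    def test_roster_is_deterministic_under_seed(self):
        a = sd.make_rat_study(seed=5)
        b = sd.make_rat_study(seed=5)
        assert a.subjects == b.subjects

    def test_rat_body_weight_distribution(self):
        tpl = sd.make_rat_study(n_per_group=(3000, 1, 1, 1), seed=3)
        bw = [s.body_weight_g for s in tpl.subjects if s.subject_id.startswith("naive_3_")]
        assert np.mean(bw) == pytest.approx(260.0, abs=0.5)
        assert np.std(bw) == pytest.approx(5.0, abs=0.5)

    def test_human_injected_activity_distribution(self):
        tpl = sd.make_human_study(n=3000, seed=4)
        act = [s.injected_kbq[0] for s in tpl.subjects]
        assert np.mean(act) == pytest.approx(379_000.0, rel=2e-3)

    def test_invalid_counts_rejected(self):
        with pytest.raises(mc.ModelError):
            sd.make_rat_study(n_per_group=(0, 4, 5, 5))
        with pytest.raises(mc.ModelError):
            sd.make_human_study(n=0)


@pytest.fixture(scope="module")
def tiny_template():
    return sd.make_rat_study(n_per_group=(2, 1, 1, 1), seed=8, frame_scheme="coarse")


class TestSimulateDataset:
    def test_noise_free_simulation_equals_model_prediction(self, tiny_template, rat_true_model):
        tm = sd.TrueModel(
            plasma=rat_true_model.plasma, brain=rat_true_model.brain,
            effs=rat_true_model.effs,
            iiv=[], sigma_plasma=0.0, sigma_brain=0.0,
        )
        ds = sd.simulate_dataset(tiny_template, tm, seed=1)
        sub = ds.observations[
            (ds.observations["subject_id"] == "naive_3_01")
            & (ds.observations["scan"] == 1)
        ]
        design = ds.subjects[
            (ds.subjects["subject_id"] == "naive_3_01") & (ds.subjects["scan"] == 1)
        ].iloc[0]
        dose = mc.DoseEvent(design["injected_kbq"], 0.0, design["inj_duration_min"])
        plasma = sub[sub["obs_type"] == "plasma"]
        expected = mc.simulate_plasma(
            tm.plasma, [dose], plasma["time_min"].to_numpy()
        ).values
        np.testing.assert_allclose(plasma["value"].to_numpy(), expected, rtol=1e-10)
        brain = sub[sub["obs_type"] == "brain:WB"]
        modes = mc.plasma_modes(tm.plasma, [dose], 140.0)
        ev = [mc.TariquidarEvent(3.0, 60.0, 1.0)]
        expected_b = mc.simulate_brain(
            tm.brain["WB"], tm.effs, modes, ev, 1, brain["time_min"].to_numpy()
        ).values
        np.testing.assert_allclose(brain["value"].to_numpy(), expected_b, rtol=1e-10)

    def test_proportional_noise_magnitude(self, rat_true_model):
        tpl = sd.make_rat_study(n_per_group=(6, 5, 5, 5), seed=2, frame_scheme="coarse")
        tm = sd.TrueModel(
            plasma=rat_true_model.plasma, brain=rat_true_model.brain,
            effs=rat_true_model.effs, iiv=[], sigma_plasma=0.01, sigma_brain=0.4,
        )
        noisy = sd.simulate_dataset(tpl, tm, seed=3)
        clean = sd.simulate_dataset(
            tpl,
            sd.TrueModel(plasma=tm.plasma, brain=tm.brain, effs=tm.effs,
                         iiv=[], sigma_plasma=0.0, sigma_brain=0.0),
            seed=99,
        )
        mask = noisy.observations["obs_type"] == "brain:WB"
        f = clean.observations.loc[mask, "value"].to_numpy()
        y = noisy.observations.loc[mask, "value"].to_numpy()
        rel = (y - f) / f
        assert np.std(rel) == pytest.approx(0.4, abs=0.03)

    def test_same_seed_gives_identical_dataset(self, tiny_template, rat_true_model):
        a = sd.simulate_dataset(tiny_template, rat_true_model, seed=42)
        b = sd.simulate_dataset(tiny_template, rat_true_model, seed=42)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_no_negative_observations(self, tiny_template, rat_true_model):
        tm = sd.TrueModel(
            plasma=rat_true_model.plasma, brain=rat_true_model.brain,
            effs=rat_true_model.effs, iiv=rat_true_model.iiv,
            sigma_plasma=1.5, sigma_brain=1.5,
        )
        ds = sd.simulate_dataset(tiny_template, tm, seed=5)
        assert (ds.observations["value"] >= 0).all()

    def test_every_subject_scan_has_both_streams(self, tiny_template, rat_true_model):
        ds = sd.simulate_dataset(tiny_template, rat_true_model, seed=6)
        counts = ds.observations.groupby(["subject_id", "scan", "obs_type"]).size()
        for sid in ds.subject_ids:
            for scan in (1, 2):
                assert counts[(sid, scan, "plasma")] > 0
                assert counts[(sid, scan, "brain:WB")] > 0


class TestInterIndividualVariability:
    def test_lognormal_cv_matches_theory(self):
        omega = 0.162
        blocks = [ne.IIVBlock(("cl",), omega)]
        rng = np.random.default_rng(10)
        vals = [
            sd._apply_iiv({"cl": 16.4}, blocks, rng.normal(0, 1, 1) * omega)["cl"]
            for _ in range(10_000)
        ]
        cv = np.std(vals) / np.mean(vals)
        assert cv == pytest.approx(np.sqrt(np.exp(omega**2) - 1.0), rel=0.05)

    def test_shared_eta_block_moves_parameters_together(self):
        blocks = [ne.IIVBlock(("vc", "cl", "q2"), 0.3), ne.IIVBlock(("vp1",), 0.2)]
        etas = np.array([0.37, -0.52])
        base = {"vc": 38.8, "cl": 16.4, "q2": 22.3, "vp1": 141.0}
        ind = sd._apply_iiv(base, blocks, etas)
        assert ind["vc"] / base["vc"] == pytest.approx(ind["cl"] / base["cl"], rel=1e-14)
        assert ind["vc"] / base["vc"] == pytest.approx(ind["q2"] / base["q2"], rel=1e-14)
        assert ind["vp1"] / base["vp1"] == pytest.approx(np.exp(-0.52), rel=1e-14)

    def test_negative_sigma_rejected(self, rat_true_model):
        with pytest.raises(mc.ModelError):
            sd.TrueModel(
                plasma=rat_true_model.plasma, brain=rat_true_model.brain,
                effs=rat_true_model.effs, iiv=[], sigma_plasma=-0.1, sigma_brain=0.4,
            )
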