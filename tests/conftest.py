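"""Shared fixtures: reference parameter sets and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from petpop import model_core as mc
from petpop import nlme_engine as ne
from petpop import reference
from petpop import synthetic_data as sd


@pytest.fixture(scope="session")
def rat_plasma() -> mc.PlasmaParams:
    return reference.reference_plasma_params("rat")


@pytest.fixture(scope="session")
def rat_brain_wb() -> mc.BrainParams:
    return reference.reference_brain_params("rat", "WB", "all_data")


@pytest.fixture(scope="session")
def rat_effects() -> mc.CovariateEffects:
    return reference.reference_covariate_effects("rat", "WB", "all_data")


@pytest.fixture(scope="session")
def rat_true_model() -> sd.TrueModel:
    return sd.default_rat_true_model()


@pytest.fixture(scope="session")
def small_rat_study(rat_true_model):
    """A 6-rat study with coarse frames, plus the realized individual truth."""
    tpl = sd.make_rat_study(n_per_group=(2, 1, 2, 1), seed=11, frame_scheme="coarse")
    ds, truth = sd.simulate_dataset(tpl, rat_true_model, seed=12, return_truth=True)
    return tpl, ds, truth


@pytest.fixture(scope="session")
def small_rat_subjects(small_rat_study):
    _, ds, _ = small_rat_study
    return ne.subjects_from_dataset(ds)


def true_plasma_forcings(subjects, truth) -> dict[str, mc.PlasmaParams]:
    """Individual plasma parameters realized in the simulation."""
    return {
        s.subject_id: mc.PlasmaParams(
            vc=truth[s.subject_id]["vc"], vp1=truth[s.subject_id]["vp1"],
            vp2=truth[s.subject_id]["vp2"], cl=truth[s.subject_id]["cl"],
            q1=truth[s.subject_id]["q1"], q2=truth[s.subject_id]["q2"],
        )
        for s in subjects
    }


@pytest.fixture(scope="session")
def small_rat_forcings(small_rat_study, small_rat_subjects):
    _, _, truth = small_rat_study
    return true_plasma_forcings(small_rat_subjects, truth)
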