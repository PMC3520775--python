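"""Synthetic paired-scan PET studies with the statistical structure the analysis assumes.

The generator reproduces the two study designs analyzed by the package:

* the rat design — 21 animals in four groups (naive / 48-h post status
  epilepticus, crossed with tariquidar 3 or 15 mg/kg), a 140-min baseline
  scan with the tracer given as a short intravenous bolus at t = 0 and
  tariquidar as a 60-s bolus at 60 min, followed by a 60-min post-inhibition
  scan started 2 h after tariquidar;
* the human design — 5 healthy volunteers, 120- and 40-min scans, tariquidar
  2 mg/kg infused over 30 min starting at 40 min into the baseline scan,
  with the second scan 2 h 50 min after the end of the infusion.

Body weights, injected activities and injection durations are drawn from
the group means and SDs reported for the original studies (truncated at
zero).  True parameters default to the published population estimates;
inter-individual variability is lognormal with the reported plasma omegas
and a conventional 20% CV on the brain transport clearances; residual
error is proportional with the reported SDs.  Observations are the model
predictions at frame midpoints times ``(1 + eps)``, ``eps ~ N(0, sigma^2)``,
clipped at zero (activity concentrations cannot be negative).

Each scan starts from zero tracer amounts: the inter-scan gap is about six
carbon-11 half-lives, and the curves are decay-corrected per scan.

The PET frame schedule is not part of the published designs; the default
here is a conventional dynamic schedule (12 x 10 s, 6 x 30 s, 5 x 60 s,
then 5-min frames), with a coarser variant for quick simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .model_core import (
    BrainParams,
    CovariateEffects,
    DoseEvent,
    ModelError,
    Placement,
    PlasmaParams,
    TariquidarEvent,
    plasma_modes,
    simulate_brain,
    eval_modes,
)
from .nlme_engine import IIVBlock

MBQ = 1000.0  # kBq per MBq
SEC = 1.0 / 60.0  # min per second


# ---------------------------------------------------------------------------
# Design containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalSpec:
    """Mean +/- SD of a positive design quantity."""

    mean: float
    sd: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd < 0:
            raise ModelError("sd must be non-negative")
        x = rng.normal(self.mean, self.sd, size=n)
        while np.any(x <= 0):  # truncate at zero; rare for the given designs
            bad = x <= 0
            x[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
        return x


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group of a study."""

    name: str
    group: str  # "control" | "post_SE"
    tq_dose: float
    n: int
    body_weight_g: NormalSpec
    injected_kbq: tuple[NormalSpec, NormalSpec]
    inj_duration_min: tuple[NormalSpec, NormalSpec]


@dataclass(frozen=True)
class ScanSpec:
    """Timing of one scan, shared by all subjects of a study."""

    index: int
    duration: float
    tq_start: float | None
    tq_duration: float | None
    frames: np.ndarray  # frame midpoints, min


@dataclass(frozen=True)
class SubjectDesign:
    subject_id: str
    species: str
    group: str
    tq_dose: float
    body_weight_g: float
    injected_kbq: tuple[float, float]
    inj_duration_min: tuple[float, float]


@dataclass
class StudyTemplate:
    """Full study design: groups, scan timing, and the sampled roster."""

    species: str
    groups: list[GroupSpec]
    scans: list[ScanSpec]
    subjects: list[SubjectDesign]
    inter_scan_gap_min: float

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def frame_midpoints(duration: float, scheme: str = "default") -> np.ndarray:
    """Frame midpoints (min) of a dynamic scan of the given duration."""
    if scheme == "default":
        durations = [10 * SEC] * 12 + [30 * SEC] * 6 + [1.0] * 5
        tail = 5.0
    elif scheme == "coarse":
        durations = [20 * SEC] * 6 + [1.0] * 4
        tail = 5.0
    elif scheme == "sparse":
        durations = [30 * SEC] * 4 + [2.0] * 2
        tail = 10.0
    else:
        raise ModelError(f"unknown frame scheme {scheme!r}")
    t = float(np.sum(durations))
    while t + tail <= duration + 1e-9:
        durations.append(tail)
        t += tail
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return 0.5 * (edges[:-1] + edges[1:])


# ---------------------------------------------------------------------------
# Study factories
# ---------------------------------------------------------------------------

_RAT_GROUPS = (
    # name, group, dose, (bw), (act1, act2) MBq, (inj1, inj2) sec
    ("naive_3", "control", 3.0, (260, 5), ((97, 27), (93, 27)), ((18, 7), (18, 6))),
    ("naive_15", "control", 15.0, (307, 18), ((88, 17), (101, 28)), ((39, 10), (36, 5))),
    ("se_3", "post_SE", 3.0, (234, 14), ((84, 20), (91, 9)), ((19, 2), (16, 2))),
    ("se_15", "post_SE", 15.0, (247, 16), ((94, 25), (92, 16)), ((25, 11), (32, 18))),
)


def make_rat_study(
    n_per_group: Sequence[int] = (7, 4, 5, 5),
    seed: int | None = 0,
    frame_scheme: str = "default",
) -> StudyTemplate:
    """Rat study template and roster (defaults reproduce the published design)."""
    if len(n_per_group) != 4 or any(n < 1 for n in n_per_group):
        raise ModelError("n_per_group must be four counts >= 1")
    rng = np.random.default_rng(seed)
    groups = []
    subjects = []
    for (name, grp, dose, bw, acts, injs), n in zip(_RAT_GROUPS, n_per_group):
        spec = GroupSpec(
            name=name, group=grp, tq_dose=dose, n=int(n),
            body_weight_g=NormalSpec(*bw),
            injected_kbq=(
                NormalSpec(acts[0][0] * MBQ, acts[0][1] * MBQ),
                NormalSpec(acts[1][0] * MBQ, acts[1][1] * MBQ),
            ),
            inj_duration_min=(
                NormalSpec(injs[0][0] * SEC, injs[0][1] * SEC),
                NormalSpec(injs[1][0] * SEC, injs[1][1] * SEC),
            ),
        )
        groups.append(spec)
        bw_draw = spec.body_weight_g.draw(rng, n)
        a1 = spec.injected_kbq[0].draw(rng, n)
        a2 = spec.injected_kbq[1].draw(rng, n)
        d1 = spec.inj_duration_min[0].draw(rng, n)
        d2 = spec.inj_duration_min[1].draw(rng, n)
        for i in range(n):
            subjects.append(
                SubjectDesign(
                    subject_id=f"{name}_{i + 1:02d}",
                    species="rat", group=grp, tq_dose=dose,
                    body_weight_g=float(bw_draw[i]),
                    injected_kbq=(float(a1[i]), float(a2[i])),
                    inj_duration_min=(float(d1[i]), float(d2[i])),
                )
            )
    scans = [
        ScanSpec(1, 140.0, tq_start=60.0, tq_duration=1.0,
                 frames=frame_midpoints(140.0, frame_scheme)),
        ScanSpec(2, 60.0, tq_start=None, tq_duration=None,
                 frames=frame_midpoints(60.0, frame_scheme)),
    ]
    return StudyTemplate("rat", groups, scans, subjects, inter_scan_gap_min=120.0)


def make_human_study(
    n: int = 5, seed: int | None = 0, frame_scheme: str = "default"
) -> StudyTemplate:
    """Human study template and roster (five healthy volunteers by default)."""
    if n < 1:
        raise ModelError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spec = GroupSpec(
        name="healthy", group="control", tq_dose=2.0, n=int(n),
        body_weight_g=NormalSpec(74.0 * 1000.0, 5.0 * 1000.0),
        injected_kbq=(NormalSpec(379 * MBQ, 11 * MBQ), NormalSpec(389 * MBQ, 15 * MBQ)),
        inj_duration_min=(NormalSpec(51 * SEC, 10 * SEC), NormalSpec(43 * SEC, 11 * SEC)),
    )
    bw = spec.body_weight_g.draw(rng, n)
    a1 = spec.injected_kbq[0].draw(rng, n)
    a2 = spec.injected_kbq[1].draw(rng, n)
    d1 = spec.inj_duration_min[0].draw(rng, n)
    d2 = spec.inj_duration_min[1].draw(rng, n)
    subjects = [
        SubjectDesign(
            subject_id=f"vol_{i + 1:02d}", species="human", group="control",
            tq_dose=2.0, body_weight_g=float(bw[i]),
            injected_kbq=(float(a1[i]), float(a2[i])),
            inj_duration_min=(float(d1[i]), float(d2[i])),
        )
        for i in range(n)
    ]
    scans = [
        ScanSpec(1, 120.0, tq_start=40.0, tq_duration=30.0,
                 frames=frame_midpoints(120.0, frame_scheme)),
        ScanSpec(2, 40.0, tq_start=None, tq_duration=None,
                 frames=frame_midpoints(40.0, frame_scheme)),
    ]
    return StudyTemplate("human", [spec], scans, subjects, inter_scan_gap_min=170.0)


# ---------------------------------------------------------------------------
# True model
# ---------------------------------------------------------------------------


@dataclass
class TrueModel:
    """Ground-truth population model used to simulate observations."""

    plasma: PlasmaParams
    brain: dict[str, BrainParams]
    effs: CovariateEffects
    iiv: list[IIVBlock]
    sigma_plasma: float
    sigma_brain: float

    def __post_init__(self) -> None:
        # zero is allowed (noise-free simulation); negative is not
        if self.sigma_plasma < 0 or self.sigma_brain < 0:
            raise ModelError("residual error SDs must be non-negative")


#: default between-subject CV on the brain transport clearances (the
#: original reports give no brain IIV; 20% is a conventional magnitude)
DEFAULT_BRAIN_OMEGA = 0.2


def default_rat_true_model(
    regions: Sequence[str] = ("WB",), variant: str = "all_data"
) -> TrueModel:
    """Rat ground truth seeded from the published population estimates."""
    plasma_df = reference.load_plasma_estimates("rat")
    brain = {r: reference.reference_brain_params("rat", r, variant) for r in regions}
    effs = reference.reference_covariate_effects("rat", regions[0], variant)
    brain_df = reference.load_brain_estimates("rat", variant)
    return TrueModel(
        plasma=reference.reference_plasma_params("rat"),
        brain=brain,
        effs=effs,
        iiv=[
            IIVBlock(("vc", "cl", "q2"), float(plasma_df.loc["vc", "iiv_sd"])),
            IIVBlock(("vp1", "q1"), float(plasma_df.loc["vp1", "iiv_sd"])),
            IIVBlock(("qin",), DEFAULT_BRAIN_OMEGA),
            IIVBlock(("qout",), DEFAULT_BRAIN_OMEGA),
        ],
        sigma_plasma=float(plasma_df.loc["resid_plasma", "estimate"]),
        sigma_brain=float(brain_df.loc[regions[0], "resid_brain"]),
    )


def default_human_true_model(variant: str = "all_data") -> TrueModel:
    """Human ground truth; same IIV structure as the rat model."""
    plasma_df = reference.load_plasma_estimates("human")
    brain_df = reference.load_brain_estimates("human", variant)
    return TrueModel(
        plasma=reference.reference_plasma_params("human"),
        brain={"WB": reference.reference_brain_params("human", "WB", variant)},
        effs=reference.reference_covariate_effects("human", "WB", variant),
        iiv=[
            IIVBlock(("vc", "cl", "q2"), 0.162),
            IIVBlock(("vp1", "q1"), 0.169),
            IIVBlock(("qin",), DEFAULT_BRAIN_OMEGA),
            IIVBlock(("qout",), DEFAULT_BRAIN_OMEGA),
        ],
        sigma_plasma=float(plasma_df.loc["resid_plasma", "estimate"]),
        sigma_brain=float(brain_df.loc["WB", "resid_brain"]),
    )


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

OBS_COLUMNS = ("subject_id", "scan", "time_min", "obs_type", "value")
SUBJECT_COLUMNS = (
    "subject_id", "scan", "species", "group", "tq_dose_mg_kg", "body_weight_g",
    "injected_kbq", "inj_duration_min", "scan_duration_min",
    "tq_start_min", "tq_duration_min",
)


@dataclass
class Dataset:
    """Long-format study data: observations plus per-subject-scan design."""

    observations: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(OBS_COLUMNS) - set(self.observations.columns)
        if missing:
            raise ModelError(f"observations missing columns: {sorted(missing)}")
        missing = set(SUBJECT_COLUMNS) - set(self.subjects.columns)
        if missing:
            raise ModelError(f"subjects missing columns: {sorted(missing)}")
        key = self.observations[["subject_id", "scan", "time_min", "obs_type"]]
        if key.duplicated().any():
            raise ModelError("duplicate (subject, scan, time, obs_type) records")
        if not np.all(np.isfinite(self.observations["value"].to_numpy(float))):
            raise ModelError("non-finite observation values")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects["subject_id"].unique())

    def to_long(self) -> pd.DataFrame:
        """Denormalized single-table form (one row per observation)."""
        return self.observations.merge(self.subjects, on=["subject_id", "scan"], how="left")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "Dataset":
        obs = df[list(OBS_COLUMNS)].copy()
        subj = df[list(SUBJECT_COLUMNS)].drop_duplicates().reset_index(drop=True)
        return cls(obs, subj)


def _apply_iiv(
    base: Mapping[str, float], iiv: Sequence[IIVBlock], etas: np.ndarray
) -> dict[str, float]:
    p = dict(base)
    for i, b in enumerate(iiv):
        for nm in b.names:
            if nm in p:
                p[nm] = p[nm] * float(np.exp(etas[i]))
    return p


def simulate_dataset(
    template: StudyTemplate,
    true_model: TrueModel,
    seed: int | None = 0,
    return_truth: bool = False,
) -> Dataset | tuple[Dataset, dict[str, dict[str, float]]]:
    """Simulate noisy plasma and brain observations for every subject and scan.

    With ``return_truth=True`` also returns each subject's realized
    individual parameters (plasma and brain, after the eta draws), useful
    for parameter-recovery simulation studies.
    """
    rng = np.random.default_rng(seed)
    omegas = np.asarray([b.omega for b in true_model.iiv], dtype=float)
    obs_rows = []
    subj_rows = []
    truth: dict[str, dict[str, float]] = {}
    for design in template.subjects:
        etas = rng.normal(0.0, 1.0, size=len(omegas)) * omegas
        plasma_base = {
            "vc": true_model.plasma.vc, "vp1": true_model.plasma.vp1,
            "vp2": true_model.plasma.vp2, "cl": true_model.plasma.cl,
            "q1": true_model.plasma.q1, "q2": true_model.plasma.q2,
        }
        pp_ind = PlasmaParams(**_apply_iiv(plasma_base, true_model.iiv, etas))
        if return_truth:
            rec = _apply_iiv(plasma_base, true_model.iiv, etas)
            for region, bp in true_model.brain.items():
                bb = _apply_iiv(
                    {"vbr1": bp.vbr1, "vbr2": bp.vbr2, "qin": bp.qin,
                     "qout": bp.qout, "qbr": bp.qbr},
                    true_model.iiv, etas,
                )
                rec.update({f"{k}:{region}" if len(true_model.brain) > 1 else k: v
                            for k, v in bb.items()})
            rec["etas"] = etas.copy()
            truth[design.subject_id] = rec
        for scan in template.scans:
            inj = design.injected_kbq[scan.index - 1]
            dur = design.inj_duration_min[scan.index - 1]
            dose = DoseEvent(inj, 0.0, dur)
            tq_events: list[TariquidarEvent] = []
            if scan.tq_start is not None:
                tq_events = [TariquidarEvent(design.tq_dose, scan.tq_start, scan.tq_duration)]
            elif scan.index == 2:
                # carries the scan-1 treatment into the post-inhibition scan
                tq_events = [TariquidarEvent(design.tq_dose, 0.0, 1.0)] if design.tq_dose else []
            t_end = max(scan.duration, scan.frames[-1])
            modes = plasma_modes(pp_ind, [dose], t_end)
            f_plasma = np.maximum(eval_modes(modes, scan.frames), 0.0)
            eps = rng.normal(0.0, true_model.sigma_plasma, size=len(scan.frames))
            y_plasma = np.clip(f_plasma * (1.0 + eps), 0.0, None)
            obs_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": design.subject_id, "scan": scan.index,
                        "time_min": scan.frames, "obs_type": "plasma",
                        "value": y_plasma,
                    }
                )
            )
            for region, bp in true_model.brain.items():
                brain_base = {"vbr1": bp.vbr1, "vbr2": bp.vbr2, "qin": bp.qin,
                              "qout": bp.qout, "qbr": bp.qbr}
                bi = _apply_iiv(brain_base, true_model.iiv, etas)
                if design.group == "post_SE":
                    bi["vbr1"] *= true_model.effs.eff_se
                bp_ind = BrainParams(
                    vbr1=bi["vbr1"], vbr2=bi["vbr2"], qin=bi["qin"],
                    qout=bi["qout"], qbr=bi["qbr"], vbr2_fixed=bp.vbr2_fixed,
                )
                # scan-2 inhibition state: tariquidar given in scan 1
                if scan.index == 2 and design.tq_dose:
                    ev = [TariquidarEvent(design.tq_dose, 0.0, 1.0)]
                else:
                    ev = tq_events
                tac = simulate_brain(
                    bp_ind, true_model.effs, modes, ev, scan.index, scan.frames
                )
                eps = rng.normal(0.0, true_model.sigma_brain, size=len(scan.frames))
                y_brain = np.clip(tac.values * (1.0 + eps), 0.0, None)
                obs_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": design.subject_id, "scan": scan.index,
                            "time_min": scan.frames, "obs_type": f"brain:{region}",
                            "value": y_brain,
                        }
                    )
                )
            subj_rows.append(
                {
                    "subject_id": design.subject_id, "scan": scan.index,
                    "species": design.species, "group": design.group,
                    "tq_dose_mg_kg": design.tq_dose,
                    "body_weight_g": design.body_weight_g,
                    "injected_kbq": inj, "inj_duration_min": dur,
                    "scan_duration_min": scan.duration,
                    "tq_start_min": scan.tq_start if scan.tq_start is not None else np.nan,
                    "tq_duration_min": scan.tq_duration if scan.tq_duration is not None else np.nan,
                }
            )
    dataset = Dataset(pd.concat(obs_rows, ignore_index=True), pd.DataFrame(subj_rows))
    if return_truth:
        return dataset, truth
    return dataset
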