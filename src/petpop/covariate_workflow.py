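"""Hypothesis-driven model building: stepwise covariate selection and the
influx-versus-efflux placement comparison.

Nested models are compared on the change in objective function value
(OFV, -2 log-likelihood): a drop of at least the chi-square quantile for
the added degrees of freedom is significant.  Covariates are added by
forward selection (most significant first) and then challenged by backward
deletion, by default at the same significance level.

The transport-placement question — does P-gp inhibition increase influx or
decrease efflux? — is a comparison of two *non-nested* alternatives with
equal parameter counts; the model with the lower OFV is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .model_core import ModelError, Placement
from .nlme_engine import FitResult, PopulationModel, SubjectData, fit_population

SUPPORTED_P_LEVELS = (0.05, 0.01, 0.001)


def lrt_threshold(p_level: float, df: int = 1) -> float:
    """Chi-square OFV-drop threshold for a likelihood-ratio test.

    For one degree of freedom: 3.84 (p < 0.05), 6.63 (p < 0.01),
    10.83 (p < 0.001).
    """
    if p_level not in SUPPORTED_P_LEVELS:
        raise ModelError(f"unsupported p level {p_level!r}; use one of {SUPPORTED_P_LEVELS}")
    if df < 1:
        raise ModelError("df must be >= 1")
    return float(scipy.stats.chi2.ppf(1.0 - p_level, df))


@dataclass(frozen=True)
class Candidate:
    """A covariate-parameter hypothesis to test.

    ``params`` are the theta names the candidate adds (all freed together,
    so a structured candidate like tariquidar-effect-plus-scan-effect is a
    single test with df = len(params)); ``init`` gives starting values.
    """

    name: str
    params: tuple[str, ...]
    init: Mapping[str, float] | None = None

    def df(self) -> int:
        return len(self.params)


@dataclass
class SelectionStep:
    phase: str  # "forward" | "backward"
    candidate: str
    delta_ofv: float
    threshold: float
    decision: str  # "added" | "rejected" | "removed" | "retained" | "skipped"


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_model: PopulationModel | None = None
    final_fit: FitResult | None = None
    selected: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "phase": s.phase, "candidate": s.candidate,
                    "delta_ofv": s.delta_ofv, "threshold": s.threshold,
                    "decision": s.decision,
                }
                for s in self.steps
            ]
        )


def _with_candidate(model: PopulationModel, cand: Candidate) -> PopulationModel:
    m = model.copy()
    for p in cand.params:
        m.theta[p] = float((cand.init or {}).get(p, 1.0))
        m.fixed.discard(p)
    m.name = f"{model.name}+{cand.name}" if model.name else cand.name
    return m


def _without_candidate(model: PopulationModel, cand: Candidate) -> PopulationModel:
    m = model.copy()
    for p in cand.params:
        m.theta.pop(p, None)
        m.fixed.discard(p)
    return m


def stepwise_select(
    subjects: Sequence[SubjectData],
    base_model: PopulationModel,
    candidates: Sequence[Candidate],
    forward_p: float = 0.05,
    backward_p: float | None = None,
    **fit_kwargs,
) -> SelectionTrace:
    """Forward-addition / backward-deletion covariate selection on the OFV.

    Candidates are tested one at a time; in each forward round the candidate
    with the largest significant OFV drop is added (ties broken
    lexicographically by name).  Backward deletion then removes any included
    covariate whose deletion raises the OFV by less than the backward
    threshold.  A failed member fit skips that candidate with a logged step.
    """
    backward_p = forward_p if backward_p is None else backward_p
    trace = SelectionTrace()
    memo: dict[tuple, FitResult | None] = {}

    def _fit(model: PopulationModel) -> FitResult | None:
        key = (frozenset(model.theta), frozenset(model.fixed))
        if key not in memo:
            try:
                memo[key] = fit_population(subjects, model, **fit_kwargs)
            except (ModelError, FloatingPointError):
                memo[key] = None
        return memo[key]

    current = base_model.copy()
    current_fit = _fit(current)
    if current_fit is None or not current_fit.success:
        raise ModelError("base model fit failed")
    remaining = sorted(candidates, key=lambda c: c.name)
    included: list[Candidate] = []

    while remaining:
        results = []
        for cand in remaining:
            thr = lrt_threshold(forward_p, cand.df())
            fit = _fit(_with_candidate(current, cand))
            if fit is None or not fit.success:
                trace.steps.append(
                    SelectionStep("forward", cand.name, np.nan, thr, "skipped")
                )
                continue
            results.append((cand, current_fit.ofv - fit.ofv, thr, fit))
        best = None
        for cand, dofv, thr, fit in results:
            if dofv >= thr and (best is None or dofv > best[1]):
                best = (cand, dofv, thr, fit)
        for cand, dofv, thr, fit in results:
            if best is not None and cand is best[0]:
                continue
            trace.steps.append(SelectionStep("forward", cand.name, dofv, thr, "rejected"))
        if best is None:
            break
        cand, dofv, thr, fit = best
        trace.steps.append(SelectionStep("forward", cand.name, dofv, thr, "added"))
        included.append(cand)
        remaining = [c for c in remaining if c is not cand]
        current, current_fit = fit.model, fit

    # backward deletion, least-harmful first, until all survivors are needed
    changed = True
    while changed and included:
        changed = False
        results = []
        for cand in sorted(included, key=lambda c: c.name):
            thr = lrt_threshold(backward_p, cand.df())
            fit = _fit(_without_candidate(current, cand))
            if fit is None or not fit.success:
                trace.steps.append(
                    SelectionStep("backward", cand.name, np.nan, thr, "skipped")
                )
                continue
            results.append((cand, fit.ofv - current_fit.ofv, thr, fit))
        weakest = None
        for cand, dofv, thr, fit in results:
            if dofv < thr and (weakest is None or dofv < weakest[1]):
                weakest = (cand, dofv, thr, fit)
        for cand, dofv, thr, fit in results:
            if weakest is not None and cand is weakest[0]:
                continue
            trace.steps.append(SelectionStep("backward", cand.name, dofv, thr, "retained"))
        if weakest is not None:
            cand, dofv, thr, fit = weakest
            trace.steps.append(SelectionStep("backward", cand.name, dofv, thr, "removed"))
            included = [c for c in included if c is not cand]
            current, current_fit = fit.model, fit
            changed = True

    trace.final_model = current
    trace.final_fit = current_fit
    trace.selected = [c.name for c in included]
    return trace


@dataclass
class PlacementComparison:
    ofv_on_qout: float | None
    ofv_on_qin: float | None
    preferred: str  # "on_Qout" | "on_Qin" | "inconclusive"
    fits: dict[str, FitResult] = field(default_factory=dict)

    @property
    def delta_ofv(self) -> float | None:
        if self.ofv_on_qout is None or self.ofv_on_qin is None:
            return None
        return self.ofv_on_qout - self.ofv_on_qin


def compare_transport_placement(
    subjects: Sequence[SubjectData],
    model_template: PopulationModel,
    **fit_kwargs,
) -> PlacementComparison:
    """Fit the inhibition effect on efflux vs on influx; prefer the lower OFV.

    The two models are non-nested alternatives with identical dimension,
    fitted to the identical dataset; the comparison is inconclusive if
    either fit fails.
    """
    fits: dict[str, FitResult] = {}
    ofvs: dict[str, float | None] = {}
    for placement in (Placement.ON_QOUT, Placement.ON_QIN):
        m = model_template.copy()
        m.structure = model_template.structure.with_placement(placement)
        m.name = f"{model_template.name}_{placement.value}"
        try:
            fit = fit_population(subjects, m, **fit_kwargs)
        except (ModelError, FloatingPointError):
            fit = None
        if fit is not None and fit.success:
            fits[placement.value] = fit
            ofvs[placement.value] = fit.ofv
        else:
            ofvs[placement.value] = None
    qout, qin = ofvs[Placement.ON_QOUT.value], ofvs[Placement.ON_QIN.value]
    if qout is None or qin is None:
        preferred = "inconclusive"
    else:
        preferred = Placement.ON_QOUT.value if qout <= qin else Placement.ON_QIN.value
    return PlacementComparison(qout, qin, preferred, fits)
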