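"""Nonlinear mixed-effects estimation for the tracer kinetic models.

The marginal likelihood of each subject's data is approximated by a
Laplace-class method: the subject's random effects (etas) are optimized to
the mode of the joint density, and the integral over etas is corrected with
the log-determinant of the curvature there.  Two curvature choices are
offered: ``"focei"`` (the default) uses a Gauss-Newton / expected-information
approximation built from the sensitivities of the prediction to the etas,
evaluated with the proportional residual variance at the conditional
estimates (first-order conditional with interaction); ``"laplace"`` uses the
exact finite-difference Hessian of the joint negative log density.  When the
Gauss-Newton curvature is not positive definite the engine falls back to the
Laplace Hessian.

The objective function value (OFV) is -2 times the approximate marginal
log-likelihood summed over subjects; lower is better, and differences
between nested models are compared with chi-square thresholds.

Inter-individual variability is lognormal: each parameter in a shared-eta
block is multiplied by ``exp(eta)`` with ``eta ~ N(0, omega^2)``.  Residual
error is proportional, with a separate sigma per observation stream
(plasma / brain).

The population analysis is sequential, as is standard for PET tracer data:
the plasma model is fitted first; the brain model is then fitted with each
subject's plasma parameters fixed at their empirical-Bayes values, the
individual plasma curve acting as the forcing function of the brain system.

Parameters are estimated on the log scale (enforcing positivity) with a
bounded quasi-Newton outer optimizer.  Default tolerances: 1e-8 on the
inner eta gradient, 1e-6 (relative) on the outer objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from . import model_core as mc
from .model_core import (
    BrainParams,
    CovariateEffects,
    DoseEvent,
    ModelError,
    Placement,
    PlasmaParams,
    TariquidarEvent,
)

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY_OFV = 1e12


def tq_effect_name(dose_group: float) -> str:
    """Theta name of the tariquidar effect for a dose group (mg/kg)."""
    return f"eff_tq_{dose_group:g}"


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanDesign:
    """Dosing and timing of one scan of one subject."""

    index: int
    duration: float
    doses: tuple[DoseEvent, ...]
    tariquidar: tuple[TariquidarEvent, ...]


@dataclass
class SubjectData:
    """One subject's design and long-format observations (sorted)."""

    subject_id: str
    group: str
    tq_dose: float | None
    body_weight_g: float
    scans: dict[int, ScanDesign]
    times: np.ndarray
    scan_idx: np.ndarray
    obs_type: np.ndarray
    y: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.y)


def subjects_from_dataset(dataset: Any) -> list[SubjectData]:
    """Build per-subject containers from a long-format Dataset.

    ``dataset`` needs ``observations`` (subject_id, scan, time_min, obs_type,
    value) and ``subjects`` (one row per subject-scan with the design
    columns) DataFrames; the Dataset class of ``synthetic_data`` and the CSV
    reader of ``io_reporting`` both provide them.
    """
    obs = dataset.observations.sort_values(
        ["subject_id", "scan", "obs_type", "time_min"], kind="mergesort"
    )
    out: list[SubjectData] = []
    for sid, sub in dataset.subjects.groupby("subject_id", sort=True):
        scans: dict[int, ScanDesign] = {}
        for _, row in sub.iterrows():
            scan = int(row["scan"])
            doses = (DoseEvent(row["injected_kbq"], 0.0, row["inj_duration_min"]),)
            tq: tuple[TariquidarEvent, ...] = ()
            if np.isfinite(row.get("tq_start_min", np.nan)):
                tq = (
                    TariquidarEvent(
                        float(row["tq_dose_mg_kg"]),
                        float(row["tq_start_min"]),
                        float(row["tq_duration_min"]),
                    ),
                )
            scans[scan] = ScanDesign(scan, float(row["scan_duration_min"]), doses, tq)
        o = obs[obs["subject_id"] == sid]
        first = sub.iloc[0]
        tq_dose = float(first["tq_dose_mg_kg"]) if np.isfinite(first.get("tq_dose_mg_kg", np.nan)) else None
        out.append(
            SubjectData(
                subject_id=str(sid),
                group=str(first["group"]),
                tq_dose=tq_dose,
                body_weight_g=float(first["body_weight_g"]),
                scans=scans,
                times=o["time_min"].to_numpy(float),
                scan_idx=o["scan"].to_numpy(int),
                obs_type=o["obs_type"].to_numpy(object),
                y=o["value"].to_numpy(float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Structural models
# ---------------------------------------------------------------------------


class PlasmaStructure:
    """Three-compartment plasma model over the ``plasma`` observation stream."""

    param_names = ("vc", "vp1", "vp2", "cl", "q1", "q2")
    obs_stream = "plasma"

    def __init__(self) -> None:
        self._subj_cache: dict[str, tuple] = {}

    def mask(self, subj: SubjectData) -> np.ndarray:
        return self._layout(subj)[0]

    def _layout(self, subj: SubjectData):
        got = self._subj_cache.get(subj.subject_id)
        if got is None:
            m = np.asarray([t == "plasma" for t in subj.obs_type])
            times, scans = subj.times[m], subj.scan_idx[m]
            per_scan = [
                (scan, np.nonzero(scans == scan)[0], times[scans == scan])
                for scan in subj.scans
                if (scans == scan).any()
            ]
            got = (m, per_scan)
            self._subj_cache[subj.subject_id] = got
        return got

    def predict(self, params: Mapping[str, float], subj: SubjectData) -> np.ndarray:
        pp = PlasmaParams(
            vc=params["vc"], vp1=params["vp1"], vp2=params["vp2"],
            cl=params["cl"], q1=params["q1"], q2=params["q2"],
        )
        m, per_scan = self._layout(subj)
        out = np.empty(int(m.sum()))
        for scan, sel, t in per_scan:
            design = subj.scans[scan]
            modes = mc.plasma_modes(pp, list(design.doses), max(design.duration, t[-1]))
            out[sel] = np.maximum(mc.eval_modes(modes, t), 0.0)
        return out


class _Degenerate(Exception):
    pass


@dataclass
class _SegCache:
    dt: float
    tq_on: bool
    lam: np.ndarray
    coef: np.ndarray
    const: float
    tau: np.ndarray
    exp_ftau: np.ndarray
    exp_lam_dt: np.ndarray
    sel: np.ndarray


try:  # pragma: no cover - exercised indirectly
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _brain_kernel_py(
    vbr1, vbr2, qin, qout, qbr, d_on, on_qout,
    dt, tq_on, const, lam, coef, nk, exp_lam_dt,
    obs_start, obs_end, tau, exp_ftau, out,
):
    """Sequential closed-form propagation of the 2-compartment brain system.

    Batched over P parameter sets (first axis of ``out``); compiled with
    numba when available.  Returns 1 on a degenerate rate matrix.
    """
    P = vbr1.shape[0]
    S = dt.shape[0]
    K = lam.shape[1]
    pp1 = np.empty(K)
    pp2 = np.empty(K)
    for p in range(P):
        x1 = 0.0
        x2 = 0.0
        obsvol = vbr1[p] + vbr2[p]
        for s in range(S):
            d = d_on[p] if tq_on[s] else 1.0
            if on_qout:
                m_out = d
                m_in = 1.0
            else:
                m_out = 1.0
                m_in = d
            b11 = -(m_out * qout[p] + qbr[p]) / vbr1[p]
            b12 = qbr[p] / vbr2[p]
            b21 = qbr[p] / vbr1[p]
            b22 = -qbr[p] / vbr2[p]
            tr = b11 + b22
            det = b11 * b22 - b12 * b21
            disc = tr * tr - 4.0 * det
            if disc <= 1e-14 * tr * tr or det == 0.0:
                return 1
            sq = math.sqrt(disc)
            mu1 = (tr - sq) / 2.0
            mu2 = (tr + sq) / 2.0
            uc = m_in * qin[p] * const[s]
            xc1 = -b22 * uc / det
            xc2 = b21 * uc / det
            s1 = 0.0
            s2 = 0.0
            for k in range(nk[s]):
                la = lam[s, k]
                detk = (la - b11) * (la - b22) - b12 * b21
                guard = 1e-12 * (la * la + 1.0)
                if abs(detk) < guard:
                    detk = guard
                u = m_in * qin[p] * coef[s, k]
                pp1[k] = u * (la - b22) / detk
                pp2[k] = u * b21 / detk
                s1 += pp1[k]
                s2 += pp2[k]
            r1 = x1 - xc1 - s1
            r2 = x2 - xc2 - s2
            dv = b12 * sq
            w1 = ((mu2 - b11) * r1 - b12 * r2) / dv
            w2 = (-(mu1 - b11) * r1 + b12 * r2) / dv
            c1 = w1 * (b12 + mu1 - b11)
            c2 = w2 * (b12 + mu2 - b11)
            for i in range(obs_start[s], obs_end[s]):
                acc = xc1 + xc2
                for k in range(nk[s]):
                    acc += exp_ftau[i, k] * (pp1[k] + pp2[k])
                acc += math.exp(mu1 * tau[i]) * c1 + math.exp(mu2 * tau[i]) * c2
                out[p, i] = acc / obsvol if acc > 0.0 else 0.0
            E1 = math.exp(mu1 * dt[s])
            E2 = math.exp(mu2 * dt[s])
            a1 = 0.0
            a2 = 0.0
            for k in range(nk[s]):
                a1 += exp_lam_dt[s, k] * pp1[k]
                a2 += exp_lam_dt[s, k] * pp2[k]
            x1 = xc1 + a1 + E1 * w1 * b12 + E2 * w2 * b12
            x2 = xc2 + a2 + E1 * w1 * (mu1 - b11) + E2 * w2 * (mu2 - b11)
    return 0


if _HAVE_NUMBA:
    _brain_kernel = _numba.njit(cache=True, fastmath=False)(_brain_kernel_py)
else:  # pragma: no cover
    _brain_kernel = _brain_kernel_py


@dataclass
class _PackedScan:
    """Arrays of one scan's segment cache, laid out for the compiled kernel."""

    dt: np.ndarray
    tq_on: np.ndarray
    const: np.ndarray
    lam: np.ndarray
    coef: np.ndarray
    nk: np.ndarray
    exp_lam_dt: np.ndarray
    obs_start: np.ndarray
    obs_end: np.ndarray
    tau: np.ndarray
    exp_ftau: np.ndarray
    n_obs: int


def _pack_segments(segs: list[_SegCache], n_obs: int) -> _PackedScan | None:
    """Pack segment caches into flat arrays; None if not kernel-compatible."""
    S = len(segs)
    K = max((len(s.lam) for s in segs), default=0)
    if K == 0:
        return None
    for s in segs:
        if np.iscomplexobj(s.lam) or np.iscomplexobj(s.coef):
            return None
        if len(s.sel) and (np.any(np.diff(s.sel) != 1)):
            return None
    dt = np.array([s.dt for s in segs])
    tq_on = np.array([s.tq_on for s in segs], dtype=np.bool_)
    const = np.array([s.const for s in segs])
    lam = np.zeros((S, K))
    coef = np.zeros((S, K))
    nk = np.zeros(S, dtype=np.int64)
    exp_lam_dt = np.zeros((S, K))
    obs_start = np.zeros(S, dtype=np.int64)
    obs_end = np.zeros(S, dtype=np.int64)
    tau = np.zeros(n_obs)
    exp_ftau = np.zeros((n_obs, K))
    for j, s in enumerate(segs):
        k = len(s.lam)
        nk[j] = k
        lam[j, :k] = s.lam
        coef[j, :k] = s.coef
        exp_lam_dt[j, :k] = s.exp_lam_dt
        if len(s.sel):
            obs_start[j] = s.sel[0]
            obs_end[j] = s.sel[-1] + 1
            tau[s.sel] = s.tau
            exp_ftau[s.sel, :k] = s.exp_ftau
        else:
            obs_start[j] = obs_end[j] = 0
    return _PackedScan(dt, tq_on, const, lam, coef, nk, exp_lam_dt,
                       obs_start, obs_end, tau, exp_ftau, n_obs)


class BrainStructure:
    """Two-compartment brain model forced by fixed individual plasma curves.

    ``plasma_by_subject`` maps subject ids to the plasma parameters used as
    each subject's forcing function (typically the empirical-Bayes
    individual estimates of a prior plasma fit; optionally the population
    values).  Covariate effects are picked up from the theta vector by name
    (``eff_tq_<dose>``, ``eff_scan``, ``eff_se``); a name absent from theta
    means the effect is not in the model (factor 1).
    """

    param_names = ("vbr1", "vbr2", "qin", "qout", "qbr")

    def __init__(
        self,
        plasma_by_subject: Mapping[str, PlasmaParams],
        region: str = "WB",
        placement: Placement = Placement.ON_QOUT,
    ) -> None:
        self.plasma_by_subject = dict(plasma_by_subject)
        self.region = region
        self.placement = Placement(placement)
        self._cache: dict[tuple[str, int], list[_SegCache]] = {}

    def with_placement(self, placement: Placement) -> "BrainStructure":
        return BrainStructure(self.plasma_by_subject, self.region, placement)

    @property
    def obs_stream(self) -> str:
        return f"brain:{self.region}"

    def mask(self, subj: SubjectData) -> np.ndarray:
        cache = getattr(self, "_mask_cache", None)
        if cache is None:
            self._mask_cache = cache = {}
        m = cache.get(subj.subject_id)
        if m is None:
            want = {self.obs_stream, "brain"}
            m = np.asarray([t in want for t in subj.obs_type])
            cache[subj.subject_id] = m
        return m

    # -- cache ------------------------------------------------------------

    def _scan_cache(self, subj: SubjectData, scan: int, times: np.ndarray) -> list[_SegCache]:
        key = (subj.subject_id, scan)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        design = subj.scans[scan]
        pp = self.plasma_by_subject[subj.subject_id]
        t_end = max(design.duration, times[-1] if len(times) else 0.0)
        modes = mc.plasma_modes(pp, list(design.doses), t_end)
        if scan == 1 and design.tariquidar:
            tq0 = design.tariquidar[0].start
            pieces = [(0.0, min(tq0, t_end), False), (min(tq0, t_end), t_end, True)]
            pieces = [p for p in pieces if p[1] > p[0] + 1e-12]
        else:
            tq_on = scan == 2 and subj.tq_dose is not None
            pieces = [(0.0, t_end, tq_on)]
        segs: list[_SegCache] = []
        for t0, t1, tq_on in pieces:
            for seg in modes:
                s0, s1 = max(seg.t0, t0), min(seg.t1, t1)
                if s1 <= s0 + 1e-12:
                    continue
                sub = mc._shift_modes(seg, s0, s1)
                last = s1 >= t_end - 1e-12
                sel = np.nonzero(
                    (times >= s0 - 1e-12) & ((times <= s1 + 1e-12) if last else (times < s1))
                )[0]
                tau = np.clip(times[sel] - s0, 0.0, None)
                lam, coef = sub.lam, sub.coef
                if np.abs(lam.imag).max(initial=0.0) < 1e-9:
                    lam, coef = lam.real, coef.real
                segs.append(
                    _SegCache(
                        dt=s1 - s0, tq_on=tq_on, lam=lam, coef=coef,
                        const=float(np.real(sub.const)),
                        tau=tau,
                        exp_ftau=np.exp(np.multiply.outer(tau, lam)),
                        exp_lam_dt=np.exp(lam * (s1 - s0)),
                        sel=sel,
                    )
                )
        self._cache[key] = segs
        return segs

    def _layout(self, subj: SubjectData):
        got = getattr(self, "_subj_cache", None)
        if got is None:
            self._subj_cache = {}
            got = self._subj_cache
        entry = got.get(subj.subject_id)
        if entry is None:
            m = self.mask(subj)
            times, scans = subj.times[m], subj.scan_idx[m]
            per_scan = []
            for scan in subj.scans:
                sel = np.nonzero(scans == scan)[0]
                if len(sel):
                    t = times[sel]
                    segs = self._scan_cache(subj, scan, t)
                    per_scan.append((scan, sel, t, segs, _pack_segments(segs, len(sel))))
            entry = (m, per_scan)
            got[subj.subject_id] = entry
        return entry

    # -- evaluation (batched over parameter sets) -------------------------

    def _eval_scan(
        self, segs: list[_SegCache], vbr1: np.ndarray, vbr2: np.ndarray,
        qin: np.ndarray, qout: np.ndarray, qbr: np.ndarray, d_on: np.ndarray,
        n_obs: int,
    ) -> np.ndarray:
        """States of the brain system for ``P`` parameter sets at once.

        All parameter arguments have shape (P,); returns (P, n_obs).
        """
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return self._eval_scan_impl(segs, vbr1, vbr2, qin, qout, qbr, d_on, n_obs)

    def _eval_scan_impl(
        self, segs, vbr1, vbr2, qin, qout, qbr, d_on, n_obs,
    ) -> np.ndarray:
        P = len(vbr1)
        out = np.empty((P, n_obs))
        x1 = np.zeros(P)
        x2 = np.zeros(P)
        obsvol = vbr1 + vbr2
        on_qout = self.placement is Placement.ON_QOUT
        ones = np.ones(P)
        for seg in segs:
            d = d_on if seg.tq_on else ones
            m_out = d if on_qout else ones
            m_in = ones if on_qout else d
            b11 = -(m_out * qout + qbr) / vbr1
            b12 = qbr / vbr2
            b21 = qbr / vbr1
            b22 = -qbr / vbr2
            tr, det = b11 + b22, b11 * b22 - b12 * b21
            disc = tr * tr - 4.0 * det
            if np.any(disc <= 1e-14 * tr * tr):
                raise _Degenerate
            sq = np.sqrt(disc)
            mu1, mu2 = (tr - sq) / 2.0, (tr + sq) / 2.0
            uc = m_in * qin * seg.const
            xc1, xc2 = -b22 * uc / det, b21 * uc / det
            u = m_in * qin
            la = seg.lam
            detk = (la[None, :] - b11[:, None]) * (la[None, :] - b22[:, None]) - (
                b12 * b21
            )[:, None]
            scale = np.abs(la) ** 2 + 1.0
            tiny = np.abs(detk) < 1e-12 * scale[None, :]
            if np.any(tiny):
                detk = np.where(tiny, 1e-12 * scale[None, :], detk)
            base = (u[:, None] * seg.coef[None, :]) / detk
            p1 = base * (la[None, :] - b22[:, None])
            p2 = base * b21[:, None]
            r1 = x1 - xc1 - p1.sum(axis=1).real
            r2 = x2 - xc2 - p2.sum(axis=1).real
            dv = b12 * sq
            w1 = ((mu2 - b11) * r1 - b12 * r2) / dv
            w2 = (-(mu1 - b11) * r1 + b12 * r2) / dv
            if len(seg.sel):
                e1 = np.exp(np.multiply.outer(mu1, seg.tau))
                e2 = np.exp(np.multiply.outer(mu2, seg.tau))
                vals = (
                    ((p1 + p2) @ seg.exp_ftau.T).real
                    + e1 * (w1 * (b12 + mu1 - b11))[:, None]
                    + e2 * (w2 * (b12 + mu2 - b11))[:, None]
                    + (xc1 + xc2)[:, None]
                )
                out[:, seg.sel] = vals / obsvol[:, None]
            E1, E2 = np.exp(mu1 * seg.dt), np.exp(mu2 * seg.dt)
            ef = seg.exp_lam_dt
            x1 = xc1 + (p1 @ ef).real + E1 * w1 * b12 + E2 * w2 * b12
            x2 = xc2 + (p2 @ ef).real + E1 * w1 * (mu1 - b11) + E2 * w2 * (mu2 - b11)
        return np.maximum(out, 0.0)

    def _d_on(self, params: Mapping[str, float], subj: SubjectData, scan: int) -> float:
        if subj.tq_dose is None:
            return 1.0
        eff = float(params.get(tq_effect_name(subj.tq_dose), 1.0))
        if scan == 2:
            eff *= float(params.get("eff_scan", 1.0))
        return eff

    def predict(self, params: Mapping[str, float], subj: SubjectData) -> np.ndarray:
        return self.predict_batch([params], subj)[0]

    def predict_batch(
        self, params_list: Sequence[Mapping[str, float]], subj: SubjectData
    ) -> np.ndarray:
        P = len(params_list)
        se = subj.group == "post_SE"
        vbr1 = np.asarray(
            [p["vbr1"] * (p.get("eff_se", 1.0) if se else 1.0) for p in params_list]
        )
        vbr2 = np.asarray([p["vbr2"] for p in params_list])
        qin = np.asarray([p["qin"] for p in params_list])
        qout = np.asarray([p["qout"] for p in params_list])
        qbr = np.asarray([p["qbr"] for p in params_list])
        m, per_scan = self._layout(subj)
        out = np.empty((P, int(m.sum())))
        on_qout = self.placement is Placement.ON_QOUT
        for scan, sel, t, segs, packed in per_scan:
            d_on = np.asarray([self._d_on(p, subj, scan) for p in params_list])
            try:
                if packed is not None:
                    scan_out = np.empty((P, packed.n_obs))
                    flag = _brain_kernel(
                        vbr1, vbr2, qin, qout, qbr, d_on, on_qout,
                        packed.dt, packed.tq_on, packed.const, packed.lam,
                        packed.coef, packed.nk, packed.exp_lam_dt,
                        packed.obs_start, packed.obs_end, packed.tau,
                        packed.exp_ftau, scan_out,
                    )
                    if flag:
                        raise _Degenerate
                    out[:, sel] = scan_out
                else:
                    out[:, sel] = self._eval_scan(
                        segs, vbr1, vbr2, qin, qout, qbr, d_on, len(sel)
                    )
            except _Degenerate:
                for k, p in enumerate(params_list):
                    try:
                        out[k, sel] = self._predict_reference(p, subj, scan, t, vbr1[k])
                    except (mc.ModelError, np.linalg.LinAlgError, FloatingPointError,
                            OverflowError):
                        # numerically degenerate trial point; let the caller
                        # reject it through a non-finite likelihood
                        out[k, sel] = np.nan
        return out

    def _predict_reference(self, params, subj, scan, times, vbr1_ind) -> np.ndarray:
        """Slow reference path via model_core.simulate_brain."""
        design = subj.scans[scan]
        bp = BrainParams(
            vbr1=vbr1_ind, vbr2=float(params["vbr2"]), qin=float(params["qin"]),
            qout=float(params["qout"]), qbr=float(params["qbr"]),
        )
        eff_map = {subj.tq_dose: float(params.get(tq_effect_name(subj.tq_dose), 1.0))} if subj.tq_dose is not None else {0.0: 1.0}
        effs = CovariateEffects(
            eff_tariquidar=eff_map,
            eff_scan=float(params.get("eff_scan", 1.0)),
            placement=self.placement,
        )
        events = list(design.tariquidar)
        if scan == 2 and subj.tq_dose is not None and not events:
            # inhibitor was given during scan 1; carry the treatment state over
            events = [TariquidarEvent(subj.tq_dose, 0.0, 1.0)]
        pp = self.plasma_by_subject[subj.subject_id]
        t_end = max(design.duration, times[-1] if len(times) else 0.0)
        modes = mc.plasma_modes(pp, list(design.doses), t_end)
        tac = mc.simulate_brain(bp, effs, modes, events, scan, times)
        return tac.values


# ---------------------------------------------------------------------------
# Population model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IIVBlock:
    """Parameters sharing a single lognormal random effect with SD ``omega``."""

    names: tuple[str, ...]
    omega: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.omega < 0 or not np.isfinite(self.omega):
            raise ModelError("omega must be finite and non-negative")


@dataclass
class PopulationModel:
    """Complete specification of one population model to be fitted."""

    structure: Any
    theta: dict[str, float]
    fixed: set[str] = field(default_factory=set)
    iiv: list[IIVBlock] = field(default_factory=list)
    sigma: dict[str, float] = field(default_factory=dict)
    sigma_fixed: set[str] = field(default_factory=set)
    name: str = ""

    def __post_init__(self) -> None:
        for k, v in self.theta.items():
            if not (np.isfinite(v) and v > 0):
                raise ModelError(f"theta[{k!r}] must be positive and finite")
        for k, v in self.sigma.items():
            if not (np.isfinite(v) and v > 0):
                raise ModelError(f"sigma[{k!r}] must be positive and finite")
        seen: set[str] = set()
        for b in self.iiv:
            if seen & set(b.names):
                raise ModelError("iiv blocks must be disjoint")
            seen |= set(b.names)

    def copy(self) -> "PopulationModel":
        return PopulationModel(
            structure=self.structure, theta=dict(self.theta), fixed=set(self.fixed),
            iiv=list(self.iiv), sigma=dict(self.sigma),
            sigma_fixed=set(self.sigma_fixed), name=self.name,
        )


@dataclass
class FitResult:
    """Estimates, uncertainty, OFV, and empirical-Bayes etas of one fit."""

    model: PopulationModel
    theta: dict[str, float]
    iiv: list[IIVBlock]
    sigma: dict[str, float]
    ofv: float
    etas: dict[str, np.ndarray]
    rse: dict[str, float | None] | None
    convergence: dict[str, Any]

    @property
    def success(self) -> bool:
        return bool(self.convergence.get("success", False))


# ---------------------------------------------------------------------------
# Inner (eta) problem
# ---------------------------------------------------------------------------


def _sigma_row(sigma: Mapping[str, float], obs_type: np.ndarray) -> np.ndarray:
    def key(t: str) -> str:
        return t.split(":")[0]

    return np.asarray([float(sigma[key(t)]) for t in obs_type])


class _SubjectCtx:
    """Prediction closure and data slices for one subject under one model."""

    def __init__(self, subj: SubjectData, structure, blocks, theta, sigma) -> None:
        self.subj = subj
        self.structure = structure
        self.blocks = blocks  # list[(names, omega)]
        self.theta = theta
        m = structure.mask(subj)
        self.y = subj.y[m]
        self.sig = _sigma_row(sigma, subj.obs_type[m])
        self.n_obs = len(self.y)

    def params(self, eta: np.ndarray) -> dict[str, float]:
        p = dict(self.theta)
        for i, (names, _) in enumerate(self.blocks):
            if eta[i] != 0.0:
                fac = math.exp(min(max(eta[i], -50.0), 50.0))
                for nm in names:
                    if nm in p:
                        p[nm] = p[nm] * fac
        return p

    def predict(self, eta: np.ndarray) -> np.ndarray:
        return self.structure.predict(self.params(eta), self.subj)

    def predict_many(self, etas: Sequence[np.ndarray]) -> np.ndarray:
        """Predictions for several eta vectors, batched when supported."""
        params_list = [self.params(e) for e in etas]
        batch = getattr(self.structure, "predict_batch", None)
        if batch is not None:
            return batch(params_list, self.subj)
        return np.stack([self.structure.predict(p, self.subj) for p in params_list])


def _g_value(ctx: _SubjectCtx, f: np.ndarray, eta: np.ndarray, om2: np.ndarray) -> float:
    fs = np.maximum(f, 1e-10)
    r = ctx.y - fs
    v = (ctx.sig * fs) ** 2
    val = 0.5 * float(np.sum(np.log(2.0 * np.pi * v) + r * r / v))
    if len(eta):
        val += 0.5 * float(np.sum(eta * eta / om2))
    return val


def _inner_mode(
    ctx: _SubjectCtx,
    om2: np.ndarray,
    eta0: np.ndarray,
    gtol: float = 1e-8,
    maxiter: int = 40,
    fd_step: float = 1e-4,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Newton/Gauss-Newton optimization of the joint density over eta.

    Returns (eta_hat, g(eta_hat), f(eta_hat), J(eta_hat)).
    """
    d = len(om2)
    eta = eta0.copy()
    f = ctx.predict(eta)
    g = _g_value(ctx, f, eta, om2)
    if not np.isfinite(g):
        eta = np.zeros(d)
        f = ctx.predict(eta)
        g = _g_value(ctx, f, eta, om2)
    J = np.zeros((ctx.n_obs, d))
    for _ in range(maxiter):
        pts = []
        for j in range(d):
            ep = eta.copy()
            ep[j] += fd_step
            em = eta.copy()
            em[j] -= fd_step
            pts.extend([ep, em])
        F = ctx.predict_many(pts)
        for j in range(d):
            J[:, j] = (F[2 * j] - F[2 * j + 1]) / (2.0 * fd_step)
        fs = np.maximum(f, 1e-10)
        r = ctx.y - fs
        s2f2 = (ctx.sig * fs) ** 2
        dg_df = 1.0 / fs - r / s2f2 - r * r / (s2f2 * fs)
        grad = J.T @ dg_df + eta / om2
        if np.linalg.norm(grad) < gtol:
            break
        w = 2.0 / fs**2 + 1.0 / s2f2
        H = (J * w[:, None]).T @ J + np.diag(1.0 / om2)
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = -grad / np.diag(H)
        predicted = -0.5 * float(grad @ step)
        if predicted < 1e-10 * (1.0 + abs(g)):
            break
        # Armijo backtracking line search
        alpha, improved = 1.0, False
        slope = float(grad @ step)
        for _ in range(8):
            trial = eta + alpha * step
            f_t = ctx.predict(trial)
            g_t = _g_value(ctx, f_t, trial, om2)
            if g_t <= g + 1e-4 * alpha * slope:
                eta, f, g = trial, f_t, g_t
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    return eta, g, f, J


def _curvature(
    ctx: _SubjectCtx, om2: np.ndarray, eta: np.ndarray, f: np.ndarray,
    J: np.ndarray, objective: str, fd_step: float = 1e-4,
) -> np.ndarray:
    d = len(om2)
    if objective == "laplace":
        g0 = _g_value(ctx, f, eta, om2)
        basis = np.eye(d) * fd_step
        pts: list[np.ndarray] = []
        for i in range(d):
            pts.extend([eta + basis[i], eta - basis[i]])
            for j in range(i + 1, d):
                pts.extend(
                    [
                        eta + basis[i] + basis[j],
                        eta + basis[i] - basis[j],
                        eta - basis[i] + basis[j],
                        eta - basis[i] - basis[j],
                    ]
                )
        F = ctx.predict_many(pts) if pts else np.empty((0, ctx.n_obs))
        gv = [_g_value(ctx, F[k], pts[k], om2) for k in range(len(pts))]
        H = np.empty((d, d))
        k = 0
        for i in range(d):
            gp, gm = gv[k], gv[k + 1]
            k += 2
            H[i, i] = (gp - 2.0 * g0 + gm) / fd_step**2
            for j in range(i + 1, d):
                gpp, gpm, gmp, gmm = gv[k], gv[k + 1], gv[k + 2], gv[k + 3]
                k += 4
                H[i, j] = H[j, i] = (gpp - gpm - gmp + gmm) / (4.0 * fd_step**2)
        return H
    fs = np.maximum(f, 1e-10)
    s2f2 = (ctx.sig * fs) ** 2
    w = 2.0 / fs**2 + 1.0 / s2f2
    return (J * w[:, None]).T @ J + np.diag(1.0 / om2)


def _safe_logdet(H: np.ndarray) -> float:
    try:
        L = np.linalg.cholesky(H)
        return 2.0 * float(np.sum(np.log(np.diag(L))))
    except np.linalg.LinAlgError:
        ev = np.linalg.eigvalsh(H)
        return float(np.sum(np.log(np.clip(ev, 1e-10, None))))


def subject_ofv(
    ctx: _SubjectCtx,
    omegas: np.ndarray,
    eta0: np.ndarray | None = None,
    objective: str = "focei",
) -> tuple[float, np.ndarray]:
    """-2 log of one subject's approximate marginal likelihood, and its eta mode."""
    active = omegas > 1e-8
    d = int(active.sum())
    if ctx.n_obs == 0:
        return 0.0, np.zeros(len(omegas))
    if d == 0:
        f = ctx.predict(np.zeros(len(omegas)))
        val = 2.0 * _g_value(ctx, f, np.zeros(0), np.zeros(0))
        return val, np.zeros(len(omegas))
    om2 = omegas[active] ** 2
    sub_ctx = _ActiveEtaView(ctx, active)
    start = (eta0[active] if eta0 is not None else np.zeros(d)).astype(float)
    eta, g, f, J = _inner_mode(sub_ctx, om2, start)
    H = _curvature(sub_ctx, om2, eta, f, J, objective)
    try:
        np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        if objective != "laplace":
            H = _curvature(sub_ctx, om2, eta, f, J, "laplace")
    val = 2.0 * g + float(np.sum(np.log(om2))) + _safe_logdet(H)
    eta_full = np.zeros(len(omegas))
    eta_full[active] = eta
    return val, eta_full


class _ActiveEtaView:
    """Restrict a subject context to the etas with non-zero omega."""

    def __init__(self, ctx: _SubjectCtx, active: np.ndarray) -> None:
        self._ctx = ctx
        self._active = active
        self.y = ctx.y
        self.sig = ctx.sig
        self.n_obs = ctx.n_obs

    def predict(self, eta: np.ndarray) -> np.ndarray:
        full = np.zeros(len(self._active))
        full[self._active] = eta
        return self._ctx.predict(full)

    def predict_many(self, etas: Sequence[np.ndarray]) -> np.ndarray:
        fulls = []
        for e in etas:
            full = np.zeros(len(self._active))
            full[self._active] = e
            fulls.append(full)
        return self._ctx.predict_many(fulls)


def _build_ctxs(subjects, model, theta, sigma) -> list[_SubjectCtx]:
    blocks = [(b.names, b.omega) for b in model.iiv]
    return [_SubjectCtx(s, model.structure, blocks, theta, sigma) for s in subjects]


def ofv(
    subjects: Sequence[SubjectData],
    model: PopulationModel,
    theta: Mapping[str, float] | None = None,
    omegas: Sequence[float] | None = None,
    sigma: Mapping[str, float] | None = None,
    objective: str = "focei",
    eta_cache: dict[str, np.ndarray] | None = None,
) -> float:
    """Total objective function value (-2 approximate marginal log-likelihood)."""
    theta = dict(theta if theta is not None else model.theta)
    om = np.asarray(
        omegas if omegas is not None else [b.omega for b in model.iiv], dtype=float
    )
    sig = dict(sigma if sigma is not None else model.sigma)
    total = 0.0
    for ctx in _build_ctxs(subjects, model, theta, sig):
        eta0 = eta_cache.get(ctx.subj.subject_id) if eta_cache is not None else None
        try:
            val, eta = subject_ofv(ctx, om, eta0, objective)
        except (ModelError, FloatingPointError):
            return _PENALTY_OFV
        if not np.isfinite(val):
            return _PENALTY_OFV
        if eta_cache is not None:
            eta_cache[ctx.subj.subject_id] = eta
        total += val
    return total


# ---------------------------------------------------------------------------
# Population fit
# ---------------------------------------------------------------------------


def _pack_free(model: PopulationModel):
    free_theta = [n for n in model.theta if n not in model.fixed]
    free_omega = [
        i for i, b in enumerate(model.iiv) if not b.fixed and b.omega > 1e-8
    ]
    free_sigma = [k for k in sorted(model.sigma) if k not in model.sigma_fixed]
    x0 = np.log(
        np.concatenate(
            [
                [model.theta[n] for n in free_theta],
                [model.iiv[i].omega for i in free_omega],
                [model.sigma[k] for k in free_sigma],
            ]
        )
        if free_theta or free_omega or free_sigma
        else np.ones(0)
    )
    return free_theta, free_omega, free_sigma, x0


def _unpack(model, free_theta, free_omega, free_sigma, x):
    x = np.clip(x, -40.0, 40.0)
    vals = np.exp(x)
    theta = dict(model.theta)
    om = np.asarray([b.omega for b in model.iiv], dtype=float)
    sigma = dict(model.sigma)
    k = 0
    for n in free_theta:
        theta[n] = vals[k]
        k += 1
    for i in free_omega:
        om[i] = vals[k]
        k += 1
    for s in free_sigma:
        sigma[s] = vals[k]
        k += 1
    return theta, om, sigma


def fit_population(
    subjects: Sequence[SubjectData],
    model: PopulationModel,
    objective: str = "focei",
    maxiter: int = 200,
    compute_rse: bool = False,
    verbose: bool = False,
) -> FitResult:
    """Estimate free thetas, omegas, and sigmas by minimizing the OFV.

    Optimization runs on log-transformed parameters; fixed entries are never
    touched.  Relative standard errors (RSE %) are obtained, on request,
    from the inverse observed Hessian of the OFV surface on the log scale
    (delta method: RSE% of a lognormal-scale parameter equals 100 x the SE
    of its log).  A singular Hessian yields ``None`` entries, mirroring the
    convention of reporting "-" when no reliable uncertainty is available.
    """
    free_theta, free_omega, free_sigma, x0 = _pack_free(model)
    eta_cache: dict[str, np.ndarray] = {}
    nfev = [0]

    def fun(x: np.ndarray) -> float:
        nfev[0] += 1
        theta, om, sigma = _unpack(model, free_theta, free_omega, free_sigma, x)
        val = ofv(subjects, model, theta, om, sigma, objective, eta_cache)
        if verbose and nfev[0] % 25 == 0:
            print(f"  nfev={nfev[0]} ofv={val:.3f}")
        return val

    if len(x0):
        res = scipy.optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "eps": 1e-4, "ftol": 1e-9, "gtol": 1e-5},
        )
        # status 1 (iteration/evaluation budget reached) still yields the
        # best point found; only abnormal terminations are failures
        x_hat, success, message = res.x, res.status in (0, 1), str(res.message)
        final_ofv = float(res.fun)
    else:
        x_hat, success, message = x0, True, "nothing to estimate"
        final_ofv = fun(x0)

    theta, om, sigma = _unpack(model, free_theta, free_omega, free_sigma, x_hat)
    # final EBE pass at the optimum
    etas: dict[str, np.ndarray] = {}
    for ctx in _build_ctxs(subjects, model, theta, sigma):
        _, eta = subject_ofv(ctx, om, eta_cache.get(ctx.subj.subject_id), objective)
        etas[ctx.subj.subject_id] = eta

    rse = None
    if compute_rse and len(x_hat):
        rse_vals = _rse_from_hessian(fun, x_hat)
        names = (
            free_theta
            + [f"omega[{'+'.join(model.iiv[i].names)}]" for i in free_omega]
            + [f"sigma[{k}]" for k in free_sigma]
        )
        rse = dict(zip(names, rse_vals))

    iiv = [
        replace(b, omega=float(om[i])) for i, b in enumerate(model.iiv)
    ]
    return FitResult(
        model=model,
        theta=theta,
        iiv=iiv,
        sigma=sigma,
        ofv=final_ofv,
        etas=etas,
        rse=rse,
        convergence={
            "success": success and np.isfinite(final_ofv) and final_ofv < _PENALTY_OFV / 2,
            "message": message,
            "nfev": nfev[0],
        },
    )


def _rse_from_hessian(fun, x_hat: np.ndarray, step: float = 0.02) -> list[float | None]:
    p = len(x_hat)
    H = np.empty((p, p))
    f0 = fun(x_hat)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        fp[i] = fun(x_hat + ei)
        fm[i] = fun(x_hat - ei)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ei[i] = step
            ej = np.zeros(p)
            ej[j] = step
            fpp = fun(x_hat + ei + ej)
            fmm = fun(x_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0 + fmm - fm[i] - fm[j] + f0) / (
                2.0 * step**2
            )
    try:
        cov = 2.0 * np.linalg.inv(H)
        diag = np.diag(cov)
        return [100.0 * math.sqrt(v) if v > 0 else None for v in diag]
    except np.linalg.LinAlgError:
        return [None] * p


# ---------------------------------------------------------------------------
# Empirical Bayes & diagnostics
# ---------------------------------------------------------------------------


def empirical_bayes(
    subj: SubjectData,
    model: PopulationModel,
    theta: Mapping[str, float] | None = None,
    omegas: Sequence[float] | None = None,
    sigma: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Posterior-mode etas for one subject at fixed population estimates."""
    theta = dict(theta if theta is not None else model.theta)
    om = np.asarray(
        omegas if omegas is not None else [b.omega for b in model.iiv], dtype=float
    )
    sigma = dict(sigma if sigma is not None else model.sigma)
    ctx = _build_ctxs([subj], model, theta, sigma)[0]
    _, eta = subject_ofv(ctx, om)
    return eta


def individual_params(
    model: PopulationModel, theta: Mapping[str, float], eta: np.ndarray
) -> dict[str, float]:
    """Individual parameter set implied by the model's eta blocks."""
    p = dict(theta)
    for i, b in enumerate(model.iiv):
        for nm in b.names:
            if nm in p:
                p[nm] = p[nm] * math.exp(eta[i])
    return p


def diagnostics_table(
    fit: FitResult, subjects: Sequence[SubjectData]
) -> pd.DataFrame:
    """Per-observation diagnostics: PRED, IPRED and IWRES.

    PRED is the population prediction (eta = 0); IPRED the individual
    prediction at the empirical-Bayes etas; IWRES = (y - IPRED) /
    (sigma * IPRED), undefined (NaN) where IPRED is zero.
    """
    model = fit.model
    rows = []
    for ctx in _build_ctxs(subjects, model, fit.theta, fit.sigma):
        subj = ctx.subj
        m = model.structure.mask(subj)
        zero = np.zeros(len(model.iiv))
        pred = ctx.predict(zero)
        ipred = ctx.predict(fit.etas.get(subj.subject_id, zero))
        with np.errstate(divide="ignore", invalid="ignore"):
            iwres = np.where(
                ipred > 0, (ctx.y - ipred) / (ctx.sig * np.where(ipred > 0, ipred, 1.0)), np.nan
            )
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj.subject_id,
                    "scan": subj.scan_idx[m],
                    "time_min": subj.times[m],
                    "obs_type": subj.obs_type[m],
                    "dv": ctx.y,
                    "pred": pred,
                    "ipred": ipred,
                    "iwres": iwres,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Sequential plasma -> brain pipeline helpers
# ---------------------------------------------------------------------------


def plasma_params_from_fit(fit: FitResult, subjects: Sequence[SubjectData]) -> dict[str, PlasmaParams]:
    """Empirical-Bayes individual plasma parameters for each subject."""
    out = {}
    for s in subjects:
        eta = fit.etas.get(s.subject_id, np.zeros(len(fit.model.iiv)))
        p = individual_params(fit.model, fit.theta, eta)
        out[s.subject_id] = PlasmaParams(
            vc=p["vc"], vp1=p["vp1"], vp2=p["vp2"], cl=p["cl"], q1=p["q1"], q2=p["q2"]
        )
    return out


def build_plasma_model(
    init: Mapping[str, float] | None = None,
    iiv: Sequence[IIVBlock] | None = None,
    sigma: float = 0.4,
    species: str = "rat",
) -> PopulationModel:
    """Plasma population model with reference-informed defaults as initials."""
    from . import reference

    if init is None:
        pp = reference.reference_plasma_params(species)
        init = dict(vc=pp.vc, vp1=pp.vp1, vp2=pp.vp2, cl=pp.cl, q1=pp.q1, q2=pp.q2)
    if iiv is None:
        iiv = [IIVBlock(("vc", "cl", "q2"), 0.2), IIVBlock(("vp1", "q1"), 0.2)]
    return PopulationModel(
        structure=PlasmaStructure(),
        theta=dict(init),
        iiv=list(iiv),
        sigma={"plasma": float(sigma)},
        name=f"plasma_{species}",
    )


def build_brain_model(
    plasma_by_subject: Mapping[str, PlasmaParams],
    init: Mapping[str, float] | None = None,
    region: str = "WB",
    placement: Placement = Placement.ON_QOUT,
    covariates: Sequence[str] = ("eff_tariquidar", "eff_scan", "eff_se"),
    dose_groups: Sequence[float] = (3.0, 15.0),
    iiv: Sequence[IIVBlock] | None = None,
    sigma: float = 0.4,
    fix_vbr2: float | None = 2.0,
) -> PopulationModel:
    """Brain population model with fixed individual plasma forcings.

    ``covariates`` selects which effects are estimated; ``eff_tariquidar``
    expands to one effect per dose group.  ``fix_vbr2`` fixes the
    peripheral brain volume (2 ml for rats); pass None to estimate it.
    """
    structure = BrainStructure(plasma_by_subject, region=region, placement=placement)
    theta: dict[str, float] = {
        "vbr1": 0.15, "vbr2": fix_vbr2 if fix_vbr2 is not None else 10.0,
        "qin": 3.0, "qout": 3.0, "qbr": 0.12,
    }
    fixed: set[str] = set()
    if fix_vbr2 is not None:
        fixed.add("vbr2")
    if "eff_tariquidar" in covariates:
        for dg in dose_groups:
            theta[tq_effect_name(dg)] = 0.5
    if "eff_scan" in covariates:
        theta["eff_scan"] = 1.0
    if "eff_se" in covariates:
        theta["eff_se"] = 1.0
    if init:
        theta.update({k: float(v) for k, v in init.items()})
    if iiv is None:
        iiv = [IIVBlock(("qin",), 0.2), IIVBlock(("qout",), 0.2)]
    return PopulationModel(
        structure=structure,
        theta=theta,
        fixed=fixed,
        iiv=list(iiv),
        sigma={"brain": float(sigma)},
        name=f"brain_{region}_{Placement(placement).value}",
    )


def fit_sequential(
    subjects: Sequence[SubjectData],
    plasma_model: PopulationModel,
    brain_init: Mapping[str, float] | None = None,
    region: str = "WB",
    placement: Placement = Placement.ON_QOUT,
    dose_groups: Sequence[float] = (3.0, 15.0),
    covariates: Sequence[str] = ("eff_tariquidar", "eff_scan", "eff_se"),
    objective: str = "focei",
    maxiter: int = 200,
    compute_rse: bool = False,
    forcing: str = "individual",
    **brain_kwargs,
) -> tuple[FitResult, FitResult]:
    """The sequential analysis: fit plasma, fix it, then fit the brain model.

    ``forcing`` selects whether each subject's brain model is driven by the
    individual (empirical-Bayes) plasma curve (default) or by the
    population curve (``"population"``).
    """
    plasma_fit = fit_population(
        subjects, plasma_model, objective=objective, maxiter=maxiter,
        compute_rse=compute_rse,
    )
    if forcing == "individual":
        pp = plasma_params_from_fit(plasma_fit, subjects)
    elif forcing == "population":
        t = plasma_fit.theta
        pop = PlasmaParams(vc=t["vc"], vp1=t["vp1"], vp2=t["vp2"],
                           cl=t["cl"], q1=t["q1"], q2=t["q2"])
        pp = {s.subject_id: pop for s in subjects}
    else:
        raise ModelError(f"unknown forcing mode {forcing!r}")
    brain_model = build_brain_model(
        pp, init=brain_init, region=region, placement=placement,
        dose_groups=dose_groups, covariates=covariates, **brain_kwargs,
    )
    brain_fit = fit_population(
        subjects, brain_model, objective=objective, maxiter=maxiter,
        compute_rse=compute_rse,
    )
    return plasma_fit, brain_fit
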