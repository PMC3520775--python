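"""Structural kinetic model for (R)-[11C]verapamil plasma and brain pharmacokinetics.

The tracer distributes over a three-compartment mammillary plasma model
(central volume ``Vc`` with elimination clearance ``CL`` and two peripheral
volumes ``Vp1``/``Vp2`` exchanging with clearances ``Q1``/``Q2``) and a
two-compartment brain model (central brain volume ``Vbr1`` exchanging with
plasma through an influx clearance ``Qin`` and an efflux clearance ``Qout``,
plus a slowly equilibrating peripheral brain volume ``Vbr2`` connected by a
bidirectional clearance ``Qbr``).

P-glycoprotein inhibition by tariquidar enters as a dimensionless
multiplicative effect ``D`` on either the influx or the efflux clearance.
``D`` is the product of two categorical covariates: a dose-group effect
(active from the start of tariquidar administration onward) and a scan
effect (active only in the second, post-inhibition scan).  Status
epilepticus enters as a multiplicative effect on ``Vbr1``.

All differential equations are integrated on drug *amounts* (kBq), with
concentrations defined as amount/volume; this keeps the equations
dimensionally consistent and preserves the equilibrium brain-to-plasma
ratio ``Qin / (D * Qout)``.  The linear systems are solved exactly:
piecewise-constant infusion input and piecewise-linear or sum-of-exponential
forcing functions both admit closed-form solutions via the eigen-decomposition
of the (small) rate matrices, so no step-size error is introduced.

Internal units throughout: minutes, millilitres, kilobecquerels, grams.
Radioactive decay is not modeled; input data are assumed decay-corrected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.linalg


class Unit(str, enum.Enum):
    """Units a time-activity curve can carry."""

    KBQ_PER_ML = "kBq_per_ml"
    SUV = "SUV"


class Placement(str, enum.Enum):
    """Which transport clearance the tariquidar effect multiplies."""

    ON_QIN = "on_Qin"
    ON_QOUT = "on_Qout"


class ModelError(ValueError):
    """Invalid model configuration or parameter values."""


def _check_positive(name: str, value: float, allow_zero: bool = False) -> None:
    if not np.isfinite(value):
        raise ModelError(f"{name} must be finite, got {value!r}")
    if allow_zero:
        if value < 0:
            raise ModelError(f"{name} must be non-negative, got {value!r}")
    elif value <= 0:
        raise ModelError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class PlasmaParams:
    """Three-compartment plasma disposition parameters.

    Volumes in ml, clearances in ml/min.  ``cl`` may be zero (a closed
    system, useful for mass-balance checks); everything else must be
    strictly positive.
    """

    vc: float
    vp1: float
    vp2: float
    cl: float
    q1: float
    q2: float

    def __post_init__(self) -> None:
        for name in ("vc", "vp1", "vp2", "q1", "q2"):
            _check_positive(name, getattr(self, name))
        _check_positive("cl", self.cl, allow_zero=True)

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix for amounts (A_c, A_p1, A_p2)."""
        k_el = self.cl / self.vc
        k12, k21 = self.q1 / self.vc, self.q1 / self.vp1
        k13, k31 = self.q2 / self.vc, self.q2 / self.vp2
        return np.array(
            [
                [-(k_el + k12 + k13), k21, k31],
                [k12, -k21, 0.0],
                [k13, 0.0, -k31],
            ]
        )


@dataclass(frozen=True)
class BrainParams:
    """Two-compartment brain model parameters (volumes ml, clearances ml/min).

    For rats the peripheral brain volume is conventionally fixed at the
    total rat brain volume of 2 ml; ``vbr2_fixed`` records that convention.
    """

    vbr1: float
    vbr2: float
    qin: float
    qout: float
    qbr: float
    vbr2_fixed: bool = True

    def __post_init__(self) -> None:
        for name in ("vbr1", "vbr2", "qin", "qout", "qbr"):
            _check_positive(name, getattr(self, name))

    def rate_matrix(self, d: float, placement: Placement) -> np.ndarray:
        """Rate matrix for amounts (A_br1, A_br2) at inhibition level ``d``.

        The forcing term (influx from plasma) is not part of the matrix.
        """
        m_out = d if placement is Placement.ON_QOUT else 1.0
        return np.array(
            [
                [-(m_out * self.qout + self.qbr) / self.vbr1, self.qbr / self.vbr2],
                [self.qbr / self.vbr1, -self.qbr / self.vbr2],
            ]
        )


@dataclass
class CovariateEffects:
    """Categorical covariate effects entering the brain model.

    ``eff_tariquidar`` maps the tariquidar dose group (mg/kg) to the
    fractional change in transport while the inhibitor is on board;
    ``eff_scan`` is the additional fractional change in the second
    (post-inhibition) scan; ``eff_se`` is the fractional change in Vbr1
    for the post-status-epilepticus group.
    """

    eff_tariquidar: Mapping[float, float]
    eff_scan: float = 1.0
    eff_se: float = 1.0
    placement: Placement = Placement.ON_QOUT

    def __post_init__(self) -> None:
        for dose, eff in self.eff_tariquidar.items():
            _check_positive(f"eff_tariquidar[{dose}]", eff)
        _check_positive("eff_scan", self.eff_scan)
        _check_positive("eff_se", self.eff_se)
        self.placement = Placement(self.placement)


@dataclass(frozen=True)
class DoseEvent:
    """Zero-order tracer infusion into the central plasma compartment."""

    amount_kbq: float
    start: float = 0.0
    duration: float = 0.4
    target: str = "central_plasma"

    def __post_init__(self) -> None:
        _check_positive("amount_kbq", self.amount_kbq, allow_zero=True)
        _check_positive("duration", self.duration)


@dataclass(frozen=True)
class TariquidarEvent:
    """Tariquidar administration during scan 1 (dose group in mg/kg)."""

    dose_group: float
    start: float
    duration: float

    def __post_init__(self) -> None:
        _check_positive("duration", self.duration)


@dataclass
class TimeActivityCurve:
    """A sampled concentration-time series for one region or for plasma."""

    label: str
    times: np.ndarray
    values: np.ndarray
    unit: Unit = Unit.KBQ_PER_ML

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit(self.unit)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ModelError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ModelError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ModelError("values must be finite")


# ---------------------------------------------------------------------------
# Covariate algebra
# ---------------------------------------------------------------------------


def effect_d(
    events: Sequence[TariquidarEvent],
    scan_index: int,
    t: float,
    effs: CovariateEffects,
) -> float:
    """Tariquidar inhibition factor ``D`` at within-scan time ``t``.

    Before any tariquidar administration D = 1.  From the start of the
    administration through the end of scan 1, D equals the dose-group
    effect; throughout scan 2 it equals dose-group effect x scan effect.
    """
    if scan_index not in (1, 2):
        raise ModelError(f"scan_index must be 1 or 2, got {scan_index}")
    if not events:
        return 1.0
    event = events[0]
    if event.dose_group not in effs.eff_tariquidar:
        raise ModelError(
            f"no tariquidar effect configured for dose group {event.dose_group}"
        )
    eff_tq = effs.eff_tariquidar[event.dose_group]
    if scan_index == 2:
        return eff_tq * effs.eff_scan
    return eff_tq if t >= event.start else 1.0


def d_schedule(
    events: Sequence[TariquidarEvent],
    scan_index: int,
    effs: CovariateEffects,
    t_end: float,
) -> list[tuple[float, float, float]]:
    """Piecewise-constant schedule of D over one scan as (t0, t1, D) pieces."""
    if not events or scan_index == 2:
        return [(0.0, t_end, effect_d(events, scan_index, t_end, effs))]
    t_switch = min(events[0].start, t_end)
    pieces = []
    if t_switch > 0:
        pieces.append((0.0, t_switch, 1.0))
    if t_switch < t_end:
        pieces.append((t_switch, t_end, effect_d(events, 1, t_switch, effs)))
    return pieces


def individual_from_population(theta_pop: float, eta: float) -> float:
    """Lognormal individual parameter: theta_pop * exp(eta)."""
    _check_positive("theta_pop", theta_pop)
    return theta_pop * math.exp(eta)


def apply_se_covariate(vbr1_pop: float, eff_se: float, group: str) -> float:
    """Central brain volume for a subject, with the SE effect if applicable."""
    _check_positive("vbr1_pop", vbr1_pop)
    _check_positive("eff_se", eff_se)
    if group not in ("control", "post_SE"):
        raise ModelError(f"unknown group {group!r}; expected 'control' or 'post_SE'")
    return vbr1_pop * eff_se if group == "post_SE" else vbr1_pop


# ---------------------------------------------------------------------------
# Exact linear-system propagation
# ---------------------------------------------------------------------------


def _phi1(x: np.ndarray) -> np.ndarray:
    """(exp(x) - 1)/x with a series for small |x| (valid for complex x)."""
    x = np.asarray(x)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0 + x * x / 6.0, (np.exp(safe) - 1.0) / safe)


def _phi2(x: np.ndarray) -> np.ndarray:
    """(exp(x) - 1 - x)/x^2 with a series for small |x|."""
    x = np.asarray(x)
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    return np.where(
        small,
        0.5 + x / 6.0 + x * x / 24.0,
        (np.exp(safe) - 1.0 - safe) / (safe * safe),
    )


def lti_solve(
    M: np.ndarray,
    b_dir: np.ndarray,
    segments: Sequence[tuple[float, float, float, float]],
    x0: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Exact solution of ``dx/dt = M x + b_dir * u(t)`` with piecewise-linear input.

    ``segments`` is a sorted list of ``(t0, t1, u0, slope)`` pieces covering
    the query window; within a piece ``u(t) = u0 + slope * (t - t0)``.  The
    solution is propagated in the eigenbasis of ``M`` with closed-form
    integrals, so the result is exact for this input class (no step error).
    Returns states of shape ``(len(times), dim)``.
    """
    times = np.asarray(times, dtype=float)
    lam, V = np.linalg.eig(M)
    if np.linalg.cond(V) > 1e10:
        return _lti_solve_expm(M, b_dir, segments, x0, times)
    Vinv = np.linalg.inv(V)
    bt = Vinv @ np.asarray(b_dir, dtype=complex)
    z = Vinv @ np.asarray(x0, dtype=complex)
    out = np.empty((len(times), len(x0)))
    for i, (t0, t1, u0, slope) in enumerate(segments):
        last = i == len(segments) - 1
        sel = (times >= t0 - 1e-12) & ((times <= t1 + 1e-12) if last else (times < t1))
        if sel.any():
            tau = np.clip(times[sel] - t0, 0.0, None)
            xlt = lam[None, :] * tau[:, None]
            zt = (
                np.exp(xlt) * z[None, :]
                + tau[:, None] * _phi1(xlt) * (bt * u0)[None, :]
                + tau[:, None] ** 2 * _phi2(xlt) * (bt * slope)[None, :]
            )
            out[sel] = (zt @ V.T).real
        dt = t1 - t0
        xl = lam * dt
        z = np.exp(xl) * z + dt * _phi1(xl) * bt * u0 + dt * dt * _phi2(xl) * bt * slope
    return out


def _lti_solve_expm(M, b_dir, segments, x0, times) -> np.ndarray:
    """Matrix-exponential fallback (augmented system), exact but slower."""
    d = len(x0)
    out = np.empty((len(times), d))
    x = np.asarray(x0, dtype=float)
    for i, (t0, t1, u0, slope) in enumerate(segments):
        aug = np.zeros((d + 2, d + 2))
        aug[:d, :d] = M
        aug[:d, d] = np.asarray(b_dir, dtype=float)
        aug[d, d + 1] = slope
        last = i == len(segments) - 1
        sel = (times >= t0 - 1e-12) & ((times <= t1 + 1e-12) if last else (times < t1))
        y0 = np.concatenate([x, [u0, 1.0]])
        for j in np.nonzero(sel)[0]:
            tau = max(times[j] - t0, 0.0)
            out[j] = (scipy.linalg.expm(aug * tau) @ y0)[:d]
        x = (scipy.linalg.expm(aug * (t1 - t0)) @ y0)[:d]
    return out


def _infusion_segments(
    doses: Sequence[DoseEvent], t_end: float
) -> list[tuple[float, float, float, float]]:
    """Piecewise-constant infusion-rate pieces (kBq/min) covering [0, t_end]."""
    breaks = {0.0, t_end}
    for d in doses:
        breaks.add(min(d.start, t_end))
        breaks.add(min(d.start + d.duration, t_end))
    knots = sorted(breaks)
    segs = []
    for t0, t1 in zip(knots[:-1], knots[1:]):
        if t1 <= t0:
            continue
        mid = 0.5 * (t0 + t1)
        rate = sum(
            d.amount_kbq / d.duration
            for d in doses
            if d.start <= mid < d.start + d.duration
        )
        segs.append((t0, t1, rate, 0.0))
    return segs


def simulate_plasma(
    params: PlasmaParams,
    doses: Sequence[DoseEvent],
    times: np.ndarray,
) -> TimeActivityCurve:
    """Central plasma concentration (kBq/ml) on ``times``, solved exactly."""
    times = np.asarray(times, dtype=float)
    if len(times) and times[0] < 0:
        raise ModelError("times must be non-negative")
    t_end = float(times[-1]) if len(times) else 0.0
    segs = _infusion_segments(doses, max(t_end, max((d.start + d.duration for d in doses), default=0.0)))
    states = lti_solve(params.rate_matrix(), np.array([1.0, 0.0, 0.0]), segs, np.zeros(3), times)
    conc = states[:, 0] / params.vc
    return TimeActivityCurve("plasma", times, np.maximum(conc, 0.0))


# ---------------------------------------------------------------------------
# Exponential-mode representation of the plasma curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpModeSegment:
    """On [t0, t1]: C(t) = const + sum_k coef[k] * exp(lam[k] * (t - t0))."""

    t0: float
    t1: float
    lam: np.ndarray
    coef: np.ndarray
    const: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        tau = np.asarray(t, dtype=float) - self.t0
        return (self.const + np.exp(np.multiply.outer(tau, self.lam)) @ self.coef).real


def plasma_modes(
    params: PlasmaParams,
    doses: Sequence[DoseEvent],
    t_end: float,
) -> list[ExpModeSegment]:
    """Closed-form plasma concentration as piecewise sums of exponentials.

    Requires ``cl > 0`` (the rate matrix must be invertible).  This is the
    preferred forcing representation for the brain model: the brain response
    to each exponential mode is itself closed form.
    """
    if params.cl <= 0:
        raise ModelError("plasma_modes requires a strictly positive clearance")
    M = params.rate_matrix()
    lam, V = np.linalg.eig(M)
    Vinv = np.linalg.inv(V)
    segs_in = _infusion_segments(doses, t_end)
    out: list[ExpModeSegment] = []
    A = np.zeros(3)
    for t0, t1, rate, _ in segs_in:
        b = np.array([rate, 0.0, 0.0])
        A_star = np.linalg.solve(M, -b)
        w = Vinv @ (A - A_star)
        coef = (V[0, :] * w) / params.vc
        out.append(ExpModeSegment(t0, t1, lam.copy(), coef, float(A_star[0].real) / params.vc))
        A = (A_star + V @ (np.exp(lam * (t1 - t0)) * w)).real
    return out


def eval_modes(modes: Sequence[ExpModeSegment], times: np.ndarray) -> np.ndarray:
    """Evaluate a piecewise exponential-mode curve at sorted query times."""
    times = np.asarray(times, dtype=float)
    out = np.empty(len(times))
    for i, seg in enumerate(modes):
        last = i == len(modes) - 1
        sel = (times >= seg.t0 - 1e-12) & ((times <= seg.t1 + 1e-12) if last else (times < seg.t1))
        if sel.any():
            out[sel] = seg(times[sel])
    return out


def _shift_modes(seg: ExpModeSegment, t0: float, t1: float) -> ExpModeSegment:
    """Restrict a mode segment to [t0, t1] (t0 >= seg.t0), re-anchored at t0."""
    coef = seg.coef * np.exp(seg.lam * (t0 - seg.t0))
    return ExpModeSegment(t0, t1, seg.lam, coef, seg.const)


# ---------------------------------------------------------------------------
# Brain simulation
# ---------------------------------------------------------------------------


def _brain_segment_exp(
    B: np.ndarray,
    influx: float,
    forcing: ExpModeSegment,
    x0: np.ndarray,
    tau: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """States at offsets ``tau`` and at the segment end, for exponential forcing.

    ``influx`` scales the forcing concentration into an amount inflow into
    compartment 1 (units ml/min); ``B`` is the 2x2 amount rate matrix.
    """
    mu, V = np.linalg.eig(B)
    Vinv = np.linalg.inv(V)
    # particular solution for the constant part
    xc = np.linalg.solve(B, -np.array([influx * forcing.const, 0.0]))
    # particular solutions for each exponential mode
    lam = forcing.lam.copy()
    parts = np.zeros((len(lam), 2), dtype=complex)
    for k, lk in enumerate(lam):
        Ak = lk * np.eye(2) - B
        if abs(np.linalg.det(Ak)) < 1e-12 * max(1.0, abs(lk) ** 2):
            lk = lk + 1e-8  # nudge off resonance; negligible for smooth forcings
            Ak = lk * np.eye(2) - B
            lam[k] = lk
        parts[k] = np.linalg.solve(Ak, np.array([influx * forcing.coef[k], 0.0]))
    w = Vinv @ (x0 - xc - parts.sum(axis=0))
    t_all = np.concatenate([tau, [forcing.t1 - forcing.t0]])
    hom = (np.exp(np.multiply.outer(t_all, mu)) * w[None, :]) @ V.T
    part = np.exp(np.multiply.outer(t_all, lam)) @ parts
    states = (hom + part + xc[None, :]).real
    return states[:-1], states[-1]


ForcingType = Sequence[ExpModeSegment] | TimeActivityCurve


def simulate_brain(
    brain: BrainParams,
    effs: CovariateEffects,
    forcing: ForcingType,
    events: Sequence[TariquidarEvent],
    scan_index: int,
    times: np.ndarray,
    obs_volume: float | None = None,
) -> TimeActivityCurve:
    """Observed brain concentration on ``times`` for one scan.

    ``forcing`` is the plasma concentration, either as exponential-mode
    segments (exact closed form, the default pipeline path) or as a sampled
    curve (treated as piecewise linear and solved exactly for that input).
    The observed signal is total brain amount divided by ``obs_volume``
    (default ``vbr1 + vbr2``), which makes the equilibrium brain-to-plasma
    ratio equal ``qin / (D * qout)``.
    """
    times = np.asarray(times, dtype=float)
    t_end = float(times[-1]) if len(times) else 0.0
    if obs_volume is None:
        obs_volume = brain.vbr1 + brain.vbr2
    _check_positive("obs_volume", obs_volume)
    dsched = d_schedule(events, scan_index, effs, t_end)
    if isinstance(forcing, TimeActivityCurve):
        states = _simulate_brain_pl(brain, effs, forcing, dsched, times)
    else:
        states = _simulate_brain_modes(brain, effs, list(forcing), dsched, times)
    conc = np.maximum(states.sum(axis=1) / obs_volume, 0.0)
    return TimeActivityCurve("brain", times, conc)


def _simulate_brain_modes(brain, effs, modes, dsched, times) -> np.ndarray:
    if modes and modes[-1].t1 < (times[-1] if len(times) else 0.0) - 1e-9:
        raise ModelError("plasma forcing does not cover the requested times")
    out = np.empty((len(times), 2))
    x = np.zeros(2)
    # combined breakpoints of D pieces and forcing segments
    for t0, t1, d in dsched:
        m_in = d if effs.placement is Placement.ON_QIN else 1.0
        B = brain.rate_matrix(d, effs.placement)
        influx = m_in * brain.qin
        for seg in modes:
            s0, s1 = max(seg.t0, t0), min(seg.t1, t1)
            if s1 <= s0 + 1e-12:
                continue
            sub = _shift_modes(seg, s0, s1)
            last = s1 >= dsched[-1][1] - 1e-12
            sel = (times >= s0 - 1e-12) & ((times <= s1 + 1e-12) if last else (times < s1))
            tau = np.clip(times[sel] - s0, 0.0, None)
            vals, x = _brain_segment_exp(B, influx, sub, x, tau)
            out[sel] = vals
    return out


def _simulate_brain_pl(brain, effs, tac, dsched, times) -> np.ndarray:
    if tac.unit is not Unit.KBQ_PER_ML:
        raise ModelError("plasma forcing curve must be in kBq/ml")
    t_end = times[-1] if len(times) else 0.0
    if tac.times[-1] < t_end - 1e-9 or tac.times[0] > 1e-9:
        raise ModelError("plasma forcing does not cover the requested times")
    out = np.empty((len(times), 2))
    x = np.zeros(2)
    b_dir = np.array([1.0, 0.0])
    for t0, t1, d in dsched:
        m_in = d if effs.placement is Placement.ON_QIN else 1.0
        B = brain.rate_matrix(d, effs.placement)
        influx = m_in * brain.qin
        knots = np.unique(np.concatenate([[t0, t1], tac.times[(tac.times > t0) & (tac.times < t1)]]))
        cvals = np.interp(knots, tac.times, tac.values) * influx
        segs = [
            (knots[i], knots[i + 1], cvals[i], (cvals[i + 1] - cvals[i]) / (knots[i + 1] - knots[i]))
            for i in range(len(knots) - 1)
        ]
        last = t1 >= dsched[-1][1] - 1e-12
        sel = (times >= t0 - 1e-12) & ((times <= t1 + 1e-12) if last else (times < t1))
        if sel.any():
            out[sel] = lti_solve(B, b_dir, segs, x, times[sel])
        end = lti_solve(B, b_dir, segs, x, np.array([t1]))
        x = end[0]
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def suv_normalize(
    tac: TimeActivityCurve, injected_kbq: float, body_weight_g: float
) -> TimeActivityCurve:
    """Standardized uptake value: concentration / (injected activity / body weight)."""
    _check_positive("injected_kbq", injected_kbq)
    _check_positive("body_weight_g", body_weight_g)
    if tac.unit is not Unit.KBQ_PER_ML:
        raise ModelError("curve is already SUV-normalized")
    return TimeActivityCurve(
        tac.label, tac.times.copy(), tac.values * body_weight_g / injected_kbq, Unit.SUV
    )
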