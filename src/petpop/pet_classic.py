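"""Classic single-subject PET kinetic analyses used as reference methods.

These are the standard per-subject analyses the population model is
compared against: the two-tissue four-rate-constant (2T4K) compartment
model and Logan graphical analysis, both driven by a metabolite-corrected
arterial plasma input function.  A small utility converts whole-blood
curves to plasma using a constant plasma-to-blood ratio (1.29 for
(R)-[11C]verapamil).

Frames acquired during and immediately after P-gp inhibitor administration
violate the steady-parameter assumption of these methods and are excluded
through an explicit exclusion window (by convention, from the start of the
tariquidar administration to the end of the baseline scan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize
from scipy.integrate import cumulative_trapezoid

from .model_core import ModelError, TimeActivityCurve, Unit, lti_solve

#: published mean plasma-to-blood activity ratio of (R)-[11C]verapamil
PLASMA_TO_BLOOD_RATIO = 1.29


@dataclass(frozen=True)
class TwoTissueParams:
    """2T4K rate constants and the implied total volume of distribution."""

    k1: float  # ml plasma / (ml tissue x min)
    k2: float  # 1/min
    k3: float  # 1/min
    k4: float  # 1/min
    converged: bool = True

    @property
    def vt(self) -> float:
        """VT = K1/k2 * (1 + k3/k4)."""
        if self.k2 <= 0:
            return math.nan
        ratio = self.k3 / self.k4 if self.k4 > 0 else 0.0
        return self.k1 / self.k2 * (1.0 + ratio)


@dataclass(frozen=True)
class LoganResult:
    slope: float  # VT, ml/ml
    intercept: float  # min
    t_star: float
    r_squared: float
    n_points: int


def plasma_from_blood(
    blood_tac: TimeActivityCurve, ratio: float = PLASMA_TO_BLOOD_RATIO
) -> TimeActivityCurve:
    """Scale a whole-blood curve to plasma by a constant ratio."""
    if ratio <= 0 or not np.isfinite(ratio):
        raise ModelError("ratio must be positive and finite")
    return TimeActivityCurve(
        "plasma", blood_tac.times.copy(), blood_tac.values * ratio, blood_tac.unit
    )


def _retained(
    times: np.ndarray, exclusion_window: tuple[float, float] | None
) -> np.ndarray:
    if exclusion_window is None:
        return np.ones(len(times), dtype=bool)
    lo, hi = exclusion_window
    return (times < lo) | (times > hi)


def simulate_2t4k(
    params: Sequence[float],
    input_function: TimeActivityCurve,
    times: np.ndarray,
) -> np.ndarray:
    """Tissue concentration of the 2T4K model, exact for a piecewise-linear input."""
    k1, k2, k3, k4 = params
    times = np.asarray(times, dtype=float)
    M = np.array([[-(k2 + k3), k4], [k3, -k4]])
    knots = np.unique(np.concatenate([[0.0], input_function.times, times]))
    u = np.interp(knots, input_function.times, input_function.values, left=0.0) * k1
    segs = [
        (knots[i], knots[i + 1], u[i], (u[i + 1] - u[i]) / (knots[i + 1] - knots[i]))
        for i in range(len(knots) - 1)
    ]
    states = lti_solve(M, np.array([1.0, 0.0]), segs, np.zeros(2), times)
    return states.sum(axis=1)


def fit_2t4k(
    tac: TimeActivityCurve,
    input_function: TimeActivityCurve,
    exclusion_window: tuple[float, float] | None = None,
    inits: Sequence[Sequence[float]] = (
        (0.1, 0.1, 0.05, 0.05),
        (0.5, 0.5, 0.01, 0.01),
        (0.05, 0.02, 0.1, 0.02),
    ),
) -> TwoTissueParams:
    """Least-squares 2T4K fit to the retained frames (uniform weights).

    Rate constants are optimized on the log scale from several starting
    points; the best solution is returned, flagged unconverged if every
    start failed.
    """
    keep = _retained(tac.times, exclusion_window)
    if keep.sum() < 8:
        raise ModelError("need at least 8 frames outside the exclusion window")
    t, y = tac.times[keep], tac.values[keep]
    if input_function.times[-1] < t[-1] - 1e-9:
        raise ModelError("input function does not cover the tissue curve")

    def resid(logp: np.ndarray) -> np.ndarray:
        return simulate_2t4k(np.exp(logp), input_function, t) - y

    best, best_cost = None, np.inf
    # rate constants confined to a broad physiological range (1e-6 .. 1e3)
    bounds = (np.log(1e-6), np.log(1e3))
    for init in inits:
        try:
            res = scipy.optimize.least_squares(
                resid, np.log(init), method="trf", bounds=bounds,
                xtol=1e-12, ftol=1e-12, max_nfev=400,
            )
        except (ValueError, FloatingPointError):
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        return TwoTissueParams(np.nan, np.nan, np.nan, np.nan, converged=False)
    k1, k2, k3, k4 = np.exp(best.x)
    return TwoTissueParams(k1, k2, k3, k4, converged=bool(best.success))


def _logan_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def logan_vt(
    tac: TimeActivityCurve,
    input_function: TimeActivityCurve,
    t_star: float | None = None,
    exclusion_window: tuple[float, float] | None = None,
    r2_threshold: float = 0.99,
) -> LoganResult:
    """Logan graphical analysis: the late-time slope estimates VT.

    The regression is of the normalized integrated tissue curve on the
    normalized integrated plasma curve, over retained frames at ``t >=
    t_star``.  When ``t_star`` is not given, the earliest start time whose
    regression reaches R^2 >= 0.99 (with at least 3 points) is used,
    falling back to the best-R^2 start if none qualifies.
    """
    t, ct = tac.times, tac.values
    # integrate each curve on its own grid, anchored at t = 0 (no tracer
    # before injection); the plasma grid is typically denser around the
    # bolus peak, which dominates its integral
    tp = input_function.times
    cp = input_function.values
    if tp[0] > 0:
        tp, cp = np.concatenate([[0.0], tp]), np.concatenate([[0.0], cp])
    int_cp_grid = cumulative_trapezoid(cp, tp, initial=0.0)
    int_cp = np.interp(t, tp, int_cp_grid)
    tt, ctt = (t, ct) if t[0] == 0 else (np.concatenate([[0.0], t]), np.concatenate([[0.0], ct]))
    int_ct = cumulative_trapezoid(ctt, tt, initial=0.0)
    if t[0] != 0:
        int_ct = int_ct[1:]
    good = _retained(t, exclusion_window) & (ct > 0)
    x_all = int_cp[good] / ct[good]
    y_all = int_ct[good] / ct[good]
    t_good = t[good]

    def fit_from(ts: float):
        m = t_good >= ts - 1e-9
        if m.sum() < 3:
            return None
        slope, intercept, r2 = _logan_regression(x_all[m], y_all[m])
        return LoganResult(slope, intercept, float(ts), r2, int(m.sum()))

    if t_star is not None:
        res = fit_from(t_star)
        if res is None:
            raise ModelError("fewer than 3 retained frames at t >= t_star")
        return res

    candidates = [fit_from(ts) for ts in t_good]
    candidates = [c for c in candidates if c is not None]
    if not candidates:
        raise ModelError("not enough retained frames for Logan analysis")
    for c in candidates:  # earliest start reaching the R^2 criterion
        if c.r_squared >= r2_threshold:
            return c
    return max(candidates, key=lambda c: c.r_squared)
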