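"""Circadian blood-pressure baseline: two-component cosinor production rate
driving a pair of first-order turnover equations.

The untreated systolic and diastolic pressures are modeled as indirect-response
variables

    dSBP/dt = kin_s(t) - kout1 * SBP
    dDBP/dt = kin_d(t) - kout2 * DBP

whose production rates carry a 12-h and a 24-h cosine component

    kin(t) = M + A12 cos(W12 (t + Ta) + O12) + A24 cos(W24 (t + Ta) + O24)

with W12 = 2*pi/12 and W24 = 2*pi/24 fixed.  Time ``t`` is hours since dose
administration; ``Ta`` is the administration time in hours after awakening, so
``t + Ta`` is clock time on the awakening-anchored axis.  Because the system is
linear, the 24-h periodic steady state has the closed form

    BP(t) = M/kout + sum_c A_c / sqrt(kout^2 + W_c^2)
                      * cos(W_c (t + Ta) + O_c - atan(W_c / kout))

which this module uses both to initialize simulations at the periodic orbit and
as an analytic oracle for the numeric integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

W12 = 2.0 * np.pi / 12.0
W24 = 2.0 * np.pi / 24.0


class InvalidParameterError(ValueError):
    """A model parameter is non-finite or violates a structural invariant."""


class UnderDeterminedError(ValueError):
    """Fewer observations than parameters to estimate."""


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the failing time point in ``.t_fail``."""

    def __init__(self, msg: str, t_fail: float | None = None):
        super().__init__(msg)
        self.t_fail = t_fail


@dataclass
class CircadianInput:
    """Cosinor production-rate parameters for one pressure signal.

    M is the mesor (mmHg/h), A12/A24 the 12-h and 24-h amplitudes (mmHg/h),
    O12/O24 the acrophases (rad).  Angular frequencies are fixed at 2*pi/12 and
    2*pi/24.  Nonnegativity of kin(t) for all t requires M >= A12 + A24; that
    is enforced as a fitting bound, not at construction.
    """

    M: float
    A12: float = 0.0
    A24: float = 0.0
    O12: float = 0.0
    O24: float = 0.0

    def __post_init__(self):
        vals = (self.M, self.A12, self.A24, self.O12, self.O24)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite cosinor parameter: {vals}")
        if self.A12 < 0 or self.A24 < 0:
            raise InvalidParameterError("amplitudes must be nonnegative")


@dataclass
class CircadianBPParams:
    """Full baseline: one cosinor input per pressure plus the output rates."""

    kin_s: CircadianInput
    kin_d: CircadianInput
    kout1: float = 1.0
    kout2: float = 1.0

    def __post_init__(self):
        if not (self.kout1 > 0 and self.kout2 > 0):
            raise InvalidParameterError("kout1 and kout2 must be positive")

    def to_dict(self) -> dict:
        return {
            "kin_s": vars(self.kin_s).copy(),
            "kin_d": vars(self.kin_d).copy(),
            "kout1": self.kout1,
            "kout2": self.kout2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircadianBPParams":
        return cls(
            kin_s=CircadianInput(**d["kin_s"]),
            kin_d=CircadianInput(**d["kin_d"]),
            kout1=d["kout1"],
            kout2=d["kout2"],
        )


@dataclass
class ClockConvention:
    """Awakening-anchored clock.

    Times are hours after awakening.  The awake window defaults to [0, 15) and
    the sleep window to [15, 24), i.e. a 9-h night rest; chronological wake
    time defaults to 8 a.m. and bedtime to 11 p.m.
    """

    awakening_clock: float = 8.0
    bedtime_clock: float = 23.0
    sleep_duration: float = 9.0
    awake_window: tuple[float, float] = (0.0, 15.0)
    sleep_window: tuple[float, float] = (15.0, 24.0)

    def __post_init__(self):
        a0, a1 = self.awake_window
        s0, s1 = self.sleep_window
        if not (a0 == 0.0 and a1 == s0 and s1 == 24.0):
            raise InvalidParameterError(
                "awake and sleep windows must partition [0, 24)"
            )

    def is_awake(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau) % 24.0
        return (tau >= self.awake_window[0]) & (tau < self.awake_window[1])

    def to_chronological(self, tau: float) -> float:
        return (self.awakening_clock + tau) % 24.0


def kin_eval(p: CircadianInput, t, Ta: float):
    """Production rate kin(t) (mmHg/h) at time-after-dose ``t`` for dosing
    time ``Ta`` hours after awakening."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("t must be finite")
    tau = t + Ta
    return (
        p.M
        + p.A12 * np.cos(W12 * tau + p.O12)
        + p.A24 * np.cos(W24 * tau + p.O24)
    )


def _ss_single(kin: CircadianInput, kout: float, t, Ta: float):
    """Closed-form 24-h periodic steady state of dBP/dt = kin(t) - kout*BP."""
    t = np.asarray(t, dtype=float)
    tau = t + Ta
    out = kin.M / kout
    for A, W, O in ((kin.A12, W12, kin.O12), (kin.A24, W24, kin.O24)):
        gain = A / math.hypot(kout, W)
        out = out + gain * np.cos(W * tau + O - math.atan2(W, kout))
    return out


def steady_state_bp(p: CircadianBPParams, t, Ta: float = 0.0):
    """Analytic periodic steady state (SBP, DBP) at times ``t`` after dose."""
    return _ss_single(p.kin_s, p.kout1, t, Ta), _ss_single(p.kin_d, p.kout2, t, Ta)


def simulate_baseline(
    p: CircadianBPParams,
    Ta: float = 0.0,
    horizon: float = 24.0,
    init: tuple[float, float] | None = None,
    step: float = 0.05,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Numerically integrate the untreated baseline.

    Returns ``(t, SBP, DBP)`` on a uniform grid of spacing ``step`` covering
    [0, horizon].  When ``init`` is omitted the analytic periodic steady state
    at t=0 is used, so the trajectory is 24-h periodic from the start.
    """
    if horizon < 24.0:
        raise InvalidParameterError("horizon must cover at least one day")
    t_eval = np.arange(0.0, horizon + 0.5 * step, step)
    if init is None:
        s0, d0 = steady_state_bp(p, 0.0, Ta)
        y0 = [float(s0), float(d0)]
    else:
        y0 = [float(init[0]), float(init[1])]

    def rhs(t, y):
        return [
            kin_eval(p.kin_s, t, Ta) - p.kout1 * y[0],
            kin_eval(p.kin_d, t, Ta) - p.kout2 * y[1],
        ]

    sol = solve_ivp(rhs, (0.0, t_eval[-1]), y0, t_eval=t_eval, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"baseline integration failed: {sol.message}",
                               t_fail=float(sol.t[-1]) if sol.t.size else 0.0)
    return sol.t, sol.y[0], sol.y[1]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _wrap_phase(o: np.ndarray | float):
    """Wrap acrophase(s) to [-pi, pi)."""
    return (np.asarray(o) + np.pi) % (2.0 * np.pi) - np.pi


def fit_baseline_arrays(
    t: np.ndarray,
    y: np.ndarray,
    *,
    fix_kout: float | None = 1.0,
    n_starts: int = 20,
    seed: int = 0,
    kout_bounds: tuple[float, float] = (0.01, 100.0),
):
    """Least-squares cosinor fit of one pressure's periodic steady state.

    Returns ``(CircadianInput, kout, sse)``.  With ``fix_kout`` set (default),
    only the five cosinor parameters are estimated; ``fix_kout=None``
    additionally estimates kout within ``kout_bounds`` (note the steady-state
    curve determines kout only through the M >= A12 + A24 bound, so the joint
    fit is degenerate along kout).
    """
    from scipy.optimize import least_squares
    from scipy.stats import qmc

    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pars = 5 if fix_kout is not None else 6
    if t.size < max(7, n_pars):
        raise UnderDeterminedError(
            f"need >= {max(7, n_pars)} points, got {t.size}"
        )

    ybar = float(np.mean(y))
    span = float(np.ptp(y))

    def unpack(x):
        kout = fix_kout if fix_kout is not None else x[5]
        kin = CircadianInput(M=x[0] * kout, A12=x[1], A24=x[2],
                             O12=x[3], O24=x[4])
        return kin, kout

    def resid(x):
        kin, kout = unpack(x)
        return _ss_single(kin, kout, t, 0.0) - y

    # x = [mean_level, A12, A24, O12, O24, (kout)]; amplitudes here are the
    # kin amplitudes, mean_level = M/kout so M tracks kout in the joint fit.
    pad = max(span, 1.0)
    lo = [ybar - pad, 0.0, 0.0, -np.pi, -np.pi]
    hi = [ybar + pad, 60.0 * pad, 60.0 * pad, np.pi, np.pi]
    if fix_kout is None:
        lo.append(kout_bounds[0])
        hi.append(kout_bounds[1])
    lo = np.array(lo)
    hi = np.array(hi)

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(lo), seed=rng)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    # deterministic anchor start: data mean, modest amplitudes, zero phases
    starts[0] = np.array(
        [ybar, 0.2 * span, 0.5 * span, 0.0, 0.0]
        + ([1.0] if fix_kout is None else [])
    )

    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all baseline fit starts failed")
    kin, kout = unpack(best.x)
    kin = replace(kin, O12=float(_wrap_phase(kin.O12)),
                  O24=float(_wrap_phase(kin.O24)))
    sse = float(2.0 * best.cost)
    return kin, float(kout), sse


def fit_baseline(data, clock: ClockConvention | None = None, *,
                 fix_kout: float | None = 1.0, n_starts: int = 20,
                 seed: int = 0):
    """Fit the circadian baseline to a pre-treatment arm dataset.

    ``data`` is an :class:`~chronopkpd.fitting.ArmDataset` (or anything with an
    ``observations`` DataFrame in the tidy dialect) containing SBP and DBP
    rows.  Pre-treatment fits use Ta = 0, so observation times are hours after
    awakening.  Returns ``(CircadianBPParams, gof)`` where ``gof`` maps each
    pressure to its unweighted sum of squared residuals.
    """
    from .estimators import CircadianBaselineRegressor

    obs = data.observations
    est = CircadianBaselineRegressor(fix_kout=fix_kout, n_starts=n_starts,
                                     seed=seed)
    sub = obs[obs["variable"].isin(["SBP", "DBP"])]
    X = np.column_stack([
        sub["t"].to_numpy(float),
        (sub["variable"] == "DBP").to_numpy().astype(float),
    ])
    est.fit(X, sub["mean"].to_numpy(float))
    return est.params_, est.gof_
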