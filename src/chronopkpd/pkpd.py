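"""One-compartment PK-PD models with optional circadian kinetic constants.

Two model structures are supported under repeated once-daily oral dosing:

* non-prodrug (4 ODEs): absorbable amount Xa, plasma concentration C, and the
  two indirect-response pressures SBP/DBP whose production is inhibited by a
  Hill function of C;
* prodrug (5 ODEs): as above plus the active-metabolite concentration Cm,
  formed from C at rate Km and eliminated at Ke2; the Hill inhibition is
  driven by Cm.

Any kinetic constant may carry a 24-h cosine modulation
``Kx(t) = Kx + Ax cos(W24 (t + Ta) + Ox)`` with 0 <= Ax < Kx; at most two
constants per model are circadian (overfitting guard).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._integrate import integrate_cycle
from .baseline import (
    W24,
    CircadianBPParams,
    IntegrationError,
    InvalidParameterError,
    steady_state_bp,
)

NONPRODRUG_RATES = ("Ka", "Ke")
PRODRUG_RATES = ("Ka", "Ke1", "Km", "Ke2")


@dataclass
class PeriodicRate:
    """A first-order kinetic constant, optionally with 24-h cosine modulation."""

    Kx: float
    Ax: float = 0.0
    Ox: float = 0.0

    def __post_init__(self):
        if not (self.Kx > 0):
            raise InvalidParameterError(f"Kx must be positive, got {self.Kx}")
        if self.Ax < 0 or self.Ax >= self.Kx:
            raise InvalidParameterError(
                f"need 0 <= Ax < Kx for positivity, got Ax={self.Ax}, Kx={self.Kx}"
            )

    @property
    def circadian(self) -> bool:
        return self.Ax > 0.0


@dataclass
class DrugConstants:
    """Fixed drug constants: dose (ug), bioavailability F, distribution
    volume Vd (L), IC50 (ug/L), dosing interval (h)."""

    dose: float
    F: float
    Vd: float
    IC50: float
    dosing_interval: float = 24.0

    def __post_init__(self):
        if not (0 < self.F <= 1):
            raise InvalidParameterError("F must be in (0, 1]")
        if self.Vd <= 0 or self.IC50 <= 0 or self.dose <= 0:
            raise InvalidParameterError("dose, Vd and IC50 must be positive")


@dataclass
class EffectParams:
    """Hill inhibition of the BP production rate: Imax * C^n / (IC50^n + C^n)."""

    Imax: float
    n: float = 1.0
    hill_free: bool = False

    def __post_init__(self):
        if not (0.0 <= self.Imax <= 1.0):
            raise InvalidParameterError("Imax must lie in [0, 1]")
        if not (self.n > 0):
            raise InvalidParameterError("Hill coefficient must be positive")


@dataclass
class ModelSpec:
    """Structure + parameters of a non-prodrug or prodrug PK-PD model."""

    kind: str
    rates: dict[str, PeriodicRate]
    drug: DrugConstants
    effect: EffectParams
    baseline: CircadianBPParams

    def __post_init__(self):
        expected = NONPRODRUG_RATES if self.kind == "nonprodrug" else PRODRUG_RATES
        if self.kind not in ("nonprodrug", "prodrug"):
            raise InvalidParameterError(f"unknown model kind {self.kind!r}")
        if set(self.rates) != set(expected):
            raise InvalidParameterError(
                f"{self.kind} model needs rates {set(expected)}, got {set(self.rates)}"
            )
        n_circ = sum(r.circadian for r in self.rates.values())
        if n_circ > 2:
            raise InvalidParameterError(
                "at most two kinetic constants may be circadian"
            )

    @property
    def state_names(self) -> tuple[str, ...]:
        if self.kind == "prodrug":
            return ("Xa", "C", "Cm", "SBP", "DBP")
        return ("Xa", "C", "SBP", "DBP")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "rates": {k: vars(r).copy() for k, r in self.rates.items()},
            "drug": vars(self.drug).copy(),
            "effect": vars(self.effect).copy(),
            "baseline": self.baseline.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            kind=d["kind"],
            rates={k: PeriodicRate(**v) for k, v in d["rates"].items()},
            drug=DrugConstants(**d["drug"]),
            effect=EffectParams(**d["effect"]),
            baseline=CircadianBPParams.from_dict(d["baseline"]),
        )


def rate_eval(r: PeriodicRate, t, Ta: float):
    """Kinetic constant Kx(t) = Kx + Ax cos(W24 (t + Ta) + Ox)."""
    t = np.asarray(t, dtype=float)
    return r.Kx + r.Ax * np.cos(W24 * (t + Ta) + r.Ox)


def inhibition(conc, e: EffectParams, IC50: float):
    """Fractional inhibition Imax * C^n / (IC50^n + C^n), in [0, Imax]."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    cn = np.power(conc, e.n)
    return e.Imax * cn / (IC50 ** e.n + cn)


def bateman(drug: DrugConstants, Ka: float, Ke: float, t):
    """Single-dose one-compartment concentration closed form.

    C(t) = (F dose / Vd) * Ka/(Ka - Ke) * (exp(-Ke t) - exp(-Ka t)); the
    Ka == Ke degenerate limit (F dose / Vd) * K t exp(-K t) is used when
    |Ka - Ke| < 1e-10.
    """
    t = np.asarray(t, dtype=float)
    amp = drug.F * drug.dose / drug.Vd
    if abs(Ka - Ke) < 1e-10:
        k = 0.5 * (Ka + Ke)
        return amp * k * t * np.exp(-k * t)
    return amp * Ka / (Ka - Ke) * (np.exp(-Ke * t) - np.exp(-Ka * t))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _pack(m: ModelSpec):
    K = np.zeros(4)
    A = np.zeros(4)
    O = np.zeros(4)
    if m.kind == "nonprodrug":
        order = {"Ka": 0, "Ke": 1}
        use_metab = 0.0
        K[3] = 1.0  # inert Cm pole, keeps Cm identically 0 given Km = 0
    else:
        order = {"Ka": 0, "Ke1": 1, "Km": 2, "Ke2": 3}
        use_metab = 1.0
    for name, idx in order.items():
        r = m.rates[name]
        K[idx], A[idx], O[idx] = r.Kx, r.Ax, r.Ox
    b = m.baseline
    bp = np.array([
        b.kin_s.M, b.kin_s.A12, b.kin_s.A24, b.kin_s.O12, b.kin_s.O24, b.kout1,
        b.kin_d.M, b.kin_d.A12, b.kin_d.A24, b.kin_d.O12, b.kin_d.O24, b.kout2,
    ])
    eff = np.array([
        m.effect.Imax, m.effect.n, m.drug.IC50,
        m.drug.F / m.drug.Vd, use_metab,
    ])
    return K, A, O, bp, eff


def _rhs_python(t, y, Ta, K, A, O, bp, eff):
    from ._integrate import _deriv

    return list(_deriv.py_func(t, y[0], y[1], y[2], y[3], y[4],
                               Ta, K, A, O, bp, eff))


@dataclass
class Trajectory:
    """Multi-dose simulation output on a uniform grid of time after first dose."""

    t: np.ndarray               # h after first dose
    states: dict[str, np.ndarray]
    Ta: float
    n_doses: int
    kind: str

    @property
    def clock(self) -> np.ndarray:
        """Hours after awakening for each grid time."""
        return (self.t + self.Ta) % 24.0

    def final_cycle(self) -> "Trajectory":
        """The post-last-dose 24-h window (times rebased to [0, 24])."""
        t0 = (self.n_doses - 1) * 24.0
        mask = self.t >= t0 - 1e-9
        return Trajectory(
            t=self.t[mask] - t0,
            states={k: v[mask] for k, v in self.states.items()},
            Ta=self.Ta, n_doses=1, kind=self.kind,
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        clock = self.clock
        for name, vals in self.states.items():
            rows.append(pd.DataFrame({
                "t_after_dose_h": self.t, "clock_h": clock,
                "variable": name, "value": vals,
            }))
        return pd.concat(rows, ignore_index=True)


def simulate_regimen(
    m: ModelSpec,
    Ta: float,
    n_doses: int = 1,
    out_step: float = 0.05,
    method: str = "rk4",
    rk4_substeps: int = 4,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate ``n_doses`` once-daily doses.

    BP starts on the untreated periodic orbit at clock time Ta; Xa jumps by
    the dose at each 24-h dosing event while C (and Cm) are continuous.
    ``method="rk4"`` uses the fixed-step compiled kernel (default sub-step
    0.05/4 = 0.0125 h); ``method="lsoda"`` uses the adaptive scipy solver at
    (rtol, atol).
    """
    if n_doses < 1:
        raise InvalidParameterError("n_doses must be >= 1")
    K, A, O, bp, eff = _pack(m)
    s0, d0 = steady_state_bp(m.baseline, 0.0, Ta)
    y = np.array([0.0, 0.0, 0.0, float(s0), float(d0)])

    tout = np.arange(0.0, 24.0 + 0.5 * out_step, out_step)
    all_t = []
    all_y = []
    for dose_idx in range(n_doses):
        y[0] += m.drug.dose
        t0 = dose_idx * 24.0
        if method == "rk4":
            block = integrate_cycle(y, t0, Ta, tout, rk4_substeps, K, A, O, bp, eff)
        elif method == "lsoda":
            sol = solve_ivp(
                _rhs_python, (t0, t0 + 24.0), y, t_eval=t0 + tout,
                method="LSODA", rtol=rtol, atol=atol,
                args=(Ta, K, A, O, bp, eff),
            )
            if not sol.success:
                raise IntegrationError(
                    f"integration failed at dose {dose_idx}: {sol.message}",
                    t_fail=float(sol.t[-1]) if sol.t.size else t0,
                )
            block = sol.y.T
        else:
            raise ValueError(f"unknown method {method!r}")
        y = block[-1].copy()
        keep = block if dose_idx == n_doses - 1 else block[:-1]
        tkeep = tout if dose_idx == n_doses - 1 else tout[:-1]
        all_t.append(t0 + tkeep)
        all_y.append(keep)

    t = np.concatenate(all_t)
    Y = np.vstack(all_y)
    names = ("Xa", "C", "Cm", "SBP", "DBP")
    states = {n: Y[:, i] for i, n in enumerate(names)}
    if m.kind == "nonprodrug":
        del states["Cm"]
    return Trajectory(t=t, states=states, Ta=Ta, n_doses=n_doses, kind=m.kind)


class SteadyStateWarning(UserWarning):
    """Dose cap reached before inter-cycle convergence; carries the residual."""


def steady_state_window(
    m: ModelSpec,
    Ta: float,
    tol: float = 1e-3,
    max_doses: int = 14,
    out_step: float = 0.05,
    method: str = "rk4",
    rk4_substeps: int = 4,
) -> Trajectory:
    """Dose until consecutive 24-h cycles agree within ``tol`` (max-abs over
    all states on the output grid), then return the final cycle.

    ``tol=inf`` returns the first cycle.  Hitting ``max_doses`` emits a
    :class:`SteadyStateWarning` with the residual, not a failure.
    """
    if not (tol > 0):
        raise InvalidParameterError("tol must be positive")
    K, A, O, bp, eff = _pack(m)
    s0, d0 = steady_state_bp(m.baseline, 0.0, Ta)
    y = np.array([0.0, 0.0, 0.0, float(s0), float(d0)])
    tout = np.arange(0.0, 24.0 + 0.5 * out_step, out_step)

    prev = None
    block = None
    n = 0
    disc = np.inf
    while n < max_doses:
        y[0] += m.drug.dose
        if method == "rk4":
            block = integrate_cycle(y, n * 24.0, Ta, tout, rk4_substeps,
                                    K, A, O, bp, eff)
        else:
            sol = solve_ivp(_rhs_python, (n * 24.0, n * 24.0 + 24.0), y,
                            t_eval=n * 24.0 + tout, method="LSODA",
                            rtol=1e-8, atol=1e-10,
                            args=(Ta, K, A, O, bp, eff))
            if not sol.success:
                raise IntegrationError(
                    f"integration failed at dose {n}: {sol.message}")
            block = sol.y.T
        y = block[-1].copy()
        n += 1
        if prev is not None:
            disc = float(np.max(np.abs(block - prev)))
            if disc < tol:
                break
        elif not np.isfinite(tol):
            break
        prev = block
    else:
        warnings.warn(
            f"steady state not reached after {max_doses} doses "
            f"(inter-cycle residual {disc:.3g})", SteadyStateWarning)

    names = ("Xa", "C", "Cm", "SBP", "DBP")
    states = {nm: block[:, i] for i, nm in enumerate(names)}
    if m.kind == "nonprodrug":
        del states["Cm"]
    return Trajectory(t=tout.copy(), states=states, Ta=Ta, n_doses=1,
                      kind=m.kind)
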