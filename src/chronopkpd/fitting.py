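"""Joint estimation across dosing-time arms, likelihood / AICc, and the
circadian-variant lattice.

The objective is the grand mean of standardized squared residuals over every
(variable, arm, time) observation,

    Fobj = (1 / N_tot) * sum ((y_exp - y_model) / sigma)^2,

with sigma the reported standard error of each mean data point.  The Gaussian
log-likelihood with known sigma and the small-sample-corrected Akaike
criterion follow directly:

    LogL = -(N_tot/2) log 2*pi - sum log sigma - (1/2) sum r^2
    AICc = 2 n_pars - 2 LogL + 2 n_pars (n_pars + 1) / (N_tot - n_pars - 1)

Model variants differ in which kinetic constants carry a 24-h cosine (at most
two) and whether the Hill coefficient is estimated: 8 variants for the
non-prodrug model, 22 for the prodrug model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import CircadianBPParams, InvalidParameterError
from .pkpd import (
    NONPRODRUG_RATES,
    PRODRUG_RATES,
    DrugConstants,
    EffectParams,
    ModelSpec,
    PeriodicRate,
    steady_state_window,
)

VALID_VARIABLES = ("SBP", "DBP", "C", "Cm")

# amplitude/phase parameter names per rate, following cosinor usage
RATE_PARAM_NAMES = {
    "Ka": ("Aa", "Oa"),
    "Ke": ("Ae", "Oe"),
    "Ke1": ("Ae1", "Oe1"),
    "Km": ("Am", "Om"),
    "Ke2": ("Ae2", "Oe2"),
}


class MissingSEError(ValueError):
    """A zero/absent standard error; use ``fill_missing_se`` (2% of mean)."""


@dataclass
class ArmDataset:
    """One dosing-time arm's observed means and standard errors.

    ``observations`` is a tidy DataFrame with columns
    ``variable`` (SBP/DBP/C/Cm), ``t`` (hours after awakening, in [0, 24]),
    ``mean`` and ``se``.
    """

    arm_id: str
    ta: float
    observations: pd.DataFrame

    def __post_init__(self):
        obs = self.observations
        missing = {"variable", "t", "mean", "se"} - set(obs.columns)
        if missing:
            raise InvalidParameterError(f"observations missing columns {missing}")
        bad = ~obs["variable"].isin(VALID_VARIABLES)
        if bad.any():
            raise InvalidParameterError(
                f"unknown variables {sorted(obs.loc[bad, 'variable'].unique())}"
            )
        t = obs["t"].to_numpy(float)
        if np.any(t < 0) or np.any(t > 24):
            raise InvalidParameterError("times must lie in [0, 24]")
        se = obs["se"].to_numpy(float)
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise MissingSEError(
                "every observation needs se > 0; substitute 2% of the mean "
                "via fill_missing_se()"
            )

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def variables(self) -> list[str]:
        return sorted(self.observations["variable"].unique())


def fill_missing_se(obs: pd.DataFrame, frac: float = 0.02) -> pd.DataFrame:
    """Replace missing/zero standard errors by ``frac`` of the mean value."""
    obs = obs.copy()
    se = obs["se"].to_numpy(float) if "se" in obs else np.zeros(len(obs))
    bad = ~np.isfinite(se) | (se <= 0)
    se[bad] = frac * np.abs(obs["mean"].to_numpy(float)[bad])
    obs["se"] = se
    return obs


def stack_observations(data: list[ArmDataset]) -> pd.DataFrame:
    """Concatenate arm observations with arm metadata columns attached."""
    frames = []
    for arm in data:
        f = arm.observations.copy()
        f["arm_id"] = arm.arm_id
        f["ta"] = arm.ta
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Objective, likelihood, information criteria
# ---------------------------------------------------------------------------

def _standardized_residuals(y_model: np.ndarray, data: list[ArmDataset]):
    obs = stack_observations(data)
    y = obs["mean"].to_numpy(float)
    se = obs["se"].to_numpy(float)
    y_model = np.asarray(y_model, dtype=float)
    if y_model.shape != y.shape:
        raise InvalidParameterError(
            f"prediction length {y_model.shape} != observation length {y.shape}"
        )
    return (y - y_model) / se, se


def fobj(y_model: np.ndarray, data: list[ArmDataset]) -> float:
    """Grand mean of standardized squared residuals over all arms."""
    r, _ = _standardized_residuals(y_model, data)
    return float(np.mean(r ** 2))


def loglik(y_model: np.ndarray, data: list[ArmDataset]) -> float:
    """Gaussian log-likelihood with the data's standard errors as known sigma."""
    r, se = _standardized_residuals(y_model, data)
    n = r.size
    return float(-0.5 * n * math.log(2.0 * math.pi)
                 - np.sum(np.log(se)) - 0.5 * np.sum(r ** 2))


def aicc(LogL: float, n_pars: int, N_tot: int) -> float:
    """Corrected Akaike information criterion."""
    if N_tot <= n_pars + 1:
        raise ValueError(
            f"AICc correction undefined for N_tot={N_tot}, n_pars={n_pars}"
        )
    return (2.0 * n_pars - 2.0 * LogL
            + 2.0 * n_pars * (n_pars + 1) / (N_tot - n_pars - 1))


def bic(LogL: float, n_pars: int, N_tot: int) -> float:
    """Bayesian information criterion (auxiliary ranking)."""
    return n_pars * math.log(N_tot) - 2.0 * LogL


# ---------------------------------------------------------------------------
# Variant lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantKey:
    """Which kinetic constants are circadian and whether n is estimated."""

    circadian_set: frozenset
    hill_free: bool
    kind: str = "nonprodrug"

    def __post_init__(self):
        allowed = set(NONPRODRUG_RATES if self.kind == "nonprodrug"
                      else PRODRUG_RATES)
        extra = set(self.circadian_set) - allowed
        if extra:
            raise InvalidParameterError(f"unknown rates {extra} for {self.kind}")
        if len(self.circadian_set) > 2:
            raise InvalidParameterError("at most two circadian rates")

    @property
    def label(self) -> str:
        if not self.circadian_set:
            circ = "No circadian Kx"
        else:
            circ = "Circadian " + " and ".join(sorted(self.circadian_set))
        hill = "n free" if self.hill_free else "n = 1"
        return f"{circ}, {hill}"

    def param_names(self, estimate_fvd: bool = False) -> list[str]:
        rates = NONPRODRUG_RATES if self.kind == "nonprodrug" else PRODRUG_RATES
        names = []
        for r in rates:
            names.append(r)
            if r in self.circadian_set:
                names.extend(RATE_PARAM_NAMES[r])
        names.append("Imax")
        if self.hill_free:
            names.append("n")
        if estimate_fvd:
            names.append("F_over_Vd")
        return names


def variant_lattice(kind: str) -> list[VariantKey]:
    """All admissible variants: 8 for non-prodrug, 22 for prodrug."""
    rates = NONPRODRUG_RATES if kind == "nonprodrug" else PRODRUG_RATES
    max_size = 2
    sets = []
    for size in range(0, max_size + 1):
        for combo in itertools.combinations(rates, size):
            if kind == "nonprodrug" or size <= 2:
                sets.append(frozenset(combo))
    variants = []
    for hill_free in (False, True):
        for s in sets:
            variants.append(VariantKey(circadian_set=s, hill_free=hill_free,
                                       kind=kind))
    return variants


def build_model(
    variant: VariantKey,
    drug: DrugConstants,
    baseline: CircadianBPParams,
    values: dict[str, float],
) -> ModelSpec:
    """Assemble a ModelSpec from named parameter values for one variant.

    ``values`` holds every estimated parameter: each rate's Kx under its rate
    name, amplitudes/acrophases under their cosinor names (Aa/Oa, Ae/Oe, ...),
    Imax, optionally n, and optionally F_over_Vd (applied by rescaling Vd so
    F stays at its configured value).
    """
    from dataclasses import replace as _replace

    rate_names = NONPRODRUG_RATES if variant.kind == "nonprodrug" else PRODRUG_RATES
    rates = {}
    for r in rate_names:
        kx = float(values[r])
        if r in variant.circadian_set:
            an, on = RATE_PARAM_NAMES[r]
            rates[r] = PeriodicRate(kx, float(values.get(an, 0.0)),
                                    float(values.get(on, 0.0)))
        else:
            rates[r] = PeriodicRate(kx)
    eff = EffectParams(Imax=float(values["Imax"]),
                       n=float(values.get("n", 1.0)),
                       hill_free=variant.hill_free)
    d = drug
    if "F_over_Vd" in values:
        d = _replace(drug, Vd=drug.F / float(values["F_over_Vd"]))
    return ModelSpec(kind=variant.kind, rates=rates, drug=d, effect=eff,
                     baseline=baseline)


@dataclass
class FitResult:
    """Outcome of fitting one variant jointly across arms."""

    variant: VariantKey
    params: ModelSpec
    param_values: dict[str, float]
    Fobj: float
    LogL: float
    AICc: float
    BIC: float
    n_pars: int
    N_tot: int
    converged: bool
    seed: int
    n_starts: int = 0
    start_diagnostics: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Prediction at observation times
# ---------------------------------------------------------------------------

def predict_observations(
    m: ModelSpec,
    data: list[ArmDataset],
    *,
    out_step: float = 0.1,
    ss_tol: float = 1e-3,
    max_doses: int = 14,
    method: str = "rk4",
) -> np.ndarray:
    """Model prediction for every observation, arm by arm.

    Each arm is simulated to its post-last-dose cycle with the arm's Ta;
    observations (clock times, hours after awakening) are read off the dense
    final cycle by linear interpolation.
    """
    preds = []
    for arm in data:
        window = steady_state_window(m, arm.ta, tol=ss_tol,
                                     max_doses=max_doses, out_step=out_step,
                                     method=method)
        tgrid = window.t
        for _, row in arm.observations.iterrows():
            var = row["variable"]
            if var not in window.states:
                raise InvalidParameterError(
                    f"variable {var!r} not produced by a {m.kind} model"
                )
            t_obs = (float(row["t"]) - arm.ta) % 24.0
            preds.append(float(np.interp(t_obs, tgrid, window.states[var])))
    return np.array(preds)


def evaluate_model(m: ModelSpec, data: list[ArmDataset], n_pars: int,
                   **sim_kwargs) -> dict:
    """Fobj / LogL / AICc / BIC of a fully specified model on the data."""
    pred = predict_observations(m, data, **sim_kwargs)
    F = fobj(pred, data)
    L = loglik(pred, data)
    N = int(sum(a.n_obs for a in data))
    return {"Fobj": F, "LogL": L, "AICc": aicc(L, n_pars, N),
            "BIC": bic(L, n_pars, N), "N_tot": N}


# ---------------------------------------------------------------------------
# Thin wrappers over the estimators
# ---------------------------------------------------------------------------

def fit_variant(
    variant: VariantKey,
    data: list[ArmDataset],
    drug: DrugConstants,
    baseline: CircadianBPParams,
    *,
    bounds: dict | None = None,
    seed: int = 0,
    n_starts: int = 50,
    estimate_fvd: bool = False,
    **sim_kwargs,
) -> FitResult:
    """Fit one circadian variant jointly across arms (multi-start least
    squares on standardized residuals; deterministic given seed)."""
    from .estimators import PKPDVariantRegressor

    est = PKPDVariantRegressor(
        kind=variant.kind, circadian_set=tuple(sorted(variant.circadian_set)),
        hill_free=variant.hill_free, drug=drug, baseline=baseline,
        bounds=bounds, seed=seed, n_starts=n_starts,
        estimate_fvd=estimate_fvd, **sim_kwargs,
    )
    est.fit(data)
    return est.result_


def select_model(
    data: list[ArmDataset],
    kind: str,
    drug: DrugConstants,
    baseline: CircadianBPParams,
    *,
    seed: int = 0,
    n_starts: int = 50,
    **kwargs,
) -> list[FitResult]:
    """Fit every variant of the lattice and rank by AICc (ties toward fewer
    parameters).  Individual variant failures are recorded, not fatal."""
    from .estimators import VariantSelector

    sel = VariantSelector(kind=kind, drug=drug, baseline=baseline, seed=seed,
                          n_starts=n_starts, **kwargs)
    sel.fit(data)
    return sel.results_


def selection_table(results: list[FitResult]) -> pd.DataFrame:
    """Variant x {Fobj, AICc, BIC} table (the model-comparison layout)."""
    rows = []
    best = min(r.AICc for r in results)
    for r in results:
        rows.append({
            "variant": r.variant.label,
            "circadian_set": "+".join(sorted(r.variant.circadian_set)) or "none",
            "hill_free": r.variant.hill_free,
            "n_pars": r.n_pars,
            "Fobj": r.Fobj,
            "LogL": r.LogL,
            "AICc": r.AICc,
            "dAICc": r.AICc - best,
            "BIC": r.BIC,
            "converged": r.converged,
        })
    return pd.DataFrame(rows)
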