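"""Local sensitivity trajectories and FIM-based identifiability.

Raw sensitivities S_ij(t) = dy_i(t)/dp_j are computed by central finite
differences on the full multi-dose simulation; normalized trajectories
Srel_ij = S_ij * p_j / y_i are dimensionless and invariant to parameter
units.  The per-parameter summary is the mean of squared normalized
sensitivities over all variables and times,

    delta_j = (1 / (k N)) * sum_i sum_n Srel_ij(t_n)^2.

Identifiability uses the Fisher information matrix

    FIM = sum_n S(t_n) Q(t_n) S(t_n)^T,    Q = diag(1 / sigma_i^2),

whose (pseudo-)inverse approximates the estimator covariance; 95% CIs are
p_j +/- 1.96 sqrt(cov_jj) and the parameter correlation is
kappa_jh = cov_jh / sqrt(cov_jj cov_hh).  With Q the inverse data variance
the linear-model FIM reduces to X' W X, matching the weighted-least-squares
covariance — the property the CI formula assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import InvalidParameterError
from .fitting import (
    ArmDataset,
    FitResult,
    RATE_PARAM_NAMES,
    build_model,
    stack_observations,
)
from .pkpd import ModelSpec, SteadyStateWarning, simulate_regimen

# parameter name -> (component, attribute) for perturbation
_EFFECT_PARAMS = {"Imax": "Imax", "n": "n"}


def _param_location(m: ModelSpec, name: str):
    """Resolve a paper-style parameter name to its slot in a ModelSpec."""
    if name in m.rates:
        return ("rate_K", name)
    for rate, (an, on) in RATE_PARAM_NAMES.items():
        if rate in m.rates:
            if name == an:
                return ("rate_A", rate)
            if name == on:
                return ("rate_O", rate)
    if name in _EFFECT_PARAMS:
        return ("effect", name)
    if name == "F_over_Vd":
        return ("fvd", name)
    raise InvalidParameterError(f"unknown parameter {name!r} for this model")


def get_param(m: ModelSpec, name: str) -> float:
    kind, key = _param_location(m, name)
    if kind == "rate_K":
        return m.rates[key].Kx
    if kind == "rate_A":
        return m.rates[key].Ax
    if kind == "rate_O":
        return m.rates[key].Ox
    if kind == "effect":
        return getattr(m.effect, key)
    return m.drug.F / m.drug.Vd


def set_param(m: ModelSpec, name: str, value: float) -> ModelSpec:
    """Return a copy of ``m`` with one named parameter replaced."""
    from dataclasses import replace

    kind, key = _param_location(m, name)
    if kind in ("rate_K", "rate_A", "rate_O"):
        r = m.rates[key]
        attr = {"rate_K": "Kx", "rate_A": "Ax", "rate_O": "Ox"}[kind]
        rates = dict(m.rates)
        rates[key] = replace(r, **{attr: value})
        return replace(m, rates=rates)
    if kind == "effect":
        return replace(m, effect=replace(m.effect, **{key: value}))
    # F/Vd ratio: rescale Vd, keep F
    return replace(m, drug=replace(m.drug, Vd=m.drug.F / value))


@dataclass
class SensitivityResult:
    """Raw and/or normalized sensitivity trajectories.

    ``S`` has shape (n_vars, n_params, n_times).
    """

    S: np.ndarray
    variables: list[str]
    params: list[str]
    times: np.ndarray
    values: dict[str, float]
    y: np.ndarray | None = None          # base trajectories (n_vars, n_times)
    normalized: bool = False

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(self.variables):
            for j, p in enumerate(self.params):
                rows.append(pd.DataFrame({
                    "variable": v, "parameter": p, "t": self.times,
                    "S": self.S[i, j],
                }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class IdentifiabilityResult:
    """FIM, covariance, 95% CIs and parameter correlation matrix."""

    params: list[str]
    values: np.ndarray
    fim: np.ndarray
    cov: np.ndarray
    ci95: np.ndarray               # (n_pars, 2) lower/upper
    correlation: np.ndarray
    high_corr_pairs: list[tuple[str, str, float]]
    singular: bool = False
    null_space: list[dict] = field(default_factory=list)

    def ci_table(self) -> pd.DataFrame:
        sd = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
        return pd.DataFrame({
            "parameter": self.params, "estimate": self.values,
            "sd": sd, "ci_lo": self.ci95[:, 0], "ci_hi": self.ci95[:, 1],
        })


def local_sens(
    m: ModelSpec,
    params_of_interest: list[str],
    times: np.ndarray,
    Ta: float = 0.0,
    n_doses: int = 5,
    h_rel: float = 1e-5,
    h_abs_floor: float = 1e-7,
    out_step: float = 0.05,
    method: str = "rk4",
) -> SensitivityResult:
    """Central finite-difference sensitivities of every state variable.

    ``times`` are hours after the first dose within the simulated horizon;
    states are read off the dense simulation grid by interpolation.  When a
    perturbation step would leave the model's validity region (e.g. push Ax
    past Kx), the step is shrunk with a warning.
    """
    times = np.asarray(times, dtype=float)

    def run(model):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            traj = simulate_regimen(model, Ta, n_doses=n_doses,
                                    out_step=out_step, method=method)
        return traj

    base = run(m)
    variables = list(base.states)
    Y0 = np.vstack([
        np.interp(times, base.t, base.states[v]) for v in variables
    ])

    S = np.empty((len(variables), len(params_of_interest), times.size))
    for j, name in enumerate(params_of_interest):
        p0 = get_param(m, name)
        h = abs(p0) * h_rel if p0 != 0 else h_abs_floor
        h = max(h, h_abs_floor)
        step = h
        up = dn = None
        for attempt in range(8):
            try:
                up = run(set_param(m, name, p0 + step))
                dn = run(set_param(m, name, p0 - step))
                break
            except InvalidParameterError:
                step *= 0.25
                warnings.warn(
                    f"sensitivity step for {name} shrunk to {step:.3g} to "
                    "stay inside the validity region")
        if dn is None:
            # boundary parameter (e.g. amplitude at 0): one-sided difference
            step = h
            up = run(set_param(m, name, p0 + step))
            for i, v in enumerate(variables):
                yu = np.interp(times, up.t, up.states[v])
                S[i, j] = (yu - Y0[i]) / step
            continue
        for i, v in enumerate(variables):
            yu = np.interp(times, up.t, up.states[v])
            yd = np.interp(times, dn.t, dn.states[v])
            S[i, j] = (yu - yd) / (2.0 * step)

    values = {nm: get_param(m, nm) for nm in params_of_interest}
    return SensitivityResult(S=S, variables=variables,
                             params=list(params_of_interest), times=times,
                             values=values, y=Y0, normalized=False)


def normalize_sens(sens: SensitivityResult, eps: float = 1e-9
                   ) -> SensitivityResult:
    """Srel = S * p / y; points with |y| < eps are excluded (NaN) with a
    warning.  Dimensionless and invariant under parameter rescaling."""
    if sens.y is None:
        raise InvalidParameterError("raw result lacks base trajectories")
    Srel = np.empty_like(sens.S)
    tiny = np.abs(sens.y) < eps
    if tiny.any():
        warnings.warn(f"{int(tiny.sum())} points with |y| < {eps} excluded "
                      "from normalized sensitivities")
    for j, nm in enumerate(sens.params):
        p = sens.values[nm]
        with np.errstate(divide="ignore", invalid="ignore"):
            Srel[:, j, :] = sens.S[:, j, :] * p / sens.y
        Srel[:, j, :][tiny] = np.nan
    return SensitivityResult(S=Srel, variables=sens.variables,
                             params=sens.params, times=sens.times,
                             values=sens.values, y=sens.y, normalized=True)


def sens_summary(sens: SensitivityResult) -> pd.DataFrame:
    """Per-parameter summary delta_j = mean of squared Srel over variables and
    times, with the per-variable stacked contributions."""
    if not sens.normalized:
        raise InvalidParameterError("summary is defined on normalized result")
    k = len(sens.variables)
    N = sens.times.size
    rows = {}
    for j, nm in enumerate(sens.params):
        contrib = {}
        for i, v in enumerate(sens.variables):
            s2 = sens.S[i, j, :]
            contrib[v] = float(np.nansum(s2 ** 2) / (k * N))
        contrib["delta"] = float(sum(contrib.values()))
        rows[nm] = contrib
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    return out


def fim(S_list, se_list, params: list[str] | None = None,
        values: np.ndarray | None = None,
        cond_threshold: float = 1e12,
        corr_threshold: float = 0.95) -> IdentifiabilityResult:
    """FIM from per-time sensitivity matrices.

    ``S_list[n]`` is (n_params, n_vars) at time t_n; ``se_list[n]`` the
    matching per-variable standard errors.  Covariance is the (pseudo-)
    inverse of the FIM; a singular FIM triggers a structural report of the
    null-space parameter combinations.
    """
    S_list = [np.atleast_2d(np.asarray(S, dtype=float)) for S in S_list]
    n_pars = S_list[0].shape[0]
    F = np.zeros((n_pars, n_pars))
    for S, se in zip(S_list, se_list):
        se = np.atleast_1d(np.asarray(se, dtype=float))
        if np.any(se <= 0):
            raise InvalidParameterError("standard errors must be positive")
        Q = np.diag(1.0 / se ** 2)
        F += S @ Q @ S.T
    F = 0.5 * (F + F.T)

    params = params if params is not None else [f"p{j}" for j in range(n_pars)]
    values = (np.asarray(values, dtype=float) if values is not None
              else np.full(n_pars, np.nan))

    u, sv, vt = np.linalg.svd(F)
    singular = bool(sv[0] <= 0 or sv[-1] < sv[0] / cond_threshold)
    null_space = []
    if singular:
        for idx in np.where(sv < sv[0] / cond_threshold)[0]:
            combo = {params[j]: float(vt[idx, j]) for j in range(n_pars)
                     if abs(vt[idx, j]) > 1e-6}
            null_space.append(combo)
        cov = np.linalg.pinv(F, rcond=1.0 / cond_threshold)
    else:
        cov = np.linalg.inv(F)
    cov = 0.5 * (cov + cov.T)

    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ci = np.column_stack([values - 1.96 * sd, values + 1.96 * sd])
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    pairs = []
    for j in range(n_pars):
        for h in range(j + 1, n_pars):
            if np.isfinite(corr[j, h]) and abs(corr[j, h]) > corr_threshold:
                pairs.append((params[j], params[h], float(corr[j, h])))
    return IdentifiabilityResult(params=list(params), values=values, fim=F,
                                 cov=cov, ci95=ci, correlation=corr,
                                 high_corr_pairs=pairs, singular=singular,
                                 null_space=null_space)


def fit_identifiability(
    result: FitResult,
    data: list[ArmDataset],
    h_rel: float = 1e-5,
    corr_threshold: float = 0.95,
    **sim_kwargs,
) -> IdentifiabilityResult:
    """FIM / CIs / correlations of a fitted variant at its optimum.

    Sensitivities of the predicted observations with respect to every
    estimated parameter (natural scale) are computed by central differences;
    each observation contributes S(t_n) Q(t_n) S(t_n)^T with Q the inverse
    squared standard error.
    """
    from .fitting import predict_observations

    names = list(result.param_values)
    m0 = result.params
    obs = stack_observations(data)
    se = obs["se"].to_numpy(float)

    def pred(model):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            return predict_observations(model, data, **sim_kwargs)

    n_obs = len(obs)
    S = np.empty((len(names), n_obs))
    for j, nm in enumerate(names):
        p0 = get_param(m0, nm)
        h = max(abs(p0) * h_rel, 1e-8)
        step = h
        yu = yd = None
        for _ in range(8):
            try:
                yu = pred(set_param(m0, nm, p0 + step))
                yd = pred(set_param(m0, nm, p0 - step))
                break
            except InvalidParameterError:
                step *= 0.25
        if yd is None:
            yu = pred(set_param(m0, nm, p0 + h))
            y0 = pred(m0)
            S[j] = (yu - y0) / h
        else:
            S[j] = (yu - yd) / (2.0 * step)

    values = np.array([result.param_values[nm] for nm in names])
    return fim([S[:, i:i + 1] for i in range(n_obs)],
               [se[i:i + 1] for i in range(n_obs)],
               params=names, values=values, corr_threshold=corr_threshold)
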