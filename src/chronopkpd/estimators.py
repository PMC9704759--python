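"""Scikit-learn-style estimators wrapping the cosinor-baseline and PK-PD
variant fits.

``CircadianBaselineRegressor`` fits the two-cosinor periodic steady state to
pre-treatment SBP/DBP means; ``PKPDVariantRegressor`` fits one circadian
variant of the non-prodrug/prodrug model jointly across dosing-time arms by
multi-start least squares on standardized residuals; ``VariantSelector``
fits the whole variant lattice and ranks by AICc.  All three follow the
fit/predict, ``get_params``/``set_params``, trailing-underscore conventions
and compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .baseline import (
    CircadianBPParams,
    InvalidParameterError,
    fit_baseline_arrays,
    steady_state_bp,
)
from .fitting import (
    ArmDataset,
    FitResult,
    VariantKey,
    aicc,
    bic,
    build_model,
    selection_table,
    stack_observations,
    variant_lattice,
)
from .pkpd import (
    DrugConstants,
    ModelSpec,
    SteadyStateWarning,
    steady_state_window,
)

DEFAULT_BOUNDS = {
    "rate": (1e-3, 20.0),       # Kx, 1/h
    "amp_frac": (0.0, 0.95),    # Ax as a fraction of Kx
    "phase": (-np.pi, np.pi),   # Ox, rad
    "Imax": (0.0, 1.0),
    "n": (0.1, 10.0),
    "F_over_Vd": (1e-4, 10.0),  # 1/L
}


class CircadianBaselineRegressor(BaseEstimator, RegressorMixin):
    """Cosinor fit of the untreated periodic blood-pressure steady state.

    Parameters
    ----------
    fix_kout : float or None
        Output rate (1/h) held fixed for both pressures (default 1.0).  The
        periodic steady state determines only five features per pressure, so
        kout is structurally non-identifiable from pre-treatment data alone;
        ``None`` estimates it jointly anyway (bounds ``kout_bounds``), which
        recovers the observed curve but not a unique kout.
    n_starts, seed : multi-start control (Latin hypercube, deterministic).

    ``fit(X, y)`` takes ``X`` of shape (n, 2) with columns
    ``[t_hours_after_awakening, channel]`` (channel 0 = SBP, 1 = DBP) and
    ``y`` the observed means (mmHg).  Fitted attributes: ``params_``
    (:class:`CircadianBPParams`), ``gof_`` (per-pressure SSE).
    """

    def __init__(self, fix_kout: float | None = 1.0, n_starts: int = 20,
                 seed: int = 0, kout_bounds: tuple = (0.01, 100.0)):
        self.fix_kout = fix_kout
        self.n_starts = n_starts
        self.seed = seed
        self.kout_bounds = kout_bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidParameterError("X must be (n, 2): [t, channel]")
        if X.shape[0] != y.shape[0]:
            raise InvalidParameterError("X and y length mismatch")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise InvalidParameterError("non-finite input")
        chan = X[:, 1].astype(int)
        fits = {}
        gof = {}
        for c, label in ((0, "SBP"), (1, "DBP")):
            mask = chan == c
            kin, kout, sse = fit_baseline_arrays(
                X[mask, 0], y[mask], fix_kout=self.fix_kout,
                n_starts=self.n_starts, seed=self.seed,
                kout_bounds=self.kout_bounds,
            )
            fits[label] = (kin, kout)
            gof[label] = sse
        self.params_ = CircadianBPParams(
            kin_s=fits["SBP"][0], kin_d=fits["DBP"][0],
            kout1=fits["SBP"][1], kout2=fits["DBP"][1],
        )
        self.gof_ = gof
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        s, d = steady_state_bp(self.params_, X[:, 0], 0.0)
        return np.where(X[:, 1].astype(int) == 0, s, d)


class _FastPredictor:
    """Precomputed observation layout for repeated model evaluation."""

    def __init__(self, data: list[ArmDataset], out_step: float,
                 ss_tol: float, max_doses: int, method: str):
        self.out_step = out_step
        self.ss_tol = ss_tol
        self.max_doses = max_doses
        self.method = method
        self.arms = []
        y_parts, se_parts = [], []
        n_total = 0
        for arm in data:
            groups = []
            for var, g in arm.observations.groupby("variable", sort=False):
                # interpolation abscissa: time since dose on the final cycle
                t_obs = (g["t"].to_numpy(float) - arm.ta) % 24.0
                groups.append((var, t_obs))
                y_parts.append(g["mean"].to_numpy(float))
                se_parts.append(g["se"].to_numpy(float))
                n_total += len(g)
            self.arms.append((arm.ta, groups))
        self.y = np.concatenate(y_parts)
        self.se = np.concatenate(se_parts)
        self.n_obs = n_total

    def predict(self, m: ModelSpec) -> np.ndarray:
        out = np.empty(self.n_obs)
        pos = 0
        for ta, groups in self.arms:
            window = steady_state_window(
                m, ta, tol=self.ss_tol, max_doses=self.max_doses,
                out_step=self.out_step, method=self.method,
            )
            for var, t_obs in groups:
                vals = np.interp(t_obs, window.t, window.states[var])
                out[pos:pos + len(t_obs)] = vals
                pos += len(t_obs)
        return out


class PKPDVariantRegressor(BaseEstimator, RegressorMixin):
    """Fit one circadian variant of the PK-PD model across dosing-time arms.

    Free parameters are every rate's mean Kx, amplitude/acrophase for each
    circadian rate, Imax, the Hill coefficient when ``hill_free``, and
    optionally F/Vd as a single ratio.  The drug constants and the circadian
    BP baseline are frozen (two-stage protocol).  Optimization is seeded
    multi-start trust-region least squares on standardized residuals; the
    reported Fobj is the mean standardized squared residual.
    """

    def __init__(self, kind: str = "nonprodrug",
                 circadian_set: tuple = (), hill_free: bool = False,
                 drug: DrugConstants | None = None,
                 baseline: CircadianBPParams | None = None,
                 bounds: dict | None = None, seed: int = 0,
                 n_starts: int = 50, estimate_fvd: bool = False,
                 out_step: float = 0.1, ss_tol: float = 1e-3,
                 max_doses: int = 14, method: str = "rk4",
                 max_nfev: int = 300, x0: dict | list | None = None):
        self.kind = kind
        self.circadian_set = circadian_set
        self.hill_free = hill_free
        self.drug = drug
        self.baseline = baseline
        self.bounds = bounds
        self.seed = seed
        self.n_starts = n_starts
        self.estimate_fvd = estimate_fvd
        self.out_step = out_step
        self.ss_tol = ss_tol
        self.max_doses = max_doses
        self.method = method
        self.max_nfev = max_nfev
        self.x0 = x0

    # -- internal vector layout -------------------------------------------
    def _layout(self):
        variant = VariantKey(circadian_set=frozenset(self.circadian_set),
                             hill_free=self.hill_free, kind=self.kind)
        names = variant.param_names(estimate_fvd=self.estimate_fvd)
        b = dict(DEFAULT_BOUNDS)
        if self.bounds:
            b.update(self.bounds)
        lo, hi, kinds = [], [], []
        from .fitting import NONPRODRUG_RATES, PRODRUG_RATES, RATE_PARAM_NAMES

        rate_names = set(NONPRODRUG_RATES if self.kind == "nonprodrug"
                         else PRODRUG_RATES)
        amp_names = {a for a, _ in RATE_PARAM_NAMES.values()}
        phase_names = {o for _, o in RATE_PARAM_NAMES.values()}
        for nm in names:
            if nm in rate_names:
                lo.append(b["rate"][0]); hi.append(b["rate"][1]); kinds.append("rate")
            elif nm in amp_names:
                lo.append(b["amp_frac"][0]); hi.append(b["amp_frac"][1]); kinds.append("amp_frac")
            elif nm in phase_names:
                lo.append(b["phase"][0]); hi.append(b["phase"][1]); kinds.append("phase")
            elif nm == "Imax":
                lo.append(b["Imax"][0]); hi.append(b["Imax"][1]); kinds.append("Imax")
            elif nm == "n":
                lo.append(b["n"][0]); hi.append(b["n"][1]); kinds.append("n")
            elif nm == "F_over_Vd":
                lo.append(b["F_over_Vd"][0]); hi.append(b["F_over_Vd"][1]); kinds.append("F_over_Vd")
        return variant, names, np.array(lo), np.array(hi), kinds

    def _values_from_vector(self, x, names, kinds):
        """Internal vector -> natural-scale named values (amp_frac -> Ax)."""
        values = {}
        last_rate = None
        for xi, nm, kd in zip(x, names, kinds):
            if kd == "rate":
                values[nm] = float(xi)
                last_rate = nm
            elif kd == "amp_frac":
                values[nm] = float(xi) * values[last_rate]
            else:
                values[nm] = float(xi)
        return values

    def fit(self, X, y=None):
        data = self._as_arms(X)
        variant, names, lo, hi, kinds = self._layout()
        pred = _FastPredictor(data, self.out_step, self.ss_tol,
                              self.max_doses, self.method)

        def resid(x):
            values = self._values_from_vector(x, names, kinds)
            m = build_model(variant, self.drug, self.baseline, values)
            return (pred.predict(m) - pred.y) / pred.se

        rng = np.random.default_rng(self.seed)
        sampler = qmc.LatinHypercube(d=len(lo), seed=rng)
        u = sampler.random(max(self.n_starts, 1))
        starts = np.empty_like(u)
        for j, kd in enumerate(kinds):
            if kd == "rate":
                # log-uniform over the rate bounds
                starts[:, j] = 10 ** (np.log10(lo[j])
                                      + u[:, j] * (np.log10(hi[j]) - np.log10(lo[j])))
            else:
                starts[:, j] = lo[j] + u[:, j] * (hi[j] - lo[j])
        starts[0] = self._heuristic_start(data, names, kinds, lo, hi)
        if self.x0 is not None:
            extra = self.x0 if isinstance(self.x0, (list, tuple)) else [self.x0]
            warm = [self._vector_from_values(v, names, kinds, lo, hi)
                    for v in extra]
            starts = np.vstack([starts, warm])

        best = None
        diagnostics = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            for x0 in starts:
                try:
                    res = least_squares(resid, x0, bounds=(lo, hi),
                                        method="trf", x_scale="jac",
                                        max_nfev=self.max_nfev,
                                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
                    diagnostics.append((float(res.cost), int(res.status)))
                    if best is None or res.cost < best.cost:
                        best = res
                except Exception as exc:  # noqa: BLE001 - per-start diagnostic
                    diagnostics.append((math.inf, str(exc)))
        if best is None:
            raise RuntimeError(
                f"all {len(starts)} starts failed: {diagnostics}")

        values = self._values_from_vector(best.x, names, kinds)
        model = build_model(variant, self.drug, self.baseline, values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            y_model = pred.predict(model)
        N = pred.n_obs
        # residuals in the predictor's own (grouped) observation order
        r = (y_model - pred.y) / pred.se
        F = float(np.mean(r ** 2))
        L = float(-0.5 * N * math.log(2.0 * math.pi)
                  - np.sum(np.log(pred.se)) - 0.5 * np.sum(r ** 2))
        n_pars = len(names)
        self.variant_ = variant
        self.model_ = model
        self.values_ = values
        self.result_ = FitResult(
            variant=variant, params=model, param_values=values,
            Fobj=F, LogL=L, AICc=aicc(L, n_pars, N), BIC=bic(L, n_pars, N),
            n_pars=n_pars, N_tot=N, converged=bool(best.status > 0),
            seed=self.seed, n_starts=len(starts),
            start_diagnostics=diagnostics,
        )
        return self

    def predict(self, X):
        data = self._as_arms(X)
        pred = _FastPredictor(data, self.out_step, self.ss_tol,
                              self.max_doses, self.method)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            return pred.predict(self.model_)

    def score(self, X, y=None):
        """Negative Fobj (higher is better, sklearn convention)."""
        data = self._as_arms(X)
        pred = _FastPredictor(data, self.out_step, self.ss_tol,
                              self.max_doses, self.method)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            r = (pred.predict(self.model_) - pred.y) / pred.se
        return -float(np.mean(r ** 2))

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_arms(X) -> list[ArmDataset]:
        if isinstance(X, ArmDataset):
            return [X]
        if isinstance(X, (list, tuple)) and all(
                isinstance(a, ArmDataset) for a in X):
            return list(X)
        raise InvalidParameterError(
            "X must be an ArmDataset or a list of ArmDataset")

    def _heuristic_start(self, data, names, kinds, lo, hi):
        """Data-driven anchor: rates at 1/h, modest circadian amplitude, Imax
        from the observed mean BP depression versus the frozen baseline."""
        obs = stack_observations(data)
        bpmask = obs["variable"].isin(["SBP", "DBP"])
        depress = 0.15
        if bpmask.any():
            sub = obs[bpmask]
            base = []
            for _, row in sub.iterrows():
                s, d = steady_state_bp(self.baseline, float(row["t"]), 0.0)
                base.append(s if row["variable"] == "SBP" else d)
            base = np.asarray(base, dtype=float)
            depress = float(np.clip(
                1.0 - np.mean(sub["mean"].to_numpy(float) / base), 0.02, 0.6))
        x0 = np.empty(len(names))
        for j, (nm, kd) in enumerate(zip(names, kinds)):
            if kd == "rate":
                x0[j] = 1.0 if nm == "Ka" else 0.5
            elif kd == "amp_frac":
                x0[j] = 0.3
            elif kd == "phase":
                x0[j] = 0.0
            elif kd == "Imax":
                x0[j] = min(3.0 * depress, 0.9)
            elif kd == "n":
                x0[j] = 1.5
            else:  # F_over_Vd
                x0[j] = self.drug.F / self.drug.Vd
        return np.clip(x0, lo, hi)

    def _vector_from_values(self, values, names, kinds, lo, hi):
        x = np.empty(len(names))
        last_rate = None
        for j, (nm, kd) in enumerate(zip(names, kinds)):
            if kd == "rate":
                x[j] = values[nm]
                last_rate = nm
            elif kd == "amp_frac":
                x[j] = values[nm] / values[last_rate]
            else:
                x[j] = values[nm]
        return np.clip(x, lo, hi)


class VariantSelector(BaseEstimator):
    """Fit every variant of the 8- or 22-member lattice and rank by AICc.

    Fitted attributes: ``results_`` (AICc-ascending, ties toward fewer
    parameters), ``best_result_``, ``best_variant_``, ``table_`` (the
    model-comparison DataFrame), ``failures_``.
    """

    def __init__(self, kind: str = "nonprodrug",
                 drug: DrugConstants | None = None,
                 baseline: CircadianBPParams | None = None,
                 seed: int = 0, n_starts: int = 50,
                 estimate_fvd: bool = False, out_step: float = 0.1,
                 ss_tol: float = 1e-3, max_doses: int = 14,
                 method: str = "rk4", max_nfev: int = 300):
        self.kind = kind
        self.drug = drug
        self.baseline = baseline
        self.seed = seed
        self.n_starts = n_starts
        self.estimate_fvd = estimate_fvd
        self.out_step = out_step
        self.ss_tol = ss_tol
        self.max_doses = max_doses
        self.method = method
        self.max_nfev = max_nfev

    def fit(self, X, y=None):
        data = PKPDVariantRegressor._as_arms(X)
        results = []
        failures = []
        # fit simple variants first; their optima warm-start nested richer
        # ones, which both speeds the lattice up and enforces Fobj nesting
        lattice = sorted(variant_lattice(self.kind),
                         key=lambda v: (len(v.circadian_set), v.hill_free))
        fitted: dict[tuple, dict] = {}
        for variant in lattice:
            warm = self._warm_starts(variant, fitted)
            est = PKPDVariantRegressor(
                kind=self.kind,
                circadian_set=tuple(sorted(variant.circadian_set)),
                hill_free=variant.hill_free, drug=self.drug,
                baseline=self.baseline, seed=self.seed,
                n_starts=self.n_starts, estimate_fvd=self.estimate_fvd,
                out_step=self.out_step, ss_tol=self.ss_tol,
                max_doses=self.max_doses, method=self.method,
                max_nfev=self.max_nfev, x0=warm or None,
            )
            try:
                est.fit(data)
                results.append(est.result_)
                fitted[(variant.circadian_set, variant.hill_free)] = (
                    est.result_.param_values)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures.append((variant, repr(exc)))
        if not results:
            raise RuntimeError(f"every variant failed: {failures}")
        results.sort(key=lambda r: (r.AICc, r.n_pars))
        self._finalize(results, failures)
        return self

    def _warm_starts(self, variant, fitted: dict) -> list[dict]:
        from .fitting import RATE_PARAM_NAMES

        warm = []
        key_set = variant.circadian_set
        parents = []
        for r in key_set:
            parents.append((key_set - {r}, variant.hill_free, r))
        if variant.hill_free:
            parents.append((key_set, False, None))
        for pset, phill, new_rate in parents:
            vals = fitted.get((frozenset(pset), phill))
            if vals is None:
                continue
            cand = dict(vals)
            if new_rate is not None:
                an, on = RATE_PARAM_NAMES[new_rate]
                cand[an] = 0.1 * cand[new_rate]
                cand[on] = 0.0
            if variant.hill_free and "n" not in cand:
                cand["n"] = 1.2
            warm.append(cand)
        return warm

    def _finalize(self, results, failures):
        self.results_ = results
        self.failures_ = failures
        self.best_result_ = results[0]
        self.best_variant_ = results[0].variant
        self.table_ = selection_table(results)
        return self
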