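"""Seeded generator of synthetic chronotherapy study data.

Emulates the statistical structure of ambulatory-BP chronotherapy studies:
hourly study-mean SBP/DBP profiles (optionally drug / metabolite plasma
concentrations) for two dosing-time arms (awakening and bedtime), reported as
mean +/- SE with independent Gaussian noise of about 2% of the mean — the SE
convention of summary-level BP datasets.  Baselines come in dipper (~15%
nocturnal dip) and non-dipper (~5%) phenotypes in the untreated hypertensive
range (awake means near 140/88 mmHg).

The drug archetypes (one non-prodrug with circadian absorption and
elimination plus a free Hill coefficient; one prodrug with circadian
absorption and metabolite elimination) are this package's own plausible
parameter sets with rates in the 0.1-2 1/h range, sized to produce mean BP
reductions of roughly 10-15 mmHg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import (
    W12,
    W24,
    CircadianBPParams,
    CircadianInput,
    ClockConvention,
    steady_state_bp,
)
from .chrono import dipper_pct
from .fitting import ArmDataset
from .pkpd import (
    DrugConstants,
    EffectParams,
    ModelSpec,
    PeriodicRate,
    SteadyStateWarning,
    steady_state_window,
)

DEFAULT_KOUT = 1.0  # 1/h; BP turnover convention, see methods note


def _window_mean_cos(W: float, peak: float, a: float, b: float) -> float:
    """Mean of cos(W (tau - peak)) over the window [a, b]."""
    return (math.sin(W * (b - peak)) - math.sin(W * (a - peak))) / (W * (b - a))


def _cosinor_from_profile(level: float, comps, kout: float) -> CircadianInput:
    """Invert a BP-space cosine profile to the kin-space cosinor input.

    ``comps`` is a list of (amplitude_bp, W, peak_h); the periodic steady
    state of the returned input under ``kout`` reproduces the profile.
    """
    amps = {}
    phases = {}
    for a_bp, W, peak in comps:
        gain = math.hypot(kout, W)
        O = math.atan2(W, kout) - W * peak
        O = (O + math.pi) % (2 * math.pi) - math.pi
        amps[W] = a_bp * gain
        phases[W] = O
    return CircadianInput(M=level * kout,
                          A12=amps.get(W12, 0.0), A24=amps.get(W24, 0.0),
                          O12=phases.get(W12, 0.0), O24=phases.get(W24, 0.0))


def make_baseline_scenario(profile_kind: str = "dipper", seed: int = 0,
                           clock: ClockConvention | None = None
                           ) -> CircadianBPParams:
    """Construct a dipper (~15% dip) or non-dipper (~5%) hypertensive
    baseline, deterministically jittered by ``seed``.

    The awake-window means land near 140/88 mmHg; the nocturnal dip is set by
    solving the two window-mean equations for the cosine level and amplitude,
    then inverting to kin-space, and is verified with :func:`dipper_pct`.
    """
    if profile_kind not in ("dipper", "nondipper"):
        raise ValueError(f"unknown profile kind {profile_kind!r}")
    clock = clock or ClockConvention()
    rng = np.random.default_rng(seed)
    if profile_kind == "dipper":
        dip = float(np.clip(0.15 + 0.01 * rng.standard_normal(), 0.12, 0.18))
    else:
        dip = float(np.clip(0.05 + 0.008 * rng.standard_normal(), 0.03, 0.07))
    sbp_awake = 140.0 + 2.0 * rng.standard_normal()
    dbp_awake = 88.0 + 1.5 * rng.standard_normal()
    p24 = 6.5 + 0.5 * rng.standard_normal()   # 24-h peak, h after awakening
    p12 = 9.0 + 0.5 * rng.standard_normal()
    r12 = 0.35                                 # 12-h / 24-h amplitude ratio

    a0, a1 = clock.awake_window
    s0, s1 = clock.sleep_window
    g24 = _window_mean_cos(W24, p24, a0, a1)
    h24 = _window_mean_cos(W24, p24, s0, s1)
    g12 = _window_mean_cos(W12, p12, a0, a1)
    h12 = _window_mean_cos(W12, p12, s0, s1)

    def solve(awake_mean):
        denom = (g24 + r12 * g12) - (h24 + r12 * h12)
        a24 = awake_mean * dip / denom
        level = awake_mean - a24 * (g24 + r12 * g12)
        return level, a24

    params = {}
    for label, awake_mean in (("s", sbp_awake), ("d", dbp_awake)):
        level, a24 = solve(awake_mean)
        params[label] = _cosinor_from_profile(
            level, [(a24, W24, p24), (r12 * a24, W12, p12)], DEFAULT_KOUT)

    out = CircadianBPParams(kin_s=params["s"], kin_d=params["d"],
                            kout1=DEFAULT_KOUT, kout2=DEFAULT_KOUT)
    # verify the phenotype by construction
    tau = np.arange(0.0, 24.0, 0.25)
    s, _ = steady_state_bp(out, tau, 0.0)
    d = dipper_pct(tau, s, clock)
    if profile_kind == "dipper":
        assert 10.0 <= d <= 20.0, f"dipper construction failed: {d:.2f}%"
    else:
        assert d < 10.0, f"non-dipper construction failed: {d:.2f}%"
    return out


def nonprodrug_archetype(baseline: CircadianBPParams | None = None
                         ) -> ModelSpec:
    """Non-prodrug drug archetype: circadian Ka and Ke, free Hill coefficient."""
    baseline = baseline or make_baseline_scenario("dipper", seed=0)
    return ModelSpec(
        kind="nonprodrug",
        rates={
            "Ka": PeriodicRate(Kx=1.0, Ax=0.4, Ox=-1.0),
            "Ke": PeriodicRate(Kx=0.35, Ax=0.12, Ox=0.6),
        },
        drug=DrugConstants(dose=10_000.0, F=0.6, Vd=50.0, IC50=40.0),
        effect=EffectParams(Imax=0.45, n=1.6, hill_free=True),
        baseline=baseline,
    )


def prodrug_archetype(baseline: CircadianBPParams | None = None) -> ModelSpec:
    """Prodrug archetype: circadian Ka and Ke2 (slow metabolite elimination)."""
    baseline = baseline or make_baseline_scenario("dipper", seed=0)
    return ModelSpec(
        kind="prodrug",
        rates={
            "Ka": PeriodicRate(Kx=1.2, Ax=0.5, Ox=-0.8),
            "Ke1": PeriodicRate(Kx=0.8),
            "Km": PeriodicRate(Kx=0.5),
            "Ke2": PeriodicRate(Kx=0.25, Ax=0.08, Ox=0.5),
        },
        drug=DrugConstants(dose=10_000.0, F=0.5, Vd=60.0, IC50=15.0),
        effect=EffectParams(Imax=0.4, n=1.3, hill_free=True),
        baseline=baseline,
    )


@dataclass
class SynthScenario:
    """Study design for one synthetic dataset."""

    true_model: ModelSpec
    arms: tuple = (0.0, 15.0)              # Ta: awakening and bedtime
    times: np.ndarray = field(default_factory=lambda: np.arange(24.0))
    se_frac: float = 0.02
    seed: int = 0
    include_concentrations: bool = False
    profile_kind: str = "dipper"

    def __post_init__(self):
        if not (self.se_frac >= 0):
            raise ValueError("se_frac must be nonnegative")


def generate(scn: SynthScenario):
    """Sample one synthetic study.

    Returns ``(pre, post, truth)``: the pre-treatment arm (untreated baseline
    means), one post-treatment ArmDataset per dosing time, and the truth
    record used by recovery tests.  Negative BP draws (pathological noise)
    are resampled and counted in the truth record.
    """
    rng = np.random.default_rng(scn.seed)
    m = scn.true_model
    tau = np.asarray(scn.times, dtype=float)
    n_resampled = 0

    def noisy(truth, se):
        nonlocal n_resampled
        truth = np.asarray(truth, dtype=float)
        vals = truth + rng.normal(0.0, se)
        bad = vals < 0
        while bad.any():
            n_resampled += int(bad.sum())
            vals[bad] = truth[bad] + rng.normal(0.0, se[bad])
            bad = vals < 0
        return vals

    # pre-treatment: untreated periodic baseline
    s, d = steady_state_bp(m.baseline, tau, 0.0)
    rows = []
    for var, truth in (("SBP", s), ("DBP", d)):
        se = np.maximum(scn.se_frac * np.abs(truth), 1e-12)
        rows.append(pd.DataFrame({"variable": var, "t": tau,
                                  "mean": noisy(truth, se), "se": se}))
    pre = ArmDataset(arm_id="pre", ta=0.0,
                     observations=pd.concat(rows, ignore_index=True))

    post = []
    for k, ta in enumerate(scn.arms):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SteadyStateWarning)
            window = steady_state_window(m, float(ta))
        variables = ["SBP", "DBP"]
        if scn.include_concentrations:
            variables.append("C")
            if m.kind == "prodrug":
                variables.append("Cm")
        rows = []
        t_obs = (tau - ta) % 24.0
        for var in variables:
            truth = np.interp(t_obs, window.t, window.states[var])
            # SE floor at 1% of the cycle maximum keeps near-zero
            # concentration troughs from getting unbounded weight
            floor = 0.01 * float(np.max(np.abs(window.states[var])))
            se = np.maximum(scn.se_frac * np.abs(truth),
                            max(scn.se_frac * floor, 1e-12))
            rows.append(pd.DataFrame({"variable": var, "t": tau,
                                      "mean": noisy(truth, se), "se": se}))
        post.append(ArmDataset(arm_id=f"arm{k}", ta=float(ta),
                               observations=pd.concat(rows, ignore_index=True)))

    truth = {
        "model": m.to_dict(),
        "arms": list(scn.arms),
        "se_frac": scn.se_frac,
        "seed": scn.seed,
        "profile_kind": scn.profile_kind,
        "n_resampled": n_resampled,
    }
    return pre, post, truth
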