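"""PK-PD simulation: periodic rates, Hill inhibition, Bateman oracle,
multi-dose accumulation, positivity and clock-shift invariances."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronopkpd.baseline import InvalidParameterError, steady_state_bp
from chronopkpd.pkpd import (
    DrugConstants,
    EffectParams,
    ModelSpec,
    PeriodicRate,
    SteadyStateWarning,
    bateman,
    inhibition,
    rate_eval,
    simulate_regimen,
    steady_state_window,
)


def test_rate_eval_values_and_periodicity():
    r = PeriodicRate(Kx=1.0, Ax=0.5, Ox=0.0)
    assert rate_eval(r, 0.0, 0.0) == pytest.approx(1.5)
    assert rate_eval(PeriodicRate(Kx=0.7), 13.0, 5.0) == pytest.approx(0.7)
    t = np.linspace(0, 24, 50)
    assert rate_eval(r, t, 3.0) == pytest.approx(rate_eval(r, t + 24.0, 3.0))
    assert np.all(rate_eval(r, t, 3.0) > 0)


def test_rate_positivity_enforced():
    with pytest.raises(InvalidParameterError):
        PeriodicRate(Kx=1.0, Ax=1.0)
    with pytest.raises(InvalidParameterError):
        PeriodicRate(Kx=0.0)


def test_inhibition_half_maximal_and_limits():
    e = EffectParams(Imax=0.8, n=1.0)
    assert inhibition(0.0, e, 40.0) == 0.0
    assert inhibition(40.0, e, 40.0) == pytest.approx(0.4)
    e2 = EffectParams(Imax=0.8, n=2.0)
    assert inhibition(40.0, e2, 40.0) == pytest.approx(0.4)
    assert inhibition(1e9, e2, 40.0) == pytest.approx(0.8, rel=1e-4)
    with pytest.raises(ValueError):
        inhibition(-1.0, e, 40.0)


@settings(derandomize=True, max_examples=30)
@given(c=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=6),
       n=st.floats(0.3, 4.0))
def test_inhibition_monotone(c, n):
    e = EffectParams(Imax=0.9, n=n)
    c = np.sort(np.array(c))
    vals = inhibition(c, e, 50.0)
    assert np.all(np.diff(vals) >= -1e-12)


def test_effect_params_bounds():
    with pytest.raises(InvalidParameterError):
        EffectParams(Imax=1.2)
    with pytest.raises(InvalidParameterError):
        EffectParams(Imax=0.5, n=0.0)


def test_modelspec_structure_validation(dipper_baseline):
    drug = DrugConstants(dose=1e4, F=0.5, Vd=50.0, IC50=30.0)
    with pytest.raises(InvalidParameterError):
        ModelSpec(kind="nonprodrug",
                  rates={"Ka": PeriodicRate(1.0)}, drug=drug,
                  effect=EffectParams(Imax=0.3), baseline=dipper_baseline)
    with pytest.raises(InvalidParameterError):
        ModelSpec(kind="prodrug",
                  rates={"Ka": PeriodicRate(1.0, 0.3, 0.0),
                         "Ke1": PeriodicRate(1.0, 0.3, 0.0),
                         "Km": PeriodicRate(1.0, 0.3, 0.0),
                         "Ke2": PeriodicRate(1.0)},
                  drug=drug, effect=EffectParams(Imax=0.3),
                  baseline=dipper_baseline)


@pytest.mark.parametrize("method", ["rk4", "lsoda"])
@pytest.mark.parametrize("ka,ke", [(1.2, 0.3), (0.5, 0.5), (2.0, 1.999999999999)])
def test_single_dose_matches_bateman(dipper_baseline, method, ka, ke):
    m = ModelSpec(kind="nonprodrug",
                  rates={"Ka": PeriodicRate(ka), "Ke": PeriodicRate(ke)},
                  drug=DrugConstants(dose=1e4, F=0.6, Vd=50.0, IC50=40.0),
                  effect=EffectParams(Imax=0.0), baseline=dipper_baseline)
    traj = simulate_regimen(m, Ta=6.0, n_doses=1, method=method)
    c_ref = bateman(m.drug, ka, ke, traj.t)
    assert np.max(np.abs(traj.states["C"] - c_ref)) / np.max(c_ref) < 1e-6


def test_no_effect_reproduces_baseline(nonprodrug_model):
    m = replace(nonprodrug_model, effect=EffectParams(Imax=0.0))
    traj = simulate_regimen(m, Ta=4.0, n_doses=3)
    s_ref, d_ref = steady_state_bp(m.baseline, traj.t, 4.0)
    assert np.max(np.abs(traj.states["SBP"] - s_ref)) < 1e-5
    assert np.max(np.abs(traj.states["DBP"] - d_ref)) < 1e-5


def test_prodrug_without_metabolism_has_no_effect(prodrug_model):
    rates = dict(prodrug_model.rates)
    rates["Km"] = PeriodicRate(Kx=1e-12)
    m = replace(prodrug_model, rates=rates)
    traj = simulate_regimen(m, Ta=0.0, n_doses=2)
    assert np.max(traj.states["Cm"]) < 1e-6
    s_ref, _ = steady_state_bp(m.baseline, traj.t, 0.0)
    assert np.max(np.abs(traj.states["SBP"] - s_ref)) < 1e-4


def test_mass_positivity_and_xa_decay(nonprodrug_model, prodrug_model):
    for m in (nonprodrug_model, prodrug_model):
        traj = simulate_regimen(m, Ta=9.0, n_doses=3)
        for name, vals in traj.states.items():
            assert np.min(vals) > -1e-9, name
        # Xa strictly nonincreasing between doses
        xa = traj.states["Xa"]
        jumps = np.searchsorted(traj.t, [24.0, 48.0])
        segs = np.split(np.diff(xa), jumps)
        for seg in segs:
            interior = seg[np.abs(seg) < m.drug.dose / 2]
            assert np.all(interior <= 1e-9)


def test_effect_bounds_production(nonprodrug_model):
    """BP stays between the fully inhibited and untreated envelopes."""
    traj = steady_state_window(nonprodrug_model, Ta=2.0)
    s_base, _ = steady_state_bp(nonprodrug_model.baseline, traj.t, 2.0)
    imax = nonprodrug_model.effect.Imax
    assert np.all(traj.states["SBP"] <= s_base + 1e-6)
    assert np.all(traj.states["SBP"] >= s_base * (1 - imax) - 1e-6)


def test_trough_accumulation_matches_geometric_series(dipper_baseline):
    """Linear non-circadian PK accumulates to 1/(1-exp(-Ke*24)) at trough."""
    ke = 0.25
    m = ModelSpec(kind="nonprodrug",
                  rates={"Ka": PeriodicRate(1.5), "Ke": PeriodicRate(ke)},
                  drug=DrugConstants(dose=1e4, F=0.6, Vd=50.0, IC50=40.0),
                  effect=EffectParams(Imax=0.0), baseline=dipper_baseline)
    traj = simulate_regimen(m, Ta=0.0, n_doses=40)
    c = traj.states["C"]
    troughs = c[np.isclose(traj.t % 24.0, 0.0) & (traj.t > 0)]
    single = bateman(m.drug, 1.5, ke, 24.0)
    ratio = troughs[-1] / single
    # geometric-series accumulation; the Ka exponential is negligible at 24 h
    assert ratio == pytest.approx(1.0 / (1.0 - np.exp(-ke * 24.0)), rel=1e-3)


def test_steady_state_window_tol_inf_returns_first_cycle(nonprodrug_model):
    w = steady_state_window(nonprodrug_model, Ta=0.0, tol=np.inf)
    traj = simulate_regimen(nonprodrug_model, Ta=0.0, n_doses=1)
    assert np.allclose(w.states["C"], traj.states["C"])


def test_steady_state_window_warns_at_cap(dipper_baseline):
    m = ModelSpec(kind="nonprodrug",
                  rates={"Ka": PeriodicRate(1.0), "Ke": PeriodicRate(0.01)},
                  drug=DrugConstants(dose=1e4, F=0.6, Vd=50.0, IC50=40.0),
                  effect=EffectParams(Imax=0.0), baseline=dipper_baseline)
    with pytest.warns(SteadyStateWarning):
        steady_state_window(m, Ta=0.0, tol=1e-9, max_doses=3)


def test_circadian_amplitude_continuity(nonprodrug_model):
    """Ax -> 0 limit of a circadian rate converges to the constant-rate
    window."""
    rates = dict(nonprodrug_model.rates)
    rates["Ka"] = PeriodicRate(Kx=1.0, Ax=1e-8, Ox=0.3)
    rates["Ke"] = PeriodicRate(Kx=0.35)
    m_eps = replace(nonprodrug_model, rates=rates)
    rates0 = {"Ka": PeriodicRate(Kx=1.0), "Ke": PeriodicRate(Kx=0.35)}
    m0 = replace(nonprodrug_model, rates=rates0)
    w_eps = steady_state_window(m_eps, Ta=5.0)
    w0 = steady_state_window(m0, Ta=5.0)
    assert np.max(np.abs(w_eps.states["SBP"] - w0.states["SBP"])) < 1e-5


def test_clock_shift_equivalence(nonprodrug_model):
    """Simulating at Ta and Ta + 24 gives identical trajectories."""
    w1 = steady_state_window(nonprodrug_model, Ta=7.0)
    w2 = steady_state_window(nonprodrug_model, Ta=31.0)
    assert np.allclose(w1.states["SBP"], w2.states["SBP"], atol=1e-10)


def test_linear_regime_dose_proportionality(nonprodrug_model):
    """With n = 1 and C << IC50 the BP depression scales linearly in dose."""
    m = replace(nonprodrug_model,
                rates={"Ka": PeriodicRate(1.0), "Ke": PeriodicRate(0.35)},
                effect=EffectParams(Imax=0.4, n=1.0))
    base_s, _ = steady_state_bp(m.baseline, np.arange(0, 24.05, 0.05), 0.0)

    def depression(scale):
        md = replace(m, drug=replace(m.drug, dose=m.drug.dose * scale))
        w = steady_state_window(md, Ta=0.0)
        return base_s - w.states["SBP"]

    d1 = depression(1e-3)
    d2 = depression(2e-3)
    mask = d1 > 1e-8
    assert np.max(np.abs(d2[mask] / d1[mask] - 2.0)) < 0.01


def test_modelspec_json_roundtrip(prodrug_model):
    d = prodrug_model.to_dict()
    m2 = ModelSpec.from_dict(d)
    assert m2.to_dict() == d


def test_trajectory_frame_layout(nonprodrug_model):
    traj = simulate_regimen(nonprodrug_model, Ta=3.0, n_doses=2)
    df = traj.to_frame()
    assert set(df.columns) == {"t_after_dose_h", "clock_h", "variable",
                               "value"}
    assert set(df["variable"]) == {"Xa", "C", "SBP", "DBP"}
    final = traj.final_cycle()
    assert final.t[0] == 0.0 and final.t[-1] == pytest.approx(24.0)
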