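# Methods

## Model

The package models ambulatory blood pressure under once-daily oral
antihypertensive dosing as a pair of indirect-response (turnover) variables
driven by a circadian production rate, coupled to a one-compartment
pharmacokinetic model.

**Untreated baseline.** Systolic and diastolic pressure each obey

    dBP/dt = kin(t) − kout · BP,
    kin(t) = M + A12 cos(W12 (t + Ta) + O12) + A24 cos(W24 (t + Ta) + O24),

with W12 = 2π/12 and W24 = 2π/24 fixed. `t` is hours since dose
administration and `Ta` the dosing time in hours after awakening, so `t + Ta`
is the awakening-anchored clock. Because the system is linear, the 24-h
periodic orbit has the closed form

    BP(t) = M/kout + Σ_c A_c/√(kout² + W_c²) · cos(W_c (t + Ta) + O_c − atan(W_c/kout)),

which is used to initialize every simulation on the periodic orbit and as the
analytic oracle for the integrator. SBP and DBP carry separate cosinor
parameter sets; a single production shape cannot let the two pressures differ
in waveform.

**Treatment.** Non-prodrugs add two PK states — the amount available for
absorption `Xa` (initialized at the dose, re-incremented at each 24-h dosing
event) and the plasma concentration `C` — and inhibit BP production through a
Hill term:

    dXa/dt = −Ka(t)·Xa
    dC/dt  = (F/Vd)·Ka(t)·Xa − Ke(t)·C
    dBP/dt = kin(t)·(1 − Imax·Cⁿ/(IC50ⁿ + Cⁿ)) − kout·BP.

Prodrugs insert a metabolite compartment: the parent is eliminated at
`Ke1(t)` and converted at `Km(t)` into the active metabolite `Cm`, eliminated
at `Ke2(t)`; the Hill term is driven by `Cm`. Any kinetic constant may carry
a 24-h cosine, `Kx(t) = Kx + Ax cos(W24(t + Ta) + Ox)` with `0 ≤ Ax < Kx`; at
most two constants per model are circadian (overfitting guard), giving 8
non-prodrug and 22 prodrug variants once the free-vs-fixed Hill coefficient
is included.

`Imax` is restricted to [0, 1]: negative values would mean the drug raises
BP, values above 1 would allow non-physical negative pressures.

## Fitting

The protocol is two-stage. The baseline cosinor parameters are estimated
first from pre-treatment profiles and frozen; drug constants (dose, F, Vd,
IC50) come from configuration; only the kinetic and effect parameters of a
variant are then estimated jointly across all dosing-time arms.

The objective is the grand mean of standardized squared residuals over every
(variable, arm, time) observation (`Fobj`), with each observation weighted by
its reported standard error. Missing standard errors are replaced by 2% of
the mean value, the typical SE of summary-level ambulatory BP data. The
Gaussian log-likelihood with known σ, AICc and BIC follow directly; `N` in
the likelihood and AICc is the grand observation count, which makes
multi-arm joint fits well defined (a constant normalizer in `Fobj` does not
affect the AICc ranking).

Optimization is seeded multi-start trust-region least squares
(`scipy.optimize.least_squares`, `trf`) on the standardized residuals.
Starts combine a data-driven heuristic (rates near 1 h⁻¹, `Imax` scaled from
the observed mean BP depression) with Latin-hypercube draws (rates sampled
log-uniformly) and, inside the lattice selector, warm starts from the optima
of nested simpler variants — which also enforces the nesting property that a
richer variant never fits worse. Amplitudes are parameterized internally as
fractions `Ax/Kx ∈ [0, 0.95]` so positivity of `Kx(t)` is a box constraint;
results are reported on the natural scale. Bounds: `Kx ∈ [10⁻³, 20] h⁻¹`,
`Ox ∈ [−π, π)`, `Imax ∈ [0, 1]`, `n ∈ [0.1, 10]`. Each local search is
capped at 300 objective evaluations; fits are bit-reproducible given the
seed. F and Vd are never estimated separately; an option estimates the
ratio F/Vd as a single parameter when concentration data are absent.

**Baseline output rates are a convention, not an estimate.** The periodic
steady state exposes exactly five features per pressure (mean, two
amplitudes, two phases) for six parameters: for any `kout` the remaining
cosinor parameters can be rescaled to reproduce the same curve, so `kout` is
structurally non-identifiable from pre-treatment data alone. The default fit
therefore fixes `kout1 = kout2 = 1 h⁻¹` (a BP turnover half-life of ~0.7 h,
consistent with rapid hemodynamic regulation) and estimates the five cosinor
features; a joint fit with `kout` free (bounds [0.01, 100] h⁻¹) is available
and recovers the observed curve but not a unique `kout`. The same
degeneracy is why parameter-recovery checks for the baseline are run with
`kout` held at its generating value, while curve-recovery checks exercise
the joint fit.

## Numerics

Two integrator paths exist and are cross-checked against closed forms:

* `lsoda`: adaptive stiff/non-stiff switching (`scipy.integrate.solve_ivp`),
  rtol 1e-8 / atol 1e-10 — the reference path;
* `rk4` (default): a compiled fixed-step RK4 kernel with a 0.05-h output
  grid and 4 substeps (h = 0.0125 h). The Monte-Carlo studies need on the
  order of 10³ model fits, and the fixed-step kernel evaluates a multi-dose
  simulation in ~1 ms.

Both paths reproduce the Bateman single-dose closed form
`(F·dose/Vd)·Ka/(Ka−Ke)·(e^{−Ke t} − e^{−Ka t})` — and its degenerate
`Ka = Ke` limit `(F·dose/Vd)·K·t·e^{−Kt}`, detected at |Ka−Ke| < 1e-10 in
the oracle — to better than 1e-6 relative to the curve maximum, and the
baseline two-cosine closed form to the same tolerance. Dosing events are
state jumps on `Xa` with integrator restart; nothing integrates through a
discontinuity. Dosing is repeated until consecutive 24-h cycles agree to
1e-3 (max-abs over all states on the output grid) or a 14-dose cap is hit
(warning, not error); predictions at observation times are read off the
dense final cycle by linear interpolation, with hourly observations landing
exactly on grid nodes.

Sensitivities are central finite differences with relative step 1e-5 on the
natural parameter scale (one-sided at validity-region boundaries such as
`Ax = 0`). The Fisher information matrix is `FIM = Σ_n S(t_n) Q(t_n) S(t_n)ᵀ`
with `Q = diag(1/σ²)` — the only reading under which the linear-model FIM
reduces to `XᵀWX` and its inverse to the weighted-least-squares covariance,
which the 95% CI formula `p ± 1.96·√cov_jj` assumes. Parameter correlations
are `κ_jh = cov_jh/√(cov_jj·cov_hh)` (dividing by standard deviations, not
variances — otherwise |κ| ≤ 1 fails); pairs with |κ| > 0.95 are flagged. A
singular FIM (condition number above 1e12) switches to the pseudo-inverse
and reports the null-space parameter combinations.

## Dosing-time optimization

For each `Ta` on a circular grid (default 15-min resolution) the treated
model is run to its post-last-dose cycle and compared with the untreated
analytic baseline at the same clock points:

* dipper % = 100·(awake mean − sleep mean)/awake mean of the treated
  profile, awake window [0, 15) h and sleep window [15, 24) h after
  awakening (both configurable; defaults follow the 8 a.m. wake / 11 p.m.
  bed convention with 9-h sleep);
* `BP_reduced` = mean pre-minus-post difference over the cycle;
* `BP_peaks` = the same difference restricted to clock times where the
  untreated profile exceeds its own mean (undefined and reported as NA for a
  flat profile).

The therapeutic window takes the cycle **maxima** strictly below 130/80 mmHg
(the fallback rules below only make sense against maxima) and the dipper
band as the inclusive interval [10, 20] %. Windows are computed as runs on
the circular `Ta` axis, so ranges may wrap through midnight-after-awakening;
the optimal window is their intersection. When a criterion is unattainable
the report falls back to the `Ta` minimizing `SBP_max` and/or `DBP_max`, or
the `Ta` of the extreme dipper percentage (arg-max when the band is missed
from below, arg-min from above). Metric evaluation uses the uniform dense
simulation grid rather than any particular study's sampling times.

## Synthetic data

The generator emulates summary-level chronotherapy studies: study-mean
hourly SBP/DBP profiles for two dosing arms (awakening `Ta = 0` and bedtime
`Ta = 15`), optionally with parent and metabolite plasma concentrations, and
independent Gaussian noise with σ = 2% of the mean (the SE convention of
such datasets; concentration SEs are floored at 2% of 1% of the cycle
maximum so near-zero troughs do not get unbounded weight). Baselines come in
two phenotypes built by solving the awake/sleep window-mean equations for a
two-cosine profile and inverting to kin-space: dipper (~15% nocturnal dip)
and non-dipper (~5%), both with awake means near 140/88 mmHg and the
phenotype verified by construction via `dipper_pct`. Seeded jitter (±1–2% on
levels, ±0.5 h on peak times) makes replicates distinct but deterministic.

The drug archetypes are this package's own plausible parameter sets, not any
published drug: a non-prodrug with circadian absorption and elimination and
a free Hill coefficient (Ka = 1.0 (Aa 0.4, Oa −1.0), Ke = 0.35 (Ae 0.12,
Oe 0.6) h⁻¹, Imax 0.45, n 1.6, 10 mg, F 0.6, Vd 50 L, IC50 40 µg/L), and a
prodrug with circadian absorption and metabolite elimination. Effect sizes
were chosen once so the mean SBP reduction lands in the 8–15 mmHg range
typical of first-line monotherapy.

What the generator does **not** emulate: between-subject variability (it
models study means, not individuals), autocorrelated noise, napping or
irregular sleep schedules, absorption lag or food effects, and
multi-compartment kinetics. Passing recovery tests therefore show the
estimation machinery is correct under the stated noise model, not that real
datasets are this benign.

## Validation studies and problem sizes

The studies in `chronopkpd.validation` (run by both the test suite and
`scripts/acceptance.py`) use: 100 random draws for each analytic oracle;
50 replicates for the FIM-CI coverage study (per-parameter coverage of the
95% CI, required ≥ 90%) and for the selection-recovery study at 0.5% noise
(the standard design plus concentration observations, which carry the
information that separates circadian absorption from circadian elimination);
30 replicates for the null-selection study, whose objective surface is a
flat plateau in the PK parameters and therefore runs with a tightened
optimizer budget (80 evaluations, 8-dose cap, 0.25-h grid) — refinement on
the plateau changes nothing about the AICc comparison; 1000 random profile
pairs for the metric oracles. Ta scans in the studies use 5-to-30-minute
grids.

## Known limitations

* `kout` is conventional (see above); absolute response-lag predictions
  inherit that convention even though the fitted periodic cycles do not.
* Identifiability is local (FIM at the optimum); no profile likelihood or
  global (Sobol/Morris) analysis.
* With BP-only data, `Imax` and `n` are strongly correlated whenever the
  concentration range is narrow relative to IC50; the correlation screen
  flags this but cannot repair it.
* Single daily dose, one-compartment kinetics, no lag time; twice-daily
  regimens and combination therapy are out of scope.
* The null-selection criterion (minimal variant within 2 AICc of the best on
  effect-free data) is inherently stochastic: nested least-squares refits
  chase noise with roughly a χ² gain per extra parameter, so a minority of
  replicates legitimately exceed the 2-AICc margin.
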