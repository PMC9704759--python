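# chronopkpd

Circadian PK-PD modeling and dosing-time optimization for antihypertensive
therapy.

Blood pressure follows a circadian rhythm — in healthy "dipper" phenotypes
it falls 10–20% during night rest, in "non-dippers" less than 10% — and the
kinetics of orally dosed antihypertensives vary with the clock as well. The
time of day a drug is taken therefore changes both how much it lowers blood
pressure and whether the patient keeps (or regains) a dipper profile.
`chronopkpd` is a toolkit for researchers in chronopharmacology who want to
fit such models to summary-level ambulatory BP (and optionally plasma
concentration) data and simulate their way to an optimal administration
time.

## The model

The untreated pressures are indirect-response variables with a two-component
cosinor production rate (t in hours since dosing, Ta the dosing time in
hours after awakening):

    dBP/dt = kin(t) − kout·BP
    kin(t) = M + A12·cos(W12(t+Ta) + O12) + A24·cos(W24(t+Ta) + O24),
    W12 = 2π/12,  W24 = 2π/24

Treatment couples a one-compartment oral PK model — for non-prodrugs the
absorbable amount Xa and plasma concentration C; for prodrugs additionally
the active metabolite Cm formed at rate Km — and inhibits BP production
through a Hill term:

    dBP/dt = kin(t)·(1 − Imax·Cⁿ/(IC50ⁿ + Cⁿ)) − kout·BP

Each kinetic constant may carry a 24-h cosine, Kx(t) = Kx + Ax·cos(W24(t+Ta)
+ Ox), with at most two circadian constants per model. The resulting
variant lattices (8 non-prodrug, 22 prodrug models, with the Hill
coefficient fixed at 1 or estimated) are fitted jointly across dosing-time
arms by weighted least squares and ranked by AICc; identifiability is
assessed through the Fisher information matrix (95% CIs, parameter
correlations, |κ| > 0.95 screening). A scan over Ta ∈ [0, 24) then reports
dipper percentage, mean BP reduction (BP_reduced), peak-time reduction
(BP_peaks) and the dosing windows where predicted BP stays below 130/80 mmHg
while the dip lies in the 10–20% band.

## Worked example

```python
import numpy as np
from chronopkpd import VariantSelector, fit_baseline, optimal_ta, scan_ta
from chronopkpd.synth import (SynthScenario, generate,
                              make_baseline_scenario, nonprodrug_archetype)

# 1. synthesize a two-arm study (awakening vs bedtime dosing, 2% SEs)
truth_baseline = make_baseline_scenario("dipper", seed=0)
drug = nonprodrug_archetype(truth_baseline)
scn = SynthScenario(true_model=drug, seed=42, se_frac=0.02,
                    include_concentrations=True)
pre, post, _ = generate(scn)

# 2. fit the circadian baseline from the pre-treatment profile
baseline, sse = fit_baseline(pre)

# 3. fit all 8 non-prodrug variants jointly across both arms, rank by AICc
sel = VariantSelector(kind="nonprodrug", drug=drug.drug, baseline=baseline,
                      seed=0, n_starts=2).fit(post)
print(sel.table_[["variant", "n_pars", "Fobj", "AICc"]].head(3))

# 4. scan the administration time with the selected model
scan = scan_ta(sel.best_result_.params, grid_step=0.25)
rep = optimal_ta(scan).report()
print("Ta with dip 10-20%:", rep["ta_dip_10_20"])
print("Ta with BP<130/80:", rep["ta_bp_target"], "| fallback:", rep["fallback"])
```

prints

```
                    variant  n_pars     Fobj       AICc
Circadian Ka and Ke, n free       8 0.921958 287.867381
 Circadian Ka and Ke, n = 1       7 1.503758 369.403372
       Circadian Ke, n free       6 5.844008 992.189058
Ta with dip 10-20%: 08:00-10:45 and 19:45-22:00
Ta with BP<130/80:  | fallback: {'ta_min_sbp_max': '02:00', 'ta_min_dbp_max': '02:00'}
```

The generating variant (circadian absorption and elimination, free Hill
coefficient) wins the AICc ranking with Fobj ≈ 0.92 — a mean standardized
squared residual near 1, i.e. the fit sits at the noise level. For this
synthetic drug the dipper band is reachable in two dosing windows
(morning, 08:00–10:45 after awakening, or evening), but the 130/80 mmHg
target is not reachable at any Ta; the report then falls back to the dosing
time minimizing the cycle maxima (02:00 after awakening), mirroring how
such tables handle drugs that miss the therapeutic target.

The same workflow is scriptable from the shell:

```
chronopkpd synth --profile dipper --seed 42 --conc -o data/
chronopkpd pipeline --config examples/config.json -o run/
chronopkpd scan-ta --model run/best_fit.json --step 0.083 -o run/scan/
```

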