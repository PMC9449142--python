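# vanctdm

Vancomycin therapeutic drug monitoring (TDM) for critically ill adults:
individualized pharmacokinetic estimation from a sparse 4-sample schedule,
AUC- and trough-guided dose individualization, and ROC-based derivation of
nephrotoxicity cut-offs — with a seeded virtual-ICU-cohort generator so the
whole pipeline can be exercised and validated end to end without patient
data.

## Who this is for

Clinical pharmacists and pharmacometricians who run steady-state vancomycin
TDM on intermittent intravenous infusions and want a reproducible,
scriptable path from timed plasma concentrations to individualized doses
and exposure–toxicity cut-offs; and methodologists who want to study how
well sparse-sampling estimators and Youden cut-offs behave under known
ground truth.

## The model

Vancomycin kinetics are treated as one-compartment with first-order
elimination. Four plasma samples per patient are drawn at steady state over
one dosing interval τ (nominally 0, 1, 6, 12 h for a Q12 regimen with a 1-h
infusion): trough 1 pre-dose, peak at end of infusion, an intermediate
point, and trough 2 before the next dose. From these:

- AUCτ by the linear trapezoidal rule over the interval, and
  AUC₂₄ = AUCτ · 24/τ (exact doubling for Q12);
- Cl = X₀ / AUCτ (dose over interval AUC — a steady-state mass balance);
- V_d = X₀ / (C_max − C_min) (the peak–trough swing brackets one dose);
- k = Cl / V_d and t½ = 0.693 / k;
- agreement of the two troughs confirms steady state.

Dose individualization uses the target-trough administration rate
k₀ = C_min,target · V_d · k / (1 − e^(−kτ)) cross-checked against an exact
inversion of the forward intermittent-infusion model, and linear AUC
scaling Dose₂ = Dose₁ · AUC₂/AUC₁.

The toxicity analysis classifies exposure into the standard monitoring
bands (trough <10, 10–15, 15–20, ≥20 µg/ml; AUC₂₄ <400, 400–600,
≥600 µg·h/ml), tests each PK parameter against the acute-kidney-injury
(AKI) outcome with normality-gated t / Mann-Whitney tests, runs Pearson
chi-square across bands, adjusts the exposure association for concomitant
nephrotoxins by logistic regression, and derives per-marker cut-offs by
maximizing the Youden index J = sensitivity + specificity − 1 on empirical
ROC curves.

The synthetic cohort generator draws demographics from truncated normals
(age 50 ± 19 y, ideal body weight 66 ± 10 kg, baseline serum creatinine
0.95 ± 0.32 mg/dl), computes baseline GFR through Cockcroft–Gault (never
independently, which forces the clinical negative creatinine–GFR
coupling), links clearance to GFR, and drives AKI through a logistic
exposure–toxicity process tuned to a 17% cohort prevalence.

## Worked example

```python
from vanctdm import RunConfig, CohortConfig, run_pipeline

cfg = RunConfig(seed=42, cohort=CohortConfig(n_patients=53, seed=42))
report = run_pipeline(cfg)
print(report.tox_results.summary())
```

prints (abridged):

```
Nephrotoxicity analysis: n=53, AKI prevalence 17.0%

Association with AKI (two-group tests):
         parameter    test_used  p_value
           trough1       t_test   0.0021
           trough2 mann_whitney   0.0062
       mean_trough mann_whitney   0.0089
           auc_tau mann_whitney   0.1518
...

ROC cut-offs (Youden):
  parameter  cutoff  auroc  sensitivity_pct  specificity_pct
    trough1    8.92   0.78           100.00            54.55
mean_trough    9.26   0.78           100.00            56.82
    auc_tau  364.58   0.65            44.44            88.64
          k    0.08   0.82            88.89            68.18

Nephrotoxin-adjusted exposure odds ratio (per ug/ml mean trough): 1.111
(95% CI 1.026-1.204, p=0.0098)
```

Nine of the 53 virtual patients developed AKI (17.0%); their troughs sit
significantly higher than the non-AKI group, and the Youden cut-off on
trough 1 (8.9 µg/ml in this small noisy cohort) trades specificity for
100% sensitivity. The elimination-constant marker is oriented the other
way: *slower* elimination (k below its cut-off) indicates accumulation
risk.

The same run is available from the shell:

```bash
vanctdm pipeline --n 53 --seed 42 --out report/
vanctdm simulate --n 100 --seed 7 --out-patients p.csv --out-samples s.csv
vanctdm estimate --patients p.csv --samples s.csv --out estimates.csv
```

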