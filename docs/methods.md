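# Methods

## Kinetic model

All patients are modeled as a single well-stirred compartment with
first-order elimination, receiving repeated constant-rate infusions of
duration T every τ hours. With k = Cl/V_d and k₀ = X₀/T, the steady-state
profile is the closed-form superposition of all previous doses: the
pre-dose trough is

    C_trough = (k₀ / (V_d k)) · (1 − e^{−kT}) · e^{−k(τ−T)} / (1 − e^{−kτ}),

the concentration rises as C_trough·e^{−kt} + (k₀/(V_d k))(1 − e^{−kt})
during the infusion, and the end-of-infusion peak decays
mono-exponentially to the next trough. The profile is periodic
(C(0) = C(τ)); the implementation is verified against brute-force
dose-by-dose superposition to 1e−6 relative over randomized kinetics
(truncating the dose sum after 30 half-lives, whose own error is ~1e−9).

Steady state is assumed by the fifth dose. Sampling covers one interval at
(0, T, τ/2, τ) — the classic (0, 1, 6, 12) h design for Q12 with a 1-h
infusion.

## Individualized estimators

Per patient, from the four samples:

- **AUCτ** — linear trapezoid on every segment. Log-linear interpolation
  is deliberately not used: the linear rule matches the arithmetic of
  routine TDM practice and keeps AUC₂₄ = (24/τ)·AUCτ self-consistent.
  At steady state the exact interval AUC equals X₀/Cl (mass balance),
  which gives a closed-form oracle: on noiseless profiles with
  k ∈ [0.02, 0.15] h⁻¹ the 4-point trapezoid is within 5% of X₀/Cl (worst
  measured error 4.4% at the top of the range), so the Cl estimator
  inherits the same bound. Faster eliminators need denser sampling; the
  estimators still run but the 5% bound no longer applies.
- **Cl** = X₀/AUCτ.
- **V_d** = X₀/(C_max − C_min), with C_min the pre-dose trough and C_max
  the end-of-infusion sample, so the swing brackets exactly one dose. The
  estimator is exact in the bolus limit (T→0) and carries an
  infusion-shape bias of order 10% for a 1-h infusion at k = 0.1 h⁻¹
  (bounded at 15% in the tests).
- **k** = Cl/V_d, **t½** = 0.693/k. The clinical constant 0.693 is used
  for report parity; ln 2 is available via `half_life(..., use_ln2=True)`.
- **Steady-state check** — per-patient relative trough difference against
  a 25% default tolerance (a per-patient screening heuristic; the
  cohort-level paired t-test is exposed separately). Two zero troughs are
  indeterminate, not confirmed.

Report tables round decimal-half-up at 2 decimals (`report_round`):
clinical software rounds the displayed decimal value, which differs from
binary-float banker's rounding in edge cases such as 0.693/0.28.

## Dose individualization

- Initial dosing: loading 25 mg/kg and maintenance 17.5 mg/kg of ideal
  body weight by default (mid-range of the 20–35 / 15–20 mg/kg guideline
  bands; values outside the bands warn but compute), rounded to 250-mg
  vial increments.
- Target-trough: the closed-form rate k₀ = C_min·V_d·k/(1 − e^{−kτ}) is
  reported alongside an exact dose obtained by bisection on the forward
  model's trough. The closed form is correct in the continuous-infusion
  limit but, applied as a rate over a short infusion, under-doses
  substantially; recommendations whose two doses disagree by more than
  20% are flagged for review rather than silently chosen, and the
  reported predicted trough is always recomputed through the forward
  model, never assumed.
- AUC targeting: Dose₂ = Dose₁·AUC₂/AUC₁, exact under linear kinetics;
  the closed-loop residual equals the trapezoid estimation bias only
  (verified ≤5% in-range).

## Toxicity analysis

- Normality is screened per outcome group with the estimated-parameter
  Kolmogorov–Smirnov test (Lilliefors critical values, as SPSS-style
  workflows use); groups below n = 4 skip the gate with a warning. Both
  groups normal → pooled-variance t-test; otherwise Mann-Whitney U.
  Raw p-values are reported (no multiplicity correction by default,
  matching routine single-study practice); `holm_adjust` is available.
- Exposure bands are lower-inclusive/upper-exclusive and partition the
  positive axis; band × AKI tables use Pearson chi-square without
  continuity correction, warning on expected counts < 5 with a Fisher
  exact fallback for 2×2 tables.
- ROC curves place thresholds at midpoints between sorted unique marker
  values plus ±∞ sentinels; the trapezoidal area equals the
  concordant-pair fraction U/(n₁n₂) with ties counted one half (proved
  exact to 1e−12 against pair counting in the tests). The cut-off
  maximizes Youden's J; ties break toward the lower (more sensitive)
  threshold. Troughs and AUCs are "higher ⇒ toxic"; the elimination
  constant is oriented "lower ⇒ toxic" (slow elimination means
  accumulation) by negation, with cut-offs reported on the original
  scale. The "mean trough" marker is the per-patient arithmetic mean of
  the two bracketing troughs. A constant marker yields AUROC 0.5 and an
  explicitly undefined cut-off.
- The exposure–AKI association is adjusted for concomitant-nephrotoxin
  co-treatment by maximum-likelihood logistic regression; constant
  covariates are dropped with a warning and separation is an explicit
  failure (a penalized refit is a user decision, never applied silently).

## Synthetic cohort: what it emulates

Defaults describe a critically ill adult ICU TDM population:

| Quantity | Default | Basis |
|---|---|---|
| age | truncated N(50.25, 19.12²) on [18, 85] y | population mean ± SD and range |
| ideal body weight | truncated N(65.52, 10.16²) on [44, 95] kg | idem |
| height | truncated N(166.62, 9.72²) on [140, 185] cm | reporting only |
| baseline SCr | truncated N(0.95, 0.32²) on [0.5, 2.2] mg/dl | idem |
| female fraction | 0.472 | idem |
| baseline GFR | Cockcroft–Gault of the draws; redrawn until ≥ 45 ml/min | eligibility rule; forces r(SCr, GFR) ≈ −0.67 |
| Cl | 0.06·GFR · exp(N(0, 0.25²)) L/h | ~80–90% renal elimination; spans ≈1–21 L/h |
| V_d | 0.7·IBW · exp(N(0, 0.5²)) L | population 0.7 L/kg median; σ chosen to reproduce the order-of-magnitude clinical spread |
| regimen | 15/17.5/20 mg/kg Q12, 1-h infusion, 250-mg rounding | guideline maintenance menu |
| assay CV | 0.10 proportional | HPLC plus clinical pre-analytic variability |
| nephrotoxin co-treatment | 24.5% | cohort-typical rate |
| AKI | Bernoulli(logistic(β₀ + 0.15·mean trough)), β₀ tuned by bisection to 17% expected prevalence (±0.005) | exposure-driven toxicity, cohort prevalence anchor |

Measurement noise is mean-one multiplicative lognormal with the stated
coefficient of variation, so zero CV returns exact model values and
concentrations are always positive. Randomness is keyed per patient as
(master seed, patient id, stream), making cohorts bit-stable under
reordering and patient records independent of cohort size.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: time-varying renal function within an
interval (augmented renal clearance, evolving AKI), two-compartment
distribution, correlated assay errors, missed or mistimed samples,
non-adherent dosing histories, and an AKI outcome defined from creatinine
trajectories (the outcome is a latent Bernoulli process, since consensus
staging criteria require longitudinal SCr that the generator does not
model mechanistically).

## Numerical choices

- `expm1`-based evaluation of 1 − e^{−kt} terms for small k·t; the
  target-trough rate is guarded the same way and a zero interval raises.
- Intercept tuning and exact-dose inversion both use plain bisection
  (monotone objectives) with explicit iteration caps.
- Truncated normals are drawn by inverse-CDF transform of a single
  uniform, preserving one-draw-per-quantity stream discipline.
- Degenerate inputs have explicit behaviors rather than NaNs: zero-trough
  steady-state checks are indeterminate, constant markers give undefined
  cut-offs, empty on-target selections return an explicit empty result,
  and single-outcome cohorts are rejected up front.
- A noisy near-flat profile can measure its trough at or above its peak,
  leaving V_d undefined. The estimator primitive raises (the profile
  signals an assay or sampling problem); the cohort-level fit drops such
  patients with a warning and records them in ``results.dropped``, so one
  bad profile never aborts a cohort analysis (``fit(on_error="raise")``
  restores strictness).

## Problem sizes used in validation

The bundled checks run the study-sized cohort (53 patients, 212 samples),
a 5,000-patient calibration cohort for prevalence and the renal coupling,
50 × 2,000-patient cohorts for Youden cut-off recovery (the estimated
cut-off falls within ±2 µg/ml of the constructed 17 µg/ml threshold in
50/50 seeds), and 500 random small ROC instances for the exact
pair-counting identity.

## Known limitations

- The trapezoid/mass-balance 5% bound is specific to the 4-point design
  and k ≤ 0.15 h⁻¹; Q8 regimens use the generalized (0, T, τ/2, τ)
  schedule on the same assumption.
- The V_d estimator's infusion-shape bias is uncorrected (matching the
  peak–trough definition used in routine practice) and propagates into k
  and t½.
- No Bayesian/MAP or population mixed-effects estimation; no
  renal-replacement or continuous-infusion regimens; microbiological
  targets (AUC/MIC) are out of scope.
- Small-cohort ROC cut-offs are highly variable (the 53-patient worked
  example illustrates this); cut-offs intended for decision-making should
  come from larger cohorts or be bootstrapped.
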