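# Methods

## Scope and model

`gfrbench` implements a complete external-validation study of six GFR
estimating equations against a measured reference, in the form used by
clinical method-comparison papers: per-equation agreement statistics,
subgroup stratification, and pairwise statistical comparison of the
equations. Because no patient-level data are distributed with the study
population it emulates, the cohort itself is synthetic; the statistical
machinery is exact and the generator is designed so that the pipeline's
correctness is provable (see "What the synthetic cohort does and does not
show").

## Equations

The six equations are evaluated exactly as printed in their sources, at
full floating precision:

| id | inputs | form |
|---|---|---|
| MDRD7 | Scr, age, sex, race, BUN, Alb | 170·Scr⁻⁰·⁹⁹⁹·Age⁻⁰·¹⁷⁶·BUN⁻⁰·¹⁷⁰·Alb⁰·³¹⁸ ×0.762♀ ×1.180 black |
| AMDRD | Scr, age, sex, race | 186·Scr⁻¹·¹⁵⁴·Age⁻⁰·²⁰³ ×0.742♀ ×1.212 black |
| RE_AMDRD | as AMDRD | same with constant 175 (IDMS re-expression) |
| CKD_EPI_CR | Scr, age, sex, race | sex-specific threshold κ (0.7♀/0.9♂), shallow exponent below κ (−0.329♀/−0.411♂), −1.209 above; 144♀/141♂; 0.993^Age; ×1.159 black |
| CKD_EPI_CYS | Scys, age, sex | threshold 0.8, exponents −0.499/−1.328; 133; 0.996^Age; ×0.932♀ |
| CKD_EPI_CR_CYS | Scr, Scys, age, sex, race | 130♀/135♂; Scr exponents −0.248♀/−0.207♂ below κ, −0.601 above; Scys exponents −0.375/−0.711 at 0.8; 0.995^Age; ×1.08 black |

Numerical conventions:

- Threshold ties go to the low branch ("≤" as printed). The piecewise maps
  are continuous at every breakpoint, so the choice is numerically
  irrelevant; the branch taken is still tested.
- Age is continuous; no integer truncation is applied.
- The black-race factors are implemented because the printed formulas
  include them, but default to false — the emulated population is Chinese.
- Serum creatinine is assumed IDMS-comparable (the emulated study used an
  enzymatic assay); no calibration correction is applied.
- The 7-variable MDRD equation takes urea **nitrogen** (mg/dl). A converter
  (urea ↔ urea-N, factor 28/60, plus SI conversions for creatinine and
  urea) supports laboratories reporting either quantity.
- Missing analytes produce explicit missing values in the estimate table
  (never silent exclusion); every downstream metric uses complete pairs
  per equation and reports the n used.

## Validation statistics

With error eᵢ = eGFRᵢ − mGFRᵢ (positive = overestimation):

- **bias** = ē; **precision** = sample SD of e (n−1 denominator);
- **P15/P30/P50** = 100 × #{|eᵢ|/mGFRᵢ ≤ τ}/n for τ = 0.15/0.30/0.50
  (monotone in τ by construction);
- **limits of agreement** = bias ± 1.96·precision (Bland–Altman); both the
  classical abscissa (pairwise mean) and mGFR are emitted for the plot
  data, so either convention can be drawn;
- **Pearson r** with the univariate regression slope/intercept of eGFR on
  mGFR;
- **ROC AUC** for the positive class mGFR < 60 ml/min/1.73 m² (the chronic
  kidney disease staging boundary, also the lowest stratification cutoff),
  scoring by −eGFR so an informative estimator gives AUC ≥ 0.5; computed
  as the Mann–Whitney statistic (scikit-learn), ties counted ½; the
  orientation and positive-class definition are recorded in run metadata;
- **sensitivity** at the natural clinical operating point eGFR < 60
  classifying mGFR < 60; the Youden-optimal cutoff and its sensitivity are
  also emitted for reference, since validation reports rarely state their
  operating point;
- **paired t test** on signed per-patient error differences eₐ − e_b (bias
  is the mean signed error, so its difference is tested on the signed
  scale), two-sided, n−1 df; identical vectors give t = 0, p = 1, and a
  zero-variance nonzero-mean difference is reported as degenerate;
- **McNemar test** on within-P30 discordance: statistic
  (|b − c| − 1)²/(b + c) with continuity correction; p from the exact
  binomial when b + c < 25, otherwise the χ²₁ tail; b + c = 0 is
  degenerate (p = 1, flagged);
- p-values are two-sided throughout; raw p-values are reported alongside a
  Holm-adjusted column, clearly an extension over the usual uncorrected
  multiple comparisons.

Subgroup bins follow the printed stratification labels, read so the three
labels partition the line: GFR [0, 60), [60, 90], (90, ∞) and age
[18, 45), [45, 60], (60, ∞); sex, obstruction laterality (unilateral /
bilateral) and disease-duration class (≥ 3 months / < 3 months, an opaque
boolean) are categorical. Records missing a stratification variable are
excluded from that stratification only, with counts recorded in metadata.
Subgroup stratification by GFR uses measured GFR. On complete-case data the
overall bias equals the n-weighted mean of any one variable's subgroup
biases; this algebraic identity is tested.

## Synthetic cohort

The generator targets a published obstructive-nephropathy population
summary: n = 245, 53.5 % male, age 51.6 ± 14.2 y (truncated ≥ 18),
mGFR 66.54 ± 23.99 ml/min/1.73 m², weight 62.0 ± 12.1 kg, height
163.9 ± 7.2 cm, albumin 3.7 ± 0.5 g/dl, urea (nitrogen) ≈ 18 mg/dl.

The joint distribution of (Scr, Scys, mGFR) is not recoverable from a
summary table, so a **shared-latent-true-GFR** model is used: each
patient's true GFR G is drawn from N(66.54, 23.99²) truncated to [5, 150]
(spanning end-stage disease to supra-normal filtration), and

- Scr = invert_CKD-EPIcr(G, age, sex) · exp(N(0, σ_m)),
- Scys = invert_CKD-EPIcys(G, age, sex) · exp(N(0, σ_m)),
- BUN = (8 + 500/G) · exp(N(0, σ_m))  (an inverse-GFR retention curve
  whose constants put the cohort mean near 18 mg/dl),
- mGFR = G · exp(N(0, σ_d)), reported both indexed (ml/min/1.73 m²) and
  raw (× BSA/1.73),

with marker noise σ_m = 0.15 and measurement noise σ_d = 0.08 on the log
scale. The inversions are closed-form: each CKD-EPI map is continuous and
strictly decreasing in its marker, so the low branch is solved first and
the steep branch used when the solution crosses the sex threshold.

Choices made where the emulated summary is silent:

- creatinine (1.2 ± 1.1) and cystatin C (1.4 ± 0.7) are *not* sampled
  directly; they emerge from the GFR-driven model (defaults give cohort
  means ≈ 1.2 mg/dl and ≈ 1.3 mg/l). This makes equation-recovery
  properties provable: with σ_m = σ_d = 0 the CKD-EPI estimates equal
  mGFR to inversion round-off;
- the "serum urea 18.0 ± 10.8 mg/dl" row is read as urea nitrogen (the
  7-variable MDRD input); both a BUN and a urea (×60/28) column are
  emitted so either reading is available;
- sex-specific height/weight offsets of ±4 cm/±4 kg around the combined
  means keep BSA realistic per sex;
- noise magnitudes: σ_m = 0.15 yields overall P30 values in the 80–95 %
  range and r ≈ 0.8–0.9 — an idealised but not degenerate regime; σ_d =
  0.08 reflects that tracer clearance is itself an imperfect measurement;
- unilateral fraction 0.68 and duration fraction 0.5 are free parameters
  with no published anchor.

### What passing tests do and do not show

The generator shares its creatinine/cystatin model with two of the
equations under test, so the CKD-EPI family is *structurally favoured* on
synthetic data: its near-zero bias there verifies the pipeline's internal
consistency, not clinical superiority. MDRD-family bias on synthetic data
reflects formula disagreement with the CKD-EPI forms, not performance in
patients. Real cohorts add non-GFR determinants of both markers (muscle
mass, inflammation, assay drift) that the model omits; absolute accuracies
here are therefore optimistic, and published cohort values (r ≈ 0.68–0.72,
P30 ≈ 53–69 %) are not expected to be reproduced. What the tests *do*
establish: the equations match an independent arbitrary-precision
re-evaluation to < 1e-12; every metric matches its oracle (brute-force
pair counting for AUC, closed forms elsewhere); the paired t comparison is
calibrated under the null; and the full pipeline is bit-reproducible given
a seed.

## Problem sizes and tolerances

Default test runs use cohorts of 150–2,000 patients and 10,000 for
marginal-recovery checks; the null-calibration simulation uses 2,000
replicates at n = 25–30. Equation-vs-oracle agreement is asserted at
relative 1e-12 (the implementation is double precision; the oracle carries
50 digits); inversion round-trips at 1e-10; metric identities at 1e-9 or
exact. Report CSVs round to 2 decimals (display precision of the source
tables), except p-values, which keep 4 decimals so significance structure
survives rounding.

## Known limitations

- The synthetic cohort cannot validate equations clinically (see above);
  it is a test harness with realistic marginals.
- Confidence intervals for AUC, smoothed ROC curves and regression-based
  agreement (Passing–Bablok, Deming) are out of scope.
- Cockcroft–Gault and paediatric equations are not included.
- The McNemar exact/asymptotic switch at 25 discordant pairs is a
  convention; near the switch the two p-values differ slightly.
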