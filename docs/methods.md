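# Methods

This note documents the models, constants, and design choices behind
the package, in the order the pipeline runs them, and states what the
synthetic cohort does and does not emulate.

## 1. The DLW energy chain

The criterion method is the two-point doubly-labelled-water protocol: a
weighed oral dose of ²H₂O and H₂¹⁸O, a baseline urine sample, a
post-dose sample at 4 h (isotope equilibration), and a final sample on
day 10 collected at the same clock time. Both isotopes wash out
exponentially above baseline; ¹⁸O leaves as water **and** CO₂, ²H as
water only, so the rate difference measures CO₂ production.

Per participant, with excess enrichments `E(t) = sample − baseline`
(ppm):

| step | formula | units |
|---|---|---|
| elimination rate | `k = [ln E(t₁) − ln E(t₂)] / ((t₂−t₁)/24)` | /day |
| dose-time excess | `E₀ = E(t₁)·exp(k·t₁/24)` (back-extrapolation along the fitted line) | ppm |
| dilution space | `N = (dose_g/M)·a / (E₀·10⁻⁶)` | mol |
| total body water | `TBW_mol = (N_D/f_D + N_O/f_O)/2`, `f_D = 1.041`, `f_O = 1.007` | mol |
| body composition | `FFM = TBW_kg / HC(sex, age)`, `FM = weight − FFM` | kg |
| CO₂ production | `rCO₂ = 0.4554·TBW_mol·(f_O·k_O − f_D·k_D)` | mol/day |
| energy expenditure | `TEE = 22.4·rCO₂·(3.941/FQ + 1.106)`, `FQ = 0.86` | kcal/day |
| basal rate | Schofield weight-only band equations (boys `17.686·W + 658.2`, girls `13.384·W + 692.6`, 10–18 y) | kcal/day |
| activity expenditure | `PAEE = (0.9·TEE − BMR)/1440` | kcal/min |

All constants live in one overridable record (`DlwConstants`), because
the literature states them with small variations: `f_D`/`f_O` serve
double duty as non-aqueous-exchange corrections and in the Schoeller
rate combination; 0.4554/day is the combined Schoeller factor; 22.4
L/mol converts CO₂ moles to volume; 3.941 and 1.106 kcal/L are the
modified-Weir caloric equivalents. The `0.9` multiplier encodes the
assumption that the thermic effect of food is 10% of TEE.

Assumptions and contracts:

* **Two-point design.** Only the 4-h and day-10 samples exist, so the
  log-linear slope is exact, and the dilution-space excess is the 4-h
  excess back-extrapolated to dose time. Multi-point fitting is out of
  scope by design.
* **Hydration coefficients.** The sex- and age-specific fraction of FFM
  that is water defaults to 0.765/0.764/0.762 (boys 11/12/13) and
  0.770/0.768/0.766 (girls) — plausible adolescent values, fully
  overridable, with age taken as the completed year. Generator and
  analyser always share one table, so round-trip correctness never
  depends on the literature choice.
* **Schofield variant.** The weight-only 10–18-year equations are the
  default; a weight-and-height variant can be swapped in through
  `SchofieldTable` without code changes.
* **Flags vs exclusions.** Incomplete sample sets and post-dose
  enrichments at/below baseline raise a flagged-participant exclusion
  (mirroring the study protocol). Physiologically odd but computable
  results — FFM above body weight, negative FM or PAEE, an N_D/N_O
  ratio outside 1.015–1.060 — are flagged and retained; removal is the
  outlier screen's job, keeping stages orthogonal.
* **Food quotient sensitivity.** `∂TEE` is ≈ −1% per +0.01 FQ around
  0.86 (the `3.941/FQ` term); the suite pins this to the 0.8–1.1%
  band across FQ ∈ [0.80, 0.94].

## 2. Accelerometry

Streams are triaxial integer counts at 15-s epochs (1-s and 60-s also
accepted). Processing:

1. **Re-integrate** to 60-s per-axis totals (sums; a trailing partial
   window is dropped with a warning, never zero-padded — padding would
   deflate CPM).
2. **Vector magnitude** per minute: `√(a₁² + a₂² + a₃²)`, unrounded.
   Axes are summed first, then combined (sum-then-VM); the alternative
   per-epoch-VM-then-sum differs for fluctuating axes and is not the
   default because minute counts must be well defined for the
   minute-based non-wear rule.
3. **Non-wear**: scanning left to right, a candidate bout starts at a
   zero minute and extends through zeros, spending a 2-minute budget on
   interruptions with `0 < vm < 100` counts/min; a minute ≥ 100, or a
   third interruption, terminates the candidate, which is trimmed back
   to its last zero; candidates spanning ≥ 60 min (interruptions
   included) are non-wear. All thresholds are parameters. The test
   suite holds an independent minute-by-minute reference implementation
   and checks exact agreement on 1,000+ random streams.
4. **Valid days**: ≥ 600 wear minutes per midnight-to-midnight calendar
   day; "wake time" is operationalized purely by the non-wear detector,
   since devices were removed for sleep. Weekend = Saturday/Sunday.
5. **CPM** = Σ wear-time VM counts / Σ wear minutes over *valid* days
   only; the protocol requires ≥ 3 valid weekdays and ≥ 1 valid weekend
   day, otherwise the participant is flagged for exclusion. With zero
   valid wear time CPM is undefined (NaN), never 0.

## 3. Equation development and validation

* **Outlier screen**: single pass; a row is removed when any analysis
  column (age, weight, height, BMI, FFM, FM, CPM, PAEE) deviates more
  than 3 SDs from that column's mean, with moments computed once on the
  full input. No iteration after removals.
* **Split**: within each sex, sort by ascending age (ties broken by
  participant id for determinism) and send 1-based positions 3, 6, 9, …
  to the cross-validation group — 41 boys + 38 girls → 13 + 12 = 25
  held out, 54 for development.
* **Stepwise regression**: forward selection by smallest
  coefficient p-value < 0.05 (ties by candidate order), backward
  removal at p > 0.10 after each entry, candidates barred when their
  VIF against the current model exceeds 10. The candidate set is the
  union of the anthropometric and activity covariates (age, sex,
  weight, height, BMI, FFM, FM, CPM).
* **Goodness of fit**: R² = 100·(1 − SSE/SST); RMSE is the residual
  standard error `√(SSE/(n − p − 1))` — the denominator convention is
  recorded here because printed tables cannot adjudicate it.
* **Model selection**: the pooled equation is preferred unless the
  sex-specific pair improves R² by more than 5 percentage points *and*
  lowers RMSE in both sexes.
* **Cross-validation**: the fixed preliminary equation is applied to
  the held-out group; agreement is assessed by a paired t-test,
  Pearson correlation, pure error `√(Σ(obs − pred)²/n)` (denominator n:
  no parameter was estimated on these rows), and Bland–Altman bias ±
  1.96·SD limits (1.96, not a t-quantile).
* **PRESS**: leave-one-out residuals by the hat-matrix closed form
  `e_i/(1 − h_ii)` (explicit refit at leverage 1), `PRESS = Σ` squares,
  `PRESS-RMSE = √(PRESS/n)` so it is commensurable with pure error, and
  `PRESS-R² = 100(1 − PRESS/SST) ≤ R²` always.

## 4. The synthetic cohort

The generator emulates the study conditions: 41 boys and 38 girls in
the final sample (49 + 47 enrolled in the planted-exclusion
configuration), 10-day protocols, and per-sex covariate moments set to
the development-group values (boys: age 12.0 ± 0.8 y, weight 34.2 ± 7.5
kg, height 1.40 ± 0.10 m, CPM 403.5 ± 181.7; girls: 12.0 ± 0.8,
36.8 ± 9.2, 1.50 ± 0.10, 388.9 ± 163.6). True PAEE follows the
published final equation `0.001·CPM − 0.112` plus sex-specific Gaussian
residuals (SD 0.139 boys / 0.122 girls, the published per-sex RMSEs),
truncated to positive values; true TEE is constructed by inverting
`PAEE = (0.9·TEE − BMR)/1440` with the Schofield BMR, so the
regression ground truth is exact by construction.

Design choices a user should know:

* **Bounded draws.** Covariates are symmetric truncated normals (±2.5
  population SDs; CPM at `min(2.5, μ/σ)` to stay positive and
  symmetric; age within the 11–13.75-y recruitment window), and the
  generated cohort is certified against the actual ±3 SD screen: the
  rare clean row the screen would flag is redrawn. Means are therefore
  unbiased while realized SDs shrink by the closed-form truncation
  factor (≈ 3.5% at z = 2.5; the tests use this factor). This is what
  makes the exclusion arithmetic — 96 enrolled, 1 incomplete + 4
  below-baseline + 4 wear-protocol + 8 outliers → 79 analysed —
  deterministic for every seed.
* **Body composition.** FFM is `weight·(1 − body-fat fraction)` with
  per-sex fat-fraction moments (0.266 ± 0.10 boys, 0.321 ± 0.10 girls,
  bounded to [0.05, 0.45]) chosen to reproduce the group FFM/FM means;
  drawing FFM independently of weight would produce negative fat
  masses. TBW truth is FFM times the hydration coefficient.
* **Isotope forward model.** Dilution spaces sit at a fixed
  N_D/N_O = 1.034 around the true TBW; `k_D` defaults to 0.10/day
  (≈ 2 L/day water turnover at these body sizes) and `k_O` is solved so
  the Schoeller–Weir chain returns the true TEE exactly. Doses are
  0.12 g/kg (²H₂O, 99.8%) and 1.8 g/kg (H₂¹⁸O, 10%) of assumed body
  water (0.6 × weight — the protocol doses on pre-study estimates).
  Baselines are fixed at natural-abundance-like values (155.76 /
  2005.2 ppm). Measurement noise is multiplicative on the post-dose
  *excesses* at CV 1.0% (²H) and 0.08% (¹⁸O); this yields ≈ 5–6% TEE
  CV, the method's known field precision. (Applying those CVs to the
  absolute ppm readings instead would imply ≈ 30% TEE CV, which no DLW
  laboratory would accept; the excess reading is the deliberate one.)
  With CVs at zero the analysis chain inverts the generator to
  round-off (≤ 10⁻⁹ relative), which the suite asserts.
* **Epoch streams.** Each day has overnight non-wear (00:00–06:00 and
  22:00–24:00) and one seeded daytime bout of 60–120 min; wear-minute
  VM totals are lognormal (σ = 0.7), split across axes in fixed
  proportions and rescaled so that the mean over wear minutes equals
  the true CPM before integer rounding. The accelerometry pipeline
  recovers the planted wear mask exactly and the true CPM to ≈ 3·10⁻⁶
  relative (integer rounding is the floor), comfortably inside the 1%
  recovery contract. Wear-protocol failures are planted by ending wear
  after day 2.
* **What is not emulated.** No weight–height or age–size correlations
  (only CPM enters the final model, so the joint structure is
  inessential); no mechanistic activity patterns, school-day or
  seasonal effects; no diurnal CPM profile; FFM/FM dispersion is wider
  than the printed group SDs because it derives from weight. Passing
  tests therefore demonstrate the *procedures* are correct on data with
  the study's first-order statistical shape, not that the generator
  mimics real children in every joint moment.
* **Known distortion.** The PAEE > 0 truncation lifts the low-CPM end
  of the response, so refitting the generating equation on a truncated
  cohort attenuates the slope by roughly 15–20% at these moments (still
  0.001 at the printed 3-decimal precision). Analyses that need
  unbiased recovery switch the truncation off
  (`truncate_paee_at_zero=False`), which is also the protocol used by
  `scripts/acceptance.py`.

## 5. Numerical choices and degenerate inputs

* Elimination rates and dilution spaces raise flagged-participant
  errors on non-positive excesses; equal sample times are a domain
  error.
* The stepwise loop treats NaN p-values (perfect fits) as non-entries;
  a rank-deficient trial design bars the candidate.
* `paired_t` refuses zero-variance differences rather than returning
  an infinite statistic; `validate_equation` records the degeneracy in
  its notes instead of failing.
* Zero-variance columns are skipped (with a warning) by the outlier
  screen.
* PRESS falls back to an explicit refit when a leverage reaches 1.
* Determinism: one seed governs all stages; per-participant substreams
  come from `SeedSequence((seed, index, purpose))`, so regenerating any
  participant's record or stream does not depend on iteration order.

## 6. Problem sizes

The test suite exercises cohorts of 6–24 participants end to end
(full 10-day streams), one 96-participant enrolled replication, 5,000
participants for coefficient recovery, and 10⁴-scale cohorts for moment
convergence; Monte-Carlo checks use 300–10,000 replicates. These sizes
keep every statistical assertion's sampling error well below its band
while the whole suite runs in well under a minute of CPU.
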