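# Methods

## The model

Minute ventilation is modelled as a power function of wearable-measurable
predictors. On the log scale, for record *j* of subject *i*:

ln V̇E_ij = β₀ + β₁ ln HR_ij + β₂ ln f_B,ij + β₃ ln age_i + β₄ ln sex_i
          + β₅ ln FVC_i + u₀ᵢ + u₁ᵢ ln HR_ij + u₂ᵢ ln f_B,ij + ε_ij

with u₀ᵢ, u₁ᵢ, u₂ᵢ mutually independent zero-mean Gaussians (a
variance-components covariance) and ε_ij i.i.d. Gaussian. Exponentiating the
fixed-effect part gives V̇E = e^{β₀}·HR^{β₁}·f_B^{β₂}·age^{β₃}·sex^{β₄}·FVC^{β₅}.

Why this form:

* Log-transforming both sides linearizes the strongly non-linear HR–V̇E and
  f_B–V̇E relationships without higher-order terms, and the prediction can
  never go negative (several published linear models do at resting HR).
* Interaction terms are implicit: ln(HR·f_B) = ln HR + ln f_B is an exact
  linear combination of columns already in the design, so adding an explicit
  log-interaction column cannot change the fitted-value space — the
  no-interaction exponents absorb it (β₁′ = β₁ + β₃ for any least-squares
  solution of the augmented design). The test suite verifies this with a
  rank-revealing OLS oracle.
* Sex enters as the numeric code 1 (male) / 2 (female) treated as a continuous
  covariate, so its exponent is equivalent to a female indicator scaled by
  ln 2: the female/male ratio at equal covariates is exactly 2^{β₄}.
* FVC (liters) proxies functional lung size. When no measurement exists it is
  predicted from height, age, sex and reference group via GLI-style reference
  equations. The default resolution policy prefers a measurement when present
  (`prefer_measured`), since measured FVC captures individual deviation from
  the demographic prediction; `predicted_only` reproduces the estimation
  setting in which all coefficients were calibrated.

The random intercept absorbs stable subject-level ventilation offsets; random
slopes on ln HR and ln f_B absorb subject-specific dose–response differences
(the dominant source of the wide cross-validated IQR). A random effect for
study, lagged/factorial HR terms, and AR(1) residual covariance are
deliberately out of scope.

## Estimation

Fitting is delegated to statsmodels `MixedLM` with `re_formula="1"` and a
`vc_formula` carrying the independent slopes. Reported estimates and 95%
Wald CIs (±1.96·SE on the log scale) use REML; likelihood-ratio tests of fixed
effects always use a matched pair of ML refits on the identical row set
(REML likelihoods are not comparable across fixed-effect structures, so REML
fits are refused). The optimizer chain is L-BFGS with Powell and Nelder–Mead
fallbacks, deterministic given the data (no random starts). Non-convergence
raises; a random-effect variance estimated at the boundary only warns and
flags the result `singular`.

Degenerate noise-free input (OLS residual variance below 1e-12) short-circuits
to the exact least-squares solution flagged `OLS-degenerate`: the profiled
mixed-model likelihood is unbounded there, and the least-squares coefficients
are already exact.

Rows missing observed V̇E, HR, or (when modelled) f_B are excluded from
fitting and counted; they remain available for prediction. Records with
missing f_B are retained in the dataset so HR-only models can use them —
this mirrors pooled analyses where one contributing study measured no f_B.

## Cross-validation and error metrics

Validation is always grouped by subject: record-level k-fold would leak
within-subject correlation and overstate generalization. Folds are a seeded
balanced random partition of subjects (sizes ⌊n/k⌋ or ⌈n/k⌉); group mode makes
one fold per value of a profile field (study, sex, reference group) for
leave-one-group-out designs. Held-out subjects are predicted at the population
level (random effects zero) — no subject-specific effect exists for an unseen
person.

Percent error is (prediction − observation)/observation·100. Summaries report
the median, IQR (Q3−Q1, linear-interpolation quantiles — R's default type 7;
configurable because printed IQRs depend on the rule), the over/under split
(an exact zero counts as "over"; ties are measure-zero in practice), and the
shares at least 25 percentage points over/under (inclusive bounds).
Stratified reports count records, not subjects, per lung-function status.

Benchmark mode evaluates a fixed, never-refit model in a single pass; the
result is independent of any fold assignment. The linear Greenwald-2014 model
may produce nonpositive predictions at low HR/f_B; these are returned raw with
a flag (an opt-in clamp replaces them with NaN) so error comparisons match
raw-formula behaviour.

## Reference equations

Predicted lung volumes use exp(a₀ + a₁ ln height + a₂ ln age + spline(age))
per (sex, reference group, outcome), with the age-varying spline consumed as a
tabulated lookup with linear interpolation (ages outside the tabulated range
extrapolate flat with a warning). The packaged table is **synthetic**: its
coefficients are chosen for physiologic plausibility (healthy-adult FVC in the
2–7 L range, FEV₁ ≈ 0.8·FVC, group/sex offsets of realistic magnitude), not
taken from any published study, so that tests and simulation run offline.
Production use loads a real table (`ReferenceCoefficientTable.load`) or
supplies measured FVC. Percent-predicted status uses strict <85% (low) and
>115% (high) with both boundaries classified normal. No z-scores or
lower-limit-of-normal computation is attempted.

## The synthetic-data generator

`simulate_dataset` produces cohorts the fitting pipeline can be validated
against, with retained ground truth:

* **Demographics**: ages Beta(1.5, 2.5) scaled to 4–80 y (mean ≈ 33); sexes
  alternate (exactly balanced); adult heights N(176, 7) male / N(163, 6.5)
  female with a concave growth curve below 18 y, giving a cohort mean near
  163 ± 18 cm; ethnicity labels drawn with weights 79% Caucasian, 11%
  Hispanic, 5.8% Asian, 4.2% African-American.
* **Protocol**: per subject one 31-minute session — 5 min rest plateau, 20 min
  monotone ramp to 75–95% of (220 − age), 6 min exponential recovery — or,
  for a 20% ambulatory share, a bounded HR random walk. 471 subjects thus
  yield ≈14.6k one-minute records, the scale of the pooled study data.
* **Coupling**: f_B = max(8, 2 + 0.18·HR + N(0, 2)) breaths·min⁻¹, spanning
  the physiologic 10–60 range. No published joint HR–f_B distribution backs
  this; it is a documented modelling choice.
* **Outcome**: ln V̇E follows the mixed model above with the built-in D2
  coefficients as the generating truth, random-effect SDs (0.25 intercept,
  0.10 per slope), and residual SD 0.15. A 17% subset of subjects receives a
  "measured" FVC equal to the reference prediction times a log-centred 10%-SD
  perturbation — matching the reported spread of reference-equation FVC
  around true values — and that measured value is what enters their
  generating power law.

What passing tests show — and don't: parameter recovery and CV
self-consistency on these cohorts validate the estimation and validation
machinery under the model's own assumptions. They cannot certify performance
on real data, where HR–V̇E coupling is not exactly a power law, ventilation
responds to stress and noise as well as activity, device error is structured,
and demographics are jointly correlated in ways the marginal sampler ignores.

## Numerical choices and degenerate inputs

* Minute aggregation of sub-minute samples takes the arithmetic mean per
  calendar minute (median by config); minutes with no valid HR are omitted;
  unsorted timestamps are sorted with a warning; the operation is idempotent
  on per-minute data.
* Ingest drops and counts rows per reason (invalid HR/f_B/V̇E, unparseable
  cells, unknown subject, duplicate minute); rows_in = kept + dropped exactly.
  A subject failing profile invariants is dropped with their records. FEV₁
  exceeding FVC warns but keeps the subject (measurement noise can produce
  this legitimately).
* Dose integration is a rectangle rule at one-minute resolution with the
  single unit conversion 10⁻³ m³/L; gaps are never interpolated — they reduce
  `minutes_covered` and are counted by reason.
* The optional resting floor (clamp predictions below 0.78·FVC, the minimum
  observed resting ventilation fraction in the pooled data) is off by default:
  the power-function form cannot go negative, so the floor only matters for
  the legacy linear forms it was introduced to repair.

## Problem sizes used in the automated checks

Parameter recovery uses 20 cohorts of 200 subjects (~6.2k records each);
cross-validation self-consistency uses one 200-subject cohort with k=10;
the interaction-absorption identity uses a 50-subject cohort. These sizes give
stable Monte-Carlo behaviour for the quantities asserted (2·SE coverage,
pooled medians) while keeping a full run in the low minutes on one CPU.

## Known limitations

* Unit conventions (BTPS vs STPD) are not modelled; the toolkit assumes
  internally consistent L·min⁻¹ and liters throughout.
* The packaged reference table is synthetic; coefficient-level agreement with
  any published reference-equation implementation is not expected or claimed.
* Exponent estimates for age, sex and FVC are between-subject quantities with
  wide CIs at small cohort sizes, and age/height/FVC are collinear in children;
  the fitter reports honest SEs rather than regularizing.
* No modelling of stress/noise-driven ventilation, sub-minute dynamics, or
  respiratory-tract deposition.
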