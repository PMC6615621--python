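# minvent

Estimating **minute ventilation** (V̇E, the volume of air a person inhales per
minute, L·min⁻¹) matters for air-pollution exposure science because inhaled
dose is the product of pollutant concentration and V̇E. V̇E is intrusive to
measure in the field, but heart rate (HR) and breath frequency (f_B) are cheap
to record with wearables. `minvent` is a toolkit for researchers who need to
turn wearable physiology into ventilation and dose estimates:

* **Closed-form prediction models** of the power-function form

  V̇E = e^{β₀} · HR^{β₁} · f_B^{β₂} · age^{β₃} · sex^{β₄} · FVC^{β₅}

  with HR in beats·min⁻¹, f_B in breaths·min⁻¹, age in years, sex coded 1 for
  males and 2 for females, and FVC (forced vital capacity) in liters. Two
  pooled-data calibrations ship built-in: an HR-only model
  (`MODEL_D1`: β₀=−9.59, HR^2.39, age^0.274, sex^−0.204, FVC^0.520) and an
  HR+f_B model (`MODEL_D2`: β₀=−8.57, HR^1.72, f_B^0.611, age^0.298,
  sex^−0.206, FVC^0.614), plus six previously published V̇E models
  (Zuurbier, Ramos, Cozza, Do Vale, McArdle, Greenwald 2014) for benchmarking.
* **Mixed-model fitting**: refit the power function to your own per-minute
  data with a log-log linear mixed model (random intercept per subject,
  independent random slopes on ln HR and ln f_B), REML estimates with Wald
  CIs, ML likelihood-ratio tests per predictor.
* **Spirometry reference equations** in the GLI functional form
  (exp(a₀ + a₁ ln height + a₂ ln age + age-spline)) behind a pluggable
  coefficient table, with ethnicity-label → reference-group mapping and
  percent-predicted FVC classification (<85% low, 85–115% normal, >115% high).
* **Subject-grouped cross-validation** with percent-error reporting (median,
  IQR, over/under and ±25% tails), stratified by lung-function status.
* **Inhaled-dose integration** of predicted V̇E against a pollutant
  concentration series on a one-minute grid.
* **A synthetic-data generator** that produces cohorts with the full
  generative structure (demographics, exercise-ramp HR, HR-coupled f_B,
  power-law V̇E with subject-level random effects), so the entire pipeline is
  testable offline with known ground truth.

## Worked example

```python
import minvent as mv

# 1. Closed-form prediction: a 35-year-old woman, FVC 3.8 L, HR 110, f_B 24
ve = mv.predict_ve_power(mv.MODEL_D2, hr=110, fb=24, age=35, sex_code=2, fvc=3.8).ve
print(round(float(ve), 2))            # 24.36  (L/min)

# 2. Simulate a 120-subject cohort from the D2 power law, refit, cross-validate
table = mv.ReferenceCoefficientTable.synthetic_default()
sim = mv.simulate_dataset(mv.SimulationConfig(n_subjects=120), seed=42)
fit = mv.fit_loglog_lmm(sim.dataset, mv.ModelFormula.d2(), reference_table=table)
print({k: round(v["estimate"], 3) for k, v in fit.coefficients.items()})
# {'intercept': -8.235, 'hr': 1.719, 'fb': 0.59, 'age': 0.189, 'sex': -0.148, 'fvc': 0.633}

folds = mv.make_folds(sim.dataset, k=10, seed=42)
rep = mv.cross_validate(sim.dataset, mv.ModelFormula.d2(), folds, reference_table=table)
print(round(rep.overall.median_pe, 2), round(rep.overall.iqr_pe, 1))
# -3.12 86.0   (median % error near zero; IQR reflects between-subject spread)

# 3. Inhaled dose for one subject at a constant 35 µg/m³ PM2.5 exposure
sid = "sim0000"; p = sim.dataset.subjects[sid]
rec = sim.dataset.records.query("subject_id == @sid")
fvc, src = mv.resolve_fvc(p, predicted=mv.predict_fvc(p, table))
ve_hat = mv.MODEL_D1.predict(hr=rec.hr.to_numpy(), age=p.age, sex=float(p.sex_code), fvc=fvc)
conc = mv.ExposureSeries({m: 35.0 for m in range(31)}, pollutant="PM2.5")
dose = mv.integrate_dose({int(m): float(v) for m, v in zip(rec.minute_index, ve_hat)}, conc)
print(round(dose.total_dose, 2), dose.minutes_covered, src)
# 27.9 31 measured   (µg inhaled over a 31-minute session)
```

The refit in step 2 recovers the within-subject exponents (HR, f_B) tightly;
the between-subject terms (age, sex, FVC) carry wider CIs at 120 subjects, and
the fitted values bracket the generating coefficients. The cross-validated
median percent error near zero says the population-level model is unbiased for
people it never saw; the wide IQR is the irreducible between-subject
variability the random effects encode.

A command-line interface mirrors the library:

```sh
minvent simulate --seed 1 --n-subjects 50 --out cohort/
minvent fit --formula d2 --records cohort/records.csv --subjects cohort/subjects.csv --out fit.json
minvent cross-validate --formula d2 --k 10 --seed 1 \
    --records cohort/records.csv --subjects cohort/subjects.csv --out cv/
minvent benchmark --records cohort/records.csv --subjects cohort/subjects.csv --out bench.json
```

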