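"""Mixed-model fitting: design identities, recovery, LRTs, power-model export."""

import shutil
import subprocess

import numpy as np
import pytest

import minvent as mv
from minvent.exceptions import InputError
from minvent.mixed_model import build_design, chi2_lrt_pvalue


class TestInteractionAbsorption:
    """On the log scale, ln(HR*f_B) is an exact linear combination of ln HR and
    ln f_B, so an explicit interaction column changes nothing about the fitted
    value space and the no-interaction exponents absorb it: b1' = b1 + b3."""

    def test_redundant_column_leaves_fitted_values_unchanged(self, small_sim):
        df, _ = build_design(small_sim.dataset, mv.ModelFormula(fixed_terms=("hr", "fb")))
        y = df["ln_ve"].to_numpy()
        x1, x2 = df["ln_hr"].to_numpy(), df["ln_fb"].to_numpy()
        ones = np.ones_like(y)
        X_plain = np.column_stack([ones, x1, x2])
        X_redundant = np.column_stack([ones, x1, x2, x1 + x2])  # ln(HR*fB)

        beta_plain, *_ = np.linalg.lstsq(X_plain, y, rcond=None)
        beta_red, *_ = np.linalg.lstsq(X_redundant, y, rcond=None)
        np.testing.assert_allclose(X_plain @ beta_plain, X_redundant @ beta_red, atol=1e-8)

    def test_exponents_absorb_the_interaction_term(self, small_sim):
        df, _ = build_design(small_sim.dataset, mv.ModelFormula(fixed_terms=("hr", "fb")))
        y = df["ln_ve"].to_numpy()
        x1, x2 = df["ln_hr"].to_numpy(), df["ln_fb"].to_numpy()
        ones = np.ones_like(y)
        beta_plain, *_ = np.linalg.lstsq(np.column_stack([ones, x1, x2]), y, rcond=None)
        beta_red, *_ = np.linalg.lstsq(np.column_stack([ones, x1, x2, x1 + x2]), y, rcond=None)
        # any minimum-norm solution satisfies b1 + b3 = b1' and b2 + b3 = b2'
        assert beta_red[1] + beta_red[3] == pytest.approx(beta_plain[1], abs=1e-8)
        assert beta_red[2] + beta_red[3] == pytest.approx(beta_plain[2], abs=1e-8)


class TestFit:
    def test_noise_free_exact_recovery(self, reference_table):
        cfg = mv.SimulationConfig(
            n_subjects=25, residual_sd=0.0,
            random_effect_sds={"intercept": 0.0, "hr": 0.0, "fb": 0.0},
        )
        sim = mv.simulate_dataset(cfg, seed=5)
        with pytest.warns(UserWarning, match="noise-free"):
            fit = mv.fit_loglog_lmm(sim.dataset, mv.ModelFormula.d2(), reference_table=reference_table)
        assert fit.estimate("intercept") == pytest.approx(mv.MODEL_D2.intercept, abs=1e-8)
        for term, beta in mv.MODEL_D2.exponents.items():
            assert fit.estimate(term) == pytest.approx(beta, abs=1e-8)

    def test_estimates_near_truth_under_noise(self, small_fit):
        truth = {"intercept": mv.MODEL_D2.intercept, **mv.MODEL_D2.exponents}
        for term in ("hr", "fb"):  # within-subject terms are tightly estimated
            assert small_fit.estimate(term) == pytest.approx(truth[term], abs=4 * small_fit.se(term))
        assert small_fit.converged

    def test_ci_brackets_estimate(self, small_fit):
        for term, c in small_fit.coefficients.items():
            assert c["ci_low"] <= c["estimate"] <= c["ci_high"]

    def test_random_variances_reported(self, small_fit):
        rv = small_fit.random_variances
        assert {"subject_intercept", "hr_slope", "fb_slope", "residual"} <= set(rv)
        assert all(v >= 0 for v in rv.values())

    def test_single_subject_rejected(self, reference_table):
        sim = mv.simulate_dataset(mv.SimulationConfig(n_subjects=1), seed=0)
        with pytest.raises(InputError):
            mv.fit_loglog_lmm(sim.dataset, mv.ModelFormula.d2(), reference_table=reference_table)

    def test_refit_stability(self, small_sim, reference_table, small_fit):
        again = mv.fit_loglog_lmm(small_sim.dataset, mv.ModelFormula.d2(),
                                  reference_table=reference_table)
        for term in small_fit.coefficients:
            assert again.estimate(term) == small_fit.estimate(term)

    def test_log_residual_symmetry(self, small_sim, reference_table, small_fit):
        model = mv.as_power_model(small_fit)
        df, _ = build_design(small_sim.dataset, mv.ModelFormula.d2(),
                             reference_table=reference_table)
        pred = (small_fit.estimate("intercept")
                + sum(small_fit.estimate(t) * df[f"ln_{t}"] for t in small_fit.formula.fixed_terms))
        resid = df["ln_ve"] - pred
        assert abs(resid.mean()) < 0.1

    def test_rows_missing_ve_excluded_but_counted(self, small_sim, reference_table):
        ds = small_sim.dataset
        records = ds.records.copy()
        records.loc[records.index[:50], "ve_observed"] = np.nan
        ds2 = mv.PhysioDataset(ds.subjects, records, dict(ds.provenance))
        fit = mv.fit_loglog_lmm(ds2, mv.ModelFormula.d2(), reference_table=reference_table)
        assert fit.n_excluded_rows == 50
        assert fit.n_obs == ds.n_records - 50


class TestLikelihoodRatio:
    def test_zero_statistic_gives_p_one(self):
        assert chi2_lrt_pvalue(0.0, 1) == 1.0

    def test_chi2_tail_value(self):
        assert chi2_lrt_pvalue(10.83, 1) == pytest.approx(0.001, abs=5e-5)

    def test_reml_fits_refused(self, small_sim, reference_table, small_fit):
        reduced = mv.fit_loglog_lmm(small_sim.dataset, mv.ModelFormula.d2().drop("age"),
                                    reference_table=reference_table)
        with pytest.raises(InputError, match="ML"):
            mv.likelihood_ratio_test(small_fit, reduced)

    def test_fb_term_strongly_significant_on_synthetic_data(self, small_sim, reference_table):
        res = mv.lrt_for_term(small_sim.dataset, mv.ModelFormula.d2(), "fb",
                              reference_table=reference_table)
        assert res.df == 1
        assert res.pvalue < 1e-6

    def test_mismatched_row_sets_rejected(self, small_sim, reference_table):
        full = mv.fit_loglog_lmm(small_sim.dataset, mv.ModelFormula.d2(),
                                 reference_table=reference_table, reml=False)
        sub = mv.validation._subset(small_sim.dataset, list(small_sim.dataset.subjects)[:40])
        reduced = mv.fit_loglog_lmm(sub, mv.ModelFormula.d2().drop("age"),
                                    reference_table=reference_table, reml=False)
        with pytest.raises(InputError, match="row sets"):
            mv.likelihood_ratio_test(full, reduced)


class TestPowerModelExport:
    def test_round_trip_matches_fixed_effect_prediction(self, small_sim, reference_table, small_fit):
        model = mv.as_power_model(small_fit, name="refit")
        df, _ = build_design(small_sim.dataset, mv.ModelFormula.d2(),
                             reference_table=reference_table)
        linpred = (small_fit.estimate("intercept")
                   + sum(small_fit.estimate(t) * df[f"ln_{t}"] for t in ("hr", "fb", "age", "sex", "fvc")))
        ve = model.predict(
            hr=np.exp(df["ln_hr"]), fb=np.exp(df["ln_fb"]), age=np.exp(df["ln_age"]),
            sex=np.exp(df["ln_sex"]), fvc=np.exp(df["ln_fvc"]),
        )
        np.testing.assert_allclose(ve, np.exp(linpred), rtol=1e-12)

    def test_exponent_keys_are_fixed_terms_minus_intercept(self, small_fit):
        model = mv.as_power_model(small_fit)
        assert set(model.exponents) == set(small_fit.formula.fixed_terms)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstLme4:
    """Independent oracle: the same variance-components model fit by lme4."""

    def test_fixed_effects_agree_with_lme4(self, tmp_path, reference_table):
        sim = mv.simulate_dataset(mv.SimulationConfig(n_subjects=40), seed=21)
        df, _ = build_design(sim.dataset, mv.ModelFormula.d2(), reference_table=reference_table)
        csv = tmp_path / "design.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            m <- lmer(ln_ve ~ ln_hr + ln_fb + ln_age + ln_sex + ln_fvc +
                      (1 | subject_id) + (0 + ln_hr | subject_id) + (0 + ln_fb | subject_id),
                      data = d, REML = TRUE)
            cat(sprintf("%.10f\\n", fixef(m)))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        lme4_fe = [float(x) for x in out.stdout.split()]
        fit = mv.fit_loglog_lmm(sim.dataset, mv.ModelFormula.d2(), reference_table=reference_table)
        ours = [fit.estimate(t) for t in ("intercept", "hr", "fb", "age", "sex", "fvc")]
        np.testing.assert_allclose(ours, lme4_fe, atol=2e-3)
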