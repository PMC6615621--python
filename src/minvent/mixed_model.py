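"""Log-log linear mixed-model fitting for minute ventilation.

The model is

    ln(V̇E_ij) = b0 + Σ_k b_k * ln(x_kij) + u0_i + u_hr_i * ln(HR_ij)
                 [+ u_fb_i * ln(f_B_ij)] + e_ij,

i.e. fixed effects for log-transformed predictors (HR, optionally f_B, age,
sex coded 1/2, FVC), a per-subject random intercept and per-subject random
slopes on ln HR (and ln f_B when f_B is a fixed term), mutually independent
(variance-components covariance), with i.i.d. Gaussian residuals. Exponentiating
the fixed-effect part yields a :class:`~minvent.ventilation_models.PowerFunctionModel`,
so the fitted object predicts V̇E for new subjects at the population level.

Estimation is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`
(REML by default for reported estimates; ML refits for likelihood-ratio tests
of fixed effects). ln(sex) enters as a continuous covariate of the 1/2 coding —
equivalent to a female indicator scaled by ln 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PhysioDataset
from .exceptions import InputError, NotConvergedError, UnavailableFVCError
from .lung_reference import ReferenceCoefficientTable, predict_fvc
from .ventilation_models import PowerFunctionModel, resolve_fvc

__all__ = [
    "ModelFormula",
    "FitResult",
    "LRTResult",
    "build_design",
    "fit_loglog_lmm",
    "likelihood_ratio_test",
    "lrt_for_term",
    "chi2_lrt_pvalue",
    "as_power_model",
]

_PREDICTORS = ("hr", "fb", "age", "sex", "fvc")
_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ModelFormula:
    """Fixed terms plus the implied random structure.

    Random slopes attach to the within-subject time-varying terms (hr, and fb
    when present); the random intercept is always included. All random effects
    are mutually independent (variance components).
    """

    fixed_terms: tuple = ("hr", "age", "sex", "fvc")
    random_slopes: Optional[tuple] = None  # None -> auto: hr (+ fb if fixed term)

    def __post_init__(self):
        unknown = set(self.fixed_terms) - set(_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        if self.random_slopes is not None:
            bad = set(self.random_slopes) - set(self.fixed_terms)
            if bad:
                raise ValueError(f"random slopes {sorted(bad)} not among fixed terms")

    @property
    def slopes(self) -> tuple:
        if self.random_slopes is not None:
            return tuple(self.random_slopes)
        return tuple(t for t in ("hr", "fb") if t in self.fixed_terms)

    @classmethod
    def d1(cls) -> "ModelFormula":
        """HR as the only field-measured predictor (plus age, sex, FVC)."""
        return cls(fixed_terms=("hr", "age", "sex", "fvc"))

    @classmethod
    def d2(cls) -> "ModelFormula":
        """HR and breath frequency (plus age, sex, FVC)."""
        return cls(fixed_terms=("hr", "fb", "age", "sex", "fvc"))

    def drop(self, term: str) -> "ModelFormula":
        """The reduced formula without ``term`` (for likelihood-ratio tests)."""
        if term not in self.fixed_terms:
            raise ValueError(f"term {term!r} not in formula")
        remaining = tuple(t for t in self.fixed_terms if t != term)
        slopes = tuple(t for t in self.slopes if t in remaining)
        return ModelFormula(fixed_terms=remaining, random_slopes=slopes)


@dataclass
class FitResult:
    """Converged estimates: fixed effects with Wald CIs, random-effect variances."""

    coefficients: dict  # term -> {estimate, se, ci_low, ci_high}
    random_variances: dict  # e.g. subject_intercept, hr_slope, fb_slope, residual
    log_likelihood: Optional[float]
    n_obs: int
    n_subjects: int
    converged: bool
    method: str  # "REML" | "ML" | "OLS-degenerate"
    formula: ModelFormula
    singular: bool = False
    n_excluded_rows: int = 0
    fvc_policy: str = "prefer_measured"
    optimizer: str = ""

    def estimate(self, term: str) -> float:
        return self.coefficients[term]["estimate"]

    def se(self, term: str) -> float:
        return self.coefficients[term]["se"]

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": self.coefficients,
            "random_variances": self.random_variances,
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "method": self.method,
            "fixed_terms": list(self.formula.fixed_terms),
            "random_slopes": list(self.formula.slopes),
            "singular": self.singular,
            "n_excluded_rows": self.n_excluded_rows,
            "fvc_policy": self.fvc_policy,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_design(
    ds: PhysioDataset,
    formula: ModelFormula,
    fvc_policy: str = "prefer_measured",
    reference_table: Optional[ReferenceCoefficientTable] = None,
) -> tuple[pd.DataFrame, int]:
    """Assemble the log-scale design frame; returns (frame, n_excluded_rows).

    Rows missing any required field (observed V̇E, HR, f_B when modelled) are
    excluded. When the formula involves FVC it is resolved per subject under
    ``fvc_policy``, predicting from ``reference_table`` where needed; an
    unresolvable subject raises :class:`UnavailableFVCError`.
    """
    df = ds.records.copy()
    n_in = len(df)
    mask = df["ve_observed"].notna() & (df["ve_observed"] > 0) & df["hr"].notna() & (df["hr"] > 0)
    if "fb" in formula.fixed_terms:
        mask &= df["fb"].notna() & (df["fb"] > 0)
    df = df[mask]

    subj_rows = []
    needed_subjects = set(df["subject_id"])
    for sid in needed_subjects:
        profile = ds.subjects[sid]
        row = {"subject_id": sid, "age": profile.age, "sex": float(profile.sex_code)}
        if "fvc" in formula.fixed_terms:
            predicted = None
            if profile.measured_fvc is None or fvc_policy == "predicted_only":
                if reference_table is not None:
                    predicted = predict_fvc(profile, reference_table)
            try:
                fvc_val, fvc_src = resolve_fvc(profile, predicted=predicted, policy=fvc_policy)
            except UnavailableFVCError:
                raise UnavailableFVCError(
                    f"subject {sid}: FVC not resolvable under policy {fvc_policy!r} "
                    "(supply a reference table or measured FVC)"
                )
            row["fvc"] = fvc_val
            row["fvc_source"] = fvc_src
        subj_rows.append(row)
    df = df.merge(pd.DataFrame(subj_rows), on="subject_id", how="inner")

    out = pd.DataFrame({"subject_id": df["subject_id"].to_numpy(), "ln_ve": np.log(df["ve_observed"].to_numpy(float))})
    for term in formula.fixed_terms:
        out[f"ln_{term}"] = np.log(df[term].to_numpy(float))
    if "fvc_source" in df.columns:
        out["fvc_source"] = df["fvc_source"].to_numpy()
    out["minute_index"] = df["minute_index"].to_numpy()
    return out.reset_index(drop=True), n_in - len(out)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid) / max(len(y) - X.shape[1], 1)


def fit_loglog_lmm(
    ds: PhysioDataset,
    formula: ModelFormula,
    fvc_policy: str = "prefer_measured",
    reference_table: Optional[ReferenceCoefficientTable] = None,
    reml: bool = True,
    maxiter: int = 2000,
) -> FitResult:
    """Fit the log-log mixed model and return REML (default) or ML estimates.

    Deterministic given data, formula and optimizer settings: the optimizer
    starts from the profiled defaults and uses L-BFGS with Powell and Nelder-Mead
    fallbacks. Non-convergence raises :class:`NotConvergedError`; a singular
    random-effect variance only warns (the result is still returned, flagged).

    Degenerate noise-free input (OLS residual variance ~ 0) short-circuits to
    the exact least-squares solution, flagged ``singular`` with method
    ``OLS-degenerate``.
    """
    design, n_excluded = build_design(ds, formula, fvc_policy, reference_table)
    n_subjects = design["subject_id"].nunique()
    if n_subjects < 2:
        raise InputError(f"mixed model needs >= 2 subjects with usable records, got {n_subjects}")
    counts = design.groupby("subject_id").size()
    if int((counts >= 2).sum()) < 2:
        raise InputError("mixed model needs >= 2 subjects with >= 2 records each")

    terms = [f"ln_{t}" for t in formula.fixed_terms]
    X = np.column_stack([np.ones(len(design))] + [design[c].to_numpy(float) for c in terms])
    y = design["ln_ve"].to_numpy(float)
    ols_beta, ols_s2 = _ols(y, X)

    names = ["intercept"] + list(formula.fixed_terms)
    if ols_s2 < 1e-12:
        warnings.warn("residual variance ~ 0 (noise-free data); returning exact least-squares fit", stacklevel=2)
        coefficients = {
            nm: {"estimate": float(b), "se": 0.0, "ci_low": float(b), "ci_high": float(b)}
            for nm, b in zip(names, ols_beta)
        }
        return FitResult(
            coefficients=coefficients,
            random_variances={"residual": ols_s2},
            log_likelihood=None,
            n_obs=len(design),
            n_subjects=int(n_subjects),
            converged=True,
            method="OLS-degenerate",
            formula=formula,
            singular=True,
            n_excluded_rows=n_excluded,
            fvc_policy=fvc_policy,
            optimizer="lstsq",
        )

    import statsmodels.api as sm

    vc_formula = {f"{t}_slope": f"0 + ln_{t}" for t in formula.slopes}
    model = sm.MixedLM.from_formula(
        "ln_ve ~ " + " + ".join(terms),
        groups="subject_id",
        re_formula="1",
        vc_formula=vc_formula or None,
        data=design,
    )
    result = None
    last_exc: Optional[Exception] = None
    used = ""
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=reml, method=method, maxiter=maxiter)
            if candidate.converged:
                result, used = candidate, method
                break
            if result is None:
                result, used = candidate, method
        except Exception as exc:  # keep trying the fallback chain
            last_exc = exc
    if result is None:
        raise NotConvergedError(f"mixed-model optimization failed: {last_exc}")
    if not result.converged:
        raise NotConvergedError(
            f"mixed-model optimizer ({used}) did not converge after {maxiter} iterations"
        )

    fe = result.fe_params
    se = result.bse_fe
    coefficients = {}
    for nm, col in zip(names, ["Intercept"] + terms):
        est, s = float(fe[col]), float(se[col])
        coefficients[nm] = {
            "estimate": est,
            "se": s,
            "ci_low": est - _Z975 * s,
            "ci_high": est + _Z975 * s,
        }

    random_variances = {"subject_intercept": float(np.asarray(result.cov_re)[0, 0])}
    vc_names = list(model.exog_vc.names) if vc_formula else []
    for nm, v in zip(vc_names, np.asarray(result.vcomp, dtype=float)):
        random_variances[nm] = float(v)
    random_variances["residual"] = float(result.scale)

    singular = any(v <= 1e-10 for k, v in random_variances.items() if k != "residual")
    if singular:
        warnings.warn("singular random-effect variance (estimated at boundary)", stacklevel=2)

    return FitResult(
        coefficients=coefficients,
        random_variances=random_variances,
        log_likelihood=float(result.llf),
        n_obs=len(design),
        n_subjects=int(n_subjects),
        converged=bool(result.converged),
        method="REML" if reml else "ML",
        formula=formula,
        singular=singular,
        n_excluded_rows=n_excluded,
        fvc_policy=fvc_policy,
        optimizer=used,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def chi2_lrt_pvalue(statistic: float, df: int) -> float:
    """Upper-tail χ² probability of the LRT statistic."""
    if statistic <= 0:
        return 1.0
    return float(stats.chi2.sf(statistic, df))


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> LRTResult:
    """LRT of nested fixed-effect structures; both fits must be ML on the same rows."""
    for fit, label in ((full, "full"), (reduced, "reduced")):
        if fit.method != "ML":
            raise InputError(f"{label} fit uses {fit.method}; ML estimation is required for a fixed-effect LRT")
    if full.n_obs != reduced.n_obs:
        raise InputError(f"row sets differ: full n={full.n_obs}, reduced n={reduced.n_obs}")
    full_terms = set(full.formula.fixed_terms)
    red_terms = set(reduced.formula.fixed_terms)
    if not (red_terms < full_terms):
        raise InputError("reduced model's fixed terms must be a proper subset of the full model's")
    df = len(full_terms) - len(red_terms)
    statistic = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    return LRTResult(statistic=float(statistic), df=df, pvalue=chi2_lrt_pvalue(statistic, df))


def lrt_for_term(
    ds: PhysioDataset,
    formula: ModelFormula,
    term: str,
    fvc_policy: str = "prefer_measured",
    reference_table: Optional[ReferenceCoefficientTable] = None,
) -> LRTResult:
    """Convenience: ML-refit the full and term-dropped models on the full model's
    row set and test the term.

    Note the row set is the one defined by the *full* formula (dropping fb from
    the fixed terms would otherwise re-admit rows without fb)."""
    reduced_formula = formula.drop(term)
    full = fit_loglog_lmm(ds, formula, fvc_policy, reference_table, reml=False)
    # Restrict the reduced fit to rows usable by the full model.
    design_cols = set(formula.fixed_terms)
    if term in ("hr", "fb") and term in design_cols:
        sub = _restrict_to_full_rows(ds, formula)
        reduced = fit_loglog_lmm(sub, reduced_formula, fvc_policy, reference_table, reml=False)
    else:
        reduced = fit_loglog_lmm(ds, reduced_formula, fvc_policy, reference_table, reml=False)
    return likelihood_ratio_test(full, reduced)


def _restrict_to_full_rows(ds: PhysioDataset, formula: ModelFormula) -> PhysioDataset:
    mask = ds.records["ve_observed"].notna() & (ds.records["hr"] > 0)
    if "fb" in formula.fixed_terms:
        mask &= ds.records["fb"].notna() & (ds.records["fb"] > 0)
    kept = ds.records[mask]
    subjects = {sid: ds.subjects[sid] for sid in kept["subject_id"].unique()}
    return PhysioDataset(subjects, kept, dict(ds.provenance))


def as_power_model(fit: FitResult, name: str = "fitted") -> PowerFunctionModel:
    """Export the fixed-effect structure as a closed-form power-function model.

    Random effects are set to zero, so the model gives population-level
    predictions: exp(fixed-effect linear predictor).
    """
    if not fit.converged:
        raise InputError("cannot export an unconverged fit")
    exponents = {t: fit.estimate(t) for t in fit.formula.fixed_terms}
    return PowerFunctionModel(name=name, intercept=fit.estimate("intercept"), exponents=exponents)
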