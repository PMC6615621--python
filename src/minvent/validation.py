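"""Cross-validation and percent-error reporting for V̇E models.

Model performance is summarized by the signed percent error
(prediction - observation)/observation * 100 over pooled held-out records:
median and IQR (accuracy and precision), the over/under split, and the shares
over- or under-predicted by at least 25%.

Cross-validation is grouped by subject — every subject's records land in
exactly one validation fold, so a model is always scored on people it never saw
(record-level k-fold would leak within-subject correlation). Held-out subjects
are predicted at the population level (random effects zero). Group mode
(``group_by="study_id"`` etc.) makes one fold per group value instead, e.g.
leave-one-study-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_model import PhysioDataset, SubjectProfile
from .exceptions import DomainError, InputError, UnavailableFVCError
from .lung_reference import ReferenceCoefficientTable, predict_fvc
from .mixed_model import ModelFormula, as_power_model, fit_loglog_lmm
from .ventilation_models import (
    LegacyModelSpec,
    PowerFunctionModel,
    predict_ve_legacy,
    resolve_fvc,
)

__all__ = [
    "FoldAssignment",
    "ErrorSummary",
    "CVReport",
    "percent_error",
    "summarize_errors",
    "make_folds",
    "cross_validate",
    "stratify_report",
    "evaluate_fixed_model",
    "benchmark",
]


def percent_error(prediction, observation):
    """Signed percent error (prediction - observation)/observation * 100."""
    prediction = np.asarray(prediction, dtype=float)
    observation = np.asarray(observation, dtype=float)
    if np.any(observation <= 0):
        raise DomainError("observation must be > 0 for percent error")
    return (prediction - observation) / observation * 100.0


@dataclass(frozen=True)
class ErrorSummary:
    """Median/IQR of percent errors plus tail shares; all percentages."""

    median_pe: float
    iqr_pe: float
    frac_over: float
    frac_under: float
    frac_over25: float
    frac_under25: float
    n: int

    def as_dict(self) -> dict:
        return {
            "median_pe": self.median_pe,
            "iqr_pe": self.iqr_pe,
            "frac_over": self.frac_over,
            "frac_under": self.frac_under,
            "frac_over25": self.frac_over25,
            "frac_under25": self.frac_under25,
            "n": self.n,
        }


def summarize_errors(errors: Iterable[float], quantile_rule: str = "linear") -> ErrorSummary:
    """Summarize percent errors: median, IQR (Q3-Q1), over/under and ±25% tails.

    ``quantile_rule`` is any numpy interpolation method; the default linear
    interpolation between order statistics matches R's type-7 quantiles. An
    exactly-zero error counts as "over".
    """
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise InputError("cannot summarize an empty error sequence")
    q1, med, q3 = np.percentile(e, [25, 50, 75], method=quantile_rule)
    n = e.size
    return ErrorSummary(
        median_pe=float(med),
        iqr_pe=float(q3 - q1),
        frac_over=100.0 * float(np.sum(e >= 0)) / n,
        frac_under=100.0 * float(np.sum(e < 0)) / n,
        frac_over25=100.0 * float(np.sum(e >= 25.0)) / n,
        frac_under25=100.0 * float(np.sum(e <= -25.0)) / n,
        n=int(n),
    )


@dataclass(frozen=True)
class FoldAssignment:
    """subject_id -> fold index (1..k); balanced random or one-fold-per-group."""

    assignments: Mapping[str, int]
    k: int
    seed: Optional[int] = None
    group_by: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "assignments", dict(self.assignments))

    def fold_subjects(self, fold: int) -> list:
        return sorted(s for s, f in self.assignments.items() if f == fold)

    def folds(self) -> range:
        return range(1, self.k + 1)


def make_folds(
    subjects: Union[Sequence[SubjectProfile], Sequence[str], PhysioDataset],
    k: int = 10,
    seed: int = 0,
    group_by: Optional[str] = None,
) -> FoldAssignment:
    """Partition subjects into validation folds.

    Random mode (default): a seeded balanced random partition — fold sizes
    differ by at most one (e.g. 471 subjects at k=10 give folds of 47 or 48).
    Group mode: one fold per distinct value of ``group_by`` (a SubjectProfile
    field such as ``study_id`` or ``sex_code``); ``k`` is ignored.
    """
    if isinstance(subjects, PhysioDataset):
        profiles: Sequence = list(subjects.subjects.values())
    else:
        profiles = list(subjects)

    if group_by is not None:
        if profiles and not isinstance(profiles[0], SubjectProfile):
            raise InputError("group mode needs SubjectProfile objects to read the grouping field")
        groups = sorted({str(getattr(p, group_by)) for p in profiles})
        index = {g: i + 1 for i, g in enumerate(groups)}
        assignments = {p.subject_id: index[str(getattr(p, group_by))] for p in profiles}
        return FoldAssignment(assignments=assignments, k=len(groups), seed=None, group_by=group_by)

    ids = [p.subject_id if isinstance(p, SubjectProfile) else str(p) for p in profiles]
    if k < 2:
        raise InputError("k must be >= 2")
    if k > len(ids):
        raise InputError(f"k={k} exceeds the number of subjects ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for idx in chunk:
            assignments[ids[idx]] = fold
    return FoldAssignment(assignments=assignments, k=k, seed=seed)


@dataclass
class CVReport:
    """Pooled held-out predictions plus error summaries."""

    per_record: pd.DataFrame  # subject_id, minute_index, fold, prediction, observation, percent_error
    fold_assignment: FoldAssignment
    overall: ErrorSummary
    per_stratum: dict = field(default_factory=dict)
    model_name: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model_name,
            "k": self.fold_assignment.k,
            "seed": self.fold_assignment.seed,
            "group_by": self.fold_assignment.group_by,
            "overall": self.overall.as_dict(),
            "per_stratum": {k: v.as_dict() for k, v in self.per_stratum.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.per_record.to_csv(path, index=False)


def _subset(ds: PhysioDataset, subject_ids) -> PhysioDataset:
    keep = set(subject_ids)
    records = ds.records[ds.records["subject_id"].isin(keep)]
    subjects = {sid: ds.subjects[sid] for sid in keep if sid in ds.subjects}
    return PhysioDataset(subjects, records, dict(ds.provenance))


def _predict_records(
    model: PowerFunctionModel,
    ds: PhysioDataset,
    subject_ids,
    fvc_policy: str,
    reference_table: Optional[ReferenceCoefficientTable],
) -> pd.DataFrame:
    """Population-level predictions for the eligible records of the given subjects."""
    rows = []
    needs_fb = "fb" in model.required_predictors
    needs_fvc = "fvc" in model.required_predictors
    for sid in subject_ids:
        profile = ds.subjects[sid]
        fvc_val = None
        if needs_fvc:
            predicted = None
            if profile.measured_fvc is None or fvc_policy == "predicted_only":
                if reference_table is not None:
                    predicted = predict_fvc(profile, reference_table)
            fvc_val, _src = resolve_fvc(profile, predicted=predicted, policy=fvc_policy)
        rec = ds.records[ds.records["subject_id"] == sid]
        mask = rec["ve_observed"].notna() & (rec["ve_observed"] > 0) & rec["hr"].notna() & (rec["hr"] > 0)
        if needs_fb:
            mask &= rec["fb"].notna() & (rec["fb"] > 0)
        rec = rec[mask]
        if rec.empty:
            continue
        pred = model.predict(
            hr=rec["hr"].to_numpy(float),
            fb=rec["fb"].to_numpy(float) if needs_fb else None,
            age=profile.age,
            sex=float(profile.sex_code),
            fvc=fvc_val,
        )
        obs = rec["ve_observed"].to_numpy(float)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "minute_index": rec["minute_index"].to_numpy(),
                    "prediction": pred,
                    "observation": obs,
                    "percent_error": percent_error(pred, obs),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "minute_index", "prediction", "observation", "percent_error"]
        )
    return pd.concat(rows, ignore_index=True)


def cross_validate(
    ds: PhysioDataset,
    formula: ModelFormula,
    folds: FoldAssignment,
    fvc_policy: str = "prefer_measured",
    reference_table: Optional[ReferenceCoefficientTable] = None,
) -> CVReport:
    """Grouped k-fold cross-validation of the mixed model.

    For each fold: fit on the training subjects, export the fixed-effect
    power-function model, predict the held-out subjects' records at the
    population level, compute percent errors; pool all validation predictions.
    A training fit that fails aborts with the fold index in the message.
    """
    all_parts = []
    for fold in folds.folds():
        valid_ids = folds.fold_subjects(fold)
        train_ids = [s for s in ds.subjects if s not in set(valid_ids)]
        try:
            fit = fit_loglog_lmm(_subset(ds, train_ids), formula, fvc_policy, reference_table)
            model = as_power_model(fit, name=f"fold{fold}")
        except Exception as exc:
            raise InputError(f"training fit failed in fold {fold}: {exc}") from exc
        part = _predict_records(model, ds, valid_ids, fvc_policy, reference_table)
        part["fold"] = fold
        all_parts.append(part)
    per_record = pd.concat(all_parts, ignore_index=True)
    if per_record.empty:
        raise InputError("cross-validation produced no predictions")
    overall = summarize_errors(per_record["percent_error"])
    return CVReport(
        per_record=per_record,
        fold_assignment=folds,
        overall=overall,
        model_name="+".join(formula.fixed_terms),
    )


def stratify_report(report: CVReport, status_by_subject: Mapping[str, str]) -> dict:
    """Per-stratum error summaries by lung-function status, plus an all-subjects row.

    ``status_by_subject`` maps subject_id -> {low, normal, high, unmeasured}.
    N counts records, not subjects; empty strata are omitted. The summaries are
    also stored on ``report.per_stratum``.
    """
    df = report.per_record
    strata: dict = {"all": summarize_errors(df["percent_error"])}
    status = df["subject_id"].map(lambda s: status_by_subject.get(s, "unmeasured"))
    for name in ("unmeasured", "normal", "low", "high"):
        sub = df[status == name]
        if len(sub):
            strata[name] = summarize_errors(sub["percent_error"])
    report.per_stratum = strata
    return strata


def evaluate_fixed_model(
    model: Union[PowerFunctionModel, LegacyModelSpec],
    ds: PhysioDataset,
    fvc_policy: str = "prefer_measured",
    reference_table: Optional[ReferenceCoefficientTable] = None,
) -> CVReport:
    """Score a fixed (no-refitting) model on every eligible record.

    This is the benchmark mode: cross-validation degenerates to a single pass,
    identical for any fold assignment, because nothing is estimated.
    """
    if isinstance(model, PowerFunctionModel):
        per_record = _predict_records(model, ds, list(ds.subjects), fvc_policy, reference_table)
        name = model.name
    else:
        rows = []
        needs_fb = model.requires_fb
        uses_hr = model.family in ("exp_linear_hr", "power_hr", "linear_hr_fb")
        for sid, profile in ds.subjects.items():
            rec = ds.records[ds.records["subject_id"] == sid]
            mask = rec["ve_observed"].notna() & (rec["ve_observed"] > 0)
            if uses_hr:
                mask &= rec["hr"].notna() & (rec["hr"] > 0)
            if needs_fb:
                mask &= rec["fb"].notna() & (rec["fb"] > 0)
            rec = rec[mask]
            if rec.empty:
                continue
            pred = predict_ve_legacy(
                model,
                hr=rec["hr"].to_numpy(float) if uses_hr else None,
                fb=rec["fb"].to_numpy(float) if needs_fb else None,
                sex_code=profile.sex_code,
            ).ve
            obs = rec["ve_observed"].to_numpy(float)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "minute_index": rec["minute_index"].to_numpy(),
                        "prediction": pred,
                        "observation": obs,
                        "percent_error": percent_error(pred, obs),
                    }
                )
            )
        if not rows:
            raise InputError(f"no eligible records for model {model.model_id!r}")
        per_record = pd.concat(rows, ignore_index=True)
        name = model.model_id
    per_record["fold"] = 1
    trivial = FoldAssignment(assignments={s: 1 for s in ds.subjects}, k=1)
    return CVReport(
        per_record=per_record,
        fold_assignment=trivial,
        overall=summarize_errors(per_record["percent_error"]),
        model_name=name,
    )


def benchmark(
    ds: PhysioDataset,
    models: Iterable[Union[PowerFunctionModel, LegacyModelSpec]],
    fvc_policy: str = "prefer_measured",
    reference_table: Optional[ReferenceCoefficientTable] = None,
) -> dict:
    """Evaluate several fixed models on the same dataset; name -> ErrorSummary."""
    out = {}
    for model in models:
        report = evaluate_fixed_model(model, ds, fvc_policy, reference_table)
        out[report.model_name] = report.overall
    return out
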