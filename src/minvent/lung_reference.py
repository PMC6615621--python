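"""Spirometry reference equations: predicted FVC/FEV1 and percent-predicted status.

Predicted lung volumes follow the Global Lung Function Initiative functional
form,

    outcome = exp(a0 + a1*ln(height_cm) + a2*ln(age_y) + spline(age_y)),

with coefficients per (sex, reference group, outcome) consumed from a pluggable
table and the age-varying spline contribution as a tabulated lookup with linear
interpolation. The package ships a small SYNTHETIC table (plausible magnitudes,
not the published GLI-2012 coefficients) so everything is testable offline;
production use loads a real table via :meth:`ReferenceCoefficientTable.load` or
supplies measured FVC.

Ethnicity labels are mapped onto the five GLI reference groups; measured FVC is
classified against the prediction as low (<85% predicted), normal (85-115%,
boundaries inclusive) or high (>115%).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InputError, UnavailablePredictionError

__all__ = [
    "GLIGroup",
    "ReferenceCoefficientTable",
    "LungFunctionPrediction",
    "map_to_gli_group",
    "predict_fvc",
    "predict_fev1",
    "classify_fvc_status",
    "evaluate_profile",
]


class GLIGroup(str, Enum):
    """The five reference groups of the GLI equations."""

    CAUCASIAN = "Caucasian"
    AFRICAN_AMERICAN = "AfricanAmerican"
    NORTH_EAST_ASIAN = "NorthEastAsian"
    SOUTH_EAST_ASIAN = "SouthEastAsian"
    OTHER = "Other"


_CAUCASIAN_COUNTRIES = {
    "uk", "united kingdom", "great britain", "england", "scotland", "wales",
    "portugal", "brazil", "canada", "us", "usa", "united states",
    "united states of america",
}


def map_to_gli_group(ethnicity_label: str, country: str = "") -> GLIGroup:
    """Deterministically map a free-text ethnicity label (and country) to a reference group.

    White/Caucasian subjects from the pooled studies' countries (UK, Portugal,
    Brazil, Canada, US) map to Caucasian; subjects of African ancestry to
    AfricanAmerican; Asian or Hispanic labels without sub-region information,
    and unknown/empty labels, map to Other (the latter with a warning). Total
    function: never raises.
    """
    label = (ethnicity_label or "").strip().lower()
    ctry = (country or "").strip().lower()
    if not label:
        warnings.warn("empty ethnicity label; assigning reference group Other", stacklevel=2)
        return GLIGroup.OTHER
    if "north" in label and "asian" in label:
        return GLIGroup.NORTH_EAST_ASIAN
    if "south" in label and "asian" in label:
        return GLIGroup.SOUTH_EAST_ASIAN
    if "african" in label or label == "black":
        return GLIGroup.AFRICAN_AMERICAN
    if label in {"white", "caucasian"} or "caucasian" in label:
        if not ctry or ctry in _CAUCASIAN_COUNTRIES:
            return GLIGroup.CAUCASIAN
        return GLIGroup.CAUCASIAN  # label dominates; country only documents provenance
    # Asian without North/South information, Hispanic, anything else
    return GLIGroup.OTHER


class ReferenceCoefficientTable:
    """Coefficients a0, a1, a2 plus an age-spline lookup per (sex, group, outcome).

    File format (see :meth:`load`): ``coefficients.csv`` with columns
    ``sex_code, group, outcome, a0, a1, a2``; ``spline.csv`` with columns
    ``sex_code, group, outcome, age, spline_value``; an optional
    ``manifest.json`` with source/version metadata.
    """

    def __init__(self, coefficients: pd.DataFrame, spline: pd.DataFrame, metadata: Optional[dict] = None):
        req = {"sex_code", "group", "outcome", "a0", "a1", "a2"}
        if not req.issubset(coefficients.columns):
            raise InputError(f"coefficient table lacks columns {sorted(req - set(coefficients.columns))}")
        reqs = {"sex_code", "group", "outcome", "age", "spline_value"}
        if not reqs.issubset(spline.columns):
            raise InputError(f"spline table lacks columns {sorted(reqs - set(spline.columns))}")
        self.coefficients = coefficients.copy()
        self.coefficients["sex_code"] = self.coefficients["sex_code"].astype(int)
        self.spline = spline.copy()
        self.spline["sex_code"] = self.spline["sex_code"].astype(int)
        self.metadata = metadata or {}
        self._coef_index = {
            (int(r.sex_code), str(r.group), str(r.outcome)): (float(r.a0), float(r.a1), float(r.a2))
            for r in self.coefficients.itertuples()
        }
        self._spline_index: dict = {}
        for key, sub in self.spline.groupby(["sex_code", "group", "outcome"]):
            sub = sub.sort_values("age")
            self._spline_index[(int(key[0]), str(key[1]), str(key[2]))] = (
                sub["age"].to_numpy(float),
                sub["spline_value"].to_numpy(float),
            )

    # -- construction -------------------------------------------------------

    @classmethod
    def synthetic_default(cls) -> "ReferenceCoefficientTable":
        """The packaged synthetic table (clearly not GLI-2012; for tests/simulation)."""
        pkg = resources.files("minvent") / "data"
        coef = pd.read_csv(pkg / "synthetic_reference_coefficients.csv")
        spl = pd.read_csv(pkg / "synthetic_reference_spline.csv")
        meta = json.loads((pkg / "synthetic_reference_manifest.json").read_text())
        return cls(coef, spl, meta)

    @classmethod
    def load(cls, directory) -> "ReferenceCoefficientTable":
        """Load a table from a directory holding coefficients.csv, spline.csv, manifest.json."""
        d = Path(directory)
        coef = pd.read_csv(d / "coefficients.csv")
        spl = pd.read_csv(d / "spline.csv")
        manifest = d / "manifest.json"
        meta = json.loads(manifest.read_text()) if manifest.exists() else {}
        return cls(coef, spl, meta)

    # -- evaluation ---------------------------------------------------------

    def covers(self, sex_code: int, group: GLIGroup | str, outcome: str) -> bool:
        return (int(sex_code), str(getattr(group, "value", group)), outcome) in self._coef_index

    def spline_value(self, sex_code: int, group: GLIGroup | str, outcome: str, age: float) -> float:
        key = (int(sex_code), str(getattr(group, "value", group)), outcome)
        if key not in self._spline_index:
            return 0.0
        ages, vals = self._spline_index[key]
        if age < ages[0] or age > ages[-1]:
            warnings.warn(
                f"age {age} outside spline table range [{ages[0]}, {ages[-1]}]; extrapolating flat",
                stacklevel=2,
            )
        return float(np.interp(age, ages, vals))

    def predict(self, sex_code: int, group: GLIGroup | str, outcome: str, height: float, age: float) -> float:
        """exp(a0 + a1*ln(height) + a2*ln(age) + spline(age)), in liters."""
        gname = str(getattr(group, "value", group))
        key = (int(sex_code), gname, outcome)
        if key not in self._coef_index:
            raise UnavailablePredictionError(
                f"reference table has no row for sex={sex_code}, group={gname}, outcome={outcome}"
            )
        if height is None or age is None or not (height > 0 and age > 0):
            raise UnavailablePredictionError("height and age (both > 0) are required for prediction")
        a0, a1, a2 = self._coef_index[key]
        ln_vol = a0 + a1 * np.log(height) + a2 * np.log(age) + self.spline_value(sex_code, gname, outcome, age)
        return float(np.exp(ln_vol))


@dataclass
class LungFunctionPrediction:
    """Predicted volumes plus measured-vs-predicted classification."""

    predicted_fvc: float
    predicted_fev1: Optional[float] = None
    percent_predicted: Optional[float] = None
    status: str = "unmeasured"  # low | normal | high | unmeasured


def predict_fvc(profile, table: ReferenceCoefficientTable) -> float:
    """Predicted FVC in liters for a SubjectProfile (requires height and age)."""
    return _predict_outcome(profile, table, "FVC")


def predict_fev1(profile, table: ReferenceCoefficientTable) -> float:
    """Predicted FEV1 in liters; same machinery as FVC."""
    return _predict_outcome(profile, table, "FEV1")


def _predict_outcome(profile, table: ReferenceCoefficientTable, outcome: str) -> float:
    if profile.height is None or profile.age is None:
        raise UnavailablePredictionError(
            f"subject {profile.subject_id}: height and age required to predict {outcome}"
        )
    group = profile.gli_group or map_to_gli_group(profile.ethnicity_label or "", profile.country or "")
    return table.predict(profile.sex_code, group, outcome, profile.height, profile.age)


def classify_fvc_status(measured: Optional[float], predicted: float) -> LungFunctionPrediction:
    """Classify measured FVC against the prediction.

    low: measured < 85% of predicted (strict); high: > 115% (strict);
    normal otherwise (both boundaries inclusive); unmeasured when no
    measurement exists.
    """
    if not (predicted > 0):
        raise InputError(f"predicted FVC must be > 0, got {predicted}")
    if measured is None:
        return LungFunctionPrediction(predicted_fvc=predicted, status="unmeasured")
    if measured <= 0:
        raise InputError(f"measured FVC must be > 0, got {measured}")
    pct = 100.0 * measured / predicted
    if pct < 85.0:
        status = "low"
    elif pct > 115.0:
        status = "high"
    else:
        status = "normal"
    return LungFunctionPrediction(predicted_fvc=predicted, percent_predicted=pct, status=status)


def evaluate_profile(profile, table: ReferenceCoefficientTable) -> LungFunctionPrediction:
    """Predict FVC (and FEV1 when covered) and classify the subject's measured FVC."""
    pred_fvc = predict_fvc(profile, table)
    out = classify_fvc_status(profile.measured_fvc, pred_fvc)
    group = profile.gli_group or map_to_gli_group(profile.ethnicity_label or "", profile.country or "")
    if table.covers(profile.sex_code, group, "FEV1"):
        out.predicted_fev1 = _predict_outcome(profile, table, "FEV1")
    return out
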