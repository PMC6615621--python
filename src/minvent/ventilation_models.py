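"""Closed-form minute-ventilation prediction models.

Two families are provided:

* :class:`PowerFunctionModel` — V̇E = exp(b0) * Π predictor_i ** b_i, the form
  produced by fitting a linear mixed model to log-transformed V̇E with
  log-transformed predictors. The built-in instances ``MODEL_D1`` (HR as the
  only field-measured predictor) and ``MODEL_D2`` (HR and breath frequency)
  carry the published pooled-data coefficients.

* :class:`LegacyModelSpec` — six previously published V̇E models (sex-stratified
  log-linear in HR, power in HR, an f_B-log form, and a linear HR+f_B form),
  evaluated exactly as printed, for benchmarking.

Predictors: hr (beats/min), fb (breaths/min), age (years), sex (1=male,
2=female, entering the power form as a base), fvc (liters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .exceptions import DomainError, MissingPredictorError, UnavailableFVCError

__all__ = [
    "PowerFunctionModel",
    "LegacyModelSpec",
    "VEPrediction",
    "MODEL_D1",
    "MODEL_D2",
    "LEGACY_MODELS",
    "MODEL_REGISTRY",
    "predict_ve_power",
    "predict_ve_legacy",
    "resolve_fvc",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class PowerFunctionModel:
    """V̇E = exp(intercept) * Π predictor ** exponent over the required predictors."""

    name: str
    intercept: float
    exponents: Mapping[str, float]  # keys from {hr, fb, age, sex, fvc}
    resting_floor: bool = False  # optional clamp at 0.78*FVC, off by default

    def __post_init__(self):
        allowed = {"hr", "fb", "age", "sex", "fvc"}
        unknown = set(self.exponents) - allowed
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}; allowed: {sorted(allowed)}")
        object.__setattr__(self, "exponents", dict(self.exponents))

    @property
    def required_predictors(self) -> frozenset:
        return frozenset(self.exponents)

    def log_predict(self, **predictors: ArrayLike) -> np.ndarray:
        """ln V̇E = intercept + Σ exponent_i * ln(predictor_i). Validates domain."""
        total = np.asarray(self.intercept, dtype=float)
        for name, beta in self.exponents.items():
            value = predictors.get(name)
            if value is None:
                raise MissingPredictorError(f"model {self.name!r} requires predictor {name!r}")
            value = np.asarray(value, dtype=float)
            if np.any(~np.isfinite(value)) or np.any(value <= 0):
                raise DomainError(f"predictor {name!r} must be strictly positive and finite")
            total = total + beta * np.log(value)
        return total

    def predict(self, **predictors: ArrayLike) -> np.ndarray:
        ve = np.exp(self.log_predict(**predictors))
        if self.resting_floor:
            fvc = predictors.get("fvc")
            if fvc is not None:
                ve = np.maximum(ve, 0.78 * np.asarray(fvc, dtype=float))
        return ve

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "intercept": self.intercept,
                "exponents": dict(self.exponents),
                "required_predictors": sorted(self.required_predictors),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PowerFunctionModel":
        d = json.loads(text)
        return cls(name=d["name"], intercept=d["intercept"], exponents=d["exponents"])


@dataclass(frozen=True)
class VEPrediction:
    """A V̇E prediction with provenance flags."""

    ve: ArrayLike
    model_name: str
    fvc_source: str = "none"  # measured | predicted | none
    flags: tuple = ()


# Published pooled-data models (intercept and exponents as printed).
MODEL_D1 = PowerFunctionModel(
    name="d1",
    intercept=-9.59,
    exponents={"hr": 2.39, "age": 0.274, "sex": -0.204, "fvc": 0.520},
)

MODEL_D2 = PowerFunctionModel(
    name="d2",
    intercept=-8.57,
    exponents={"hr": 1.72, "fb": 0.611, "age": 0.298, "sex": -0.206, "fvc": 0.614},
)


@dataclass(frozen=True)
class LegacyModelSpec:
    """A previously published V̇E model, evaluated exactly as printed.

    families: ``exp_linear_hr`` (V̇E = e^(a + b*HR), optionally sex-stratified),
    ``power_hr`` (V̇E = a * HR^b), ``fb_log`` (V̇E = f_B*(a*ln(f_B) + b)),
    ``linear_hr_fb`` (V̇E = a + b*HR + c*f_B, may go nonpositive at low input).
    """

    model_id: str
    family: str
    coefficients: Mapping[Union[int, str], tuple] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    @property
    def requires_fb(self) -> bool:
        return self.family in ("fb_log", "linear_hr_fb")

    @property
    def sex_stratified(self) -> bool:
        return set(self.coefficients) == {1, 2}


LEGACY_MODELS: dict[str, LegacyModelSpec] = {
    "zuurbier": LegacyModelSpec(
        "zuurbier", "exp_linear_hr", {1: (1.03, 0.021), 2: (0.57, 0.023)}
    ),
    "ramos": LegacyModelSpec(
        "ramos", "exp_linear_hr", {1: (1.17, 0.02), 2: (0.99, 0.02)}
    ),
    "cozza": LegacyModelSpec("cozza", "exp_linear_hr", {"all": (0.58, 0.025)}),
    "do_vale": LegacyModelSpec("do_vale", "power_hr", {"all": (0.00071, 2.17)}),
    "mcardle": LegacyModelSpec("mcardle", "fb_log", {"all": (1.8028, -3.8881)}),
    "greenwald2014": LegacyModelSpec(
        "greenwald2014", "linear_hr_fb", {"all": (-4.247, 0.0595, 0.226)}
    ),
}

#: All built-in models by name; user-defined PowerFunctionModel instances are
#: first-class and can be registered here.
MODEL_REGISTRY: dict[str, Union[PowerFunctionModel, LegacyModelSpec]] = {
    "d1": MODEL_D1,
    "d2": MODEL_D2,
    **LEGACY_MODELS,
}


def predict_ve_power(
    model: PowerFunctionModel,
    hr: ArrayLike,
    fb: Optional[ArrayLike] = None,
    age: Optional[ArrayLike] = None,
    sex_code: Optional[ArrayLike] = None,
    fvc: Optional[ArrayLike] = None,
    fvc_source: str = "none",
) -> VEPrediction:
    """Evaluate a power-function model; missing required predictors raise, never fall back."""
    ve = model.predict(hr=hr, fb=fb, age=age, sex=sex_code, fvc=fvc)
    flags = ("resting_floor",) if model.resting_floor else ()
    return VEPrediction(ve=ve, model_name=model.name, fvc_source=fvc_source, flags=flags)


def predict_ve_legacy(
    spec: LegacyModelSpec,
    hr: Optional[ArrayLike] = None,
    fb: Optional[ArrayLike] = None,
    sex_code: Optional[int] = None,
    clamp_nonpositive: bool = False,
) -> VEPrediction:
    """Evaluate a legacy model exactly as printed.

    Sex-stratified models require ``sex_code``; the f_B-only model requires
    ``fb``. The linear HR+f_B model may return nonpositive values at low
    input — flagged, and clamped to NaN only when ``clamp_nonpositive`` is set.
    """
    flags: list[str] = []
    if spec.sex_stratified:
        if sex_code not in (1, 2):
            raise MissingPredictorError(f"model {spec.model_id!r} is sex-stratified; sex_code 1 or 2 required")
        coefs = spec.coefficients[sex_code]
    else:
        coefs = spec.coefficients["all"]

    def need(value, name):
        if value is None:
            raise MissingPredictorError(f"model {spec.model_id!r} requires predictor {name!r}")
        value = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(value)) or np.any(value <= 0):
            raise DomainError(f"predictor {name!r} must be strictly positive and finite")
        return value

    if spec.family == "exp_linear_hr":
        a, b = coefs
        ve = np.exp(a + b * need(hr, "hr"))
    elif spec.family == "power_hr":
        a, b = coefs
        ve = a * need(hr, "hr") ** b
    elif spec.family == "fb_log":
        a, b = coefs
        fbv = need(fb, "fb")
        ve = fbv * (a * np.log(fbv) + b)
    elif spec.family == "linear_hr_fb":
        a, b, c = coefs
        ve = a + b * need(hr, "hr") + c * need(fb, "fb")
    else:  # pragma: no cover - registry is closed
        raise ValueError(f"unknown legacy family {spec.family!r}")

    if np.any(np.asarray(ve) <= 0):
        flags.append("nonpositive")
        if clamp_nonpositive:
            ve = np.where(np.asarray(ve) <= 0, np.nan, ve)
            flags.append("clamped")
    return VEPrediction(ve=ve, model_name=spec.model_id, flags=tuple(flags))


def resolve_fvc(
    profile,
    predicted: Optional[float] = None,
    policy: str = "prefer_measured",
) -> tuple[float, str]:
    """Choose the FVC (liters) a prediction should use, recording its source.

    ``prefer_measured`` (default, the recommended practice) takes the measured
    value when present, else the reference-equation prediction;
    ``measured_only`` and ``predicted_only`` restrict to one source.
    """
    measured = getattr(profile, "measured_fvc", None)
    if policy == "prefer_measured":
        if measured is not None:
            return float(measured), "measured"
        if predicted is not None:
            return float(predicted), "predicted"
    elif policy == "measured_only":
        if measured is not None:
            return float(measured), "measured"
    elif policy == "predicted_only":
        if predicted is not None:
            return float(predicted), "predicted"
    else:
        raise ValueError(f"unknown FVC policy {policy!r}")
    raise UnavailableFVCError(
        f"no FVC available for subject {getattr(profile, 'subject_id', '?')} under policy {policy!r}"
    )
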