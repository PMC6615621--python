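"""Synthetic physiological datasets with the statistical structure the models assume.

The generator emulates pooled exercise-physiology data: subjects with
demographics (ages 4-80 y, balanced sexes, heights following a growth curve),
per-minute HR trajectories from a rest/ramp/recovery exercise protocol or an
ambulatory random walk, breath frequency coupled to HR, and minute ventilation
generated from a power-function model with subject-level random intercept and
random slopes on ln HR / ln f_B plus log-normal residual noise:

    ln V̇E = b0 + u0_i + (b_hr + u_hr_i) ln HR + (b_fb + u_fb_i) ln f_B
            + b_age ln age + b_sex ln sex + b_fvc ln FVC + e,   e ~ N(0, sd_e).

Ground truth (the generating model and each subject's random effects) is
retained so parameter-recovery and cross-validation pipelines can be validated
end to end with no external data. Defaults mirror the pooled study conditions:
~31 records per subject (so 471 subjects give ~14.6k records), a measured-FVC
subset of ~17% of subjects whose measurement deviates from the reference
prediction with 10% SD, and heights averaging 163±18 cm across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import PhysioDataset, SubjectProfile
from .exceptions import InputError
from .lung_reference import ReferenceCoefficientTable, map_to_gli_group
from .ventilation_models import MODEL_D2, PowerFunctionModel

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_subject_session", "simulate_dataset"]

_ETHNICITIES = [
    ("Caucasian", ["US", "UK", "Portugal", "Brazil", "Canada"], 0.79),
    ("Hispanic", ["US"], 0.11),
    ("Asian", ["US", "Brazil"], 0.058),
    ("African-American", ["US"], 0.042),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the study conditions, not tuning knobs."""

    n_subjects: int = 200
    true_model: PowerFunctionModel = MODEL_D2
    random_effect_sds: dict = field(
        default_factory=lambda: {"intercept": 0.25, "hr": 0.10, "fb": 0.10}
    )
    residual_sd: float = 0.15
    age_range: tuple = (4.0, 80.0)
    rest_minutes: int = 5
    ramp_minutes: int = 20
    recovery_minutes: int = 6
    ambulatory_fraction: float = 0.2  # share of subjects with a free-living session
    hr_rest_mean: float = 65.0
    hr_rest_sd: float = 5.0
    fb_c0: float = 2.0  # f_B = max(8, c0 + c1*HR + noise)
    fb_c1: float = 0.18
    fb_noise_sd: float = 2.0
    measured_fvc_fraction: float = 82.0 / 471.0
    measured_fvc_sd: float = 0.10  # relative SD of measured vs predicted FVC
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InputError("n_subjects must be >= 1")
        if any(sd < 0 for sd in self.random_effect_sds.values()) or self.residual_sd < 0:
            raise InputError("all SDs must be >= 0")
        lo, hi = self.age_range
        if not (4.0 <= lo < hi <= 80.0):
            raise InputError("age range must lie within [4, 80]")
        if not (0.0 <= self.measured_fvc_fraction <= 1.0):
            raise InputError("measured_fvc_fraction must be in [0, 1]")

    @property
    def session_minutes(self) -> int:
        return self.rest_minutes + self.ramp_minutes + self.recovery_minutes


@dataclass
class SimulatedDataset:
    """A PhysioDataset plus the ground truth that generated it."""

    dataset: PhysioDataset
    random_effects: pd.DataFrame  # subject_id, u_intercept, u_hr, u_fb
    fvc_used: dict  # subject_id -> FVC entering the generating power law
    config: SimulationConfig


def _sample_profile(i: int, config: SimulationConfig, rng: np.random.Generator) -> SubjectProfile:
    sex_code = 1 if i % 2 == 0 else 2  # balanced by construction
    lo, hi = config.age_range
    age = float(lo + (hi - lo) * rng.beta(1.5, 2.5))
    adult_height = rng.normal(176.0, 7.0) if sex_code == 1 else rng.normal(163.0, 6.5)
    if age < 18.0:
        height = adult_height * (0.35 + 0.65 * (age / 18.0) ** 0.7)
    else:
        height = adult_height
    height = float(np.clip(height, 95.0, 210.0))
    weight = float(22.0 * (height / 100.0) ** 2 * (1.0 + rng.normal(0.0, 0.10)))
    u = rng.random()
    cum = 0.0
    label, countries = _ETHNICITIES[-1][0], _ETHNICITIES[-1][1]
    for name, ctries, p in _ETHNICITIES:
        cum += p
        if u <= cum:
            label, countries = name, ctries
            break
    country = countries[int(rng.integers(len(countries)))]
    return SubjectProfile(
        subject_id=f"sim{i:04d}",
        study_id="synthetic",
        age=age,
        sex_code=sex_code,
        height=height,
        weight=weight,
        ethnicity_label=label,
        country=country,
    )


def _hr_trajectory(profile: SubjectProfile, config: SimulationConfig,
                   rng: np.random.Generator, ambulatory: bool) -> tuple[np.ndarray, list]:
    hr_rest = max(45.0, rng.normal(config.hr_rest_mean, config.hr_rest_sd))
    hr_max = 220.0 - profile.age  # conventional cap, keeps the ramp physiologic
    n = config.session_minutes
    if ambulatory:
        hi = max(hr_rest + 20.0, 0.7 * hr_max)
        steps = rng.normal(0.0, 6.0, size=n)
        hr = np.clip(hr_rest + 15.0 + np.cumsum(steps), 50.0, hi)
        return hr, ["ambulatory"] * n
    peak = hr_max * rng.uniform(0.75, 0.95)
    rest = hr_rest + rng.normal(0.0, 1.5, size=config.rest_minutes)
    increments = rng.uniform(0.3, 1.0, size=config.ramp_minutes)
    ramp = hr_rest + (peak - hr_rest) * np.cumsum(increments) / np.sum(increments)
    decay = np.exp(-np.arange(1, config.recovery_minutes + 1) / 3.0)
    recovery = hr_rest + 15.0 + (ramp[-1] - hr_rest - 15.0) * decay
    hr = np.concatenate([rest, ramp, recovery])
    labels = (
        ["rest"] * config.rest_minutes
        + ["ramp"] * config.ramp_minutes
        + ["recovery"] * config.recovery_minutes
    )
    return np.maximum(hr, 40.0), labels


def simulate_subject_session(
    profile: SubjectProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    random_effects: Optional[dict] = None,
    fvc: Optional[float] = None,
    ambulatory: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """One subject's per-minute records; returns (records frame, random effects used).

    The HR trajectory follows the protocol (rest plateau, monotone ramp,
    recovery decay, or an ambulatory walk); f_B couples to HR through
    ``max(8, c0 + c1*HR + noise)``; ln V̇E follows the generating power law
    with the subject's random effects and residual noise. With all SDs zero the
    records satisfy the true power law exactly.
    """
    config.validate()
    sds = config.random_effect_sds
    if random_effects is None:
        random_effects = {
            "intercept": rng.normal(0.0, sds.get("intercept", 0.0)),
            "hr": rng.normal(0.0, sds.get("hr", 0.0)),
            "fb": rng.normal(0.0, sds.get("fb", 0.0)),
        }
    hr, labels = _hr_trajectory(profile, config, rng, ambulatory)
    n = len(hr)
    fb = np.maximum(8.0, config.fb_c0 + config.fb_c1 * hr + rng.normal(0.0, config.fb_noise_sd, n))

    beta = dict(config.true_model.exponents)
    ln_ve = np.full(n, config.true_model.intercept + random_effects["intercept"])
    ln_ve += (beta.get("hr", 0.0) + random_effects["hr"]) * np.log(hr)
    if "fb" in beta:
        ln_ve += (beta["fb"] + random_effects["fb"]) * np.log(fb)
    if "age" in beta:
        ln_ve += beta["age"] * np.log(profile.age)
    if "sex" in beta:
        ln_ve += beta["sex"] * np.log(float(profile.sex_code))
    if "fvc" in beta:
        if fvc is None or fvc <= 0:
            raise InputError("the generating model includes FVC; a positive fvc is required")
        ln_ve += beta["fvc"] * np.log(fvc)
    ln_ve += rng.normal(0.0, config.residual_sd, n)

    records = pd.DataFrame(
        {
            "subject_id": profile.subject_id,
            "minute_index": np.arange(n),
            "hr": hr,
            "fb": fb,
            "ve_observed": np.exp(ln_ve),
            "activity_label": labels,
        }
    )
    return records, random_effects


def simulate_dataset(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    reference_table: Optional[ReferenceCoefficientTable] = None,
) -> SimulatedDataset:
    """Generate a full cohort; identical output for identical (config, seed).

    FVC entering the generating power law is resolved the way the fitting
    pipeline resolves it: the reference-equation prediction for every subject,
    replaced by a "measured" value (prediction times a log-centered 10%-SD
    perturbation) for the measured subset.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    if reference_table is None:
        reference_table = ReferenceCoefficientTable.synthetic_default()

    subjects: dict[str, SubjectProfile] = {}
    all_records = []
    re_rows = []
    fvc_used: dict[str, float] = {}
    needs_fvc = "fvc" in config.true_model.exponents

    for i in range(config.n_subjects):
        profile = _sample_profile(i, config, rng)
        profile.gli_group = map_to_gli_group(profile.ethnicity_label, profile.country).value
        fvc = None
        if needs_fvc:
            predicted = reference_table.predict(
                profile.sex_code, profile.gli_group, "FVC", profile.height, profile.age
            )
            if rng.random() < config.measured_fvc_fraction:
                profile.measured_fvc = float(predicted * np.exp(rng.normal(0.0, config.measured_fvc_sd)))
                profile.measured_fev1 = float(0.8 * profile.measured_fvc)
                fvc = profile.measured_fvc
            else:
                fvc = float(predicted)
        ambulatory = rng.random() < config.ambulatory_fraction
        records, effects = simulate_subject_session(
            profile, config, rng, fvc=fvc, ambulatory=ambulatory
        )
        subjects[profile.subject_id] = profile
        all_records.append(records)
        if fvc is not None:
            fvc_used[profile.subject_id] = fvc
        re_rows.append(
            {
                "subject_id": profile.subject_id,
                "u_intercept": effects["intercept"],
                "u_hr": effects["hr"],
                "u_fb": effects["fb"],
            }
        )

    dataset = PhysioDataset(
        subjects,
        pd.concat(all_records, ignore_index=True),
        provenance={"source": f"synthetic (seed={config.seed})", "n_dropped": {}},
    )
    return SimulatedDataset(
        dataset=dataset,
        random_effects=pd.DataFrame(re_rows),
        fvc_used=fvc_used,
        config=config,
    )
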