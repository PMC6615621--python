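"""Domain types and ingest for per-minute physiological data.

The central container is :class:`PhysioDataset`: a subject table (demographics,
optional measured lung function) plus an ordered table of one-minute records
(heart rate in beats/min, optional breath frequency in breaths/min, optional
observed minute ventilation in L/min). Ingest reads delimited text with a
configurable column map, applies validity filters, and accounts for every
dropped row by reason.

Units are taken at face value: HR in beats/min, f_B in breaths/min, V̇E in
L/min, FVC in liters. The toolkit is agnostic to BTPS/STPD conventions beyond
requiring internal consistency.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "SubjectProfile",
    "PhysioRecord",
    "PhysioDataset",
    "ValidationReport",
    "ingest_dataset",
    "aggregate_to_minutes",
    "summarize_dataset",
    "DEFAULT_RECORD_COLUMNS",
    "DEFAULT_SUBJECT_COLUMNS",
]

# Canonical field -> canonical column name. A column map overrides the
# right-hand side to point at whatever the source file calls the column.
DEFAULT_RECORD_COLUMNS = {
    "subject_id": "subject_id",
    "minute_index": "minute_index",
    "hr": "hr",
    "fb": "fb",
    "ve_observed": "ve_observed",
    "activity_label": "activity_label",
    "session": "session",
}

DEFAULT_SUBJECT_COLUMNS = {
    "subject_id": "subject_id",
    "study_id": "study_id",
    "age": "age",
    "sex_code": "sex_code",
    "height": "height",
    "weight": "weight",
    "ethnicity_label": "ethnicity_label",
    "country": "country",
    "measured_fvc": "measured_fvc",
    "measured_fev1": "measured_fev1",
}

_ACCEPTED_UNITS = {
    "hr": {"bpm", "beats/min", "beats.min-1"},
    "ve": {"L/min", "l/min", "L.min-1"},
    "fb": {"breaths/min", "bpm", "breaths.min-1"},
    "fvc": {"L", "l", "liters", "litres"},
}


@dataclass
class SubjectProfile:
    """One participant: demographics plus optional measured lung function.

    ``sex_code`` follows the 1=male / 2=female numeric convention so that the
    log-transform of sex used by the power-function models is reproducible.
    """

    subject_id: str
    age: float
    sex_code: int
    study_id: str = ""
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    ethnicity_label: Optional[str] = None
    country: Optional[str] = None
    gli_group: Optional[str] = None
    measured_fvc: Optional[float] = None  # liters
    measured_fev1: Optional[float] = None  # liters

    def validate(self) -> None:
        if not self.subject_id:
            raise InputError("subject_id must be non-empty")
        if not (self.age > 0):
            raise InputError(f"subject {self.subject_id}: age must be > 0, got {self.age}")
        if self.sex_code not in (1, 2):
            raise InputError(
                f"subject {self.subject_id}: sex_code must be 1 (male) or 2 (female), got {self.sex_code}"
            )
        if self.measured_fvc is not None and not (self.measured_fvc > 0):
            raise InputError(f"subject {self.subject_id}: measured_fvc must be > 0")
        if self.measured_fev1 is not None and not (self.measured_fev1 > 0):
            raise InputError(f"subject {self.subject_id}: measured_fev1 must be > 0")
        if (
            self.measured_fvc is not None
            and self.measured_fev1 is not None
            and self.measured_fev1 > self.measured_fvc
        ):
            warnings.warn(
                f"subject {self.subject_id}: measured FEV1 ({self.measured_fev1}) exceeds "
                f"measured FVC ({self.measured_fvc}); kept as given",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PhysioRecord:
    """A single one-minute observation for one subject."""

    subject_id: str
    minute_index: int
    hr: float
    fb: Optional[float] = None
    ve_observed: Optional[float] = None
    activity_label: Optional[str] = None


class PhysioDataset:
    """Subjects plus their ordered per-minute records.

    ``records`` is a pandas DataFrame with canonical columns
    ``subject_id, minute_index, hr, fb, ve_observed, activity_label``
    (optional channels hold NaN where absent). Every record's subject_id
    resolves to exactly one :class:`SubjectProfile` and no
    (subject_id, session, minute_index) pair repeats.
    """

    RECORD_COLUMNS = ["subject_id", "minute_index", "hr", "fb", "ve_observed", "activity_label"]

    def __init__(
        self,
        subjects: Mapping[str, SubjectProfile] | Iterable[SubjectProfile],
        records: pd.DataFrame,
        provenance: Optional[dict] = None,
    ):
        if not isinstance(subjects, Mapping):
            subjects = {s.subject_id: s for s in subjects}
        self.subjects: dict[str, SubjectProfile] = dict(subjects)
        records = records.copy()
        for col in self.RECORD_COLUMNS:
            if col not in records.columns:
                records[col] = np.nan
        self.records = records[
            [c for c in self.RECORD_COLUMNS if c in records.columns]
            + [c for c in records.columns if c not in self.RECORD_COLUMNS]
        ].reset_index(drop=True)
        self.provenance: dict = provenance or {}
        self._check_invariants()

    def _check_invariants(self) -> None:
        unknown = set(self.records["subject_id"]) - set(self.subjects)
        if unknown:
            raise InputError(f"records reference unknown subjects: {sorted(unknown)[:5]}")
        key_cols = ["subject_id", "minute_index"]
        if "session" in self.records.columns:
            key_cols.insert(1, "session")
        if self.records.duplicated(subset=key_cols).any():
            raise InputError("duplicate (subject_id, minute_index) pairs in records")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def subject_frame(self) -> pd.DataFrame:
        """Subject table as a DataFrame (one row per subject)."""
        rows = []
        for s in self.subjects.values():
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "study_id": s.study_id,
                    "age": s.age,
                    "sex_code": s.sex_code,
                    "height": s.height,
                    "weight": s.weight,
                    "ethnicity_label": s.ethnicity_label,
                    "country": s.country,
                    "gli_group": s.gli_group,
                    "measured_fvc": s.measured_fvc,
                    "measured_fev1": s.measured_fev1,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Records merged with subject covariates, for modelling."""
        return self.records.merge(self.subject_frame(), on="subject_id", how="left")

    def iter_records(self) -> Iterable[PhysioRecord]:
        for row in self.records.itertuples(index=False):
            yield PhysioRecord(
                subject_id=row.subject_id,
                minute_index=int(row.minute_index),
                hr=float(row.hr),
                fb=None if pd.isna(row.fb) else float(row.fb),
                ve_observed=None if pd.isna(row.ve_observed) else float(row.ve_observed),
                activity_label=None if pd.isna(row.activity_label) else str(row.activity_label),
            )

    def write(self, records_path, subjects_path) -> None:
        """Write the canonical comma-delimited representation (round-trips via ingest)."""
        self.records.to_csv(records_path, index=False)
        self.subject_frame().to_csv(subjects_path, index=False)

    def equals(self, other: "PhysioDataset") -> bool:
        if set(self.subjects) != set(other.subjects):
            return False
        if any(self.subjects[k] != other.subjects[k] for k in self.subjects):
            return False
        a = self.records[self.RECORD_COLUMNS].reset_index(drop=True)
        b = other.records[self.RECORD_COLUMNS].reset_index(drop=True)
        return a.equals(b)


@dataclass
class ValidationReport:
    """Ingest accounting plus cohort summaries (counts, mean/SD/range, sex split)."""

    n_subjects: int
    n_records: int
    n_records_with_fb: int
    n_dropped: dict[str, int] = field(default_factory=dict)
    demographic_summary: dict[str, dict] = field(default_factory=dict)
    sex_counts: dict[int, dict] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "n_subjects": self.n_subjects,
            "n_records": self.n_records,
            "n_records_with_fb": self.n_records_with_fb,
            "n_dropped": self.n_dropped,
            "demographic_summary": self.demographic_summary,
            "sex_counts": {str(k): v for k, v in self.sex_counts.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"subjects: {self.n_subjects}",
            f"records: {self.n_records} ({self.n_records_with_fb} with breath frequency)",
        ]
        if self.n_dropped:
            lines.append("dropped rows: " + ", ".join(f"{k}={v}" for k, v in sorted(self.n_dropped.items())))
        for sex, info in sorted(self.sex_counts.items()):
            label = {1: "male", 2: "female"}.get(sex, str(sex))
            lines.append(f"{label}: {info['count']} ({info['percent']:.0f}%)")
        for fieldname, stats in self.demographic_summary.items():
            sd = "undefined" if stats.get("sd") is None else f"{stats['sd']:.3g}"
            lines.append(
                f"{fieldname}: mean {stats['mean']:.3g}, SD {sd}, range {stats['min']:.3g}-{stats['max']:.3g}"
            )
        return "\n".join(lines)


def _resolve_map(defaults: Mapping[str, str], override: Optional[Mapping[str, str]]) -> dict:
    m = dict(defaults)
    if override:
        for key, col in override.items():
            if key not in defaults:
                raise ConfigurationError(f"unknown canonical field in column map: {key!r}")
            m[key] = col
    return m


def _check_units(units: Optional[Mapping[str, str]]) -> None:
    if units is None:
        return
    for channel, unit in units.items():
        accepted = _ACCEPTED_UNITS.get(channel)
        if accepted is None:
            raise ConfigurationError(f"unknown channel in units config: {channel!r}")
        if unit not in accepted:
            raise ConfigurationError(
                f"unsupported unit {unit!r} for {channel}; expected one of {sorted(accepted)}"
            )


def _read_delimited(source: Union[str, io.IOBase]) -> pd.DataFrame:
    """Read comma- or tab-delimited UTF-8 text with a header row (auto-detected)."""
    import csv as _csv

    try:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise InputError("empty input file") from exc
    except _csv.Error as exc:
        # the dialect sniffer cannot tell a delimiter on empty/degenerate input
        raise InputError(f"unreadable delimited file: {exc}") from exc
    if df.empty and len(df.columns) == 0:
        raise InputError("empty input file")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _to_float(value) -> float:
    """Parse a numeric cell; NaN for empty, raise for garbage."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "null", "none", "."}:
        return np.nan
    return float(s)


def ingest_dataset(
    records_source,
    subjects_source,
    column_map: Optional[Mapping[str, str]] = None,
    subject_column_map: Optional[Mapping[str, str]] = None,
    units: Optional[Mapping[str, str]] = None,
) -> PhysioDataset:
    """Read delimited physiological records and a subject table into a PhysioDataset.

    Rows violating record invariants (HR > 0; f_B, V̇E > 0 when present;
    resolvable subject; unique minute within subject/session) are dropped and
    counted by reason in ``dataset.provenance["n_dropped"]``; ingest is
    order-preserving within subject. Subjects violating profile invariants are
    dropped (reason ``invalid_subject``) together with their records.

    Parameters
    ----------
    records_source, subjects_source
        Paths or file-like handles to delimited UTF-8 text with a header row;
        comma or tab delimiters are auto-detected.
    column_map, subject_column_map
        Mapping canonical field -> source column name; unmapped fields use the
        canonical names. ``subject_id`` and ``hr`` are mandatory for records,
        ``subject_id``, ``age`` and ``sex_code`` for subjects.
    units
        Optional declaration, e.g. ``{"hr": "bpm", "ve": "L/min"}``; values are
        validated but never converted (the toolkit is single-unit).
    """
    _check_units(units)
    rec_map = _resolve_map(DEFAULT_RECORD_COLUMNS, column_map)
    subj_map = _resolve_map(DEFAULT_SUBJECT_COLUMNS, subject_column_map)

    rec_df = _read_delimited(records_source)
    subj_df = _read_delimited(subjects_source)

    for canon in ("subject_id", "hr"):
        if rec_map[canon] not in rec_df.columns:
            raise ConfigurationError(
                f"records file lacks mandatory column {rec_map[canon]!r} (for {canon!r})"
            )
    for canon in ("subject_id", "age", "sex_code"):
        if subj_map[canon] not in subj_df.columns:
            raise ConfigurationError(
                f"subjects file lacks mandatory column {subj_map[canon]!r} (for {canon!r})"
            )

    n_dropped: dict[str, int] = {}

    def drop(reason: str) -> None:
        n_dropped[reason] = n_dropped.get(reason, 0) + 1

    subjects: dict[str, SubjectProfile] = {}
    for _, row in subj_df.iterrows():
        try:
            profile = SubjectProfile(
                subject_id=str(row[subj_map["subject_id"]]).strip(),
                study_id=str(row.get(subj_map["study_id"], "") or "").strip(),
                age=_to_float(row.get(subj_map["age"])),
                sex_code=int(_to_float(row.get(subj_map["sex_code"]))),
                height=_opt(row, subj_map, "height"),
                weight=_opt(row, subj_map, "weight"),
                ethnicity_label=_opt_str(row, subj_map, "ethnicity_label"),
                country=_opt_str(row, subj_map, "country"),
                measured_fvc=_opt(row, subj_map, "measured_fvc"),
                measured_fev1=_opt(row, subj_map, "measured_fev1"),
            )
            profile.validate()
        except (InputError, ValueError):
            drop("invalid_subject")
            continue
        subjects[profile.subject_id] = profile

    seen_keys: set = set()
    kept_rows = []
    next_minute: dict[str, int] = {}
    for _, row in rec_df.iterrows():
        sid = str(row[rec_map["subject_id"]]).strip()
        session = str(row.get(rec_map["session"], "") or "").strip()
        try:
            hr = _to_float(row.get(rec_map["hr"]))
            fb = _opt(row, rec_map, "fb")
            ve = _opt(row, rec_map, "ve_observed")
            minute_raw = _to_float(row.get(rec_map["minute_index"]))
        except ValueError:
            drop("unparseable")
            continue
        if sid not in subjects:
            drop("unknown_subject")
            continue
        if np.isnan(hr) or hr <= 0:
            drop("invalid_hr")
            continue
        if fb is not None and fb <= 0:
            drop("invalid_fb")
            continue
        if ve is not None and ve <= 0:
            drop("invalid_ve")
            continue
        if np.isnan(minute_raw):
            # assign the next sequential minute for this subject/session
            minute = next_minute.get(sid + "\x00" + session, 0)
        else:
            minute = int(minute_raw)
        next_minute[sid + "\x00" + session] = minute + 1
        key = (sid, session, minute)
        if key in seen_keys:
            drop("duplicate_minute")
            continue
        seen_keys.add(key)
        kept = {
            "subject_id": sid,
            "minute_index": minute,
            "hr": hr,
            "fb": np.nan if fb is None else fb,
            "ve_observed": np.nan if ve is None else ve,
            "activity_label": _opt_str(row, rec_map, "activity_label") or np.nan,
        }
        if session:
            kept["session"] = session
        kept_rows.append(kept)

    records = pd.DataFrame(kept_rows, columns=PhysioDataset.RECORD_COLUMNS + (
        ["session"] if any("session" in r for r in kept_rows) else []
    ))
    provenance = {
        "source": repr(records_source),
        "rows_in": len(rec_df),
        "n_dropped": n_dropped,
    }
    return PhysioDataset(subjects, records, provenance)


def _opt(row, colmap, canon) -> Optional[float]:
    col = colmap.get(canon)
    if col is None or col not in row.index:
        return None
    v = _to_float(row[col])
    return None if np.isnan(v) else v


def _opt_str(row, colmap, canon) -> Optional[str]:
    col = colmap.get(canon)
    if col is None or col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def aggregate_to_minutes(
    samples: pd.DataFrame,
    time_col: str = "timestamp",
    statistic: str = "mean",
) -> pd.DataFrame:
    """Collapse sub-minute samples to one record per calendar minute.

    Per-minute value = arithmetic mean (or median, by config) of the in-minute
    samples, per channel. Minutes containing no valid HR sample are omitted.
    Unsorted timestamps are sorted internally with a warning. Idempotent on
    data already at one-minute resolution.

    ``samples`` needs a ``timestamp`` column (datetime-like, or numeric
    seconds) and ``hr``; ``fb``, ``ve_observed`` and ``subject_id`` are
    optional. Returns a frame with ``subject_id`` (if given), ``timestamp``
    (minute start), ``minute_index`` and the averaged channels.
    """
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if samples.empty:
        return pd.DataFrame(columns=["timestamp", "minute_index", "hr", "fb", "ve_observed"])
    df = samples.copy()
    if time_col not in df.columns:
        raise ConfigurationError(f"samples lack time column {time_col!r}")
    t = df[time_col]
    if np.issubdtype(np.asarray(t).dtype, np.number):
        minute = (np.asarray(t, dtype=float) // 60.0).astype(int)
        minute_start = minute * 60
    else:
        t = pd.to_datetime(t)
        minute_start = t.dt.floor("min")
        minute = (minute_start.astype("int64") // 60_000_000_000).astype(int)
    df["_minute"] = np.asarray(minute)
    df["_minute_start"] = np.asarray(minute_start)
    if not t.is_monotonic_increasing:
        warnings.warn("timestamps not sorted; sorting before aggregation", stacklevel=2)
        df = df.sort_values("_minute", kind="stable")

    group_cols = (["subject_id"] if "subject_id" in df.columns else []) + ["_minute"]
    channels = [c for c in ("hr", "fb", "ve_observed") if c in df.columns]
    agg = getattr(df.groupby(group_cols)[channels], statistic)().reset_index()
    starts = df.groupby(group_cols)["_minute_start"].first().reset_index()
    agg = agg.merge(starts, on=group_cols)
    agg = agg[agg["hr"].notna()]
    agg = agg.rename(columns={"_minute": "minute_index", "_minute_start": "timestamp"})
    order = ([c for c in ("subject_id",) if c in agg.columns]) + ["timestamp", "minute_index"] + channels
    return agg[order].reset_index(drop=True)


def summarize_dataset(ds: PhysioDataset) -> ValidationReport:
    """Cohort summary: counts, per-field mean/SD/range, sex frequency and percent."""
    if ds.n_records == 0 or ds.n_subjects == 0:
        raise InputError("cannot summarize an empty dataset")
    subj = ds.subject_frame()
    demo = {}
    for fieldname in ("age", "height", "weight", "measured_fvc"):
        vals = pd.to_numeric(subj[fieldname], errors="coerce").dropna()
        if len(vals) == 0:
            continue
        demo[fieldname] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    sex_counts = {}
    counts = subj["sex_code"].value_counts()
    for sex in (1, 2):
        n = int(counts.get(sex, 0))
        sex_counts[sex] = {"count": n, "percent": 100.0 * n / len(subj)}
    return ValidationReport(
        n_subjects=ds.n_subjects,
        n_records=ds.n_records,
        n_records_with_fb=int(ds.records["fb"].notna().sum()),
        n_dropped=dict(ds.provenance.get("n_dropped", {})),
        demographic_summary=demo,
        sex_counts=sex_counts,
    )
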