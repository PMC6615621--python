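"""Inhaled (intake) dose: concentration x ventilation integrated over time.

Inhaled dose over an interval is the time-integral of pollutant concentration
C(t) [µg/m³] times minute ventilation V̇E(t) [L/min]. At the data's native
one-minute resolution this is a rectangle rule:

    dose [µg] = Σ_minutes C * V̇E * 1 min * 1e-3 m³/L.

Streams are aligned on an inner join of minute indices; minutes missing a
required channel are skipped and counted by reason — gaps are never
interpolated, because fabricated exposure would fabricate dose. Deposition in
the respiratory tract is out of scope; this is intake dose only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["ExposureSeries", "DoseResult", "align_to_minute_grid", "integrate_dose"]

L_TO_M3 = 1e-3  # the single unit-conversion factor in the pipeline


@dataclass(frozen=True)
class ExposureSeries:
    """Per-minute pollutant concentration in µg/m³ (non-negative)."""

    concentrations: Mapping[int, float]
    pollutant: str = ""

    def __post_init__(self):
        conc = {int(k): float(v) for k, v in dict(self.concentrations).items()}
        if any(v < 0 for v in conc.values()):
            raise InputError("concentrations must be non-negative")
        object.__setattr__(self, "concentrations", conc)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, minute_col: str = "minute_index",
                   value_col: str = "concentration", pollutant: str = "") -> "ExposureSeries":
        return cls({int(m): float(v) for m, v in zip(df[minute_col], df[value_col])}, pollutant)

    def to_frame(self) -> pd.DataFrame:
        minutes = sorted(self.concentrations)
        return pd.DataFrame(
            {"minute_index": minutes, "concentration": [self.concentrations[m] for m in minutes]}
        )


@dataclass
class DoseResult:
    """Total inhaled dose plus the per-minute ledger behind it."""

    total_dose: float  # µg
    per_minute: pd.DataFrame  # minute_index, ve, concentration, incremental_dose
    minutes_covered: int
    minutes_skipped: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "total_dose_ug": self.total_dose,
            "minutes_covered": self.minutes_covered,
            "minutes_skipped": self.minutes_skipped,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_minute_frame(series, value_name: str) -> Optional[pd.DataFrame]:
    if series is None:
        return None
    if isinstance(series, ExposureSeries):
        df = series.to_frame().rename(columns={"concentration": value_name})
        return df
    if isinstance(series, Mapping):
        return pd.DataFrame(
            {"minute_index": [int(k) for k in series], value_name: [float(v) for v in series.values()]}
        )
    df = pd.DataFrame(series)
    if "minute_index" not in df.columns:
        raise InputError(f"{value_name} series needs a 'minute_index' column")
    cols = [c for c in df.columns if c != "minute_index"]
    return df.rename(columns={cols[0]: value_name})[["minute_index", value_name]]


def align_to_minute_grid(
    hr_series,
    fb_series=None,
    conc_series=None,
    require_fb: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Inner-join per-minute channels; returns (aligned frame, skip counts by reason).

    Each series is a mapping minute -> value, an :class:`ExposureSeries`, or a
    frame with a ``minute_index`` column. ``require_fb`` mirrors the chosen
    model's needs (f_B is not required for an HR-only model). Zero overlapping
    minutes is an error.
    """
    hr = _as_minute_frame(hr_series, "hr")
    if hr is None or hr.empty:
        raise InputError("an HR series is required for alignment")
    fb = _as_minute_frame(fb_series, "fb")
    conc = _as_minute_frame(conc_series, "concentration")

    aligned = hr
    skipped: dict[str, int] = {}
    if conc is not None:
        merged = aligned.merge(conc, on="minute_index", how="outer", indicator=True)
        skipped["no_concentration"] = int((merged["_merge"] == "left_only").sum())
        skipped["no_hr"] = int((merged["_merge"] == "right_only").sum())
        aligned = merged[merged["_merge"] == "both"].drop(columns="_merge")
    if fb is not None:
        merged = aligned.merge(fb, on="minute_index", how="left")
        if require_fb:
            n_missing = int(merged["fb"].isna().sum())
            if n_missing:
                skipped["no_fb"] = n_missing
            aligned = merged[merged["fb"].notna()]
        else:
            aligned = merged
    elif require_fb:
        raise InputError("the chosen model requires breath frequency, but no f_B series was given")

    aligned = aligned.sort_values("minute_index").reset_index(drop=True)
    if aligned.empty:
        raise InputError("no overlapping minutes between the supplied series")
    return aligned, {k: v for k, v in skipped.items() if v}


def integrate_dose(
    ve_series: Union[Mapping[int, float], pd.DataFrame],
    conc: ExposureSeries,
) -> DoseResult:
    """Rectangle-rule inhaled dose from aligned per-minute V̇E and concentration.

    incremental dose per minute [µg] = C [µg/m³] * V̇E [L/min] * 1 min * 1e-3 m³/L;
    the total is the sum. Additive over time partitions and linear in C.
    """
    ve = _as_minute_frame(ve_series, "ve")
    aligned, skipped = align_to_minute_grid(
        {int(m): float(v) for m, v in zip(ve["minute_index"], ve["ve"])},
        conc_series=conc,
    )
    aligned = aligned.rename(columns={"hr": "ve"})
    inc = aligned["concentration"].to_numpy(float) * aligned["ve"].to_numpy(float) * L_TO_M3
    per_minute = pd.DataFrame(
        {
            "minute_index": aligned["minute_index"].to_numpy(int),
            "ve": aligned["ve"].to_numpy(float),
            "concentration": aligned["concentration"].to_numpy(float),
            "incremental_dose": inc,
        }
    )
    return DoseResult(
        total_dose=float(inc.sum()),
        per_minute=per_minute,
        minutes_covered=len(per_minute),
        minutes_skipped=skipped,
    )
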