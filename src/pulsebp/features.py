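"""Morphological pulse features, demographic fusion and engineered terms.

Eleven per-beat features are computed on the baseline-corrected pulse:
timing (ascending/descending time, half-max pulse width, pulse rate),
intensity (pulse intensity rate, ascending/descending intensity
difference), slope (ascending/descending) and area (ascending/descending
trapezoidal area above the onset level).  Per-record aggregation is the
arithmetic mean over retained beats, with pulse rate recomputed from the
mean period.  Demographics (age, gender, height, weight, BMI) are
appended in a fixed, documented column order, and ratio/polynomial terms
are engineered on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DegeneratePulseError, PulseSegment

__all__ = [
    "PulseFeatures",
    "MORPH_FEATURES",
    "DEMO_FEATURES",
    "BASE_COLUMNS",
    "CONTINUOUS_BASE",
    "ENGINEERED_COLUMNS",
    "ALL_COLUMNS",
    "extract_pulse_features",
    "aggregate_record_features",
    "fuse_demographics",
    "engineer_features",
    "RecordRejectedError",
]

EPS = 1e-9


class RecordRejectedError(ValueError):
    """Record cannot yield a feature vector (too few pulses / no body size)."""


@dataclass
class PulseFeatures:
    ascending_time: float  # s, onset trough -> systolic peak
    descending_time: float  # s, systolic peak -> terminal trough
    pulse_width: float  # s, width at 50% relative amplitude
    pulse_rate: float  # BPM, 60/period
    pulse_intensity_rate: float  # au/s, amplitude per beat period
    ascending_slope: float  # au/s
    descending_slope: float  # au/s, signed (<= 0)
    ascending_area: float  # au*s above onset level
    descending_area: float  # au*s above onset level
    ascending_intensity_diff: float  # au, peak - onset
    descending_intensity_diff: float  # au, peak - end

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


MORPH_FEATURES = [f.name for f in dc_fields(PulseFeatures)]
DEMO_FEATURES = ["age", "gender", "height_cm", "weight_kg", "bmi"]
BASE_COLUMNS = MORPH_FEATURES + DEMO_FEATURES
CONTINUOUS_BASE = MORPH_FEATURES + ["age", "height_cm", "weight_kg", "bmi"]
ENGINEERED_COLUMNS = (
    ["area_ratio", "intensity_diff_ratio"] + [f"{c}_sq" for c in CONTINUOUS_BASE]
)
ALL_COLUMNS = BASE_COLUMNS + ENGINEERED_COLUMNS

_GENDER_CODE = {"female": 0.0, "male": 1.0, 0: 0.0, 1: 1.0, 0.0: 0.0, 1.0: 1.0}


def _half_crossing_ascending(x: np.ndarray, peak: int, half: float, fs: float) -> float:
    """Time of the half-amplitude crossing adjacent to the peak, rising flank."""
    for j in range(peak - 1, -1, -1):
        if x[j] < half:
            frac = (half - x[j]) / (x[j + 1] - x[j])
            return (j + frac) / fs
    return 0.0


def _half_crossing_descending(
    x: np.ndarray, peak: int, half: float, fs: float
) -> float:
    """Time of the half-amplitude crossing adjacent to the peak, falling flank."""
    for j in range(peak + 1, x.size):
        if x[j] < half:
            frac = (x[j - 1] - half) / (x[j - 1] - x[j])
            return (j - 1 + frac) / fs
    return (x.size - 1) / fs


def extract_pulse_features(segment: PulseSegment) -> PulseFeatures:
    """Compute the 11 morphological features of one baseline-corrected beat."""
    x = segment.samples
    fs = segment.fs_hz
    pk = segment.peak_idx - segment.onset_idx
    a_on, a_pk, a_end = float(x[0]), float(x[pk]), float(x[-1])
    if not (a_pk > a_on and a_pk > a_end):
        raise DegeneratePulseError("peak not strictly above both troughs")

    t_pk = pk / fs
    t_end = (x.size - 1) / fs
    ascending_time = t_pk
    descending_time = t_end - t_pk
    period = t_end

    half = a_on + 0.5 * (a_pk - a_on)
    t_rise = _half_crossing_ascending(x, pk, half, fs)
    t_fall = _half_crossing_descending(x, pk, half, fs)
    t = np.arange(x.size) / fs
    rel = x - a_on
    return PulseFeatures(
        ascending_time=ascending_time,
        descending_time=descending_time,
        pulse_width=t_fall - t_rise,
        pulse_rate=60.0 / period,
        pulse_intensity_rate=(a_pk - a_on) / period,
        ascending_slope=(a_pk - a_on) / ascending_time,
        descending_slope=(a_end - a_pk) / descending_time,
        ascending_area=float(np.trapezoid(rel[: pk + 1], t[: pk + 1])),
        descending_area=float(np.trapezoid(rel[pk:], t[pk:])),
        ascending_intensity_diff=a_pk - a_on,
        descending_intensity_diff=a_pk - a_end,
    )


def aggregate_record_features(
    per_pulse: Sequence[PulseFeatures], min_pulses: int = 3
) -> PulseFeatures:
    """Mean of each feature across beats; pulse rate from the mean period.

    Averaging 60/period per beat would overweight short beats (arithmetic
    mean of rates != rate of the mean period), so the record pulse rate is
    recomputed as 60 over the mean beat period.
    """
    per_pulse = list(per_pulse)
    if len(per_pulse) < min_pulses:
        raise RecordRejectedError(
            f"only {len(per_pulse)} retained pulses (< min_pulses={min_pulses})"
        )
    means = {
        name: float(np.mean([getattr(p, name) for p in per_pulse]))
        for name in MORPH_FEATURES
    }
    mean_period = float(
        np.mean([p.ascending_time + p.descending_time for p in per_pulse])
    )
    means["pulse_rate"] = 60.0 / mean_period
    return PulseFeatures(**means)


def _code_gender(g) -> float:
    if isinstance(g, str):
        key = g.strip().lower()
        if key in ("female", "f", "0"):
            return 0.0
        if key in ("male", "m", "1"):
            return 1.0
        raise ValueError(f"unknown gender token: {g!r}")
    if g in _GENDER_CODE:
        return _GENDER_CODE[g]
    raise ValueError(f"unknown gender token: {g!r}")


def fuse_demographics(
    agg: PulseFeatures, demo: Mapping[str, object]
) -> pd.Series:
    """Concatenate aggregated features and demographics (fixed column order).

    Gender is encoded female=0 / male=1.  A missing BMI is computed from
    height and weight; a record missing height, weight and BMI is rejected.
    Other missing demographics are left as NaN for training-median
    imputation inside the model (never from the test set).
    """
    def _get(key):
        v = demo.get(key) if hasattr(demo, "get") else demo[key]
        if v is None:
            return math.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return v

    age = _get("age")
    height = _get("height_cm")
    weight = _get("weight_kg")
    bmi = _get("bmi")
    if math.isnan(bmi) and not (math.isnan(height) or math.isnan(weight)):
        bmi = weight / (height / 100.0) ** 2
    if all(math.isnan(v) for v in (height, weight, bmi)):
        raise RecordRejectedError("missing height, weight and BMI")

    gender_raw = demo.get("gender") if hasattr(demo, "get") else demo["gender"]
    row = agg.as_dict()
    row.update(
        age=age,
        gender=_code_gender(gender_raw),
        height_cm=height,
        weight_kg=weight,
        bmi=bmi,
    )
    return pd.Series({c: row[c] for c in BASE_COLUMNS})


def _guard(denom: np.ndarray) -> np.ndarray:
    return np.where(np.abs(denom) < EPS, EPS, denom)


def engineer_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Append area/intensity ratios and squared continuous terms.

    Input must contain the base columns; output appends
    ``ENGINEERED_COLUMNS`` in order.  Denominators are epsilon-guarded so
    the output is always finite where the input is.
    """
    if matrix.empty:
        raise ValueError("empty feature matrix")
    missing = [c for c in BASE_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    out = matrix.copy()
    out["area_ratio"] = out["ascending_area"] / _guard(
        out["descending_area"].to_numpy()
    )
    out["intensity_diff_ratio"] = out["ascending_intensity_diff"] / _guard(
        out["descending_intensity_diff"].to_numpy()
    )
    for c in CONTINUOUS_BASE:
        out[f"{c}_sq"] = out[c] ** 2
    return out
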