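"""Clinical validation statistics for BP estimators.

Error convention is predicted - reference everywhere.  BHS grading uses
the cumulative percentage of absolute errors within 5/10/15 mmHg with
inclusive thresholds (A >= 60/85/95, B >= 50/75/90, C >= 40/65/85, else
D); the AAMI criterion passes iff |mean error| <= 5 mmHg and the sample
SD of errors <= 8 mmHg (both inclusive); Bland-Altman limits of
agreement are mean +/- 1.96 * sample SD of the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ErrorStats",
    "BhsResult",
    "AamiResult",
    "BlandAltman",
    "regression_metrics",
    "bhs_grade",
    "aami_check",
    "bland_altman",
    "subgroup_report",
    "BHS_THRESHOLDS",
    "AAMI_ME_LIMIT",
    "AAMI_SD_LIMIT",
]

# (grade, pct within 5, within 10, within 15) from the published BHS protocol
BHS_THRESHOLDS = [
    ("A", 60.0, 85.0, 95.0),
    ("B", 50.0, 75.0, 90.0),
    ("C", 40.0, 65.0, 85.0),
]
AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0


@dataclass
class ErrorStats:
    mae: float
    rmse: float
    r2: float
    mean_error: float
    sd_error: float  # sample SD (n-1)
    n: int


@dataclass
class BhsResult:
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    grade: str


@dataclass
class AamiResult:
    passed: bool
    abs_mean_error: float
    sd_error: float


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float


def _check_pair(reference, predicted, min_n: int = 2):
    ref = np.asarray(reference, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if ref.size != pred.size:
        raise ValueError("reference and predicted must have equal length")
    if ref.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return ref, pred


def regression_metrics(reference, predicted) -> ErrorStats:
    """MAE, RMSE, R^2, mean error and sample SD of (predicted - reference)."""
    ref, pred = _check_pair(reference, predicted)
    err = pred - ref
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant reference: R^2 undefined (NaN)", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return ErrorStats(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        r2=r2,
        mean_error=float(np.mean(err)),
        sd_error=float(np.std(err, ddof=1)),
        n=int(ref.size),
    )


def bhs_grade(abs_errors) -> BhsResult:
    """Grade a vector of absolute errors (mmHg) under the BHS protocol."""
    e = np.asarray(abs_errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("empty error vector")
    if np.any(e < 0):
        raise ValueError("absolute errors must be non-negative")
    pct5 = 100.0 * float(np.mean(e <= 5.0))
    pct10 = 100.0 * float(np.mean(e <= 10.0))
    pct15 = 100.0 * float(np.mean(e <= 15.0))
    grade = "D"
    for g, t5, t10, t15 in BHS_THRESHOLDS:
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            grade = g
            break
    return BhsResult(pct5, pct10, pct15, grade)


def aami_check(reference, predicted) -> AamiResult:
    """AAMI pass/fail: |ME| <= 5 mmHg and sample SD <= 8 mmHg (inclusive)."""
    ref, pred = _check_pair(reference, predicted)
    err = pred - ref
    me = float(np.mean(err))
    sd = float(np.std(err, ddof=1))
    return AamiResult(
        passed=abs(me) <= AAMI_ME_LIMIT and sd <= AAMI_SD_LIMIT,
        abs_mean_error=abs(me),
        sd_error=sd,
    )


def bland_altman(reference, predicted) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 * SD)."""
    ref, pred = _check_pair(reference, predicted)
    diff = pred - ref
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        sd_diff=sd,
    )


def subgroup_report(reference, predicted, labels) -> pd.DataFrame:
    """Per-group and pooled error statistics, BHS grade and AAMI status.

    ``labels`` assigns each row to a group (e.g. sex, BMI >= 25); groups
    with fewer than 2 members are skipped with a warning.  The returned
    table has one row per group plus a ``pooled`` row.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    labels = np.asarray(labels)
    if labels.size != ref.size:
        raise ValueError("labels must align with rows")
    rows = []

    def _row(name: str, r: np.ndarray, p: np.ndarray) -> dict:
        stats = regression_metrics(r, p)
        bhs = bhs_grade(np.abs(p - r))
        aami = aami_check(r, p)
        ba = bland_altman(r, p)
        return {
            "group": name,
            "n": stats.n,
            "mae": stats.mae,
            "rmse": stats.rmse,
            "r2": stats.r2,
            "mean_error": stats.mean_error,
            "sd_error": stats.sd_error,
            "pct_within_5": bhs.pct_within_5,
            "pct_within_10": bhs.pct_within_10,
            "pct_within_15": bhs.pct_within_15,
            "bhs_grade": bhs.grade,
            "aami_pass": aami.passed,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
        }

    for name in pd.unique(labels):
        mask = labels == name
        if mask.sum() < 2:
            warnings.warn(f"singleton group {name!r} skipped", stacklevel=2)
            continue
        rows.append(_row(str(name), ref[mask], pred[mask]))
    rows.append(_row("pooled", ref, pred))
    return pd.DataFrame(rows)
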