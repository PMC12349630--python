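"""End-to-end glue: raw records -> quality-controlled feature table.

One record flows through baseline correction, pulse detection, IQR and
amplitude quality control, per-pulse feature extraction and per-record
aggregation; the cohort-level helper joins the result with demographics
into a model-ready table, logging every rejected pulse and record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .features import (
    BASE_COLUMNS,
    PulseFeatures,
    RecordRejectedError,
    aggregate_record_features,
    extract_pulse_features,
    fuse_demographics,
)
from .preprocess import (
    DegeneratePulseError,
    RawSignal,
    Rejection,
    amplitude_select,
    baseline_correct,
    detect_pulses,
    iqr_filter,
)

logger = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "RecordDiagnostics", "process_record",
           "build_dataset"]


@dataclass(frozen=True)
class PreprocessConfig:
    min_window_s: float = 0.4  # baseline-point local-minimum half-window
    min_distance_s: float = 0.5  # peak separation (max 120 BPM)
    iqr_k: float = 1.5
    mean_frac_low: float = 0.2
    mean_frac_high: float = float("inf")
    min_pulses: int = 3


@dataclass
class RecordDiagnostics:
    subject_id: str
    n_detected: int = 0
    n_after_iqr: int = 0
    n_after_amplitude: int = 0
    iqr_rejections: list[Rejection] = field(default_factory=list)
    rejected_reason: str | None = None


def process_record(
    signal: RawSignal, config: PreprocessConfig = PreprocessConfig()
) -> tuple[PulseFeatures | None, RecordDiagnostics]:
    """Aggregate morphological features of one record, or None if rejected."""
    diag = RecordDiagnostics(subject_id=signal.subject_id)
    corrected, _, _ = baseline_correct(signal, config.min_window_s)
    _, segments = detect_pulses(corrected, config.min_distance_s)
    diag.n_detected = len(segments)
    segments, diag.iqr_rejections = iqr_filter(segments, config.iqr_k)
    diag.n_after_iqr = len(segments)
    segments = amplitude_select(
        segments, config.mean_frac_low, config.mean_frac_high
    )
    diag.n_after_amplitude = len(segments)

    per_pulse = []
    for seg in segments:
        try:
            per_pulse.append(extract_pulse_features(seg))
        except DegeneratePulseError:
            logger.info("%s: degenerate pulse skipped", signal.subject_id)
    try:
        agg = aggregate_record_features(per_pulse, config.min_pulses)
    except RecordRejectedError as exc:
        diag.rejected_reason = str(exc)
        logger.warning("%s rejected: %s", signal.subject_id, exc)
        return None, diag
    return agg, diag


def build_dataset(
    records: list[RawSignal],
    demographics: pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[pd.DataFrame, list[RecordDiagnostics]]:
    """Feature table (one row per subject, BASE_COLUMNS order) + diagnostics."""
    demo = demographics.set_index("subject_id")
    rows = {}
    diags = []
    for rec in records:
        agg, diag = process_record(rec, config)
        diags.append(diag)
        if agg is None:
            continue
        if rec.subject_id not in demo.index:
            diag.rejected_reason = "no demographics row"
            logger.warning("%s rejected: no demographics row", rec.subject_id)
            continue
        try:
            rows[rec.subject_id] = fuse_demographics(agg, demo.loc[rec.subject_id])
        except RecordRejectedError as exc:
            diag.rejected_reason = str(exc)
            logger.warning("%s rejected: %s", rec.subject_id, exc)
    table = pd.DataFrame.from_dict(rows, orient="index")[BASE_COLUMNS]
    table.index.name = "subject_id"
    return table, diags
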