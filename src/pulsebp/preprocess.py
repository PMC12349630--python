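"""Cleaning and segmentation of raw PPG records.

The pipeline mirrors standard pulse-oximetry practice: estimate the
low-frequency baseline by interpolating a cubic spline through per-beat
local minima and subtract it, detect systolic peaks with a physiological
minimum-distance constraint, delimit single pulses by the diastolic
troughs between peaks, then reject non-physiological pulses by a
Tukey-fence (1.5*IQR) rule on amplitude and period and an amplitude gate
relative to the mean peak amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "RawSignal",
    "FiducialSet",
    "PulseSegment",
    "Rejection",
    "DegeneratePulseError",
    "FiducialInvariantError",
    "baseline_correct",
    "detect_pulses",
    "iqr_filter",
    "amplitude_select",
]


class FiducialInvariantError(RuntimeError):
    """Internal peak/trough alternation invariant violated."""


class DegeneratePulseError(ValueError):
    """A pulse whose peak does not rise strictly above both troughs."""


@dataclass(eq=False)
class RawSignal:
    """A sampled PPG trace (arbitrary units) with its sampling rate."""

    samples: np.ndarray
    fs_hz: float
    subject_id: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.samples.size < 2 * self.fs_hz:
            raise ValueError(
                "signal shorter than 2 s; too short for fiducial detection"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass(eq=False)
class FiducialSet:
    """Alternating diastolic troughs and systolic peaks (0-based indices)."""

    trough_indices: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.trough_indices = np.asarray(self.trough_indices, dtype=int)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)

    def validate(self, samples: np.ndarray) -> None:
        t, p = self.trough_indices, self.peak_indices
        if np.any(np.diff(t) <= 0) or np.any(np.diff(p) <= 0):
            raise FiducialInvariantError("fiducial indices not strictly increasing")
        if p.size and t.size != p.size + 1:
            raise FiducialInvariantError(
                f"expected {p.size + 1} troughs around {p.size} peaks, got {t.size}"
            )
        for i, pk in enumerate(p):
            lo, hi = t[i], t[i + 1]
            if not (lo < pk < hi):
                raise FiducialInvariantError("peaks and troughs do not alternate")
            if not (samples[pk] > samples[lo] and samples[pk] > samples[hi]):
                raise FiducialInvariantError(
                    "peak sample not above both adjacent troughs"
                )


@dataclass(eq=False)
class PulseSegment:
    """One beat: onset trough -> systolic peak -> terminal trough (inclusive)."""

    onset_idx: int
    peak_idx: int
    end_idx: int
    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (self.onset_idx < self.peak_idx < self.end_idx):
            raise ValueError("require onset_idx < peak_idx < end_idx")
        if self.samples.size != self.end_idx - self.onset_idx + 1:
            raise ValueError("samples must span [onset_idx, end_idx] inclusive")

    @property
    def amplitude(self) -> float:
        """Peak value minus onset-trough value (drift-invariant)."""
        return float(self.samples[self.peak_idx - self.onset_idx] - self.samples[0])

    @property
    def period_s(self) -> float:
        return (self.end_idx - self.onset_idx) / self.fs_hz


@dataclass
class Rejection:
    pulse_idx: int
    cause: str  # "amplitude" | "period"
    value: float
    low: float
    high: float


def _beat_minima(x: np.ndarray, fs_hz: float, peak_distance_s: float) -> np.ndarray:
    """One local minimum per beat: the argmin between consecutive raw peaks.

    A preliminary distance-constrained peak scan on the raw signal anchors
    the beats; the minimum sample between neighbouring peaks (plus the
    minima before the first and after the last peak) is a diastolic trough
    and serves as a baseline point.  Anchoring on inter-peak argmins
    guarantees exactly one point per beat under strong drift and never
    selects the dicrotic notch (the true trough in the same interval is
    always lower).  Ties resolve leftmost via ``argmin``.
    """
    distance = max(1, int(round(peak_distance_s * fs_hz)))
    peaks, _ = find_peaks(x, distance=distance)
    if peaks.size == 0:
        return np.array([], dtype=int)
    idx = [int(np.argmin(x[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        idx.append(int(a + np.argmin(x[a : b + 1])))
    idx.append(int(peaks[-1] + np.argmin(x[peaks[-1] :])))
    return np.unique(idx)


def baseline_correct(
    signal: RawSignal,
    min_window_s: float = 0.4,
    peak_distance_s: float = 0.5,
) -> tuple[RawSignal, np.ndarray, np.ndarray]:
    """Remove low-frequency baseline wander by spline subtraction.

    Per-beat diastolic minima (``_beat_minima``) serve as baseline points;
    a natural cubic spline through them, held constant beyond the first
    and last point, is the baseline estimate subtracted from the signal.
    ``min_window_s`` bounds how far a baseline point may sit from its
    neighbours before the beat anchoring is distrusted (kept for interface
    stability; the beat anchoring itself uses ``peak_distance_s``).

    Correction runs in two passes: a first spline through beat minima of
    the raw signal removes the bulk of the drift; baseline points are then
    re-located on that roughly-flattened signal (where a steeply rising
    drift can no longer promote the dicrotic notch over the true trough)
    and the final spline interpolates the *original* samples at those
    points.

    Returns ``(corrected, baseline, baseline_point_indices)``.  With fewer
    than two minima the baseline falls back to the constant global minimum.
    """
    if not min_window_s > 0:
        raise ValueError("min_window_s must be positive")
    x = signal.samples

    def _spline_through(idx: np.ndarray) -> np.ndarray:
        spline = CubicSpline(idx.astype(float), x[idx], bc_type="natural")
        t = np.arange(x.size, dtype=float)
        return spline(np.clip(t, idx[0], idx[-1]))  # constant extrapolation

    idx = _beat_minima(x, signal.fs_hz, peak_distance_s)
    if idx.size >= 2:
        flattened = x - _spline_through(idx)
        idx2 = _beat_minima(flattened, signal.fs_hz, peak_distance_s)
        if idx2.size >= 2:
            idx = idx2
    if idx.size < 2:
        baseline = np.full_like(x, x.min())
    else:
        baseline = _spline_through(idx)
    corrected = RawSignal(
        x - baseline,
        signal.fs_hz,
        subject_id=signal.subject_id,
        segment_id=signal.segment_id,
    )
    return corrected, baseline, idx


def detect_pulses(
    corrected: RawSignal, min_distance_s: float = 0.5
) -> tuple[FiducialSet, list[PulseSegment]]:
    """Locate systolic peaks and diastolic troughs, then cut single beats.

    Peaks are local maxima at least ``min_distance_s`` apart (the larger of
    two conflicting candidates wins).  Troughs are the minimum sample
    between consecutive peaks plus the minima before the first and after
    the last peak.  Consecutive trough pairs bracketing one peak become
    segments; spans touching the record edges are incomplete and dropped.
    """
    if not min_distance_s > 0:
        raise ValueError("min_distance_s must be positive")
    x = corrected.samples
    distance = max(1, int(round(min_distance_s * corrected.fs_hz)))
    peaks, _ = find_peaks(x, distance=distance)
    if peaks.size == 0:
        warnings.warn("no peaks detected; empty segmentation", stacklevel=2)
        return FiducialSet(np.array([], int), np.array([], int)), []

    troughs = [int(np.argmin(x[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(int(a + np.argmin(x[a : b + 1])))
    troughs.append(int(peaks[-1] + np.argmin(x[peaks[-1] :])))

    fiducials = FiducialSet(np.asarray(troughs), peaks)
    fiducials.validate(x)

    segments: list[PulseSegment] = []
    for i, pk in enumerate(peaks):
        onset, end = troughs[i], troughs[i + 1]
        if onset == 0 or end == x.size - 1:
            continue  # incomplete first/last span
        segments.append(
            PulseSegment(
                onset_idx=onset,
                peak_idx=int(pk),
                end_idx=end,
                samples=x[onset : end + 1].copy(),
                fs_hz=corrected.fs_hz,
            )
        )
    return fiducials, segments


def _tukey_fences(values: np.ndarray, k: float) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def iqr_filter(
    segments: Sequence[PulseSegment], k: float = 1.5
) -> tuple[list[PulseSegment], list[Rejection]]:
    """Reject pulses whose amplitude or period lies outside the Tukey fences.

    A segment survives iff amplitude is within [Q1-k*IQR, Q3+k*IQR] of the
    amplitude distribution AND its period is within the analogous period
    fences.  Quartiles use linear interpolation of order statistics.  With
    fewer than 4 segments quartiles are undefined and all are retained.
    """
    segments = list(segments)
    if len(segments) < 4:
        warnings.warn("fewer than 4 pulses: IQR filter skipped", stacklevel=2)
        return segments, []
    amps = np.array([s.amplitude for s in segments])
    periods = np.array([s.period_s for s in segments])
    a_lo, a_hi = _tukey_fences(amps, k)
    p_lo, p_hi = _tukey_fences(periods, k)
    retained: list[PulseSegment] = []
    report: list[Rejection] = []
    for i, seg in enumerate(segments):
        ok = True
        if not (a_lo <= amps[i] <= a_hi):
            report.append(Rejection(i, "amplitude", float(amps[i]), a_lo, a_hi))
            ok = False
        if not (p_lo <= periods[i] <= p_hi):
            report.append(Rejection(i, "period", float(periods[i]), p_lo, p_hi))
            ok = False
        if ok:
            retained.append(seg)
    return retained, report


def amplitude_select(
    segments: Sequence[PulseSegment],
    mean_frac_low: float = 0.2,
    mean_frac_high: float = np.inf,
) -> list[PulseSegment]:
    """Gate pulses by amplitude relative to the mean peak amplitude.

    Retains segments with amplitude in ``[mean_frac_low*A, mean_frac_high*A]``
    where ``A`` is the mean amplitude over the input segments.  The default
    upper gate is +inf; pass ``mean_frac_high=1.0`` for the literal closed
    interval between 20% of the average peak and the mean.
    """
    segments = list(segments)
    if not segments:
        return []
    if mean_frac_low < 0:
        raise ValueError("mean_frac_low must be >= 0")
    mean_amp = float(np.mean([s.amplitude for s in segments]))
    lo = mean_frac_low * mean_amp
    hi = mean_frac_high * mean_amp
    return [s for s in segments if lo <= s.amplitude <= hi]
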