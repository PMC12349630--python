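"""Baseline correction, fiducial detection and pulse quality control."""

import numpy as np
import pytest

from conftest import make_segment
from pulsebp.preprocess import (
    RawSignal,
    amplitude_select,
    baseline_correct,
    detect_pulses,
    iqr_filter,
)
from pulsebp.synth import PulseShapeParams, RecordConfig, synth_record


def _clean_record(**kwargs):
    cfg = RecordConfig(noise_sd=0.0, drift_amp=0.0, outlier_pulse_prob=0.0,
                       **kwargs)
    return synth_record(cfg)


class TestBaselineCorrect:
    def test_constant_signal_corrects_to_zero(self):
        sig = RawSignal(np.full(500, 3.7), 125.0)
        corrected, baseline, _ = baseline_correct(sig)
        np.testing.assert_allclose(baseline, 3.7)
        np.testing.assert_allclose(corrected.samples, 0.0, atol=1e-12)

    def test_linear_ramp_removed_within_bound(self):
        sig, truth = _clean_record(seed=1)
        ramp = 0.05 * sig.times
        ramped = RawSignal(sig.samples + ramp, sig.fs_hz)
        corrected, _, _ = baseline_correct(ramped)
        # per-period spline knots track a linear trend to within its
        # per-beat increment
        assert np.max(np.abs(corrected.samples - truth.clean)) <= 0.05 + 1e-9

    def test_sinusoidal_drift_recovered(self):
        sig, truth = synth_record(
            RecordConfig(noise_sd=0.0, drift_amp=0.5, drift_freq_hz=0.2,
                         drift_phase=1.0, outlier_pulse_prob=0.0, seed=2)
        )
        corrected, _, _ = baseline_correct(sig)
        interior = slice(50, 1200)  # exclude first/last half-period
        rmse = np.sqrt(np.mean(
            (corrected.samples[interior] - truth.clean[interior]) ** 2))
        assert rmse <= 0.05  # 5% of the unit pulse amplitude

    def test_corrected_is_zero_at_baseline_points(self):
        sig, _ = synth_record(RecordConfig(seed=3))
        corrected, _, idx = baseline_correct(sig)
        assert idx.size >= 2
        np.testing.assert_allclose(corrected.samples[idx], 0.0, atol=1e-9)

    def test_near_idempotent_without_drift(self):
        # re-correcting an already-corrected signal only re-interpolates the
        # tiny sub-zero spline-overshoot dips; changes are a vanishing
        # fraction of the pulse amplitude and contract on iteration
        sig, _ = _clean_record(seed=4)
        once, _, _ = baseline_correct(sig)
        twice, _, _ = baseline_correct(once)
        rms2 = np.sqrt(np.mean((twice.samples - once.samples) ** 2))
        assert rms2 < 1e-4
        thrice, _, _ = baseline_correct(twice)
        rms3 = np.sqrt(np.mean((thrice.samples - twice.samples) ** 2))
        assert rms3 < rms2


class TestDetectPulses:
    def test_clean_train_peak_positions(self):
        # the clean train needs no baseline removal; detection alone must
        # recover every ground-truth systolic peak
        _, truth = _clean_record(seed=5)
        clean = RawSignal(truth.clean, 125.0)
        fid, _ = detect_pulses(clean, min_distance_s=0.4)
        assert fid.peak_indices.size == truth.n_pulses == 12
        assert np.max(np.abs(fid.peak_indices - truth.peak_indices)) <= 2

    def test_single_interior_pulse_yields_one_segment(self):
        # one bell centred in a 4 s record; flanking minima are interior
        fs = 125.0
        t = np.arange(int(4 * fs)) / fs
        x = np.exp(-((t - 2.0) ** 2) / (2 * 0.1**2)) + 0.2 * np.exp(
            -((t - 2.0) ** 2) / (2 * 1.0**2)
        )
        fid, segments = detect_pulses(RawSignal(x, fs))
        assert fid.peak_indices.size == 1
        assert fid.peak_indices[0] == np.argmax(x)
        assert len(segments) == (
            1 if fid.trough_indices[0] > 0
            and fid.trough_indices[-1] < x.size - 1 else 0
        )

    def test_flat_signal_no_peaks(self):
        sig = RawSignal(np.zeros(500), 125.0)
        with pytest.warns(UserWarning, match="no peaks"):
            fid, segments = detect_pulses(sig)
        assert fid.peak_indices.size == 0
        assert segments == []

    def test_fiducials_alternate(self):
        sig, _ = synth_record(RecordConfig(seed=6))
        corrected, _, _ = baseline_correct(sig)
        fid, segments = detect_pulses(corrected)
        t, p = fid.trough_indices, fid.peak_indices
        assert t.size == p.size + 1
        for i, pk in enumerate(p):
            assert t[i] < pk < t[i + 1]
        for seg in segments:
            rel = seg.peak_idx - seg.onset_idx
            assert seg.samples[rel] == seg.samples.max()

    def test_segments_exclude_record_edges(self):
        sig, _ = _clean_record(seed=7)
        corrected, _, _ = baseline_correct(sig)
        _, segments = detect_pulses(corrected)
        for seg in segments:
            assert seg.onset_idx > 0
            assert seg.end_idx < sig.samples.size - 1


def _brute_force_iqr(amps, periods, k=1.5):
    """Independent oracle: quartiles from sorted order statistics."""
    def quartiles(v):
        s = sorted(v)
        n = len(s)

        def q(p):
            h = (n - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, n - 1)
            return s[lo] + (h - lo) * (s[hi] - s[lo])

        return q(0.25), q(0.75)

    qa1, qa3 = quartiles(amps)
    qp1, qp3 = quartiles(periods)
    ia, ip_ = qa3 - qa1, qp3 - qp1
    keep = []
    for i, (a, p) in enumerate(zip(amps, periods)):
        if (qa1 - k * ia <= a <= qa3 + k * ia) and (
            qp1 - k * ip_ <= p <= qp3 + k * ip_
        ):
            keep.append(i)
    return keep


class TestIqrFilter:
    def test_identical_pulses_all_retained(self):
        segs = [make_segment(1.0, 0.8) for _ in range(20)]
        kept, report = iqr_filter(segs)
        assert len(kept) == 20
        assert report == []

    def test_planted_amplitude_outlier_rejected(self):
        segs = [make_segment(1.0, 0.8) for _ in range(19)]
        segs.insert(7, make_segment(5.0, 0.8))
        kept, report = iqr_filter(segs)
        assert len(kept) == 19
        assert all(s.amplitude == pytest.approx(1.0) for s in kept)
        assert [r.cause for r in report] == ["amplitude"]

    def test_planted_period_outlier_rejected(self):
        segs = [make_segment(1.0, 0.8) for _ in range(19)]
        segs.insert(3, make_segment(1.0, 2.0))
        kept, report = iqr_filter(segs)
        assert len(kept) == 19
        assert [r.cause for r in report] == ["period"]

    def test_too_few_segments_skipped_with_warning(self):
        segs = [make_segment(1.0, 0.8) for _ in range(3)]
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, report = iqr_filter(segs)
        assert len(kept) == 3 and report == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(4, 51))
            amps = rng.uniform(0.2, 3.0, n)
            periods = rng.uniform(0.4, 1.6, n)
            segs = [make_segment(a, p) for a, p in zip(amps, periods)]
            kept, _ = iqr_filter(segs)
            expected = _brute_force_iqr(
                [s.amplitude for s in segs], [s.period_s for s in segs]
            )
            got = [segs.index(s) for s in kept]
            assert got == expected

    def test_filter_only_removes_and_preserves_order(self):
        rng = np.random.default_rng(1)
        segs = [
            make_segment(a, p)
            for a, p in zip(rng.uniform(0.5, 4, 30), rng.uniform(0.4, 2, 30))
        ]
        kept, _ = iqr_filter(segs)
        ids = [id(s) for s in segs]
        assert all(id(s) in ids for s in kept)
        assert [ids.index(id(s)) for s in kept] == sorted(
            ids.index(id(s)) for s in kept
        )


class TestAmplitudeSelect:
    def test_equal_amplitudes_all_retained(self):
        segs = [make_segment(1.0) for _ in range(10)]
        assert len(amplitude_select(segs)) == 10

    def test_small_pulse_rejected_by_mean_fraction(self):
        segs = [make_segment(1.0) for _ in range(9)] + [make_segment(0.05)]
        kept = amplitude_select(segs)
        # mean amplitude 0.905, lower gate 0.181 > 0.05
        assert len(kept) == 9
        assert all(s.amplitude == pytest.approx(1.0) for s in kept)

    def test_zero_fraction_is_identity(self):
        segs = [make_segment(a) for a in (0.1, 1.0, 2.0, 0.01)]
        assert amplitude_select(segs, mean_frac_low=0.0) == segs

    def test_literal_closed_interval_upper_gate(self):
        segs = [make_segment(a) for a in (0.5, 1.0, 1.0, 3.0)]
        kept = amplitude_select(segs, mean_frac_low=0.2, mean_frac_high=1.0)
        assert [s.amplitude for s in kept] == pytest.approx([0.5, 1.0, 1.0])

    def test_empty_input(self):
        assert amplitude_select([]) == []
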