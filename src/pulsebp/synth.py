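"""Synthetic PPG cohort generator with known ground truth.

Each beat is modelled as the sum of two Gaussian-shaped components — a
systolic upstroke and a smaller, later dicrotic wave — which is the
minimal morphology exposing every feature the extractor computes.  A
record is a superposition of such beats at regular onsets plus a
low-frequency sinusoidal baseline drift and white noise; occasional
beats are rescaled far outside the physiological amplitude range to
exercise the quality-control filters.

At the cohort level each subject carries a latent arterial-stiffness
score s ~ Uniform(0,1) that deforms the pulse shape (faster, sharper
upstroke and attenuated dicrotic wave as s grows) and drives blood
pressure through a known linear map with demographic (age) contribution,
so the downstream regression problem has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .preprocess import RawSignal

__all__ = [
    "PulseShapeParams",
    "RecordConfig",
    "CohortConfig",
    "RecordTruth",
    "CohortTruth",
    "Cohort",
    "synth_pulse",
    "synth_record",
    "synth_cohort",
    "DEFAULT_SHAPE",
]


@dataclass(frozen=True)
class PulseShapeParams:
    """Two-component bell parameterisation of one beat.

    Timing parameters (mu, sigma) are fractions of the beat period;
    amplitudes are in arbitrary units.
    """

    period_s: float = 0.8
    amp_sys: float = 1.0
    mu_sys: float = 0.25
    sigma_sys: float = 0.08
    amp_dic: float = 0.35
    mu_dic: float = 0.60
    sigma_dic: float = 0.12

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise ValueError("period_s must be positive")
        if not self.amp_sys > 0:
            raise ValueError("amp_sys must be positive")
        if not 0 <= self.amp_dic < self.amp_sys:
            raise ValueError("require 0 <= amp_dic < amp_sys")
        if not 0 < self.mu_sys < self.mu_dic < 1:
            raise ValueError("require 0 < mu_sys < mu_dic < 1")
        if not (self.sigma_sys > 0 and self.sigma_dic > 0):
            raise ValueError("sigmas must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Closed-form pulse value at times ``t`` (seconds from beat onset)."""
        t = np.asarray(t, dtype=float)
        p = self.period_s
        sys = self.amp_sys * np.exp(
            -((t - self.mu_sys * p) ** 2) / (2 * (self.sigma_sys * p) ** 2)
        )
        dic = self.amp_dic * np.exp(
            -((t - self.mu_dic * p) ** 2) / (2 * (self.sigma_dic * p) ** 2)
        )
        return sys + dic


DEFAULT_SHAPE = PulseShapeParams()


@dataclass(frozen=True)
class RecordConfig:
    duration_s: float = 10.0
    fs_hz: float = 125.0
    drift_amp: float = 0.5  # 0.5*amp_sys: below the 0.5 Hz high-pass corner
    drift_freq_hz: float = 0.2
    drift_phase: float = 0.0
    noise_sd: float = 0.003  # in-band residual noise of curated, band-passed PPG
    outlier_pulse_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_pulse_prob <= 1:
            raise ValueError("outlier_pulse_prob must be in [0, 1]")


@dataclass(eq=False)
class RecordTruth:
    """Everything needed to reproduce and verify one generated record."""

    clean: np.ndarray  # drift- and noise-free pulse train
    onsets_s: np.ndarray  # beat onset times
    peak_indices: np.ndarray  # argmax sample of each beat in the clean train
    pulse_scales: np.ndarray  # amplitude multipliers (1.0 except outliers)
    shape: PulseShapeParams

    @property
    def n_pulses(self) -> int:
        return self.onsets_s.size


def synth_pulse(shape: PulseShapeParams, fs_hz: float) -> np.ndarray:
    """Render one isolated beat: ``round(period_s * fs_hz)`` samples."""
    if not fs_hz > 0:
        raise ValueError("fs_hz must be positive")
    n = int(round(shape.period_s * fs_hz))
    t = np.arange(n) / fs_hz
    return shape.evaluate(t)


def synth_record(
    config: RecordConfig, shape: PulseShapeParams = DEFAULT_SHAPE
) -> tuple[RawSignal, RecordTruth]:
    """Generate a PPG record: pulse train + sinusoidal drift + noise.

    The clean train superposes ``floor(duration/period)`` complete beats
    at onsets ``k*period`` (Gaussian tails overlap naturally).  With
    probability ``outlier_pulse_prob`` a beat's amplitude is multiplied
    by a factor far outside [0.3, 3].  Identical seeds give bit-identical
    output.
    """
    if config.duration_s < shape.period_s:
        raise ValueError("duration shorter than one pulse period")
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n_samples) / config.fs_hz
    n_pulses = int(np.floor(config.duration_s / shape.period_s))
    onsets = np.arange(n_pulses) * shape.period_s

    scales = np.ones(n_pulses)
    outlier_mask = rng.random(n_pulses) < config.outlier_pulse_prob
    for k in np.flatnonzero(outlier_mask):
        if rng.random() < 0.5:
            scales[k] = rng.uniform(0.05, 0.28)
        else:
            scales[k] = rng.uniform(3.2, 6.0)

    clean = np.zeros(n_samples)
    for k, onset in enumerate(onsets):
        clean += scales[k] * shape.evaluate(t - onset)

    peak_indices = np.array(
        [
            int(np.argmin(np.abs(t - (onset + shape.mu_sys * shape.period_s))))
            for onset in onsets
        ]
    )
    drift = config.drift_amp * np.sin(
        2 * np.pi * config.drift_freq_hz * t + config.drift_phase
    )
    noise = rng.normal(0.0, config.noise_sd, n_samples) if config.noise_sd > 0 else 0.0
    signal = RawSignal(clean + drift + noise, config.fs_hz)
    truth = RecordTruth(
        clean=clean,
        onsets_s=onsets,
        peak_indices=peak_indices,
        pulse_scales=scales,
        shape=shape,
    )
    return signal, truth


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    The BP map is ``SBP = bp_intercept_sbp + bp_stiffness_gain_sbp*s +
    bp_age_coef*(age-50) + N(0, bp_noise_sd)`` and analogously for DBP;
    default intercepts/gains reproduce a clinical mix with SBP mean ~115,
    SD ~22 mmHg and DBP mean ~63, SD ~14 mmHg, with SBP > DBP guaranteed
    by the intercept/gain margins.
    """

    n_subjects: int = 300
    age_range: tuple[float, float] = (18.0, 91.0)
    sex_ratio: float = 0.543  # fraction male
    bp_intercept_sbp: float = 76.0
    bp_intercept_dbp: float = 39.0
    bp_stiffness_gain_sbp: float = 75.0
    bp_stiffness_gain_dbp: float = 47.0
    bp_age_coef: float = 0.25
    bp_noise_sd: float = 3.0
    seed: int = 0
    record: RecordConfig = field(default_factory=RecordConfig)
    base_shape: PulseShapeParams = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.bp_noise_sd < 0:
            raise ValueError("bp_noise_sd must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass(eq=False)
class CohortTruth:
    stiffness: np.ndarray  # latent s_i in [0,1]
    shapes: list[PulseShapeParams]
    records: list[RecordTruth]


@dataclass(eq=False)
class Cohort:
    records: list[RawSignal]
    demographics: pd.DataFrame  # subject_id, age, gender, height_cm, weight_kg, bmi
    targets: pd.DataFrame  # subject_id, sbp, dbp
    truth: CohortTruth


def _shape_for_stiffness(
    base: PulseShapeParams, s: float, amp_sys: float, period_s: float
) -> PulseShapeParams:
    """Deform the base morphology monotonically with stiffness ``s``.

    Stiffer arteries give a faster, sharper systolic upstroke (mu_sys and
    sigma_sys shrink) and an attenuated dicrotic wave (amp_dic shrinks).
    The reflected wave also arrives earlier and merges into the falling
    limb as compliance drops, modelled as a broadening of the dicrotic
    component (sigma_dic grows); this keeps the diastolic decay sloped all
    the way to the next onset, as in real pulse waveforms, so the
    onset-trough remains a well-posed minimum at every stiffness.
    """
    return replace(
        base,
        period_s=period_s,
        amp_sys=amp_sys,
        mu_sys=base.mu_sys * (1 - 0.4 * s),
        sigma_sys=base.sigma_sys * (1 - 0.1 * s),
        amp_dic=base.amp_dic * (1 - 0.15 * s),
        sigma_dic=base.sigma_dic * (1 + 0.3 * s),
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def synth_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort of records, demographics and SBP/DBP targets."""
    rng = np.random.default_rng(config.seed)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)

    records: list[RawSignal] = []
    demo_rows = []
    target_rows = []
    stiffness = rng.uniform(0.0, 1.0, config.n_subjects)
    shapes: list[PulseShapeParams] = []
    truths: list[RecordTruth] = []

    lo_age, hi_age = config.age_range
    for i in range(config.n_subjects):
        sid = f"S{i:04d}"
        s = float(stiffness[i])
        male = rng.random() < config.sex_ratio
        age = _truncated_normal(rng, 59.0, 15.0, lo_age, hi_age)
        if male:
            height = _truncated_normal(rng, 175.0, 7.0, 140.0, 210.0)
            weight = _truncated_normal(rng, 78.0, 12.0, 40.0, 160.0)
        else:
            height = _truncated_normal(rng, 162.0, 7.0, 130.0, 200.0)
            weight = _truncated_normal(rng, 65.0, 11.0, 35.0, 150.0)
        bmi = weight / (height / 100.0) ** 2

        period = float(np.clip(rng.normal(0.8, 0.012), 0.65, 0.95))
        amp_sys = float(np.clip(rng.normal(1.0, 0.05), 0.8, 1.2))
        shape = _shape_for_stiffness(config.base_shape, s, amp_sys, period)
        shapes.append(shape)

        rec_seed = int(seeds[i].generate_state(1, np.uint32)[0] % (2**31))
        rec_cfg = replace(
            config.record,
            seed=rec_seed,
            drift_phase=float(rng.uniform(0, 2 * np.pi)),
        )
        signal, truth = synth_record(rec_cfg, shape)
        signal.subject_id = sid
        signal.segment_id = "seg0"
        records.append(signal)
        truths.append(truth)

        eps = rng.normal(0.0, config.bp_noise_sd, 2) if config.bp_noise_sd > 0 else (
            np.zeros(2)
        )
        sbp = (
            config.bp_intercept_sbp
            + config.bp_stiffness_gain_sbp * s
            + config.bp_age_coef * (age - 50.0)
            + eps[0]
        )
        dbp = (
            config.bp_intercept_dbp
            + config.bp_stiffness_gain_dbp * s
            + config.bp_age_coef * (age - 50.0)
            + eps[1]
        )
        if not sbp > dbp:
            raise RuntimeError(
                f"generated DBP >= SBP for subject {sid}; "
                "intercept/gain margins too small for bp_noise_sd"
            )
        demo_rows.append(
            dict(
                subject_id=sid,
                age=age,
                gender="male" if male else "female",
                height_cm=height,
                weight_kg=weight,
                bmi=bmi,
            )
        )
        target_rows.append(dict(subject_id=sid, sbp=sbp, dbp=dbp))

    return Cohort(
        records=records,
        demographics=pd.DataFrame(demo_rows),
        targets=pd.DataFrame(target_rows),
        truth=CohortTruth(stiffness=stiffness, shapes=shapes, records=truths),
    )
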