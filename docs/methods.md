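# Methods

`pulsebp` estimates systolic and diastolic blood pressure (SBP/DBP, mmHg)
from single-channel photoplethysmogram (PPG) pulse morphology fused with
demographics. This note documents the models, the numerical choices, what
the bundled synthetic cohort does and does not emulate, and the known
limitations.

## Signal model and preprocessing

Input records are 10 s PPG segments sampled at 125 Hz, assumed already
band-pass filtered (0.5–8 Hz) as in curated clinical waveform databases.
Residual low-frequency baseline wander is removed by subtracting a natural
cubic spline through per-beat diastolic minima:

1. A preliminary peak scan (local maxima ≥ `peak_distance_s` = 0.5 s apart,
   the larger of two conflicting candidates kept) anchors the beats; the
   minimum sample between consecutive raw peaks is a baseline point. This
   anchoring yields exactly one point per beat under strong drift and never
   selects the dicrotic notch, because the true trough in the same
   inter-peak interval is always lower.
2. Correction is two-pass: the first spline removes the bulk of the drift;
   baseline points are then re-located on the flattened signal and the final
   natural cubic spline interpolates the *original* samples at those points,
   held constant beyond the first/last point. The second pass matters when
   the drift rises steeply: on the raw signal the drift can climb more than
   the notch depth (~0.2 au) between a trough and the following notch, which
   would otherwise promote the notch to a baseline point. A shape-preserving
   (PCHIP) spline was evaluated instead of the natural spline and rejected:
   it cannot dip below the chord between knots and therefore cannot follow
   the drift's local minima, leaving residuals above the 5 % recovery target.
   With the two-pass natural spline, a 0.2 Hz sinusoidal drift at half the
   pulse amplitude is removed to ≤ 3.5 % interior RMSE at every phase, and
   the corrected signal is exactly zero at every baseline point.

   Re-correcting an already-corrected signal re-interpolates the tiny
   sub-zero overshoot dips of the spline (≈ 4·10⁻⁵ RMS on a unit-amplitude
   record) and contracts further on iteration; correction is a fixed-point
   iteration rather than an exact projection.

Systolic peaks are then detected on the corrected signal as local maxima
with a minimum separation of `min_distance_s` = 0.5 s (maximum 120 BPM);
diastolic troughs are the minimum between consecutive peaks plus the minima
before the first and after the last peak. Peaks and troughs strictly
alternate (asserted on every call). Consecutive trough pairs bracketing one
peak become single-beat segments; spans touching the record edges are
incomplete and discarded. The 0.5 s default is deliberate: every sample of
a beat lies within half a period (≤ 0.43 s at 75 BPM) of a true systolic
peak, so all intra-beat candidates — dicrotic waves and noise bumps in the
diastolic tail — conflict with a kept peak and are suppressed by
construction, whereas at 0.4 s a tail bump can survive by conflicting only
with the already-suppressed dicrotic candidate. The trade-off is an upper
heart-rate bound of 120 BPM, adequate for resting clinical segments;
tachycardic data requires lowering `min_distance_s` (exposed in the
configuration).

Quality control applies two gates in order:

- **Tukey fences (1.5·IQR)** on pulse amplitude (peak − onset value) and
  pulse period, quartiles by linear interpolation of order statistics
  (type 7). With fewer than four beats the filter is skipped with a warning.
- **Amplitude gate**: retain beats with amplitude ≥ 0.2 × the mean amplitude
  of the surviving beats. The upper gate defaults to +∞; the literal closed
  interval [0.2·Ā, Ā] is available via `mean_frac_high = 1.0`. A literal
  upper gate at the mean would reject every above-average beat, which cannot
  be the intent of gating on "20 % of the average peak".

## Morphological features

Eleven per-beat features are computed on the baseline-corrected segment
with onset value A_on, peak A_pk, end A_end at times t_on, t_pk, t_end:

| feature | definition | units |
|---|---|---|
| ascending_time | t_pk − t_on | s |
| descending_time | t_end − t_pk | s |
| pulse_width | width at 50 % relative amplitude, sub-sample linear interpolation on the crossings adjacent to the peak | s |
| pulse_rate | 60 / (t_end − t_on) | BPM |
| pulse_intensity_rate | (A_pk − A_on) / (t_end − t_on) | au/s |
| ascending_slope | (A_pk − A_on) / ascending_time | au/s |
| descending_slope | (A_end − A_pk) / descending_time (signed ≤ 0) | au/s |
| ascending_area | trapezoidal ∫ (x − A_on) over [t_on, t_pk] | au·s |
| descending_area | trapezoidal ∫ (x − A_on) over [t_pk, t_end] | au·s |
| ascending_intensity_diff | A_pk − A_on | au |
| descending_intensity_diff | A_pk − A_end | au |

Areas are measured above the onset level so they are offset- and
drift-invariant; the signed descending slope preserves information. Width
at half maximum is used because pulse width is a distinct quantity from the
pulse period. Pulse intensity rate is defined as amplitude change per beat
period; the intensity-ratio alternative found in the literature is
inapplicable after baseline correction drives troughs to zero. These two
conventions are configurable interpretation points, not physical constants.

Per record, features are aggregated by the arithmetic mean across retained
beats (≥ `min_pulses` = 3, otherwise the record is rejected with a logged
reason); the record pulse rate is recomputed as 60 over the mean beat
period, since averaging per-beat rates overweights short beats.
Demographics (age, gender, height, weight, BMI) are appended in a fixed
column order — gender encoded female = 0 / male = 1 for the tree models and
as a categorical token for the embedder; a missing BMI is computed from
height and weight; other missing demographics are imputed with
training-fold medians at fit time, never from held-out data. Engineered
terms are appended: ascending/descending area ratio, intensity-difference
ratio (denominators ε-guarded at 10⁻⁹), and the square of every continuous
base feature.

## Model

The regressor is a two-level stack, fitted per target (SBP and DBP
separately) with shared representation stages:

1. **Robust scaling**: (x − median)/IQR per continuous column (type-7
   quartiles); zero-IQR columns are centred only; the categorical channel
   passes through.
2. **Mutual-information selection**: MI(feature; target) estimated on an
   8×8 quantile-binned contingency table, averaged over the SBP and DBP
   targets; the top `k_keep` = 20 continuous columns are retained, ties
   broken by original column order. The binned estimator is deterministic,
   which a k-NN MI estimator is not.
3. **Tabular transformer embedder**: the categorical token (gender) is
   embedded (dim 64) and passed through 6 post-norm transformer blocks
   (8 heads, dropout 0.2); the attended embedding is flattened,
   concatenated with the scaled continuous features (combined width d) and
   regressed jointly on (SBP, DBP) through a two-hidden-layer ReLU
   perceptron of widths (4d, 2d) with squared-error loss. Training uses
   Adam (lr 10⁻³), batch 64, up to 100 epochs with patience 10 on a 15 %
   validation split; everything is float64 and fully seeded, so two fits
   with the same seed are bit-identical. `transform` exposes the
   penultimate 2d-dimensional activations. The network is implemented
   directly in NumPy with manual backpropagation; gradients are verified
   against central finite differences in the test suite. With a single
   categorical column self-attention over one token is mathematically a
   per-token transformation; the implementation is general in the number of
   categorical columns.
4. **Base regressors**: three gradient-boosted tree families — XGBoost,
   LightGBM, and sklearn's classical GradientBoostingRegressor — each tuned
   by seeded random search (default 25 trials; 5 in the bundled study
   conditions) over estimators ∈ [300, 1000], learning rate ∈ [0.01, 0.1]
   (log-uniform), depth ∈ [3, 10], plus subsample/colsample ∈ [0.5, 1.0]
   for XGBoost; each trial scored by 3-fold mean absolute error inside the
   training partition.
5. **Out-of-fold stacking**: base-model meta-features are strictly
   out-of-fold predictions under 5-fold splits (shuffle, seed 42) of the
   training partition — no row is ever predicted by a model trained on it;
   an internal integrity check raises if any row lacks an OOF prediction.
   The meta-input is [3 OOF predictions ‖ embedder representation ‖ scaled
   engineered features] and the meta-regressor is a gradient-boosting
   machine fixed at 200 estimators, learning rate 0.05, depth 4. Base
   models are refit on the full training partition for deployment.

Evaluation uses subject-level 5-fold cross-validation (shuffle, seed 42):
every fitted component — imputer, scaler, selector, embedder, bases, meta —
is learned inside each training fold only, and validation-fold predictions
are pooled. The meta-model's pooled MAE is monitored against the best
single base model: a ratio above 1.1 logs a warning, above 1.25 raises.
SBP and DBP are predicted independently; no ordering constraint is imposed
at prediction time.

## Clinical evaluation

Errors are predicted − reference throughout. Reported statistics: MAE,
RMSE, R² (about the reference mean), mean error and sample SD (n − 1, the
device-validation convention); BHS grading on the cumulative percentage of
absolute errors within 5/10/15 mmHg with inclusive thresholds
(A ≥ 60/85/95, B ≥ 50/75/90, C ≥ 40/65/85, else D); the AAMI criterion
(|ME| ≤ 5 mmHg and SD ≤ 8 mmHg, both inclusive); Bland–Altman limits of
agreement at mean ± 1.96·SD. Subgroup reports (sex, BMI ≥ 25) apply the
same statistics within each group; singleton groups are skipped with a
warning.

## Synthetic cohort

The generator exists so the entire pipeline is testable with known ground
truth and no external data. One beat is the sum of two Gaussian bells —
systolic upstroke and dicrotic wave — with defaults (fractions of the
0.8 s period) mu_sys 0.25, sigma_sys 0.08, amp_sys 1, mu_dic 0.60,
sigma_dic 0.12, amp_dic 0.35. A record superposes floor(duration/period)
beats at onsets k·period (Gaussian tails overlap naturally), adds a 0.2 Hz
sinusoidal drift of amplitude 0.5 — deliberately below the 0.5 Hz high-pass
corner of the assumed pre-filter, so baseline correction is genuinely
exercised — plus white noise (sd 0.003 au, the in-band residual of a
band-passed, quality-screened clinical PPG), and rescales each beat with
probability 0.05 by a factor far outside [0.3, 3] to exercise the IQR gate.

Each subject carries a latent arterial-stiffness score s ~ Uniform(0, 1)
deforming the shape: mu_sys ×(1 − 0.4 s) and sigma_sys ×(1 − 0.1 s)
(faster, sharper upstroke), amp_dic ×(1 − 0.15 s) (attenuated dicrotic
wave), sigma_dic ×(1 + 0.3 s) (the reflected wave returns earlier and
merges into the falling limb as compliance drops). The gains were chosen
so that the onset trough stays a well-posed minimum at every stiffness:
with argmin-based trough fiducials, deformations that flatten the
diastolic decay (a strong dicrotic attenuation or a much narrower systolic
bell) make the detected onset wander and would systematically bias
ascending time upward with stiffness. Under the chosen map the aggregated
ascending time is strongly monotone in s (Spearman ρ ≈ −0.95 at n = 300).
Per-subject heart period is N(0.8 s, 0.012 s) (clipped to [0.65, 0.95]) —
deliberately a modest spread so beat-timing features reflect stiffness
rather than heart-rate variation — and pulse amplitude N(1, 0.05) adds
nuisance gain variation.

Blood pressure follows a known linear map:
SBP = 76 + 75·s + 0.25·(age − 50) + N(0, 3) and
DBP = 39 + 47·s + 0.25·(age − 50) + N(0, 3) (mmHg), with SBP > DBP
guaranteed by the intercept/gain margins and validated per subject. The
defaults reproduce a clinical mix: SBP ≈ 115 ± 22, DBP ≈ 63 ± 14 mmHg.
Ages are N(59, 15) truncated to [18, 91]; sex is Bernoulli(0.543 male);
heights and weights are sex-conditional truncated normals and BMI is
computed, never drawn. All randomness flows from a single seed through
spawned per-subject streams; identical configurations and seeds give
bit-identical cohorts.

What the generator does **not** emulate: motion artifacts, sensor
saturation, arrhythmic beat-to-beat variability, multi-segment subjects,
drug-induced BP dynamics, and any nonlinear BP–morphology relation. Passing
the bundled study therefore demonstrates that the pipeline recovers a known
monotone morphology→BP map through realistic drift/noise/outlier
corruption with honest cross-validation — not clinical-grade accuracy on
real patients.

## Study conditions and problem sizes

The bundled end-to-end study (also what `scripts/acceptance.py` runs) uses
300 subjects, 3 mmHg target noise, 5-fold subject-level cross-validation,
and random search reduced to 5 trials per base family; the leakage control
repeats the identical pipeline on permuted targets, where pooled
out-of-fold R² is expected at or below zero. Workflow determinism is
checked by running the complete synthetic pipeline twice at the same seed
and comparing outputs byte for byte.

## Known limitations

- Heart rates above 120 BPM require lowering `min_distance_s`.
- Baseline correction is a contraction, not an exact projection
  (re-correction changes the signal at the 10⁻⁵ level).
- The dicrotic notch is not localized; notch-timing features (and the
  larger feature catalogues built on them) are out of scope.
- SBP and DBP are modelled independently; predicted SBP ≤ DBP is possible
  in principle and not corrected.
- The MI estimator's histogram bias (~0.05 nats at n = 2000) is immaterial
  for ranking but makes absolute MI values approximate.
- Single 10 s segment per subject; the subject-level CV contract prevents
  identity leakage if multi-segment data is plugged in, but this path is
  untested against real multi-segment cohorts.
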