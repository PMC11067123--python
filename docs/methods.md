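# Methods

This note documents the models, numerical choices and limitations behind
`pdmotion`, in the order data flows through the package.

## Synthetic trajectory generator

The generator (`pdmotion.simulate`) stands in for pose-estimation output of
real clinical video, which is not publicly available for this class of
study. It is first-class, tested code — the study conditions for every
downstream validation — not a throwaway fixture.

**Movement model.** The arm is a two-link planar-dominant chain
(shoulder–elbow–wrist) with the hand rigidly attached, driven by a phase
variable φ(t) whose instantaneous frequency is `base_freq_hz +
freq_slope_hz_per_s·t` (floored at 0.05 Hz). For FTN, the elbow opens from
~0.7 to ~2.8 rad with the phase and the shoulder elevates with the reach;
for HPS the arm is held out while the hand rotates ±1.3 rad about the
forearm axis, with small elbow/wrist wobble so that the wrist and thumb
angle channels carry signal. A slight compensatory trunk lean couples the
shoulder to the reach — without it the shoulder is constant in the
egocentric frame and its velocity channels degenerate to pure round-off,
which max-abs scaling would amplify into noise; shoulder compensation is
also a clinically observed phenomenon. Trajectories are emitted in a world
frame with a constant body offset plus slow postural sway, so the
egocentric transform does real work.

**Symptom mechanisms.** Four independent mechanisms, each with a parameter
and an activation threshold:

| mechanism | parameter | unit | symptomatic strength used by cohorts |
|---|---|---|---|
| sequence effect | `freq_slope_hz_per_s` | Hz/s | −0.05 |
| amplitude decrement | `amp_decrement_per_cycle` | fraction/cycle | 0.05 |
| pauses | `pause_dwell_s` | s held at each extremum | 0.4 |
| tremor | `tremor_amp` | length units at 5 Hz | 0.02 |

Amplitude decays smoothly as (1−d)^(φ/2π), so successive peaks shrink by
the configured fraction. Pauses hold the phase at each half-cycle extremum
for the dwell time. Tremor is a sinusoid along a random fixed direction,
full amplitude at wrist/hand, 30% at the elbow. Measurement error is
i.i.d. Gaussian jitter per keypoint axis (`noise_sd`); view changes are
rigid rotations + translations (`perturb_view`).

**Severity mapping.** The severity score is the number of mechanisms whose
parameter crosses its threshold, capped at 4; it is 0 iff all symptom
parameters are at their asymptomatic defaults. This gives a reproducible
score→parameter link for label-recovery testing; it is a stand-in, not a
clinical claim — only score > 0 (symptom presence) is used downstream.

**Cohorts.** `simulate_cohort` keeps participant identity stable across
assessments (limb lengths ±8%, preferred rate ±20%, handedness) and
redraws the severity per assessment from a configurable mix, mimicking
changing medication state. The default mix (45% score 0, 42% score 1, 13%
above 1) reproduces the FTN class balance reported clinically (55%
positive). Defaults: 19 s videos at 30 fps (the reported median duration),
~1 Hz repetition rate.

**What the generator does not emulate.** Pose-estimation error is far
richer than i.i.d. jitter: motion blur, identity swaps, depth ambiguity,
frame drops, and systematically worse hand tracking (the reported likely
cause of poor HPS performance in practice). Symptom magnitudes here are
strong and mechanisms are independent; real severity is correlated,
graded and noisier. Passing tests therefore demonstrate that the pipeline
recovers the symptom structure it targets when that structure is present —
not that comparable accuracy transfers to clinical video.

## Kinematic channels

Joint angles use the three-point arccos formula with the cosine clamped to
[−1, 1]; degenerate frames (zero-length limb vector) yield missing samples
that are linearly interpolated before differentiation, with a logged
count. Each keypoint is reduced to one scalar per frame — the Euclidean
norm of its hip-relative position — which is forced by the channel
enumeration (5 keypoints → 5 positional signals, not 15) and has the side
benefit of rotation invariance. The thumb angle uses the wrist as vertex
between the wrist→finger and wrist→thumb vectors, the only construction
available from the tracked keypoint set that follows pronation–supination.

Gaussian "width" is interpreted as the kernel σ in seconds (σ·fps
samples), truncated at 4σ with reflected boundaries. Filtering is applied
to the base position/angle signal *before* differentiation, so each filter
width's velocity/acceleration channels are derivatives of the
correspondingly filtered position. Forward differences are used as
defined (v_t = (x_{t+1}−x_t)·fps, length N−1; a_t likewise with fps²,
length N−2). Max-abs scaling maps every channel into [−1, 1]; an all-zero
channel is returned unchanged rather than divided by zero. Note that
max-abs scaling makes near-constant channels sensitive to additive noise
(the scaling limitation also noted for abnormally small movements in
practice); the hip channel, identically zero in the egocentric frame, is
stable because the subtraction is exact.

## Features

* **Dominant-frequency series**: 6.6-s rectangular window (198 frames at
  30 fps, no taper or detrending), hop of 1 frame by default (maximal
  overlap; configurable). Within each window the maximum-magnitude non-DC
  DFT bin is taken; DC is excluded because channels are amplitude-scaled,
  not mean-centered. Ties break toward the lower frequency; a window with
  no non-DC content (relative magnitude below 1e−9·window) reports a
  missing value. Frequency resolution is 1/6.6 ≈ 0.15 Hz.
* **Trend regressions** are ordinary least squares; fewer than two defined
  points (or fewer than two peaks) yields missing coefficients.
* **Peak detection** uses strict local maxima with minimum topographic
  prominence 0.01 on the [−1, 1] scale, suppressing numerical ripple. Edge
  peaks have truncated prominence, so a constant-amplitude sinusoid's
  amplitude slope is only approximately zero (an order of magnitude below
  a genuine decrement).
* **Pause Metric** is summed with `math.fsum` (correctly rounded), so it
  agrees exactly with the defining per-frame loop regardless of summation
  order. It is non-decreasing in T and bounded by T·N.
* **Fourier bin features** are whole-signal rfft magnitudes named by bin
  edges (e.g. `0.47-0.52Hz`). `extract_feature_vector` band-limits them to
  < 6 Hz by default: voluntary task movement lies below ~4.2 Hz and rest
  tremor at 4–6 Hz, and the full grid would multiply the feature count
  several-fold without adding physiologically meaningful predictors. The
  full spectrum is available via `max_freq_hz=None`.
* **Generic descriptors** go through a pluggable extractor interface; the
  bundled minimal set (mean, variance, longest run above the mean,
  relative position of the maximum, sum of recurring values, linear trend
  slope) covers the kinds of generic features that prove useful for this
  problem while keeping the package self-contained. A comprehensive
  external extractor can be dropped in through the same interface.

Missing feature values are data, not errors: a 4-s channel has no
frequency trend (shorter than the window) but a well-defined Pause Metric,
and downstream filtering/imputation handles the gaps.

## Modeling

Stages run in a fixed order on training rows only; every fitted statistic
(means, scales, imputer neighbors, kept-feature lists, classifier state)
is frozen and replayed identically at prediction time.

Tuned ranges: missing-fraction threshold [0, 1); minimum post-scaling
variance [0, 0.4); correlation cutoff [0.7, 0.9); imputation and SMOTE
neighbor counts {1, 2, 3}; LASSO coefficient threshold [0.01, 0.035); SVM
C [0, 2) and γ [0, 0.1]. C = 0 and γ = 0 are degenerate for an SVM, so
draws exclude exact zero (floor 1e−6). The LASSO penalty strength itself
is fixed at α = 0.01 on standardized features (only the coefficient
threshold is tuned); it is exposed as an argument. Correlation pruning
scans columns in canonical (sorted-name) order and drops the later column
of any pair with |r| above the cutoff — deterministic and
order-reproducible; the correlation matrix is computed in float32 (a
~10⁴-column matrix fits comfortably and the 1e−3-level rounding is far
below any sensible cutoff). SMOTE synthesizes x + u·(x′−x) with u ~
U(0, 1) between a minority row and one of its k nearest minority
neighbors until exact class parity.

SVM probabilities come from a sigmoid (Platt) fit to decision values on
internal training folds (`CalibratedClassifierCV`, `ensemble=False`),
required because evaluation thresholds probabilities at 0.5. The random
forest uses library default tree settings with a fixed seed. Tenfold CV in
the randomized search groups folds by participant when the training set
has at least 10 participants, otherwise falls back to stratified folds;
oversampling, selection and fitting all happen inside each training fold,
and only original rows are ever scored. Failed draws (e.g. every feature
filtered away) score −∞ rather than aborting the search.

## Evaluation

Precision, recall and F1 use the 0.5 operating point; zero denominators
produce 0 with a logged warning. AUROC is trapezoidal with midrank tie
handling and is reported missing for single-class label sets. Bootstrap
CIs are percentile 2.5/97.5 over 100 resamples of the validation set
(each of the original size, drawn with replacement); resamples whose label
draw makes a metric undefined are skipped for that metric with a logged
count. Percentile (rather than BCa) intervals are the simplest defensible
choice at 100 resamples.

## Problem sizes and determinism

The validation suite uses 19-s, 30-fps videos; cohort-level checks use 28
participants × 6 assessments (168 videos) with the default severity mix,
median over 10 seeds for label-recovery, and 5 cohorts in the acceptance
script. One global seed fans out to per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, so trajectory files,
feature tables and metrics reproduce bit-identically for a fixed seed.

## Known limitations

* The generator's realism gap (above) means synthetic-cohort accuracy is
  an upper bound sanity check, not a clinical performance estimate.
* Max-abs scaling discards absolute movement amplitude; abnormally small
  but well-formed movements look normal after scaling.
* The severity mapping is mechanism-counting, not a calibrated clinical
  scale; multiclass severity prediction is out of scope.
* Fold grouping by participant inside CV is a package choice where the
  procedure is underdetermined; with fewer than 10 training participants
  folds are stratified and may mix a participant across folds (the outer
  train/validation split is always participant-disjoint).
* The feature-name scheme ties Fourier bin features to the signal length;
  cohorts of mixed video durations produce sparsely aligned Fourier
  columns that the missing-fraction filter then removes.
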