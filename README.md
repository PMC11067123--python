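# pdmotion

Detection of Parkinsonian motor symptoms from 3D body-keypoint time series.

Markerless human pose estimation turns consumer-grade video of a clinical
motor exam into per-frame 3D keypoint trajectories. `pdmotion` implements
the downstream analysis for two upper-limb tasks — **finger-to-nose (FTN)**
and **hand pronation–supination (HPS)** — from those trajectories to a
binary symptom call with confidence intervals. It is aimed at researchers
in clinical movement analysis and digital biomarkers who need an
end-to-end, testable reference for this class of pipeline, including a
synthetic trajectory generator with controllable symptom structure so
every stage can be validated without clinical video data.

## Method

Keypoints (hip, shoulder, elbow, wrist, finger, and thumb for HPS) are
re-expressed in an egocentric frame with the same-side hip as origin. Each
video becomes a fixed enumeration of scalar kinematic channels: per-keypoint
position norms and three-point joint angles

θ = arccos( (A−B)·(C−B) / |A−B||C−B| )

for the shoulder, elbow, wrist (and thumb) vertices, each as position /
velocity / acceleration (first and second forward differences), each
unfiltered or Gaussian-smoothed (σ = 0.1 s, 0.2 s), each scaled by its
maximum absolute value. This yields 72 channels for FTN and 90 for HPS.

Per channel, three custom bradykinesia features target the cardinal
phenomena:

* **sequence effect** — slope of the dominant non-DC Fourier frequency of a
  6.6-s sliding window regressed on time (progressive slowing ⇒ slope < 0);
* **amplitude decrement** — slope of topographic peak prominence regressed
  on peak time (shrinking excursions ⇒ slope < 0);
* **Pause Metric** — P = Σ_t (T − |x_t|)·1[|x_t| < T] on the scaled signal,
  evaluated on the threshold grid T ∈ {0.05, 0.10, …, 0.95}; time dwelling
  in low-motion states raises P.

These are complemented by whole-signal Fourier bin magnitudes and generic
time-series descriptors. Classification binarizes the clinician severity
score (positive iff > 0) and runs, on training participants only:
missing-fraction filter → standardization → variance filter → k-NN
imputation → correlation pruning → SMOTE oversampling to class parity →
LASSO coefficient-threshold feature selection → RBF-SVM (calibrated
probabilities) or random forest, with hyperparameters drawn by randomized
search scored by tenfold cross-validated F1. Validation uses an 80–20
participant-grouped split (no participant in both sets), a 0.5 operating
point, and 100-fold bootstrap confidence intervals for precision, recall
and F1.

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

simulates a 28-participant × 6-assessment FTN cohort (55–60% of videos
symptomatic), trains the SVM pipeline on 80% of participants and prints:

```
cohort: 168 videos, 100 symptomatic (60%)
validation: 36 videos from held-out participants
confusion at 0.5: TP=25 FP=0 FN=0 TN=11
precision 1.00, recall 1.00, F1 1.00, AUROC 1.00
  bootstrap precision: mean 1.00 [1.00, 1.00] (100 resamples)
  ...
7 features selected:
      type    joint       signal filter_width      detail
   generic    elbow acceleration          0.0    variance
   fourier   finger acceleration          0.0 0.32-0.37Hz
freq_trend   finger acceleration          0.0       slope
   ...
```

The confusion matrix counts held-out videos at the 0.5 probability
threshold; the selected-feature table decomposes each surviving feature
into its channel provenance (joint, signal, filter width) and type —
here the pipeline picked, among others, a frequency-trend slope (sequence
effect) and a Pause Metric threshold, the interpretable symptom measures.
Synthetic cohorts with strong symptom expression are cleanly separable,
so perfect held-out scores are expected; real video data is harder (see
`docs/methods.md` for what the generator does and does not emulate).

The other examples walk the earlier stages: `01_simulate_trajectories.py`
(trajectory generation and file format), `02_kinematic_channels.py`
(channel enumeration: 72/24/8 for FTN, 90/30/10 for HPS), and
`03_symptom_features.py` (feature responses to known symptom structure).

A thin CLI mirrors the same chain for shell use:

```bash
pdmotion simulate --task ftn --seed 3 --out run/
pdmotion extract  --trajectories run/trajectories_ftn.csv --out run/
pdmotion train    --features run/features_ftn.csv --model svm --n-iter 0 --out run/
pdmotion evaluate --features run/features_ftn.csv --pipeline run/pipeline.joblib --out run/
pdmotion report   --pipeline run/pipeline.joblib
```

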