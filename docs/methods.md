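# Methods

## The problem and the pipeline

Surface EMG recorded from forearm (extrinsic) and hand (intrinsic) muscles
during a sustained hand grasp changes with wrist posture: joint angle
alters muscle geometry and the position of muscle fibres relative to the
electrodes, so a motion classifier trained with the wrist in one position
degrades when the wrist moves. `wristemg` implements an offline study of
that effect and of a training scheme that removes the need to record
training data in every wrist position: model how each EMG feature's mean
and variance change with wrist angle, then *simulate* multi-position
training data from neutral-position recordings.

The pipeline stages and their fixed protocol constants:

| stage | constants (defaults) |
|---|---|
| session | 4 classes (rest, open, chuck, key), 13 wrist positions, 6 reps x 3 s holds, 9+4 channels, 1 kHz |
| EMG filter | Chebyshev type I, order 8, 30-350 Hz band-pass, 0.5 dB ripple, causal SOS |
| angle filter | Butterworth, order 3, 10 Hz low-pass |
| windows | 200 ms length, 20 ms increment (141 windows per 3 s hold) |
| features | MAV, ZC, SSC, WL + 6 Burg AR coefficients per channel; optional 3 POS angles |
| splits | 50% train / 20% validation / 30% test, stratified per (class, position); two folds |
| classifiers | LDA, QDA, LNN (4 identity hidden units), MLPANN (7 tanh hidden units) |
| ratio model | per (class, channel, feature) x {mean, variance}: 3-3-1 tanh network |

All network training uses scaled conjugate gradient (Møller's algorithm in
the netlab formulation): a Hessian-free batch method with no learning-rate
hyperparameter, implemented batched over networks so the ~2000-regressor
bank trains as one vectorised run.

## The synthetic-data generator

No public dataset exists for this protocol, so a generator emulates it.
The EMG model is the standard interference model: band-limited Gaussian
noise whose per-channel standard deviation encodes muscle activation.
Band-limiting is exact — white noise is masked to 30–350 Hz on the rFFT
grid and rescaled analytically — so a trial's sample standard deviation
equals its configured amplitude up to sampling error and all power lies in
band.

Amplitude follows an affine-quadratic law in the wrist angles. With
θ_n = θ / end-range ∈ [−1, 1] per degree of freedom,

    A(class, channel, θ) = base_gain · (1 + α·θ_n + β·θ_n²) + noise_floor,

with per-(class, channel) coefficients α ∈ [−0.6, 0.6] and β ∈ [−0.3, 0.6]
drawn once from a fixed parameter seed (the default modulation is a module
constant, not per-session randomness). The quadratic term makes the law
smooth but non-linear — learnable by a 3-unit tanh network, not by a
linear regressor. Design choices behind the defaults:

* **Class structure.** The three grasps share one activation profile
  (0.10–0.30 mV per channel) with ±18% class-specific deviations, so
  classes overlap realistically at the window level; rest is low-level
  postural tone (0.02–0.05 mV, above the 0.01 mV noise floor) with full
  angle sensitivity — holding a non-neutral wrist takes muscle activity
  even with no hand motion, which is why the rest class's ratio curves are
  the cleanest to learn.
* **Intrinsic channels** get half the angle sensitivity of extrinsic ones,
  mirroring the weaker position dependence of muscles inside the hand.
* **Effort variability.** Grasp force is only held within a feedback band,
  so active-class trials carry mean-one lognormal amplitude multipliers:
  5% (common across channels) and 2.5% (per channel) between repetitions.
  The rest class gets none. This is the dominant noise source in the
  ratio targets.
* **Wrist-angle traces** are the target angles plus slow (≤1 Hz) jitter
  clipped at ±5°, matching the hold tolerance of the protocol.
* **Ranges**: ±60° flexion/extension, ±20° deviation, ±80°
  pronation/supination; mid-range = half. These are typical wrist ranges
  of motion and are configurable.

`true_ratio` exposes the generator's analytic ground truth: amplitude-
linear features (MAV, WL) scale with A(θ)/A(0) in mean and with its square
in variance. ZC, SSC and AR coefficients are amplitude-invariant, so their
true ratio curves are identically 1 — an intentional property used to test
the degenerate-regressor handling below.

What the generator does **not** emulate: motor-unit structure, spectral
changes with posture or fatigue (all features that are not amplitude-driven
are position-flat here, unlike real EMG), electrode shift, day-to-day
non-stationarity, and cross-feature dependence beyond what MAV/WL share
through the common amplitude. Passing tests therefore show the pipeline
recovers a known smooth amplitude effect and that simulated training data
closes the position gap *under this model*; they do not certify
performance on human recordings.

## Ratio targets and splits

Per (class, position) cell, feature means and variances are computed on
three disjoint subsets and divided by the same subset's neutral-position
statistics, giving training, validation and test targets whose neutral
value is exactly 1 by construction. Because 200 ms windows advanced by
20 ms overlap 90%, rows within a repetition are strongly dependent; the
three subsets are therefore drawn at the **repetition** level (~50% of
repetitions for the training targets, ~20% validation, ~30% test), which
keeps their sampling noise independent — the classifier splits, by
contrast, are row-level, as is conventional for windowed EMG.

Numerical edge cases:

* **Signed features near zero.** A mean *ratio* is meaningless when the
  neutral mean is essentially zero (possible for AR coefficients); such
  features switch to a difference-from-neutral target, flagged per
  regressor and inverted correspondingly when simulating.
* **Variance floor** of 1e-12 in every variance denominator; negative
  predicted variances are clipped to the floor when simulating.
* **Degenerate (flat) targets.** A regressor is degenerate when its
  training and validation targets correlate below 0.8 across the 13
  positions, or are exactly constant. The gate is split-half reliability:
  flat-up-to-noise targets (all amplitude-invariant features here)
  correlate near 0 between independent repetition subsets, genuinely
  position-dependent ones near 1. The 0.8 threshold is the ~99.9% null
  quantile of a 13-point correlation — chosen because each bank screens
  on the order of 10³ regressors at once, so a per-test 95% gate would
  pass tens of flat regressors whose noise-fitted networks then produce
  arbitrarily negative test r². Degenerate regressors predict the constant
  training-target mean and report r² = NaN, excluded from bank averages.
* **Angle inputs** are scaled by the grid's end ranges to [−1, 1] before
  entering the tanh networks.
* **Early stopping** follows the validation-increase rule literally: stop
  after 6 *consecutive* increases of validation loss, restore the
  best-validation weights. Counting non-improving (plateau) iterations
  instead systematically underfits these tiny noisy regressions.
* **Restarts**: 3 seeded restarts per network, best validation loss kept.

## What the numbers mean

On a default synthetic session the bank's mean-ratio test r² averages
0.82–0.88 over non-degenerate regressors, and its predictions recover the
generator's analytic ratio curves with r² ≈ 0.94. The variance-ratio
networks score far lower (often below 0) — with 6 repetitions and ~45
effectively independent windows per cell, a cell variance estimate carries
20–30% noise, and 13 such targets rarely support a network fit that beats
a constant. The mean-below-variance ordering is expected and stable; the
absolute variance-side r² is a limitation of the session size, not of the
optimiser.

In the three-dataset comparison (real vs bank-simulated vs neutral-only
training, all LDA, all tested on held-out real repetitions across the 13
positions), neutral-only training errs at ~11–14% (combined muscles),
bank-simulated training at ~2–3%, real multi-position training at ~1–2%:
a 74–86% relative error reduction from the position-adjusted simulation,
with simulated-trained performance close to real-trained. Holding out
whole repetitions here matters: with row-level holdout, near-duplicate
overlapping windows from the same hold appear on both sides of the split
and push the real-trained error to a floor no simulated-data classifier
could reach.

The simulator draws every feature column independently (an explicit
modelling assumption); preserving cross-feature covariance is out of
scope. Count-valued features (ZC, SSC) are sampled continuously — the
downstream discriminants are moment-driven and rounding would distort
low-variance cells.

## Experiment drivers

* **Grid**: 4 classifiers × {TDAR, TDAR+POS} × {extrinsic, intrinsic,
  combined}, two-fold cross-validated, errors averaged across positions;
  the relative change from adding POS features is tabulated per cell.
* **Subset search**: exhaustive evaluation of all C(13, n) training-
  position combinations for an LDA tested on all positions; ties broken by
  the lexicographically smallest index tuple. Named presets expose the
  end-range-only and mid-range-only training sets.
* **Paradigms**: one classifier trained on all positions and tested per
  position, versus 13 position-specific classifiers — both reported as the
  mean of 13 position-wise errors.
* Statistical testing of the resulting tables (repeated-measures ANOVA
  etc.) is deliberately out of scope; tables are emitted in long format
  for external tools.

## Problem sizes used in the checks

The full-protocol session (312 trials, 43,992 windows) is used for the
ratio-model recovery and simulated-training checks; the grid, paradigm and
subset-search checks run on reduced sessions (3 repetitions, 0.4–0.5 s
holds), and the seed-wise real-vs-simulated comparison uses four reduced
sessions (3 repetitions, 1 s holds). These sizes keep the whole suite at
a few minutes on one CPU while leaving every per-cell estimate enough
windows to be meaningful.
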