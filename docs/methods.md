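# Methods

## Scope and data model

`dyskit` estimates per-limb dystonia severity (integer 0–4, the amplitude
convention of the Dyskinesia Impairment Scale) from four limb-worn IMUs
sampling free acceleration (m/s²), angular velocity (deg/s) and ZYX Euler
angles (deg) at a nominal 60 Hz. The unit of analysis is one
(5-s window, limb) pair: its input is the 11-signal block of that limb's
own sensor (three acceleration axes plus resultant, three gyro axes plus
resultant, three angles), and its label is the median of three clinician
scores for that window. Samples from left and right limbs are pooled into
an upper-extremity and a lower-extremity table; a left/right indicator is
deliberately not exposed to the classifiers.

## Synchronization and windowing

Home-recorded streams lose timestamps and occasionally a whole sensor. The
four streams are resampled by linear interpolation onto a uniform
`1000/60` ms grid spanning the intersection of their time ranges; nothing
is extrapolated, and a sensor that ends early truncates the recording to
the common overlap (flagged degraded). Euler angles are unwrapped
(period 360°) before interpolation and rewrapped to [−180°, 180°), so
interpolation across the seam stays near ±180° instead of crossing zero.
Grid points within 1 ms of a raw sample are marked observed, all others
interpolated; windows whose sensor is more than 50 % interpolated are
flagged but retained. Duplicate raw timestamps are averaged with a warning;
decreasing timestamps are an error. Windows are consecutive and
non-overlapping from the recording start (300 samples each at 60 Hz); a
trailing remainder is dropped, and window indices match the annotation
indices by construction. Recordings with an empty four-sensor overlap are
excluded and counted rather than patched.

## Features

The ten feature classes are named but conventionally underspecified, so the
package fixes total, testable definitions (n = 300 samples, guard
ε = 1e−12 in channel units):

- absolute harmonic mean: `n / Σ 1/max(|s_i|, ε)`
- absolute maximum, maximum, median, minimum: order statistics
- geometric mean: `exp(mean(ln max(|s_i|, ε)))`
- root-mean-square, root-sum-of-squares
- Shannon entropy: `−Σ s_i² ln(s_i²)` with `0·ln 0 := 0` — the
  signal-energy entropy, computed on raw (unnormalized) values; the
  histogram-probability alternative was considered and rejected because it
  introduces a binning choice with no principled default
- bandpower: mean one-sided periodogram power of the mean-removed signal
  over (0, Nyquist], computed by FFT; by Parseval this equals the average
  AC power `mean((s − mean s)²)`, which the test suite asserts to 1e−9
  relative on random signals

All classes except entropy are positively homogeneous (degree 1, bandpower
degree 2), a property-tested invariant. Columns are named
`{class}__{signal}` for stable joins. Normalization maps each column
through `(x − min)/(max − min)` with min/max observed on the training
partition only; constant columns map to 0 and out-of-partition values are
clipped into [0, 1]. A globally fitted (leaking) variant of the original
description was rejected; fit-on-train is the default and only mode.

## Selection

Screening scores each candidate feature class alone: its 11-signal feature
vectors are cross-validated (5-fold, same per-fold oversample/normalize
protocol) through each classifier family at default hyperparameters, and
the class passes if the best macro F1 reaches the threshold (default 0.7).

Sequential forward selection is a greedy wrapper with the downstream
family (default hyperparameters) inside. The budget (default 20) caps the
*total number of candidate evaluations*, each being one inner-CV
misclassification estimate; candidates are scanned in column order, the
best evaluated candidate is accepted only if it strictly lowers the
current objective, and ties keep the lower column index — determinism over
elegance. With an unbounded budget this reduces to exhaustive greedy
forward search, which the tests assert against an independent oracle.

## Training protocol

Per dataset, the grid is 6 algorithm families × 4 settings. Within every
outer fold: oversample the training rows to equal class counts (random
duplication with replacement), fit normalization on them, fit the
classifier, and predict the normalized test rows; test predictions are
pooled across folds so every sample is tested exactly once. SFS and
hyperparameter tuning run once on the first fold's training partition and
are reused in later folds (per the reference protocol; statistically
unusual, retained deliberately). Validation F1 is the mean over outer
folds of the inner 5-fold cross-validated macro F1 on the training
partition. Single-class datasets are skipped with a reason. Fold plans:
stratified 5-fold when every class has ≥ 5 members (plain shuffled k-fold
otherwise); leave-two-subjects-out pairs subjects from a seeded shuffle,
requiring an even subject count. Classifiers treat scores as unordered
categories; ordinality enters only through RMSE and the adjacent-error
fraction.

Hyperparameter tuning is sequential model-based optimization: random
initial design, then a Gaussian-process surrogate (Matern 5/2 + white
noise, unit-cube encoding; categorical axes ordinal-encoded) with
expected-improvement acquisition over a 256-point random candidate pool.
Exactly `budget` (default 15) objective evaluations are spent and the best
*observed* configuration is returned. Search spaces: k-NN k ∈ [1,
min(30, n/2)] (log), metric {euclidean, cityblock}, vote {uniform,
distance}; decision tree min leaf ∈ [1, n/4] (log), criterion {gini,
log-loss}; SVM (RBF, one-vs-one) C and kernel scale ∈ [1e−3, 1e3] (log);
naive Bayes density {gaussian, kernel} with kernel-bandwidth scale ∈
[1e−2, 10] (log) — the kernel option is a per-feature Gaussian-KDE naive
Bayes with Silverman bandwidths implemented in `training.py`; discriminant
{linear, quadratic} with regularization γ ∈ [0, 1]; ensemble {bagging
(random forest), AdaBoost} with 10–200 learners (log) and boosting
learning rate ∈ [0.01, 1] (log). If the GP fit degenerates the next point
falls back to a random draw, preserving the evaluation budget.

## Evaluation

Per-class precision/recall are one-vs-rest from the 5×5 confusion matrix
with zero-denominator cases set to 0 (and kept in the aggregate — this
matters for rare extreme scores). The aggregate is the unweighted (macro)
mean over classes present in the true labels; a weighted mode exists and
the mode is recorded in every report. Winners are selected by validation
F1, ties broken toward the simpler setting (ALL < SFS < ALL+HYP <
SFS+HYP) then the family order — never by test score. RMSE treats labels
as integers; the adjacent-error fraction is undefined (None) when there
are no errors. Cohort summaries report unweighted mean ± sample SD across
subjects, excluding skipped subjects.

## Synthetic cohorts

The generator emulates what the analysis assumes, not limb biomechanics:

- per-limb severity follows a first-order Markov chain over windows
  (default: stay probability 0.6, remainder split between neighbouring
  scores, initial state from the stationary law — extremes rarer, as in
  clinical score distributions);
- each acceleration/gyro channel is baseline Gaussian noise (SD 0.05
  channel units) plus two sinusoids with frequencies uniform in 0.5–3 Hz,
  random phases, and amplitude `amplitude_per_score[score] ×
  subject_factor`; defaults (0, 0.5, 1, 2, 4) are spaced so neighbouring
  classes overlap under noise, reproducing the adjacent-error structure;
- orientation is the wrapped integral of angular velocity;
- subject factors are `exp(N(0, heterogeneity_sd))`;
- raters are `round(score + N(0, rater_noise_sd))` clipped to [0, 4]
  (default SD 0.3 ≈ a rater deviating ~10 % of the time, the median
  almost always correct);
- artifacts: i.i.d. timestamp dropout (default 2 %), whole-sensor
  truncation at a uniform point (default 2 % per sensor), and unscorable
  (limb-not-visible) windows (default 2 %);
- all randomness flows from one seed through named substreams per
  (subject, recording, limb, purpose), so outputs are bit-reproducible
  and partial regeneration is stable.

What it does **not** model: realistic kinematics or posture, activity
context (eating, wheelchair driving, …), spectral signatures of real
dystonia beyond a band, rater bias or drift, and choreoathetosis. Passing
recovery tests therefore demonstrates that the pipeline machinery is
correct and leakage-free and that it *can* recover a severity signal of
this simple form — not clinical-grade performance on real patients.

## Problem sizes in the shipped tests

The recovery experiments use 12 subjects × 3 one-minute recordings
(12 windows each, ≈ 70 labelled upper-extremity samples per subject),
rater noise SD 0.3, and a reduced grid (k-NN and decision tree, ALL
setting) — sufficient because only the best model per subject is scored.
Under these conditions individual models reach macro F1 ≥ 0.8 for every
subject; with no heterogeneity the generalized leave-two-subjects-out F1
matches the individual mean within 0.1, while heterogeneity SD 0.8 (same
seed) degrades it by well over 0.1 with ≥ 60 % of errors in neighbouring
scores and pooled RMSE ≤ 1.2 — the qualitative individual-vs-generalized
gap the pipeline is designed to expose.

## Known limitations

- First-fold-only SFS/tuning reuse couples later folds to fold 1's
  partition; a per-fold variant would be cleaner but is not the reference
  protocol.
- The evaluation-budget reading of the SFS stopping rule means large
  feature sets (110 columns, budget 20) only ever scan the first 20
  candidates of round one; this is faithful to the stated budget but makes
  SFS column-order dependent at default settings.
- Kernel-density naive Bayes is O(n_train × n_test × n_features) per
  prediction; fine at cohort scale, slow beyond it.
- The annotation-window alignment assumes index identity from the
  recording start; sub-window clock offsets between video and sensors are
  not modelled or corrected.
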