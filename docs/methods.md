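# Methods

## Overview

`rehabhar` implements the computational core of a smartwatch-based
home-rehabilitation system for upper-limb stroke exercises: a synthetic
generator of labeled wrist-IMU recordings, a sliding-window CNN
recognizer, a cross-validated evaluation harness comparing sensor
subsets and training regimes, an exercise-time tracker, and the study
design arithmetic (drop-out rates, power-analysis sample size).

## Sensor and motion model

Each session is a 6-axis stream — 3-axis accelerometer (m/s²) and
3-axis gyroscope (rad/s) — sampled at a nominal 10 Hz with a
per-sample label from five classes: rest plus four bilateral exercises
(bilateral shoulder flexion, wall push, active scapular exercise,
towel slide).

The generator models each exercise as quasi-periodic rotation of the
forearm about a class-specific unit axis **u**:

    θ(t) = A sin(2π f t)

* **Gyroscope**: analytic angular velocity `θ'(t) u`, expressed in the
  device frame, plus white Gaussian noise.
* **Accelerometer**: specific force — gravity rotated into the device
  frame (convention: a flat, stationary device reads +9.81 m/s² on its
  z channel) — plus a small class-specific linear-acceleration term at
  twice the repetition frequency (repetitions accelerate and
  decelerate twice per cycle) and white Gaussian noise.
* **Rest (NO_EXERCISE)**: the resting orientation with a slow,
  small-amplitude wobble (default 0.05 rad at 0.02 Hz). With the
  wobble and noise at zero, statics are exact: accelerometer norm is
  9.81 at every sample and the gyroscope is identically zero.

Class kinematic defaults (amplitude, tempo) are plausible slow
rehabilitation movements and are fully configurable: flexion 80° at
0.25 Hz, wall push 30° at 0.5 Hz, scapular exercise 40° at 0.4 Hz,
towel slide 60° at 0.33 Hz, each about a distinct axis. Every axis has
a component perpendicular to gravity so orientation change is visible
to both sensors.

### Mounting frame

The motion model lives in the arm frame; the watch is strapped to the
wrist with a fixed per-subject mounting rotation `R_mnt`, so device
signals are

    a_dev = R_mntᵀ R_arm(t)ᵀ g + R_mntᵀ a_lin(t),   ω_dev = R_mntᵀ θ'(t) u.

This matters: a mounting offset rotates *both* the gravity pattern and
the gyroscope axes, which is how strap placement produces genuinely
subject-specific signal signatures.

### Inter-subject variability

A subject profile is drawn once per subject from population
distributions (truncated normals for positive quantities),
deterministically from `(seed, subject_id)`:

| parameter | mean | SD | rationale |
|---|---|---|---|
| amplitude scale | 1.0 | 0.2 | range-of-motion differences |
| tempo (per class) | class default | 15 % | personal pacing |
| rotation-axis tilt | 0 | 10° per axis | idiosyncratic movement plane |
| mounting rotation | 0 | 40° per rotvec axis | the watch body can sit almost anywhere around the wrist circumference |
| accel noise SD | 0.3 m/s² | 0.05 | consumer-watch magnitude |
| gyro noise SD | 0.05 rad/s | 0.01 | consumer-watch magnitude |

The spread — the large mounting variability in particular — is what
makes the pooled-training problem genuinely heterogeneous: different
subjects' exercises can collide in signal space (one subject's wall
push can resemble another's scapular exercise after an arbitrary wrist
rotation), while each subject's own five classes stay well separated.
Personally trained models are therefore never worse, and usually
better, than population-pooled ones on these data — the qualitative
behavior the evaluation module is designed to measure. Smaller
mounting spread (e.g. 15°) removes the pooled-model penalty; the
parameter is exposed on `SimConfig` for sensitivity analysis.

What the generator does **not** emulate: biomechanically faithful
shoulder kinematics, hemiparesis severity, waveform irregularity
within a session (tremor, pauses mid-repetition), magnetometer data,
and non-stationary noise. Passing tests therefore show the pipeline is
correct and that the qualitative regime/sensor orderings emerge under
controlled heterogeneity — not that the specific accuracy numbers
transfer to real patient recordings.

## Windowing

Sessions are segmented into 3 s windows (30 samples at 10 Hz) with a
default stride of 5 samples (0.5 s, 83 % overlap). Window count is
`floor((N − W)/stride) + 1`. A mixed-label window takes the modal
per-sample label; ties resolve toward NO_EXERCISE (conservative: the
tracker never credits ambiguous time as exercise), and a tie between
two exercises takes the lower class index. Sessions shorter than one
window yield an empty list. Timestamps are nominal (index/rate); no
resampling is attempted.

## Recognizer

Two 1-D convolutions along the time axis (kernel length 5, channels as
input depth, 8 then 16 feature maps), each followed by ReLU and
non-overlapping max-pooling of length 2; then a 32-node fully
connected ReLU layer and a softmax head with one node per class.
Kernel and pool lengths give receptive fields of roughly one second at
10 Hz. Inputs are z-scored per channel with training-set statistics
(SD floored at 1e-8 so constant channels map to zero).

Training is mini-batch Adam (step 1e-3, batch 32, 50 epochs) on
cross-entropy, with no early stopping or augmentation. The network and
its backpropagation are implemented directly in numpy; training is
deterministic for a fixed seed (single-threaded execution). Argmax
ties at prediction resolve to the lowest class index.

## Evaluation

Accuracy is counting-based: overall = trace/total of the confusion
matrix (equivalently `(TP + TN)/(TP + TN + FP + FN)` in the binary
case); per-class = diagonal/row-sum. The identity
Σ_c (per-class_c × count_c)/total = overall holds by construction and
is property-tested.

Five-fold cross-validation stratifies by class at the window level by
default. Because adjacent windows overlap by 83 %, window-level folds
share frames between train and test and the resulting accuracies are
optimistic about subject-level generalization; this protocol is kept
as the default deliberately, and a leakage-safe SEGMENT grouping
(whole contiguous label runs stay in one fold, via stratified group
k-fold) is provided for honest estimates. The normalizer is fitted
inside each fold's training data only.

The ablation grid crosses two regimes (PERSONAL: train/test on the
target subject's windows; TOTAL: train on all subjects' windows pooled
*including* the target) with three sensor subsets (accelerometer,
gyroscope, both). A leave-the-user-out variant of TOTAL is available
but is not the default protocol. Display rounding: per-class cells to
1 decimal, totals to 2.

### Benchmark problem sizes

The population benchmark in the test suite uses 10 subjects, each with
a scaled acquisition recording (5 repetitions × 1 session per
exercise, ≈ 240 windows/subject), three seeds, and the default
50-epoch training. These sizes were chosen as the smallest population
at which the regime and sensor orderings are stable across seeds;
the full acquisition protocol (15 repetitions × 2 sessions, 120
attempts) is exercised separately for the protocol arithmetic.

## Exercise-time tracking

Window predictions are smoothed by a centered sliding majority vote
over 5 windows (ties → NO_EXERCISE), then maximal exercise runs
shorter than 2 windows are relabeled as rest (flicker suppression).
Credited time per class is *window count × stride* — not × window
length — so overlapping windows tile time without double counting.
Logs are per calendar day; the patient view covers the last 3 days
(zero-filled), the therapist view the trailing 30 days per subject
(active days, mean min/day over the whole window, per-exercise
totals). How a deployed app converted predictions to displayed minutes
is not recoverable from the system's description; this crediting rule
is declared, not reverse-engineered.

## Study-design arithmetic

Drop-out rate is `100 × dropped/enrolled`, kept at full precision with
a half-away-from-zero integer display rounding.

The sample-size search assumes a paired (one-sample) t test on
pre–post change — the within-group design the effect size d = mean
change / SD of change implies. For candidate n, power is exact from
the noncentral-t distribution (df = n − 1, noncentrality d√n,
two-tailed critical value at α); the smallest n reaching the target
power is inflated for anticipated loss as `ceil(n/(1 − loss))` (the
standard divisor form; the multiplier form `ceil(n(1 + loss))` gives
the same answer at d = 1.869, 10 % loss). With d = 1.869, α = .05,
power .80 the base size is 5 (power .871; .703 at n = 4) and the
inflated size is 6.

## Numerical notes and limitations

* All randomness flows from `numpy.random.SeedSequence` keyed by
  `(seed, sha256(subject_id), stream)`; sessions are bit-reproducible.
* Truncated-normal draws use rejection sampling with a deterministic
  fallback to the clipped mean.
* Softmax is computed with max-subtraction; probabilities sum to 1
  within 1e-6.
* The CNN is small enough (~5k parameters for 6 channels) that CPU
  training is seconds per model; there is no GPU path.
* CSV round-trips rely on pandas' shortest-repr float formatting and
  are bit-exact.
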