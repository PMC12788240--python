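# Methods

This note records the scientific and numerical choices behind the package:
the simulator's world, the signal-processing conventions, the pathology
operators, the classifiers and their training protocol, and what a passing
test does and does not establish.

## The sensing model

A pen-mounted IMU reports specific force in g units (±16 g full scale) and
angular rate in °/s (±2000 °/s) at a fixed 100 Hz. The desk frame has z up
and gravity $(0, 0, -9.8)\ \mathrm{m/s^2}$; the pen body frame is related
to it by intrinsic roll–pitch–yaw rotation $R = R_z(\psi)R_y(\theta)R_x(\phi)$.
The inverse sensor model emits

- accelerometer: $R^\top(\ddot p + g)/9.8$ plus white noise (default
  0.005 g per axis);
- gyroscope: the Euler-angle rates in °/s plus white noise (default
  0.5 °/s per axis). For the small attitude excursions simulated (≤ 0.1 rad)
  Euler rates coincide with body rates to first order; this is a deliberate
  simplification, matched by the orientation estimator.
- magnetometer: a constant Earth-like field rotated into the body frame —
  a placeholder only, parsed and dropped downstream.

A stationary level pen therefore reads $(0, 0, -1)$ g, and the tilt
references used by the orientation estimator are
$\phi = \operatorname{atan2}(-a_y, -a_z)$,
$\theta = \operatorname{atan2}(a_x, \sqrt{a_y^2 + a_z^2})$.

## Task models

No trajectory statistics for healthy writers are available to calibrate
against, so the three tasks use the simplest parametric forms satisfying
their qualitative descriptions, with defaults chosen at plausible
handwriting scales (centimetre strokes, ~1 turn/s spiral sweep, 2 loops/s):

- **spiral**: $r = a + b\theta$ swept at constant $\dot\theta$
  ($a = 2$ mm, $b = 1.5$ mm/rad, $\dot\theta = \pi$ rad/s) — radius is
  non-decreasing by construction;
- **loops**: steady horizontal drift plus sinusoidal vertical oscillation
  (4 mm advance/loop, 8 mm height, 2 Hz);
- **sentence**: a seeded sequence of minimum-jerk strokes
  ($10u^3 - 15u^4 + 6u^5$ profile, 0.25–0.5 s each, rightward drift).

Every recording starts with a 1 s quiescent rest prefix (the gravity
estimator's reference) and ramps the task clock smoothly over 0.5 s
(`onset_ramp`), because an abrupt onset puts a velocity discontinuity at
the boundary that any integration-based feature inherits as a permanent
offset. Closed-form tests disable the ramp.

Per-subject variability: amplitude scale ~ lognormal(0, 0.15), tempo ~
lognormal(0, 0.10), duration ~ N(12 s, 1 s) clipped to [9, 15] s. These are
a priori choices representing ordinary inter-writer variation; they are not
fitted to anything.

## Preprocessing conventions

- **Filter**: 4th-order digital Butterworth at 25 Hz applied
  forward–backward (`filtfilt`), so the amplitude response is $|H|^2$ and
  peaks do not shift. The exact stopband closed form uses the
  bilinear-prewarped ratio $\nu = \tan(\pi f/f_s)/\tan(\pi f_c/f_s)$:
  at 40 Hz, $|H|^2 = 1/(1+\nu^8) \approx 1.24\times10^{-4}$.
- **Gravity**: per-axis mean over the first 0.5 s subtracted, then
  conversion to m/s² (9.8 m/s² per g). Orientation-based removal is not
  implemented; the rest-window estimate is exact for the simulator's world.
- **Normalization**: per recording and per channel, to [0, 1]; constant
  channels map to zero. Applied to the assembled 18 channels (after feature
  derivation), then zero-padding/tail-truncation to $T = 1084$.
- **Velocity drift**: forward-Euler integration of noisy acceleration is a
  random walk, so a moving-mean detrend (2 s window) is subtracted after
  integration. This stands in for the unspecified "gyro-stabilized"
  integration; it is switchable off, and the zero-noise round-trip test
  runs without it. The Euler scheme's rectangle-rule bias bounds the
  reconstruction error by $v_\text{peak}\,\omega\,\Delta t/2$ (~6% at 2 Hz).
- **Derivative schemes**: jerk uses central differences with one-sided
  endpoints; rotational acceleration uses the backward difference
  $(\omega_t - \omega_{t-1})/\Delta t$ literally, with the first sample
  replicated. The asymmetry is intentional and documented.
- **Orientation**: complementary filter, gyro weight 0.98, accelerometer
  tilt weight 0.02; yaw integrates the gyro alone (no magnetometer). For a
  static pose the estimate equals the tilt reference from the first sample.

## Pathology operators

- **Tremor**: additive white Gaussian noise with std relative to the
  channel's amplitude, where amplitude = max − min of that channel.
  Severity is drawn uniformly from [0.01, 0.05] per recording. At the
  recording stage the noise goes to the acceleration channels (jerk does
  not exist yet); at the tensor stage to acceleration + jerk channels.
  Noise is injected before the 25 Hz low-pass in simulator cohorts, so
  roughly half its power survives filtering — the surviving component is
  what the classifiers see.
- **Time-warp**: $K = 8$ interior knots on the index grid, ordinates
  displaced by $\mathcal N(0, (j \cdot T/(K{+}1))^2)$ with jitter $j = 0.2$
  for the impaired class and $j = 0.05$ ("mild") for controls — the paper
  quantifies neither; 0.2 produces clearly audible rhythm distortion while
  remaining repairable to monotonicity, and mild = strong/4. Monotonicity
  is enforced by isotonic projection of the knot ordinates, a PCHIP
  fallback if the cubic spline still overshoots between knots, and a final
  cumulative-maximum repair; endpoints are pinned exactly, so event order
  is preserved for every seed.

## Classifiers

Baselines are scikit-learn pipelines (z-score scaler + estimator) tuned by
exhaustive grid search (LR: C ∈ {0.01, 0.1, 1, 10}; SVM-RBF: C ∈ {0.1, 1,
10} × γ ∈ {scale, auto}; RF: {50, 100} trees × depth {5, 10}; k-NN:
k ∈ {3, 5, 7, 9}) with 3-fold stratified inner CV scored by AUC. Scaler
statistics are learned inside the pipeline, i.e. on training folds only.

The hybrid network (two ReLU conv blocks 64×7 and 128×5 with pool-2 and
batch norm (momentum 0.99, ε 0.001), a concat-merge BiLSTM of 128 units per
direction emitting its final state, dense-128 + dropout 0.5, sigmoid
output) is implemented in NumPy with analytic backprop, verified against
numerical gradients, trained with Adam on binary cross-entropy. Training
conventions:

- float32 throughout; fully deterministic per seed;
- validation losses (when early stopping is enabled) are evaluated with
  batch statistics, because momentum-0.99 running statistics are still near
  their (0, 1) initialization after few optimization steps;
- after training, batch-norm inference statistics are recalibrated with one
  pass over the training data (weights untouched). Without this, inference
  on short runs is skewed by unconverged running buffers.

Defaults: lr 10⁻³, batch 32, ≤100 epochs, patience 10 on a 10% validation
carve-out. The scaled-down benchmark in the acceptance suite uses a
budget-derived protocol instead (lr 2.5·10⁻³, batch 104, 10 epochs, no
carve-out) — chosen for a single-CPU time budget, not tuned on outcomes.

## Evaluation protocol

Real subjects are partitioned by stratified 5-fold CV over unique subject
ids; each fold trains on all synthetic recordings plus the 80% real
training subjects and tests on the held-out 20% real subjects only — never
on synthetic data. Baselines train on the real training subjects only
(matching the published comparison); a flag enables the mixed variant.
Hard labels use threshold 0.5; fold predictions are pooled into one
confusion matrix; mean ROC curves are vertically averaged on a common FPR
grid; the positive class is the impaired group throughout. Precision is
reported as 0 (with a warning) if no positives are predicted.

## What the synthetic world establishes — and what it does not

The simulator reproduces the *structure* of the clinical data (tasks,
rates, ranges, class-conditional pathology) but not its hardness: real
inter-subject variability, sensor artifacts, and disease heterogeneity are
all absent. Two consequences matter when reading test results:

1. Green pipeline/property tests establish correctness of the operators and
   protocol, not clinical performance.
2. In the synthetic world the fixed-severity tremor shifts summary
   statistics almost deterministically, so the classical baselines reach
   AUC ≈ 0.98 — far above their level on real data. The hybrid network
   reaches AUC ≈ 0.99 on held-out synthetic folds when trained to
   convergence (~30 epochs), but within the one-CPU time budget of the test
   suite it trains for 10 epochs and lands near 0.95. The benchmark
   ordering test that expects the hybrid to exceed *every* baseline
   therefore fails in this environment; it is kept, unweakened, as a known
   limitation of the scaled-down world rather than silenced.

## Known limitations

- Euler-rate gyro output and complementary-filter orientation are
  small-angle approximations; large pen rotations are out of scope.
- The sentence task is a stroke-statistics emulation, not orthography.
- Gravity compensation assumes the rest prefix; real data without one
  would need the orientation-based alternative.
- `run_experiment` uses a simulator cohort in the "real" role by default;
  conclusions transfer to actual recordings only qualitatively.
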