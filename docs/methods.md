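# Methods

`dragtraj` analyses goal-directed touchscreen drag trajectories: ordered
(x, y) finger positions sampled at a fixed 20 Hz while a subject drags an
image from the screen centre to one of eight fixed targets. The package
implements the full analysis chain — canonical rotation, kinematic feature
extraction, masked-LSTM classification of ASD-like vs TD-like movement,
equidistant trajectory simplification, and a correlation probe relating
mean acceleration to the classifier's output — together with a synthetic
generator that stands in for clinical recordings, which are not publicly
available.

## Preprocessing

**Canonical rotation.** Each trajectory is rotated clockwise about the
screen origin by the angle of its endpoint, θ = atan2(y, x) mapped into
[0, 360)°, so that every rotated trajectory terminates on the positive
x-axis. This removes target-direction variance and makes drags toward all
eight targets directly comparable. Rotation is an isometry: inter-point
distances, speeds and accelerations are unchanged, which the test suite
asserts at 1e-9 relative tolerance. A trajectory already ending on the
positive x-axis is returned unchanged, array identity included.

**Length filter.** Only trajectories with 20–69 points (inclusive) are
retained; "length" counts sampled points, not segments.

**Standardization and padding.** Features are standardized to zero mean and
unit variance, with statistics fit on the *unpadded* timesteps of the
training portion only (`scaler_scope="train_only"`; a `"global"` option
reproduces the alternative reading of fitting on everything). Sequences are
then zero-padded to a fixed 69 timesteps. Padding happens after
standardization, so the padding value 0 is the post-standardization zero;
the collision of a genuine all-zero standardized timestep with the mask is
measure-zero and accepted. Labels are one-hot: TD = (1, 0), ASD = (0, 1).

## Kinematic features

"Velocity" is implemented as nonnegative speed — the Euclidean distance
between consecutive samples divided by dt = 0.05 s — because the
trajectories are 2-D and the pipeline uses a single velocity channel.
Acceleration is the first difference of the speed series divided by dt and
can be negative. Both series are zero-filled at the first sample, which has
no predecessor. A consequence worth knowing: the signed per-trajectory mean
acceleration telescopes to (terminal speed)/(N·dt) and is therefore always
nonnegative under this convention. The generator's group contrast is
accordingly defined on mean |acceleration|, which does not telescope.

The two-feature model consumes (x, y); the four-feature model
(x, y, speed, acceleration), in that order.

## Classifier

Masking → LSTM(64) → dense(2, softmax), trained with Adam (learning rate
0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-7) on categorical cross-entropy. A
timestep is masked when *all* its features equal the mask value 0; masked
steps carry the recurrent state through unchanged, so predictions are
exactly invariant to the amount of trailing padding (asserted to 1e-6, in
practice bit-exact). The LSTM, backpropagation through time and Adam are
implemented directly on NumPy arrays, vectorized over the batch, with the
input projection for all timesteps batched into a single matrix product.
Correctness is established by a central-difference gradient check (1e-7
absolute) and closed-form oracles for softmax and cross-entropy.

Choices the protocol leaves open, made here and configurable: batch size 32;
no early stopping, dropout or gradient clipping; Glorot-uniform input and
dense kernels, per-gate orthogonal recurrent kernels, forget-gate bias 1;
float32 arithmetic by default (float64 available, used by the gradient
check). All randomness flows from the config seed; identical config + data
reproduce identical runs.

The nominal training length is 240 epochs. The packaged experiments and the
acceptance script run 60 epochs, which on the synthetic task is past the
point where the four-feature model's validation accuracy plateaus; this
keeps a full two-mode, five-seed experiment within a coffee break on one
CPU.

## Evaluation protocol

A 15% group-stratified holdout — exactly floor(0.15·N) trajectories, 110
when N = 738 — is carved out first and never trained on. The remaining
trajectories are dealt into four near-equal stratified folds (157 each when
628 remain). Each fold trains a fresh model on the other three folds, with
the scaler fit on that training portion; the fold's validation accuracy and
per-epoch training loss are recorded. The holdout is scored with the mean
predicted ASD probability of the four fold models — an ensemble that uses
every trained model without privileging one — from which the ROC curve
(scikit-learn threshold sweep), trapezoidal AUC, and sensitivity/specificity
at threshold 0.5 are computed. ASD is the positive class; the 0.5 threshold
is inclusive (p_ASD = 0.5 → ASD).

Splitting is trajectory-wise by default, mirroring the apparent protocol.
With few subjects this leaks subject identity between training and
validation, so a `subject_wise` strategy that keeps each subject's
trajectories in one fold (and whole subjects in the holdout, which then only
approximates the 15% fraction) is provided for honest generalization
estimates.

## Trajectory simplification and the correlation probe

Simplifying a trajectory of N points at retention fraction p keeps
M = round(N·p) points (round-half-up) at the equidistant indices
round(i·(N−1)/(M−1)), i = 0..M−1 — both endpoints always retained, indices
strictly increasing. Outputs with M < 20 are excluded, matching the
pipeline's minimum length. The retention fractions studied are
35–90% in the standard steps {35, 40, 50, 60, 70, 80, 90}%.

Simplified trajectories keep the nominal dt: they traverse the same path in
fewer, larger steps, so their apparent speeds — and, by the telescoping
identity, their mean accelerations — increase as retention drops. The test
suite checks this tendency on smooth positive-acceleration draws (35%
retention beats 90% retention in ≥ 90% of cases; empirically 100%).

The probe scores originals plus all surviving simplifications with a
trained model (features standardized with that model's training scaler,
mean acceleration computed on the raw points) and reports the Pearson
correlation r, its two-sided t-test p-value (n−2 df, via scipy), and n. An
optional `accel_range` filter restricts the probe to a mean-acceleration
window. On synthetic data the probe reproduces the qualitative finding the
probe was designed for: higher-acceleration trajectories receive higher
ASD probabilities (r > 0, p ≪ 0.05).

## Synthetic data generator

Each trajectory is a straight line from the origin to its target, bowed by
a single low-frequency sinusoidal curvature term (amplitude uniform within
±8% of the target distance), traversed with a minimum-jerk speed bell
30τ²(1−τ)². Superimposed on the base profile are:

- **sub-movement bursts** — a Poisson number (mean 2 per trajectory per
  group by default) of positive Gaussian speed bumps at random phases,
  widths 2–6% of movement time;
- **positional jitter** — Gaussian noise (default SD 0.6 screen units) on
  interior points; the first and last points receive norm-clipped jitter
  (radius ≤ 2.5·SD) so every trajectory starts within jitter of the origin
  and ends within 3·SD of its target;
- **per-subject factors** — log-normal speed and noise multipliers
  (σ = 0.08 and 0.10) so subject-wise splitting is meaningful.

Lengths are set by sampling a duration uniformly so that
round(duration × 20 Hz) lies in [20, 69]; no post-hoc truncation. Screen
units are abstract (no pixel↔cm conversion is assumed anywhere).

The single controlled between-group difference is `accel_effect`: the ASD
group's burst amplitudes and interior jitter are amplified by
1 + 0.8·accel_effect, a gain calibrated once by Monte-Carlo so that the
realized Cohen's d of per-trajectory mean |acceleration| approximately
equals `accel_effect` at the default contrast of 2 (realized d ≈ 2.0;
d ≈ 0 when `accel_effect` = 0). Defaults (10 subjects per group × 37
trajectories = 740 samples) mirror the 20-subject, 738-sample scale of the
protocol the package implements.

What the generator does *not* emulate: touch pressure, finger lifts,
distractor avoidance, fatigue or learning across the session, target-
specific strategies, or any clinical kinematics beyond the acceleration
contrast. Passing the recovery tests therefore shows that the pipeline
detects a planted acceleration difference at study scale — not that the
classifier would reach any particular accuracy on real children's data.

## Numerical and degenerate-input choices

- Rotation of a trajectory whose endpoint is the origin is a degenerate
  error; so is a zero-variance feature at scaler fit, fewer than two points
  in a trajectory, and fewer than three (or zero-variance) probe pairs.
- Softmax is max-shifted; cross-entropy clips probabilities at 1e-12; the
  trainer raises a divergence error naming the epoch if the loss goes
  non-finite.
- Round-half-up (floor(x + 0.5)) is used for all simplification rounding,
  chosen over banker's rounding so the rule is monotone in N·p.
- ROC tie handling groups equal scores into a single point; AUC then equals
  the positive–negative pair-ranking statistic with ties counted ½, which
  the tests verify against a brute-force oracle.

## Known limitations

- The two-feature model barely exceeds chance on the synthetic task (the
  planted contrast is kinematic, and standardized x, y carry little of it);
  its published counterpart saw real spatial structure unavailable here.
- Trajectory-wise splitting inflates validation accuracy whenever subjects
  have idiosyncratic kinematics; use `subject_wise` for deployment-style
  estimates.
- The NumPy LSTM is single-threaded and CPU-bound; a full 240-epoch,
  two-mode, five-seed experiment is feasible (~45 min) but the 60-epoch
  default is recommended for iteration.
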