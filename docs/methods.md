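# Methods

This note documents the models, assumptions and numerical choices behind
`vestigait`, in the order the pipeline runs them.

## Synthetic gait cohort

The generator emulates a two-class, single-session gait study: 15
participants with vestibular deficits and 15 age-matched controls, each
performing 7 gait tasks (self-selected, change-of-speed, vertical and
horizontal head turns, eyes closed, fast, slow) × 3 trials while wearing 13
IMUs sampling at 128 Hz. Every trial begins with a 2 s static standing
lead-in and lasts 10 s by default.

It is a *signal-level* simulator, not inverse kinematics. Each placement's
body-frame signal is composed of:

- **Feet** — alternating stance (velocity exactly zero; acceleration
  exactly gravity; angular rate exactly zero, before noise) and swing
  phases. Swing forward velocity is a raised-cosine bump whose integral is
  the drawn stride length; vertical velocity a full sine (zero net lift);
  foot pitch rate a sine bump. Stance occupies 40 % of the stride.
  Accelerations are analytic derivatives, so trapezoidal double integration
  recovers the drawn stride length to discretization error.
- **Other segments** — pitch-dominant sinusoids at stride frequency whose
  integrated pitch range equals the segment's drawn amplitude, with weaker
  roll (quarter-cycle lead, keeping the in-plane gyro covariance diagonal so
  the frontal-axis PCA has a well-defined truth) and yaw components, plus
  gait-band acceleration bobbing. A raised-cosine onset/offset envelope
  (≤ 2.5 s) emulates gait initiation/termination on a short walkway; its
  side effect is deliberate: amplitude-modulation sidebands stay above the
  0.5 Hz high-pass corner, so band-pass filtering does not bias steady-gait
  amplitudes.
- **Head turns** — the two head-turn tasks add a ±1.2 rad/s square wave
  (period ≈ 3 steps) to head pitch or yaw rate; no extra class contrast.

Last, gravity is added, each placement is rotated through a small random
mounting rotation (angle ~ N(0, 0.1 rad)), and white noise
(accelerometer 0.05 m/s², gyroscope 0.01 rad/s) plus a per-trial linear
gyroscope bias drift (rate ~ N(0, 0.002 rad/s per s)) are applied.

**Class contrast.** Controls draw left-arm pitch range from
N(0.49, 0.21²) rad and the vestibular class from N(0.26, 0.11²) rad (right
arm 0.35/0.26, SD 0.14/0.11), with stride length 1.25 vs 1.05 m and stride
time 1.0 vs 1.1 s. The contrast applies at full strength only in the
eyes-closed task; every other task applies 40 % of it (fast/slow tasks
additionally scale cadence ×1.25/×0.75). Per-class variance is split evenly
between a per-participant random effect and trial-to-trial variation, so
trials of one participant are correlated — this is what makes subject-wise
splitting matter — while the trial-level population SD matches the
configured per-class SD. Stride-parameter random effects use half the
between-class gap as their SD. Walking-speed distributions per task are the
package's own choice of plausible values; no published distributions back
them.

Ground truth records per-stride lengths and times, footfall times (stance
midpoints of the maximal stationary intervals), arm pitch ranges, and
mounting rotations, enabling exact recovery tests.

## Preprocessing

- **Gravity axis**: mean static-lead-in acceleration, normalized; rejected
  if its norm is below g/2 (sensor moving). Noise-free this is exact; at
  default noise the error is ≪ 1° (3·σ/(g·√n) with n = 256 samples).
- **Frontal axis**: PCA of the walking-segment angular velocity projected
  onto the plane ⊥ z; ambiguous (error) if the principal-variance ratio is
  < 1.05. The sign of y is fixed so mean ω_y ≥ 0 — an arbitrary but
  deterministic convention applied identically to both classes; signed
  min/max/mean features are convention-dependent, magnitudes are not.
- **Filter**: 4th-order Butterworth band-pass 0.5–25 Hz applied
  forward–backward (`sosfiltfilt`), the standard zero-phase biomechanics
  realization. Filter edge transients decay within ~2 s of the series ends;
  assertions about filter gain are made away from the edges.
- **Angular displacement**: trapezoidal cumulative integration of the
  *filtered* angular rate over the walking segment, starting at 0 — θ is
  therefore implicitly high-pass detrended and bounded.

## ZUPT stride estimation

Stationary samples satisfy `| ‖a‖ − g | < 0.8 m/s²` AND
`‖ω‖ < 0.6 rad/s` on the raw (unfiltered) body-frame signals — the
band-pass would remove gravity and destroy the first criterion. Runs
shorter than 0.08 s are discarded; runs separated by less than the 0.4 s
minimum stride time are merged; each surviving run's midpoint is a footfall
anchor. These four thresholds were tuned on the generator and are exposed
in `StationaryThresholds`.

The correction subtracts gravity, integrates acceleration to velocity, and
removes, per inter-anchor interval, the straight line through the raw
velocities at the two bounding anchors (extrapolated beyond the first/last
anchor). Under the model's assumptions — no foot slip during footfalls, and
accumulated velocity error linear in time between footfalls (equivalently a
constant per-interval acceleration bias) — the drift cancels exactly, and
velocity is pinned to exactly zero at every anchor by construction. A
linear-in-time *acceleration* error would leave a quadratic velocity
residual that this scheme does not cancel; the property suite therefore
tests the constant-bias form.

Stride length is the planar (x–y) displacement between consecutive anchors
(walking is level), stride time the anchor spacing, foot speed the planar
path length over elapsed time between first and last anchors. Degenerate
trials (0–1 anchors) yield an all-zero stride table with a logged warning
rather than aborting cohort assembly.

## Features

Per placement: 5 descriptors × (3 gyro axes + 3 accel axes + ω_total +
a_total) = 40, plus mean/range of θ_y and θ_x = 44; head and trunk add the
95 % confidence-ellipse areas of (ω_pitch, ω_roll) and (θ_y, θ_x):
`EA = π · χ²₂(0.95) · √(λ₁λ₂)` with λ the eigenvalues of the 2×2 sample
covariance (degenerate covariance → area 0); feet add the six stride
summaries. Totals: 8×44 + 3×46 + 2×50 = 590, asserted at catalogue
construction. Descriptor and sway features use the band-passed signals;
stride features use the raw aligned foot signals through the ZUPT path. The
static lead-in is excluded from all feature windows. Any non-finite feature
aborts that trial's extraction with the feature named.

## Classification

Per (placement, task): 50 independent repeated splits, each holding out 3
participants per class (24 train / 6 test); all trials of a participant stay
together. Per repeat, features are z-scored with statistics fit on the
training split only (zero-variance features map to 0), the forest is tuned
by participant-grouped 5-fold CV over a grid spanning
{100, 300, 500} estimators × {√p, 0.1p, 0.3p} max features ×
{∞, 5, 10} depth × {1, 2, 5} min leaf (ties break by grid order; inner folds
that end up single-class are skipped with a warning; a singleton grid skips
the inner CV), and held-out probabilities are predicted. All (label,
probability) pairs are pooled over repeats; the merged AUROC (midrank tie
convention), a 1000-resample percentile-bootstrap 95 % CI, and threshold-0.5
accuracy/F1/sensitivity/specificity/confusion matrix are computed on the
pool. Because participants are redrawn independently each repeat, they recur
across test sets; the pool weights trials by how often they were held out.

## Interpretation

Features are clustered by Ward linkage on the distance 1 − |Pearson r|
(constant features get correlation 0, i.e. distance 1, with a warning), cut
at 3 clusters by default. Cluster importance shuffles all features of a
cluster with one shared row permutation — preserving the intra-cluster
structure the clustering was built to respect — and records the drop in
held-out AUROC over 100 permutations (mean + percentile CI; negative drops
are reported, not clipped). Welch t-tests on the top cluster use the fixed
group order controls − vestibular, Welch–Satterthwaite df, and effect size
`r = √(t² / (t² + df))` — a formula chosen because it reproduces the
published effect sizes from their (t, df) pairs to two decimals; the
summary-statistics entry point (`welch_t_from_summary`) permits recomputing
published tables without raw data.

## Problem sizes and determinism

Default evaluations in the examples, tests and acceptance script use the
full 30-participant cohort and 50 repeats but a singleton forest
configuration (200 trees, √p features) rather than the full tuning grid,
and simulate only the tasks/placements a given analysis consumes; the full
grid path is exercised at small grid sizes. One global seed expands into
per-stage child seeds by fixed offsets; identical configuration (including
seed) reproduces identical cohorts, splits, forests and output files
byte-for-byte.

## What passing tests do and do not show

The generator produces straight, level, strictly periodic walking with
sinusoidal segment kinematics, exact zero-velocity stances, white sensor
noise and linear gyro bias. Real vestibular gait has turn-arounds,
path deviations, variable stance quality, colored noise, soft-tissue
artifacts, and class differences beyond arm swing and cadence. Passing
recovery and classification tests therefore validates the *pipeline
machinery* — alignment, drift correction, feature definitions, leakage-free
evaluation, importance attribution — under conditions where truth is known;
they do not certify clinical performance on real recordings. The
classification numbers on synthetic cohorts are structural surrogates
(ordering and magnitude class), not reproductions of real-data results.

## Known limitations

- Footfall instants are stance-run midpoints; other conventions (heel
  strike) would shift stride times by a constant offset.
- The frontal-axis sign convention can flip y between trials when mean ω_y
  is near zero, flipping signed min/max/mean features; range/RMS/magnitude
  features are immune.
- Stride length uses planar displacement, appropriate for level walking
  only.
- The 0.5 Hz high-pass distorts amplitudes of gait slower than ~0.6 Hz
  stride frequency (pathologically slow gait would need a lower corner).
- Magnetometers, turn detection, and multi-class disease differentiation
  are out of scope.
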