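# Methods

This note documents the models, conventions, and numerical choices behind
swingtrack, and what the synthetic benchmark does and does not demonstrate.

## Frames and conventions

Quaternions are Hamilton, scalar-first (w, x, y, z), right-handed; `q`
denotes q_S^U, the rotation taking sensor-frame vectors into the
ground-fixed user frame (X–Y–Z, Z up, Y roughly the swing progression
direction). The canonical representative of the {q, −q} double cover has
w ≥ 0 ("northern hemisphere"); all stored labels and returned estimates are
canonical. The accelerometer measures **specific force**: a resting sensor
reads +1 g along the sensor axis pointing up, so the user-frame acceleration
is a_user = R(q) a_sensor + g_vec with g_vec = (0, 0, −9.80665) m/s². This
gravity handling is used identically by the simulator and the tracker; it is
the single most consequential convention in the pipeline.

## Strapdown integration

Orientation is propagated by the first-order update
q(t+1) = q(t) + ½ (q(t) ⊗ [0, ω(t)]) Δt. The update is not norm-preserving,
so each step is renormalized; to first order in Δt this leaves the update
unchanged while keeping the unit-norm invariant exact. Higher-order
(Runge–Kutta) integration is deliberately out of scope.

## Anchor velocity correction

Velocity is the cumulative trapezoidal integral of a_user from t_ADD.
Drift is removed per axis with linear-in-time ramps: on (ADD, BST] the BST
residual is ramped out; on (BST, FIN] the BST offset is subtracted and the
*remaining* FIN residual (measured after that offset removal) is ramped out.
This composition makes v_Vcal exactly zero at all three anchors, which is
the stated constraint of the method; the alternative literal composition in
which the FIN ramp uses the raw FIN velocity (leaving a residual at FIN) is
available as the `eq5_literal` config flag. Velocity is integrated
continuously through BST; no restart occurs at the anchors.

## Virtual circle and endpoint constraint

The swing plane normal is the right singular vector with the smallest
singular value of the centered backswing trajectory ([t_ADD, t_BST] of
Traj_Vcal); the sign is fixed to a nonnegative Z component (nonnegative X on
a tie) purely for reproducibility. The circle is the algebraic (Kåsa)
least-squares fit of the same backswing points projected onto the plane
through their centroid — the backswing segment is used for both fits
because it carries the least accumulated drift; a Gauss–Newton geometric
refinement is available behind `circle_refine` but is not the default. The
finish displacement is decomposed into an out-of-plane offset d_FIN and an
in-plane projection r_cal, and snapped to the nearest circle point
ep = c_circ + r_circ (r_cal − c_circ)/‖r_cal − c_circ‖.

## Bias estimation

The endpoint of the re-integrated trajectory is linear in a constant
sensor-frame bias b: it enters as the double trapezoidal integral of
R(q(t)) b. We therefore solve the 3×3 system M b = Traj(t_FIN) − ep, where
column j of M is the double integral of R(q(t)) e_j under the same
quadrature, with a least-squares fallback when cond(M) > 1e8. For constant
orientation this reduces to the closed form b = 2·offset/T². A printed
per-sample form of this step (offset divided by Δt²) is dimensionally
inconsistent with a constant-bias double integral; the linear solve
implements the evident intent and makes the endpoint land on the circle to
machine precision. Note that b is an *endpoint-equivalent* bias: the anchor
velocity correction has already absorbed the secular component of any true
sensor bias, so b is expected to be much smaller than the physically
injected bias — what is guaranteed is the endpoint constraint and the
trajectory improvement, not recovery of the injected vector.

## Address-orientation CNN

Input: a 6×1000 matrix (3 standardized accelerometer rows, then 3 gyro
rows) left-aligned at t_ADD − 100 ms and zero-padded on the right (1000
columns = 5 s at 200 Hz; windows longer than that are truncated).
Standardization uses per-channel mean/SD pooled over the *training*
population only. The default window ends at t_BST; `pre_add_only`,
`to_imp`, `to_fin` windows support the input-range ablation. Architecture:
two 1-D convolutions (8 and 16 channels, kernel 9), max-pooling (width 8),
a fully connected layer to 4 outputs renormalized to a unit
quaternion, tanh after each convolution and the pooling stage; loss is
1 − |q_true · q_est| (so label canonicalization is for reproducibility, not
correctness). Training: Adam (lr 1e-3), batch 16, a random 90/10
swing-level train/validation split, validation-based early stopping
(patience 20, best weights kept), at most 400 epochs. Kernel, channel,
pool sizes and the learning rate are tunable defaults, not fixed properties
of the method. The networks are implemented directly in numpy with manual
backpropagation; training is fully seeded and bit-reproducible on a given
platform.

Because absolute yaw about gravity is observable only through the
population's shared swing direction, training uses **virtual-mount
augmentation**: extra copies of each swing with the 3-axis signals rotated
by a random small sensor-frame rotation and the label composed with the
same rotation. This is an exact physical symmetry of the problem and
substantially improves generalization to unseen sensor mounts (3 copies,
≤12°, by default).

## Swing-phase segmenter

A bidirectional tanh recurrent network (hidden size 16) labels every 4th
sample (50 Hz) with one of five phases: pre-ADD, backswing, downswing,
follow-through, post-FIN; boundaries of the best monotone phase path
(dynamic programming over the per-sample log-probabilities) give the four
events, so the ordering invariant holds for *any* network output. Training
uses cross-entropy, Adam, random head-crop augmentation (up to 0.4 s) so
absolute sample position carries no information, and validation-based early
stopping. A recording whose peak gyro magnitude is below 0.5 rad/s is
rejected as containing no swing. The impact event of a wrist-only system is
a surrogate: with no ball position observable, IMP is defined at the wrist
speed maximum, and training labels derive from the simulator's ground-truth
events.

## Synthetic swing generator

The generator constructs a wrist path on a tilted circle (default radius
1.1 m, plane normal tilted 0.6 rad from vertical) with a phase angle θ(t)
that is minimum-jerk over the backswing and an asymmetric beta-shaped speed
bump over downswing + follow-through, peaking near impact. Zero wrist
speed at ADD, BST and FIN holds by construction. The downswing sweep and
the forearm-roll span are calibrated by a short fixed-point iteration so
the ideal signals hit the configured peaks (defaults 111 m/s² and
1627 °/s — the documented population means), which with the default
durations (0.25 s hold, 0.80 s backswing, 1.10 s downswing + follow-through,
≈2.15 s active swing) yields a ~4.4 m path. A smooth out-of-plane bump
(default ≤0.15 m) vanishes through the backswing and peaks in the
follow-through, mirroring the observed per-phase planarity of real swings;
a small post-finish recoil (0.05 rad) gives the speed profile a genuine
local minimum at FIN. Orientation is a path-following frame composed with
a smooth forearm-roll profile and a configurable sensor mount.

Ground truth is **discrete-time consistent**: gyro samples are the exact
per-step incremental rotation rates (within 0.2 % of the instantaneous
angular velocity — far below real scale-factor tolerances), and the
ground-truth velocity/trajectory are the trapezoidal integrals of the ideal
acceleration after a tiny smooth consistency correction (two sine bumps per
segment, ~1e-2 m/s²) that zeroes the integrated velocity at the anchors
exactly. Noiseless round trips are therefore exact to machine precision,
and quadrature error never masquerades as algorithmic error in tests.

Populations draw one base spec per subject (plane angles, mount, radius,
durations, peak scaling) and smaller within-subject jitter per swing, plus
per-swing sensor biases (|b_accel| ≈ 0.3 ± 0.1 m/s², |b_gyro| ≈ 0.006 ±
0.002 rad/s — typical consumer-MEMS turn-on biases) and white noise
(0.15 m/s², 0.01 rad/s). The between-subject orientation spread is sized so
the leave-one-out mean-quaternion baseline lands near the ~12° regime
reported for real golfer populations.

What the simulator does **not** emulate: club dynamics and true impact
shock content above 20 Hz, soft-tissue artefacts, magnetic disturbances,
timestamp jitter, and golfer-specific swing-shape idiosyncrasies beyond
smooth parameter jitter. Passing benchmarks on this data shows the
algorithmic chain is correct and effective under the documented kinematic
regime; it does not certify error magnitudes on real recordings.

## Preprocessing

Butterworth low-pass at 20 Hz. The 10th-order magnitude response is
realized zero-phase (5th-order kernel forward–backward) by default because
phase lag would bias event timing; a causal single-pass mode is a config
switch. Clipping is detected at ≥99.9 % of full scale (saturated ADCs sit
at full scale; the tolerance catches them robustly) and repaired by a cubic
spline through the ten samples on each side of the run, falling back to a
one-sided spline with a warning at recording boundaries.

## Benchmark problem sizes

The shipped benchmarks use laptop-scale sizes chosen as defaults: 20 swings
for the drift-correction batch, 6 subjects × 10 swings for the leave-one-out
orientation study (5 × 6 in the reporting script), 5 subjects × 4 swings for
segmentation, and 3 bias levels for the monotonicity sweep. All randomness
flows through explicit seeds; generation and tracking are bit-reproducible,
and training is deterministic given the seed on a fixed platform.

## Known limitations

- The correction anchors nothing near impact, where the largest velocities
  occur; errors around IMP are reduced only indirectly (this is the method's
  own stated limitation and its main avenue for improvement).
- The virtual-circle fit uses only the backswing arc (~70–80° of the
  circle); with heavy drift the fitted radius is biased low, which the
  endpoint projection partly forgives but does not eliminate.
- The CNN estimates yaw only relative to the population's shared swing
  direction; a golfer whose aim differs systematically from the training
  population will show a corresponding yaw error.
- Orientation-symmetry-based corrections and club-head trajectory
  estimation are out of scope.
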