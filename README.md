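# swingtrack

Reconstruction of the 3D wrist trajectory of a golf swing from a **single
wrist-worn IMU** (3-axis accelerometer ±16 g, 3-axis gyroscope ±2000 dps,
200 Hz). The package is aimed at wearable-sensing and sports-biomechanics
work where camera systems or multi-sensor suits are impractical: everything
is estimated from the one inertial stream a smartwatch-class device
provides.

## The problem and the method

Dead-reckoning a fast, non-periodic motion like a golf swing from one IMU
fails for two reasons: the sensor-to-ground orientation at the start of the
swing is unknown (no calibration pose is available mid-round), and double
integration of noisy, biased acceleration drifts by tens of centimetres over
the ~2 s swing. swingtrack addresses both with the swing's own kinematics:

1. **Swing-event segmentation.** The four events — address (ADD), backswing
   top (BST), impact (IMP), finish (FIN) — are found either from a wrist
   speed profile or by a bidirectional recurrent network that labels every
   sample with one of five swing phases; an order-constrained decoder
   guarantees `t_ADD < t_BST < t_IMP < t_FIN`.

2. **Address orientation from the signal itself.** A small CNN
   (two convolutions, max-pooling, a fully connected layer, tanh
   activations) maps a standardized 6×1000 window of IMU samples spanning
   [t_ADD − 100 ms, t_BST] to the unit quaternion q_S^U at the address,
   trained with the quaternion-distance loss

   φ(q_true, q_est) = 1 − |q_true · q_est|.

   The statistical baseline is the leave-one-subject-out average address
   quaternion. Orientation over the swing follows by strapdown integration,

   q(t+1) = q(t) + ½ (q(t) ⊗ ω(t)) Δt,

   renormalized each step.

3. **Drift removal by kinematic constraints.** The wrist is (nearly) at
   rest at ADD, BST and FIN, so the integrated velocity v_ori is corrected
   per axis by piecewise-linear-in-time ramps that zero it exactly at the
   three anchors (v_Vcal). The wrist path closely follows a circle on the
   3D swing plane: the plane normal is the smallest-singular-vector of the
   backswing trajectory, the **virtual circle** (center c_circ, radius
   r_circ) is an algebraic least-squares fit of the projected points, and
   the finish displacement is snapped to its nearest point `ep` on the
   circle. The constant sensor-frame acceleration bias that moves the
   re-integrated endpoint onto `ep` is obtained by an exact 3×3 linear
   solve, and the corrected trajectory Traj_Tcal is the double integral of
   the bias-corrected acceleration.

Because the recorded study data this method was developed against are not
public, the package ships a first-class **synthetic swing simulator** that
reproduces the documented kinematic regime (~111 m/s² and ~1627 °/s peaks,
~2.15 s active swing, ~4.4 m path length on a ~1.1 m-radius tilted circle,
zero wrist speed at the anchors, sensor noise, per-swing biases, optional
full-scale clipping) with exact ground truth for every stage.

## Worked example

```python
import numpy as np
from swingtrack import (SyntheticSwingSpec, generate_swing, lowpass_filter,
                        track_swing, mae, percent_error_reduction)

rec, gt = generate_swing(SyntheticSwingSpec(seed=3))     # noisy, biased IMU
track = track_swing(lowpass_filter(rec), gt.events, gt.address_quaternion())

sl = slice(gt.events.t_ADD, gt.events.t_FIN + 1)
ref = gt.trajectory[sl] - gt.trajectory[gt.events.t_ADD]
before = mae(track.traj_ori, ref)    # simple double integration
after = mae(track.traj_tcal, ref)    # proposed correction
print(f"uncorrected MAE {before:.3f} m, corrected {after:.3f} m, "
      f"reduction {percent_error_reduction(before, after):.1f} %")
print("bias estimate (sensor frame):", np.round(track.a_bias, 3))
```

Output:

```
uncorrected MAE 0.226 m, corrected 0.028 m, reduction 87.7 %
bias estimate (sensor frame): [-0.185  0.199  0.55 ]
```

The uncorrected ("IMU only") trajectory drifts to a ~0.23 m mean 3D error;
the anchor-velocity and virtual-circle corrections cut it by ~88 % on this
clean synthetic swing. The corrected endpoint lies on the fitted circle to
machine precision and the corrected velocity is exactly zero at the three
anchors.

A command-line interface mirrors the library:

```bash
swingtrack simulate --seed 7 --out demo/          # IMU + ground-truth CSVs
swingtrack track demo/swing_imu.csv --events ... # trajectory CSV + metrics
swingtrack train-orient / train-segment          # model checkpoints
swingtrack evaluate --subjects 5 --swings 4      # leave-one-out benchmark
```

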