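"""Drift removal for the double-integrated wrist trajectory.

Two kinematic constraints of the golf swing drive the correction:

1. The wrist is (nearly) at rest at the address, the backswing top, and the
   finish, so any nonzero integrated velocity at those anchors is drift and
   is removed by a per-axis, piecewise-linear-in-time correction.
2. The wrist path closely follows a circle on the 3D swing plane, so the
   finish displacement is snapped onto a least-squares "virtual circle" by
   solving for the constant sensor-frame acceleration bias whose removal
   lands the re-integrated endpoint exactly on the circle.

Quadrature is cumulative-trapezoidal throughout, so the bias solve (which is
linear in the bias under the same quadrature) places the corrected endpoint
on the circle to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .preprocess import G, ImuRecording
from .rotations import OrientationSeries, integrate_gyro, quat_to_matrix
from .segment import SwingEvents

GRAVITY_VEC = np.array([0.0, 0.0, -G])  # user frame, Z up

__all__ = [
    "SwingPlane",
    "SwingTrack",
    "DriftConfig",
    "DegenerateGeometryError",
    "acceleration_to_user_frame",
    "integrate_velocity",
    "correct_velocity",
    "integrate_trajectory",
    "fit_swing_plane",
    "fit_virtual_circle",
    "project_endpoint",
    "estimate_sensor_bias",
    "apply_bias_and_reintegrate",
    "track_swing",
]


class DegenerateGeometryError(RuntimeError):
    """Point cloud too degenerate for a plane/circle fit or projection."""


@dataclass
class SwingPlane:
    """Unit normal, circle center (in-plane) and radius of the virtual circle."""

    v_n: np.ndarray
    c_circ: np.ndarray
    r_circ: float

    def __post_init__(self) -> None:
        self.v_n = np.asarray(self.v_n, dtype=float).reshape(3)
        self.c_circ = np.asarray(self.c_circ, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.v_n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        if self.r_circ <= 0:
            raise ValueError("circle radius must be positive")


@dataclass
class DriftConfig:
    eq5_literal: bool = False      # literal follow-through ramp (see correct_velocity)
    circle_refine: bool = False    # Gauss-Newton geometric circle refinement


@dataclass
class SwingTrack:
    """All kinematic series of one tracked swing, indexed from t_ADD.

    Velocity/trajectory series are user-frame X-Y-Z; ``a_vcal``/``a_tcal``
    are sensor-frame x-y-z; ``traj_ori`` is the uncorrected ("IMU only")
    double integration kept for comparison.
    """

    events: SwingEvents
    orientation: OrientationSeries
    a_user: np.ndarray
    v_ori: np.ndarray
    v_vcal: np.ndarray
    traj_ori: np.ndarray
    traj_vcal: np.ndarray
    traj_tcal: np.ndarray
    a_vcal: np.ndarray
    a_tcal: np.ndarray
    a_bias: np.ndarray
    d_fin: np.ndarray
    r_cal: np.ndarray
    ep: np.ndarray
    plane: SwingPlane

    @property
    def window(self) -> tuple[int, int, int]:
        """(ADD, BST, FIN) as indices into the window-local series."""
        e = self.events
        return (0, e.t_BST - e.t_ADD, e.t_FIN - e.t_ADD)


def acceleration_to_user_frame(
    accel: np.ndarray | ImuRecording, orient: OrientationSeries
) -> np.ndarray:
    """Rotate sensor-frame specific force into the user frame and remove
    gravity: a_user(t) = R(q(t)) a_sensor(t) + g_vec."""
    if isinstance(accel, ImuRecording):
        accel = accel.accel
    accel = np.asarray(accel, dtype=float)
    if accel.shape[0] != len(orient):
        raise ValueError("acceleration and orientation series length mismatch")
    rot = orient.matrices()
    return np.einsum("nij,nj->ni", rot, accel) + GRAVITY_VEC


def _window_indices(events: SwingEvents) -> tuple[int, int]:
    return events.t_BST - events.t_ADD, events.t_FIN - events.t_ADD


def integrate_velocity(a_user: np.ndarray, events: SwingEvents, dt: float) -> np.ndarray:
    """Cumulative trapezoidal integral of a_user over [t_ADD, t_FIN].

    ``a_user`` may cover the full recording (absolute event indices) or
    exactly the window; the returned series is indexed from t_ADD and starts
    at zero velocity.
    """
    a_user = np.asarray(a_user, dtype=float)
    _, fin = _window_indices(events)
    if a_user.shape[0] == fin + 1:
        window = a_user
    else:
        window = a_user[events.t_ADD : events.t_FIN + 1]
        if window.shape[0] != fin + 1:
            raise ValueError("acceleration series does not cover [t_ADD, t_FIN]")
    return cumulative_trapezoid(window, dx=dt, axis=0, initial=0.0)


def correct_velocity(
    v_ori: np.ndarray,
    events: SwingEvents,
    dt: float,
    eq5_literal: bool = False,
) -> np.ndarray:
    """Zero the velocity drift at the three rest anchors (ADD, BST, FIN).

    On (ADD, BST] a linear-in-time ramp removes the BST residual; on
    (BST, FIN] the BST offset plus a ramp in the remaining FIN residual is
    removed, so v_Vcal is exactly zero at all three anchors.  With
    ``eq5_literal`` the follow-through ramp uses the raw (not BST-offset-
    removed) FIN velocity, which leaves a residual at FIN.
    """
    v_ori = np.asarray(v_ori, dtype=float)
    bst, fin = _window_indices(events)
    if bst <= 0 or fin <= bst:
        raise ValueError("degenerate event spacing")
    if v_ori.shape[0] != fin + 1:
        raise ValueError("v_ori must cover [t_ADD, t_FIN]")
    if np.linalg.norm(v_ori[0]) > 1e-9:
        raise ValueError("v_ori must start at zero velocity")
    k = np.arange(fin + 1)[:, None].astype(float)
    out = v_ori.copy()
    ramp_bs = np.clip(k / bst, 0.0, 1.0)
    out -= v_ori[bst] * ramp_bs
    fin_residual = v_ori[fin] if eq5_literal else v_ori[fin] - v_ori[bst]
    ramp_ft = np.clip((k - bst) / (fin - bst), 0.0, 1.0)
    out -= fin_residual * ramp_ft
    return out


def integrate_trajectory(v: np.ndarray, events: SwingEvents, dt: float) -> np.ndarray:
    """Cumulative trapezoidal integral of a window velocity series."""
    v = np.asarray(v, dtype=float)
    _, fin = _window_indices(events)
    if v.shape[0] != fin + 1:
        raise ValueError("velocity series does not cover [t_ADD, t_FIN]")
    return cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)


def fit_swing_plane(points: np.ndarray) -> np.ndarray:
    """Total-least-squares plane normal of a 3D point cloud (SVD).

    Returns the right singular vector of the centered cloud with the smallest
    singular value, sign-fixed to a nonnegative Z component (nonnegative X on
    a tie) so downstream quantities are reproducible.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a plane fit")
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-6:
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    v_n = vt[-1]
    if v_n[2] < 0 or (v_n[2] == 0 and v_n[0] < 0):
        v_n = -v_n
    return v_n / np.linalg.norm(v_n)


def _plane_basis(v_n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(v_n @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(v_n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v_n, e1)
    return e1, e2


def fit_virtual_circle(
    points: np.ndarray, v_n: np.ndarray, refine: bool = False
) -> SwingPlane:
    """Least-squares circle of the points projected onto the swing plane.

    The plane passes through the centroid with normal ``v_n``; the circle is
    the algebraic (Kasa) least-squares fit in 2D plane coordinates, optionally
    refined by Gauss-Newton on the geometric distance.  The 3D center is in
    the plane by construction.
    """
    points = np.asarray(points, dtype=float)
    v_n = np.asarray(v_n, dtype=float).reshape(3)
    v_n = v_n / np.linalg.norm(v_n)
    if points.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a circle fit")
    centroid = points.mean(axis=0)
    e1, e2 = _plane_basis(v_n)
    rel = points - centroid
    u = rel @ e1
    v = rel @ e2
    spread = np.linalg.svd(np.stack([u, v], axis=1) - [u.mean(), v.mean()],
                           compute_uv=False)
    if spread[0] <= 0 or spread[1] / spread[0] < 1e-6:
        raise DegenerateGeometryError("projected points are collinear")
    a_mat = np.stack([2 * u, 2 * v, np.ones_like(u)], axis=1)
    rhs = u * u + v * v
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    cu, cv, c0 = sol
    r = float(np.sqrt(max(c0 + cu * cu + cv * cv, 0.0)))
    if refine:
        from scipy.optimize import least_squares

        def resid(p):
            return np.hypot(u - p[0], v - p[1]) - p[2]

        fit = least_squares(resid, x0=[cu, cv, r], method="lm")
        cu, cv, r = fit.x
        r = float(abs(r))
    if r <= 0:
        raise DegenerateGeometryError("degenerate circle radius")
    center = centroid + cu * e1 + cv * e2
    return SwingPlane(v_n, center, r)


def project_endpoint(
    traj_fin: np.ndarray, plane: SwingPlane
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Snap the finish displacement onto the virtual circle.

    Returns ``(d_FIN, r_cal, ep)``: the out-of-plane offset, the in-plane
    projection, and the nearest point on the circle, which satisfies the
    on-circle and in-plane constraints exactly.
    """
    traj_fin = np.asarray(traj_fin, dtype=float).reshape(3)
    d_fin = ((traj_fin - plane.c_circ) @ plane.v_n) * plane.v_n
    r_cal = traj_fin - d_fin
    radial = r_cal - plane.c_circ
    norm = np.linalg.norm(radial)
    if norm < 1e-12:
        raise DegenerateGeometryError("projected endpoint coincides with circle center")
    ep = plane.c_circ + plane.r_circ * radial / norm
    return d_fin, r_cal, ep


def _double_integral(series: np.ndarray, dt: float) -> np.ndarray:
    once = cumulative_trapezoid(series, dx=dt, axis=0, initial=0.0)
    return cumulative_trapezoid(once, dx=dt, axis=0, initial=0.0)


def _sensor_accel_from_velocity(
    v: np.ndarray, orient: OrientationSeries, dt: float
) -> np.ndarray:
    rot = orient.matrices()
    a_user = np.gradient(v, dt, axis=0)
    return np.einsum("nji,nj->ni", rot, a_user)  # R^T a_user


def estimate_sensor_bias(
    v_vcal: np.ndarray,
    orient: OrientationSeries,
    dt: float,
    ep: np.ndarray,
) -> np.ndarray:
    """Constant sensor-frame acceleration bias that lands the endpoint on ep.

    The re-integrated endpoint is linear in the bias b (it enters as the
    double integral of R(q(t)) b), so b solves the 3x3 system
    M b = Traj(t_FIN) - ep, with M's columns the double-integrated rotated
    unit biases under the same trapezoidal quadrature.  Falls back to least
    squares when M is ill-conditioned.
    """
    rot = orient.matrices()
    a_vcal = _sensor_accel_from_velocity(v_vcal, orient, dt)
    a_user = np.einsum("nij,nj->ni", rot, a_vcal)
    endpoint = _double_integral(a_user, dt)[-1]
    m = np.empty((3, 3))
    for j in range(3):
        m[:, j] = _double_integral(rot[:, :, j], dt)[-1]
    offset = endpoint - np.asarray(ep, dtype=float)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond):
        raise DegenerateGeometryError("singular bias system")
    if cond > 1e8:
        bias, *_ = np.linalg.lstsq(m, offset, rcond=None)
    else:
        bias = np.linalg.solve(m, offset)
    return bias


def apply_bias_and_reintegrate(
    v_vcal: np.ndarray,
    orient: OrientationSeries,
    dt: float,
    a_bias: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the sensor-frame bias and double-integrate the corrected
    acceleration; returns (a_Tcal sensor frame, Traj_Tcal user frame)."""
    rot = orient.matrices()
    a_vcal = _sensor_accel_from_velocity(v_vcal, orient, dt)
    a_tcal = a_vcal - np.asarray(a_bias, dtype=float)
    a_user = np.einsum("nij,nj->ni", rot, a_tcal)
    traj_tcal = _double_integral(a_user, dt)
    return a_tcal, traj_tcal


def track_swing(
    rec: ImuRecording,
    events: SwingEvents,
    q_add: np.ndarray,
    config: DriftConfig | None = None,
) -> SwingTrack:
    """Full pipeline on one preprocessed recording: orientation propagation,
    frame transform, anchor-velocity correction, virtual-circle endpoint
    constraint, bias removal, re-integration."""
    cfg = config or DriftConfig()
    events.validate_against(len(rec))
    bst, fin = _window_indices(events)
    dt = rec.dt
    gyro_window = rec.gyro[events.t_ADD : events.t_FIN + 1]
    orient = integrate_gyro(q_add, gyro_window, dt, t0=rec.timestamps[events.t_ADD])
    a_user = acceleration_to_user_frame(
        rec.accel[events.t_ADD : events.t_FIN + 1], orient
    )
    v_ori = integrate_velocity(a_user, events, dt)
    traj_ori = integrate_trajectory(v_ori, events, dt)
    v_vcal = correct_velocity(v_ori, events, dt, eq5_literal=cfg.eq5_literal)
    traj_vcal = integrate_trajectory(v_vcal, events, dt)
    backswing_pts = traj_vcal[: bst + 1]
    v_n = fit_swing_plane(backswing_pts)
    plane = fit_virtual_circle(backswing_pts, v_n, refine=cfg.circle_refine)
    d_fin, r_cal, ep = project_endpoint(traj_vcal[-1], plane)
    a_bias = estimate_sensor_bias(v_vcal, orient, dt, ep)
    a_tcal, traj_tcal = apply_bias_and_reintegrate(v_vcal, orient, dt, a_bias)
    a_vcal = _sensor_accel_from_velocity(v_vcal, orient, dt)
    return SwingTrack(
        events=events,
        orientation=orient,
        a_user=a_user,
        v_ori=v_ori,
        v_vcal=v_vcal,
        traj_ori=traj_ori,
        traj_vcal=traj_vcal,
        traj_tcal=traj_tcal,
        a_vcal=a_vcal,
        a_tcal=a_tcal,
        a_bias=a_bias,
        d_fin=d_fin,
        r_cal=r_cal,
        ep=ep,
        plane=plane,
    )
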