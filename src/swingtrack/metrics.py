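"""Evaluation metrics: per-axis / 3D-vector MAE, circle-fit R^2, relative
anchor speeds, and error-reduction percentages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drift import SwingPlane
from .segment import SwingEvents

__all__ = [
    "TrackError",
    "mae",
    "track_error",
    "circle_r_squared",
    "relative_anchor_speed",
    "percent_error_reduction",
]


@dataclass
class TrackError:
    """MAE summary of one estimated series against a reference."""

    mae_per_axis: np.ndarray        # (3,)
    mae_vector: float
    per_phase: dict[str, float]     # vector MAE per swing phase
    r2: float | None = None


def mae(
    series_est: np.ndarray, series_ref: np.ndarray, mode: str = "vector"
) -> np.ndarray | float:
    """Mean absolute error: per component (``per-axis``) or the mean
    Euclidean norm of the 3D error vector (``vector``)."""
    est = np.asarray(series_est, dtype=float)
    ref = np.asarray(series_ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("series length/shape mismatch")
    delta = est - ref
    if mode == "per-axis":
        return np.mean(np.abs(delta), axis=0)
    if mode == "vector":
        return float(np.mean(np.linalg.norm(delta, axis=-1)))
    raise ValueError(f"unknown MAE mode {mode!r}")


def track_error(
    series_est: np.ndarray,
    series_ref: np.ndarray,
    events: SwingEvents | None = None,
    window_offset: int = 0,
) -> TrackError:
    """Full MAE breakdown; the phase split (backswing / downswing /
    follow-through) uses the event indices minus ``window_offset`` (pass
    t_ADD when the series are indexed from the address)."""
    per_axis = mae(series_est, series_ref, mode="per-axis")
    vector = mae(series_est, series_ref, mode="vector")
    phases: dict[str, float] = {}
    if events is not None:
        add = events.t_ADD - window_offset
        bst = events.t_BST - window_offset
        imp = events.t_IMP - window_offset
        fin = events.t_FIN - window_offset
        for name, (a, b) in {
            "backswing": (add, bst),
            "downswing": (bst, imp),
            "follow_through": (imp, fin),
        }.items():
            phases[name] = mae(series_est[a : b + 1], series_ref[a : b + 1])
    return TrackError(np.asarray(per_axis), float(vector), phases)


def circle_r_squared(traj: np.ndarray, plane: SwingPlane) -> float:
    """Goodness of the virtual-circle approximation: 1 - SS_res/SS_tot with
    residuals the 3D distances from each point to its nearest point on the
    circle and SS_tot the squared distances from the centroid.  May be
    negative for trajectories unrelated to the circle."""
    traj = np.asarray(traj, dtype=float)
    if traj.shape[0] < 3:
        raise ValueError("need at least 3 points")
    rel = traj - plane.c_circ
    out = rel @ plane.v_n
    in_plane = rel - out[:, None] * plane.v_n
    radial = np.linalg.norm(in_plane, axis=1)
    res_sq = (radial - plane.r_circ) ** 2 + out**2
    centroid = traj.mean(axis=0)
    tot_sq = np.sum((traj - centroid) ** 2, axis=1)
    ss_tot = float(tot_sq.sum())
    if ss_tot <= 0:
        raise ValueError("zero total variance")
    return 1.0 - float(res_sq.sum()) / ss_tot


def relative_anchor_speed(
    v: np.ndarray, events: SwingEvents, window_offset: int = 0
) -> tuple[float, float, float]:
    """Speeds at ADD/BST/FIN as percentages of the maximum swing speed."""
    v = np.asarray(v, dtype=float)
    speed = np.linalg.norm(v, axis=1)
    vmax = float(speed.max())
    if vmax <= 0:
        raise ValueError("zero maximum speed")
    idx = [
        events.t_ADD - window_offset,
        events.t_BST - window_offset,
        events.t_FIN - window_offset,
    ]
    return tuple(100.0 * speed[i] / vmax for i in idx)


def percent_error_reduction(err_before: float, err_after: float) -> float:
    """100 * (before - after) / before."""
    if err_before <= 0:
        raise ValueError("err_before must be positive")
    return 100.0 * (err_before - err_after) / err_before
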