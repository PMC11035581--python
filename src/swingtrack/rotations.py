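"""Quaternion algebra, strapdown gyro integration, and orientation metrics.

Conventions
-----------
Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and represent
rotations of right-handed frames.  ``q`` maps sensor-frame vectors into the
user (ground-fixed) frame: ``v_user = R(q) @ v_sensor``.  The canonical
("northern hemisphere") representative of the double cover has ``w >= 0``.

Arrays of quaternions are ``(N, 4)`` float arrays; single quaternions are
``(4,)`` arrays.  All constructors and per-step updates renormalize, so the
unit-norm invariant holds to ~1e-9 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationSeries",
    "quat_normalize",
    "quat_canonical",
    "quat_conjugate",
    "quat_product",
    "quat_to_matrix",
    "matrix_to_quat",
    "rotate_vector",
    "integrate_gyro",
    "quat_angle_error",
    "quat_distance_loss",
    "mean_quaternion",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _check_finite(q: np.ndarray, name: str = "quaternion") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"non-finite {name}")
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Scale to unit norm.  Works on a single quaternion or an (N, 4) array."""
    q = _check_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Map q and -q to the representative with nonnegative scalar part."""
    q = quat_normalize(q)
    w = q[..., :1]
    sign = np.where(w < 0, -1.0, 1.0)
    return q * sign


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a (x) b, renormalized; composes rotations
    R(a (x) b) = R(a) R(b).  Broadcasts over leading dimensions."""
    a = _check_finite(a)
    b = _check_finite(b)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return quat_normalize(out)


def _raw_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # Hamilton product without the unit-norm renormalization (needed when one
    # factor is a pure-vector quaternion, e.g. the Eq.-of-motion update).
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of q; (..., 3, 3)."""
    q = quat_normalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_to_matrix` (Shepperd's method, canonical sign)."""
    m = np.asarray(m, dtype=float)
    single = m.ndim == 2
    if single:
        m = m[None]
    t = np.einsum("...ii->...", m)
    q = np.empty(m.shape[:-2] + (4,))
    # Branch on the largest diagonal element for numerical stability.
    for i in range(m.shape[0]):
        M = m[i]
        tr = t[i]
        if tr > 0:
            s = np.sqrt(tr + 1.0) * 2
            q[i] = [0.25 * s, (M[2, 1] - M[1, 2]) / s,
                    (M[0, 2] - M[2, 0]) / s, (M[1, 0] - M[0, 1]) / s]
        else:
            d = np.diagonal(M)
            j = int(np.argmax(d))
            k, l = (j + 1) % 3, (j + 2) % 3
            s = np.sqrt(1.0 + M[j, j] - M[k, k] - M[l, l]) * 2
            vec = np.empty(3)
            vec[j] = 0.25 * s
            vec[k] = (M[k, j] + M[j, k]) / s
            vec[l] = (M[l, j] + M[j, l]) / s
            q[i] = [(M[l, k] - M[k, l]) / s, *vec]
    q = quat_canonical(q)
    return q[0] if single else q


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply R(q) to v.  Broadcasts: (N,4) with (N,3), (4,) with (...,3)."""
    q = quat_normalize(q)
    v = _check_finite(np.asarray(v, dtype=float), "vector")
    w = q[..., 0:1]
    u = q[..., 1:4]
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


@dataclass
class OrientationSeries:
    """A uniformly sampled sequence of unit quaternions q_S^U(t)."""

    timestamps: np.ndarray
    quaternions: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.timestamps.shape[0] != self.quaternions.shape[0]:
            raise ValueError("timestamps and quaternions length mismatch")
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must be (N, 4)")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("quaternions must be unit-norm")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def dt(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[1] - self.timestamps[0])

    def matrices(self) -> np.ndarray:
        return quat_to_matrix(self.quaternions)


def integrate_gyro(
    q0: np.ndarray,
    gyro: np.ndarray,
    dt: float,
    t0: float = 0.0,
) -> OrientationSeries:
    """First-order strapdown integration of body-frame angular velocity.

    q(t+1) = q(t) + (1/2) (q(t) (x) [0, omega(t)]) * dt, renormalized each
    step.  The first element of the returned series equals ``q0``; sample k+1
    is advanced with gyro sample k, so the last gyro sample is unused and the
    output has ``max(1, len(gyro))`` elements.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q0 = quat_normalize(np.asarray(q0, dtype=float))
    gyro = np.asarray(gyro, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(gyro)):
        raise ValueError("non-finite angular velocity")
    n = max(1, gyro.shape[0])
    out = np.empty((n, 4))
    out[0] = q0
    for k in range(n - 1):
        omega = np.concatenate([[0.0], gyro[k]])
        step = out[k] + 0.5 * _raw_product(out[k], omega) * dt
        out[k + 1] = step / np.linalg.norm(step)
    t = t0 + dt * np.arange(n)
    return OrientationSeries(t, out)


def quat_angle_error(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Axis-angle magnitude of the relative rotation qa^-1 (x) qb.

    Computed as 2*atan2(||vec||, |w|) of the relative quaternion so the result
    lies in [0, pi], is symmetric, and is invariant to sign flips of either
    argument.  Broadcasts over (N, 4) inputs and returns radians.
    """
    qa = quat_normalize(qa)
    qb = quat_normalize(qb)
    rel = _raw_product(quat_conjugate(qa), qb)
    vec = np.linalg.norm(rel[..., 1:4], axis=-1)
    return 2.0 * np.arctan2(vec, np.abs(rel[..., 0]))


def quat_distance_loss(q_true: np.ndarray, q_est: np.ndarray) -> np.ndarray:
    """Quaternion-distance loss 1 - |q_true . q_est| in [0, 1].

    Zero iff both quaternions denote the same rotation (sign-insensitive by
    the absolute value).  Related to the angle metric by
    loss = 1 - |cos(theta/2)|.
    """
    q_true = quat_normalize(q_true)
    q_est = quat_normalize(q_est)
    dot = np.sum(q_true * q_est, axis=-1)
    return 1.0 - np.abs(dot)


def mean_quaternion(qs: np.ndarray) -> np.ndarray:
    """Rotation average: principal eigenvector of sum_i q_i q_i^T.

    Robust to the q/-q double cover (the outer product is sign-invariant).
    Returns the canonical (w >= 0) unit quaternion.
    """
    qs = np.asarray(qs, dtype=float).reshape(-1, 4)
    if qs.shape[0] == 0:
        raise ValueError("mean_quaternion requires a non-empty input")
    qs = quat_canonical(qs)
    acc = qs.T @ qs
    vals, vecs = np.linalg.eigh(acc)
    return quat_canonical(vecs[:, -1])
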