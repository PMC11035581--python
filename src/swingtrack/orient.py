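"""Address-pose sensor orientation estimation and propagation.

The rotation q_S^U at the address is the initial condition for the whole
swing; without calibration poses it must be inferred from the IMU stream
itself.  A small convolutional network maps a standardized 6 x 1000 window
of accelerometer + gyro samples around the address to a unit quaternion,
trained with the quaternion-distance loss 1 - |q_true . q_est|.  The
statistical baseline is the leave-one-out average address quaternion of the
other subjects.  From the estimated address quaternion the orientation over
the swing is propagated by strapdown gyro integration.

The default input window spans [t_ADD - 100 ms, t_BST]: the static segment
encodes the gravity direction, the early backswing adds consistent dynamic
information about the horizontal axes; windows extending into the downswing
carry high inter-swing variability and degrade the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _nn
from ._nn import AdamState
from .preprocess import ChannelStats, ImuRecording, standardize
from .rotations import (
    OrientationSeries,
    integrate_gyro,
    mean_quaternion,
    quat_canonical,
)
from .segment import SwingEvents

__all__ = [
    "RangeMode",
    "OrientationWindow",
    "OrientationTrainingSet",
    "OrientCnnConfig",
    "OrientationModel",
    "ModelFailureError",
    "build_input_window",
    "train_orientation_cnn",
    "estimate_address_orientation",
    "baseline_address_orientation",
    "propagate_orientation",
]

WINDOW_COLUMNS = 1000
PRE_ADDRESS_SECONDS = 0.1


class ModelFailureError(RuntimeError):
    """Network produced non-finite activations."""


class RangeMode(str, Enum):
    PRE_ADD_ONLY = "pre_add_only"
    PRE_ADD_TO_BST = "pre_add_to_bst"
    TO_IMP = "to_imp"
    TO_FIN = "to_fin"


@dataclass
class OrientationWindow:
    """6 x 1000 standardized input matrix (accel rows then gyro rows),
    left-aligned at t_ADD - 100 ms and zero-padded on the right."""

    matrix: np.ndarray
    window_start: int
    valid_length: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, WINDOW_COLUMNS):
            raise ValueError("window must be 6 x 1000")


@dataclass
class OrientationTrainingSet:
    windows: list[OrientationWindow]
    labels: np.ndarray              # (M, 4) canonical unit quaternions
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = quat_canonical(np.asarray(self.labels, dtype=float))
        if not (len(self.windows) == self.labels.shape[0] == len(self.subject_ids)):
            raise ValueError("windows/labels/subject_ids length mismatch")


def build_input_window(
    rec: ImuRecording,
    events: SwingEvents,
    stats: ChannelStats,
    range_mode: RangeMode = RangeMode.PRE_ADD_TO_BST,
) -> OrientationWindow:
    """Extract and standardize the CNN input window for one swing."""
    events.validate_against(len(rec))
    start = events.t_ADD - round(PRE_ADDRESS_SECONDS * rec.rate)
    if start < 0:
        raise ValueError("recording starts less than 100 ms before the address")
    end = {
        RangeMode.PRE_ADD_ONLY: events.t_ADD,
        RangeMode.PRE_ADD_TO_BST: events.t_BST,
        RangeMode.TO_IMP: events.t_IMP,
        RangeMode.TO_FIN: events.t_FIN,
    }[RangeMode(range_mode)]
    data = standardize(rec, stats)[start : end + 1].T  # (6, L)
    valid = min(data.shape[1], WINDOW_COLUMNS)
    matrix = np.zeros((6, WINDOW_COLUMNS))
    matrix[:, :valid] = data[:, :valid]
    return OrientationWindow(matrix, start, valid)


@dataclass
class OrientCnnConfig:
    """Hyperparameters of the 2-conv + maxpool + FC quaternion regressor.

    Kernel/channel/pool sizes and the learning rate are tunable defaults,
    not fixed properties of the method.
    """

    channels: tuple[int, int] = (8, 16)
    kernel: int = 9
    pool: int = 8
    lr: float = 1e-3
    max_epochs: int = 400
    patience: int = 20
    batch_size: int = 16
    # virtual-mount augmentation: extra training copies with the 3-axis
    # signals rotated by a random sensor-frame rotation and the label
    # composed with the same rotation (an exact physical symmetry)
    n_augment: int = 3
    augment_angle_deg: float = 12.0
    seed: int = 0


class _CnnParams:
    def __init__(self, cfg: OrientCnnConfig, rng: np.random.Generator):
        c1, c2 = cfg.channels
        k = cfg.kernel
        l1 = WINDOW_COLUMNS - k + 1
        l2 = l1 - k + 1
        lp = l2 // cfg.pool
        self.flat_dim = c2 * lp

        def glorot(*shape, fan):
            lim = np.sqrt(6.0 / fan)
            return rng.uniform(-lim, lim, size=shape)

        self.w1 = glorot(c1, 6, k, fan=6 * k + c1 * k)
        self.b1 = np.zeros(c1)
        self.w2 = glorot(c2, c1, k, fan=c1 * k + c2 * k)
        self.b2 = np.zeros(c2)
        self.wf = glorot(self.flat_dim, 4, fan=self.flat_dim + 4)
        self.bf = np.array([1.0, 0.0, 0.0, 0.0])  # start near identity
        self.pool = cfg.pool

    def flat(self):
        return [self.w1, self.b1, self.w2, self.b2, self.wf, self.bf]

    def copy_weights(self):
        return [p.copy() for p in self.flat()]

    def load_weights(self, weights):
        for p, w in zip(self.flat(), weights):
            p[...] = w


def _cnn_forward(params: _CnnParams, x: np.ndarray):
    z1, c1 = _nn.conv1d_forward(x, params.w1, params.b1)
    a1, t1 = _nn.tanh_forward(z1)
    z2, c2 = _nn.conv1d_forward(a1, params.w2, params.b2)
    a2, t2 = _nn.tanh_forward(z2)
    zp, cp = _nn.maxpool1d_forward(a2, params.pool)
    ap, tp = _nn.tanh_forward(zp)
    flat = ap.reshape(ap.shape[0], -1)
    q_raw, cf = _nn.dense_forward(flat, params.wf, params.bf)
    return q_raw, (c1, t1, c2, t2, cp, tp, ap.shape, cf)


def _cnn_backward(params: _CnnParams, cache, dq_raw):
    c1, t1, c2, t2, cp, tp, ap_shape, cf = cache
    dflat, dwf, dbf = _nn.dense_backward(dq_raw, params.wf, cf)
    dap = _nn.tanh_backward(dflat.reshape(ap_shape), tp)
    da2 = _nn.maxpool1d_backward(dap, cp)
    dz2 = _nn.tanh_backward(da2, t2)
    da1, dw2, db2 = _nn.conv1d_backward(dz2, params.w2, c2)
    dz1 = _nn.tanh_backward(da1, t1)
    _, dw1, db1 = _nn.conv1d_backward(dz1, params.w1, c1)
    return [dw1, db1, dw2, db2, dwf, dbf]


def _loss_and_grad(q_raw: np.ndarray, labels: np.ndarray):
    norms = np.linalg.norm(q_raw, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    u = q_raw / norms
    dots = np.sum(u * labels, axis=1)
    loss = float(np.mean(1.0 - np.abs(dots)))
    sign = np.where(dots >= 0, 1.0, -1.0)[:, None]
    du = -sign * (labels - dots[:, None] * u)
    dq_raw = du / norms / q_raw.shape[0]
    return loss, dq_raw


def build_training_set(
    swings: list[tuple[ImuRecording, SwingEvents, np.ndarray, str]],
    stats: ChannelStats,
    range_mode: RangeMode = RangeMode.PRE_ADD_TO_BST,
    config: OrientCnnConfig | None = None,
) -> OrientationTrainingSet:
    """Windows + labels for (recording, events, address quaternion, subject)
    tuples, including the virtual-mount rotation augmentation."""
    from .rotations import from_axis_angle, quat_product, quat_to_matrix

    cfg = config or OrientCnnConfig()
    rng = np.random.default_rng(cfg.seed + 982_451_653 % 2**31)
    windows, labels, ids = [], [], []
    for rec, events, label, sid in swings:
        windows.append(build_input_window(rec, events, stats, range_mode))
        labels.append(label)
        ids.append(sid)
        for _ in range(cfg.n_augment):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(-cfg.augment_angle_deg, cfg.augment_angle_deg))
            q_d = from_axis_angle(axis, angle)
            r_d = quat_to_matrix(q_d)
            rec_aug = ImuRecording(
                rec.timestamps, rec.accel @ r_d, rec.gyro @ r_d,
                accel_range=rec.accel_range, gyro_range=rec.gyro_range,
            )
            windows.append(build_input_window(rec_aug, events, stats, range_mode))
            labels.append(quat_product(label, q_d))
            ids.append(sid)
    return OrientationTrainingSet(windows, np.array(labels), ids)


@dataclass
class OrientationModel:
    params: _CnnParams
    config: OrientCnnConfig
    range_mode: RangeMode
    history: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        q_raw, _ = _cnn_forward(self.params, windows)
        if not np.all(np.isfinite(q_raw)):
            raise ModelFailureError("non-finite network output")
        return quat_canonical(q_raw)


def train_orientation_cnn(
    train: OrientationTrainingSet,
    val_fraction: float = 0.10,
    config: OrientCnnConfig | None = None,
    range_mode: RangeMode = RangeMode.PRE_ADD_TO_BST,
) -> OrientationModel:
    """Train the quaternion CNN with a random swing-level train/validation
    split, Adam, and validation-based early stopping (best weights kept).
    Fully deterministic given ``config.seed``."""
    if len(train.windows) < 2:
        raise ValueError("training set too small")
    if len(set(train.subject_ids)) < 2:
        raise ValueError("training requires at least 2 subjects")
    cfg = config or OrientCnnConfig()
    rng = np.random.default_rng(cfg.seed)
    x = np.stack([w.matrix for w in train.windows])
    y = train.labels
    m = x.shape[0]
    order = rng.permutation(m)
    n_val = max(1, int(round(val_fraction * m)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        raise ValueError("empty training split")
    params = _CnnParams(cfg, rng)
    opt = AdamState.for_params(params.flat(), lr=cfg.lr)
    best_val = np.inf
    best_weights = params.copy_weights()
    bad_epochs = 0
    history: list[tuple[float, float]] = []
    for _ in range(cfg.max_epochs):
        rng.shuffle(tr_idx)
        train_loss = 0.0
        for start in range(0, tr_idx.size, cfg.batch_size):
            batch = tr_idx[start : start + cfg.batch_size]
            q_raw, cache = _cnn_forward(params, x[batch])
            loss, dq = _loss_and_grad(q_raw, y[batch])
            grads = _cnn_backward(params, cache, dq)
            opt.step(params.flat(), grads)
            train_loss += loss * batch.size
        train_loss /= tr_idx.size
        q_val, _ = _cnn_forward(params, x[val_idx])
        val_loss, _ = _loss_and_grad(q_val, y[val_idx])
        history.append((train_loss, val_loss))
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = params.copy_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    params.load_weights(best_weights)
    return OrientationModel(params, cfg, RangeMode(range_mode), history)


def estimate_address_orientation(
    model: OrientationModel, window: OrientationWindow
) -> np.ndarray:
    """Forward pass for one window; unit-norm, canonical quaternion."""
    return model.predict(window.matrix[None])[0]


def baseline_address_orientation(others_labels: np.ndarray) -> np.ndarray:
    """Leave-one-out statistical baseline: the average address quaternion of
    all other subjects."""
    others_labels = np.asarray(others_labels, dtype=float).reshape(-1, 4)
    if others_labels.shape[0] == 0:
        raise ValueError("baseline requires a non-empty label set")
    return mean_quaternion(others_labels)


def propagate_orientation(
    q_add: np.ndarray,
    rec: ImuRecording,
    events: SwingEvents | tuple[int, int],
) -> OrientationSeries:
    """Strapdown-integrate the gyro from the (estimated) address quaternion
    over [t_ADD, t_FIN].  ``events`` may be a plain (start, stop) index pair,
    which permits a zero-length window."""
    if isinstance(events, SwingEvents):
        events.validate_against(len(rec))
        start, stop = events.t_ADD, events.t_FIN
    else:
        start, stop = events
        if not 0 <= start <= stop < len(rec):
            raise ValueError("invalid propagation window")
    gyro = rec.gyro[start : stop + 1]
    return integrate_gyro(q_add, gyro, rec.dt, t0=rec.timestamps[start])
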