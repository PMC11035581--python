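"""Swing-event segmentation from wrist IMU signals.

The four events — address (ADD), backswing top (BST), impact (IMP), finish
(FIN) — are defined by local minima / the maximum of the swing speed profile.
Two routes are provided: a direct speed-profile event finder (usable when a
reference speed is available, e.g. simulator ground truth), and a trained
bidirectional recurrent sequence labeller that assigns one of five phase
classes (pre-ADD, backswing, downswing, follow-through, post-FIN) to every
sample of the 6-channel IMU stream and extracts events from the phase
boundaries with an order-constrained decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from ._nn import AdamState, BiRnnParams, birnn_backward, birnn_forward
from .preprocess import ChannelStats, ImuRecording, standardize

__all__ = [
    "SwingEvents",
    "SegmentationError",
    "events_from_speed_profile",
    "SegmenterConfig",
    "SegmenterModel",
    "train_segmenter",
    "segment_swing",
    "phase_labels_from_events",
]

N_PHASES = 5


class SegmentationError(RuntimeError):
    """Raised when no physically valid event sequence can be extracted."""


@dataclass(frozen=True)
class SwingEvents:
    """0-based sample indices of the four swing events, strictly ordered."""

    t_ADD: int
    t_BST: int
    t_IMP: int
    t_FIN: int

    def __post_init__(self) -> None:
        idx = self.as_tuple()
        if any(int(i) != i for i in idx):
            raise ValueError("event indices must be integers")
        if not (self.t_ADD < self.t_BST < self.t_IMP < self.t_FIN):
            raise ValueError(f"events must be strictly ordered, got {idx}")
        if self.t_ADD < 0:
            raise ValueError("event indices must be nonnegative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.t_ADD, self.t_BST, self.t_IMP, self.t_FIN)

    def validate_against(self, n_samples: int) -> None:
        if self.t_FIN >= n_samples:
            raise ValueError("events exceed recording bounds")


def events_from_speed_profile(
    speed: np.ndarray,
    ball_crossing: int | None = None,
    rest_fraction: float = 0.02,
) -> SwingEvents:
    """Extract ADD/BST/IMP/FIN from a wrist-speed profile.

    ADD is the last (near-)rest sample before the first sustained speed rise,
    BST the first local minimum after the backswing peak, IMP the global
    speed maximum (or ``ball_crossing`` when the ball position is known), and
    FIN the first local minimum after IMP where the wrist comes back to rest.

    A profile without the rise-fall-rise-fall structure (e.g. monotone speed)
    raises :class:`SegmentationError`.
    """
    speed = np.asarray(speed, dtype=float).ravel()
    n = speed.shape[0]
    if n <= 50:
        raise ValueError("speed profile too short")
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    vmax = float(speed.max())
    if vmax <= 0:
        raise SegmentationError("speed profile is identically zero")
    thr = rest_fraction * vmax

    i_imp = int(ball_crossing) if ball_crossing is not None else int(np.argmax(speed))

    # ADD: last near-rest sample before the first sustained rise.  "Rest"
    # is relative to the quietest level seen before the rise, so an exactly
    # stationary hold is resolved to the sample.
    rise_mask = speed > 0.1 * vmax
    sustained = np.convolve(rise_mask.astype(float), np.ones(5), mode="full")[4:] >= 5
    rises = np.flatnonzero(sustained)
    if rises.size == 0:
        raise SegmentationError("no sustained speed rise found")
    i_rise = int(rises[0])
    rest_level = float(speed[:i_rise].min())
    rest = np.flatnonzero(speed[:i_rise] <= rest_level + 1e-4 * vmax)
    i_add = int(rest[-1])
    if speed[i_add] > thr:
        raise SegmentationError("no rest phase before the speed rise")
    if i_add >= i_imp:
        raise SegmentationError("address found after the speed maximum")

    # BST: first local minimum after the backswing peak.
    bs_peak = i_add + int(np.argmax(speed[i_add : i_imp + 1]))
    minima, _ = _signal.find_peaks(-speed[bs_peak : i_imp + 1])
    if minima.size:
        i_bst = bs_peak + int(minima[0])
    else:
        # Degenerate single-rise profile (no backswing structure): place BST
        # at the lowest point between the address and the speed maximum.
        if i_imp - i_add < 2:
            raise SegmentationError("no backswing minimum before the speed maximum")
        i_bst = i_add + 1 + int(np.argmin(speed[i_add + 1 : i_imp]))

    # FIN: first local minimum after IMP where the wrist returns to rest;
    # when the profile decays onto a flat plateau with no local minimum
    # (e.g. a truncated recording), fall back to the plateau onset.
    tail = speed[i_imp:]
    minima_after, _ = _signal.find_peaks(-tail)
    low_minima = [int(m) for m in minima_after if tail[m] <= 0.3 * vmax]
    if low_minima:
        i_fin = i_imp + low_minima[0]
    else:
        below = np.flatnonzero(tail <= thr)
        if below.size == 0:
            raise SegmentationError("wrist never returns to rest after impact")
        f0 = int(below[0])
        window = tail[f0:]
        plateau_level = float(window.min())
        i_fin = i_imp + f0 + int(np.flatnonzero(window <= plateau_level + 1e-4 * vmax)[0])

    if not (i_add < i_bst < i_imp < i_fin):
        raise SegmentationError(
            f"extracted events are not ordered: {(i_add, i_bst, i_imp, i_fin)}"
        )
    return SwingEvents(i_add, i_bst, i_imp, i_fin)


def phase_labels_from_events(events: SwingEvents, n_samples: int) -> np.ndarray:
    """Per-sample phase classes 0..4 delimited by the four events."""
    events.validate_against(n_samples)
    labels = np.zeros(n_samples, dtype=int)
    labels[events.t_ADD : events.t_BST] = 1
    labels[events.t_BST : events.t_IMP] = 2
    labels[events.t_IMP : events.t_FIN] = 3
    labels[events.t_FIN :] = 4
    return labels


@dataclass
class SegmenterConfig:
    hidden: int = 16
    stride: int = 4          # temporal downsampling before the recurrence
    epochs: int = 80
    lr: float = 1e-2
    val_fraction: float = 0.15
    patience: int = 10
    augment_shift_s: float = 0.4  # random crop-shift so absolute sequence
    seed: int = 0                 # position carries no information


@dataclass
class SegmenterModel:
    params: BiRnnParams
    stats: ChannelStats
    config: SegmenterConfig

    def predict_log_proba(self, rec: ImuRecording) -> np.ndarray:
        """(T, 5) log-probabilities on the downsampled time base."""
        x = standardize(rec, self.stats)[:: self.config.stride]
        logits, _ = birnn_forward(self.params, x)
        logits = logits - logits.max(axis=1, keepdims=True)
        logz = np.log(np.exp(logits).sum(axis=1, keepdims=True))
        return logits - logz


def train_segmenter(
    dataset: list[tuple[ImuRecording, SwingEvents]],
    stats: ChannelStats,
    config: SegmenterConfig | None = None,
    labels_override: list[np.ndarray] | None = None,
) -> tuple[SegmenterModel, list[float]]:
    """Train the bidirectional recurrent phase labeller.

    Returns the model and the per-epoch mean cross-entropy.  Training is fully
    seeded.  ``labels_override`` substitutes custom per-sample labels (full
    rate; they are downsampled internally) — used for control experiments.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = config or SegmenterConfig()
    rng = np.random.default_rng(cfg.seed)

    xs, ys = [], []
    for i, (rec, events) in enumerate(dataset):
        x = standardize(rec, stats)[:: cfg.stride]
        if labels_override is not None:
            y = np.asarray(labels_override[i])[:: cfg.stride]
        else:
            y = phase_labels_from_events(events, len(rec))[:: cfg.stride]
        xs.append(x.astype(np.float64))
        ys.append(y)

    params = BiRnnParams.init(n_in=6, hidden=cfg.hidden, n_out=N_PHASES, rng=rng)
    opt = AdamState.for_params(params.flat(), lr=cfg.lr)
    history: list[float] = []
    n_val = min(len(xs) - 1, max(1, int(round(cfg.val_fraction * len(xs)))))
    perm = rng.permutation(len(xs))
    val_ids, train_ids = perm[:n_val], perm[n_val:]
    max_shift = int(cfg.augment_shift_s * 200 / cfg.stride)

    def ce_loss(x, y):
        logits, cache = birnn_forward(params, x)
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        p = e / e.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))
        dlogits = p.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        return loss, cache, dlogits

    best_val = np.inf
    best_weights = [p.copy() for p in params.flat()]
    bad = 0
    order = train_ids.copy()
    for _ in range(cfg.epochs):
        rng.shuffle(order)
        total, count = 0.0, 0
        for i in order:
            # random head crop: boundaries must be found from the signal,
            # not from the absolute sample index
            off = int(rng.integers(0, max_shift + 1)) if max_shift > 0 else 0
            x, y = xs[i][off:], ys[i][off:]
            loss, cache, dlogits = ce_loss(x, y)
            grads = birnn_backward(params, cache, dlogits)
            opt.step(params.flat(), grads)
            total += loss * len(y)
            count += len(y)
        history.append(total / count)
        val_loss = float(np.mean([ce_loss(xs[i], ys[i])[0] for i in val_ids]))
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_weights = [p.copy() for p in params.flat()]
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    for p, w in zip(params.flat(), best_weights):
        p[...] = w
    return SegmenterModel(params, stats, cfg), history


def _monotone_decode(logp: np.ndarray) -> np.ndarray:
    """Best monotone 0->1->2->3->4 phase path through (T, 5) log-probs.

    Dynamic programming guarantees every phase appears at least once and the
    phase sequence is non-decreasing, so the extracted events are always
    strictly ordered regardless of the raw network output.
    """
    T, K = logp.shape
    if T < K:
        raise SegmentationError("recording too short to contain all phases")
    score = np.full((T, K), -np.inf)
    back = np.zeros((T, K), dtype=int)
    score[0, 0] = logp[0, 0]
    for t in range(1, T):
        for k in range(K):
            stay = score[t - 1, k]
            advance = score[t - 1, k - 1] if k > 0 else -np.inf
            if advance > stay:
                score[t, k] = advance + logp[t, k]
                back[t, k] = 1
            else:
                score[t, k] = stay + logp[t, k]
                back[t, k] = 0
    if not np.isfinite(score[T - 1, K - 1]):
        raise SegmentationError("no monotone phase path found")
    path = np.empty(T, dtype=int)
    k = K - 1
    for t in range(T - 1, -1, -1):
        path[t] = k
        k -= back[t, k]
    return path


def segment_swing(model: SegmenterModel, rec: ImuRecording) -> SwingEvents:
    """Predict the four swing events for one recording.

    Raises :class:`SegmentationError` on recordings without swing motion.
    """
    if float(np.linalg.norm(rec.gyro, axis=1).max(initial=0.0)) < 0.5:
        raise SegmentationError("no swing motion detected (gyro energy too low)")
    logp = model.predict_log_proba(rec)
    path = _monotone_decode(logp)
    stride = model.config.stride
    boundaries = [int(np.argmax(path >= k)) * stride for k in range(1, N_PHASES)]
    events = SwingEvents(*boundaries)
    events.validate_against(len(rec))
    return events
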