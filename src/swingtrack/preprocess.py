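"""Raw IMU conditioning: low-pass filtering, clipping repair, standardization.

The recording container mirrors the wrist device of interest: 3-axis
accelerometer (m/s^2, +/-16 g range) and 3-axis gyroscope (rad/s, +/-2000 dps
range) sampled uniformly at a nominal 200 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

G = 9.80665
DEFAULT_ACCEL_RANGE = 16.0 * G
DEFAULT_GYRO_RANGE = np.deg2rad(2000.0)

__all__ = [
    "ImuRecording",
    "ChannelStats",
    "ClipSegment",
    "lowpass_filter",
    "detect_clipping",
    "repair_clipping",
    "standardize",
    "destandardize",
    "compute_channel_stats",
]


@dataclass
class ImuRecording:
    """Uniformly sampled 6-channel inertial time series."""

    timestamps: np.ndarray          # seconds
    accel: np.ndarray               # (N, 3) m/s^2, sensor frame
    gyro: np.ndarray                # (N, 3) rad/s, sensor frame
    accel_range: float = DEFAULT_ACCEL_RANGE
    gyro_range: float = DEFAULT_GYRO_RANGE

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro must be (N, 3) matching timestamps")
        if n >= 2:
            steps = np.diff(self.timestamps)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(steps) > 1e-6:
                raise ValueError("sampling step must be constant within 1e-6 s")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def channels(self) -> np.ndarray:
        """(N, 6) view-order ax, ay, az, gx, gy, gz."""
        return np.hstack([self.accel, self.gyro])

    def with_channels(self, data: np.ndarray) -> "ImuRecording":
        data = np.asarray(data, dtype=float)
        return replace(self, accel=data[:, :3].copy(), gyro=data[:, 3:].copy())


@dataclass
class ChannelStats:
    """Per-channel mean/SD used for standardization (6 channels)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(6)
        self.sd = np.asarray(self.sd, dtype=float).reshape(6)
        if np.any(self.sd <= 0):
            raise ValueError("channel SDs must be strictly positive")


@dataclass(frozen=True)
class ClipSegment:
    """A maximal run of saturated samples on one channel (0..5)."""

    channel: int
    start: int
    stop: int  # exclusive

    def __len__(self) -> int:
        return self.stop - self.start


def lowpass_filter(
    rec: ImuRecording,
    cutoff_hz: float = 20.0,
    order: int = 10,
    mode: str = "zero-phase",
) -> ImuRecording:
    """Butterworth low-pass on all six channels.

    ``zero-phase`` (default) runs a half-order kernel forward-backward,
    matching the magnitude response of the full order without phase lag
    (phase lag would bias event timing); ``single`` applies the full-order
    kernel causally.
    """
    nyq = rec.rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    if len(rec) <= 3 * order:
        raise ValueError("recording too short for the requested filter order")
    data = rec.channels()
    if mode == "zero-phase":
        sos = signal.butter(order // 2, cutoff_hz, fs=rec.rate, output="sos")
        out = signal.sosfiltfilt(sos, data, axis=0)
    elif mode == "single":
        sos = signal.butter(order, cutoff_hz, fs=rec.rate, output="sos")
        out = signal.sosfilt(sos, data, axis=0)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return rec.with_channels(out)


def detect_clipping(
    rec: ImuRecording, tol_fraction: float = 0.999
) -> list[ClipSegment]:
    """Maximal runs with |value| >= tol_fraction * full-scale, per channel."""
    data = rec.channels()
    ranges = np.array([rec.accel_range] * 3 + [rec.gyro_range] * 3)
    segments: list[ClipSegment] = []
    for ch in range(6):
        mask = np.abs(data[:, ch]) >= tol_fraction * ranges[ch]
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            segments.append(ClipSegment(ch, int(start), int(stop)))
    return segments


def repair_clipping(
    rec: ImuRecording,
    segments: list[ClipSegment],
    context: int = 10,
) -> ImuRecording:
    """Replace clipped runs by a cubic spline through the ``context`` samples
    on each side.  Repaired values may legitimately exceed full scale.
    Segments too close to a boundary fall back to a one-sided spline with a
    warning; samples outside the given segments are never modified."""
    if not segments:
        return rec.with_channels(rec.channels())
    data = rec.channels().copy()
    n = len(rec)
    for seg in segments:
        left = np.arange(max(0, seg.start - context), seg.start)
        right = np.arange(seg.stop, min(n, seg.stop + context))
        if len(left) < context or len(right) < context:
            warnings.warn(
                f"clipping segment {seg} near recording boundary: "
                "one-sided spline fallback",
                stacklevel=2,
            )
        support = np.concatenate([left, right])
        if len(support) < 4:
            raise ValueError(f"not enough context samples to repair {seg}")
        spline = CubicSpline(rec.timestamps[support], data[support, seg.channel])
        idx = np.arange(seg.start, seg.stop)
        data[idx, seg.channel] = spline(rec.timestamps[idx])
    return rec.with_channels(data)


def standardize(rec: ImuRecording, stats: ChannelStats) -> np.ndarray:
    """(value - mean) / sd per channel; returns a dimensionless (N, 6) array.

    The stats must come from a disjoint (training) population so test swings
    are standardized exactly as the models saw during training.
    """
    return (rec.channels() - stats.mean) / stats.sd


def destandardize(data: np.ndarray, stats: ChannelStats) -> np.ndarray:
    return np.asarray(data, dtype=float) * stats.sd + stats.mean


def compute_channel_stats(recordings: list[ImuRecording]) -> ChannelStats:
    """Pooled per-channel mean/SD over a list of recordings."""
    if not recordings:
        raise ValueError("need at least one recording")
    stacked = np.vstack([r.channels() for r in recordings])
    sd = stacked.std(axis=0)
    sd = np.where(sd <= 0, 1.0, sd)
    return ChannelStats(stacked.mean(axis=0), sd)
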