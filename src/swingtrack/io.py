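"""File formats: the IMU CSV dialect, ground-truth/trajectory outputs,
YAML run configuration, and model checkpoints."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ImuRecording

logger = logging.getLogger("swingtrack")

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]

__all__ = [
    "ImuCsvError",
    "read_imu_csv",
    "write_imu_csv",
    "write_ground_truth",
    "write_track",
    "RunConfig",
    "save_orientation_model",
    "load_orientation_model",
    "save_segmenter_model",
    "load_segmenter_model",
]


class ImuCsvError(ValueError):
    """Malformed IMU CSV; the message names the offending line."""


def write_imu_csv(rec: ImuRecording, path: str | Path, gyro_unit: str = "rad/s") -> None:
    """Write the documented dialect: a ``# units:`` comment, the fixed
    header, then one row per sample.  Round-trips within 1e-9."""
    if gyro_unit not in ("rad/s", "deg/s"):
        raise ValueError("gyro_unit must be 'rad/s' or 'deg/s'")
    gyro = rec.gyro if gyro_unit == "rad/s" else np.rad2deg(rec.gyro)
    frame = pd.DataFrame(
        np.column_stack([rec.timestamps, rec.accel, gyro]), columns=IMU_COLUMNS
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {gyro_unit}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def read_imu_csv(path: str | Path) -> ImuRecording:
    """Parse the IMU CSV dialect; gyro columns declared ``deg/s`` are
    converted to rad/s on read."""
    path = Path(path)
    gyro_unit = None
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            if line[1:].strip().lower().startswith("units:"):
                gyro_unit = line.split(":", 1)[1].strip()
    if gyro_unit is None:
        gyro_unit = "rad/s"
        logger.warning("%s: no '# units:' comment, assuming rad/s", path)
    if gyro_unit not in ("rad/s", "deg/s"):
        raise ImuCsvError(f"{path}: unsupported gyro unit {gyro_unit!r}")
    frame = pd.read_csv(path, comment="#")
    if list(frame.columns) != IMU_COLUMNS:
        raise ImuCsvError(
            f"{path}: header must be {','.join(IMU_COLUMNS)} "
            f"(line {n_comment + 1})"
        )
    data = frame.to_numpy(dtype=float)
    bad = np.flatnonzero(~np.all(np.isfinite(data), axis=1))
    header_lines = n_comment + 1
    if bad.size:
        raise ImuCsvError(f"{path}: non-finite value on line {bad[0] + header_lines + 1}")
    t = data[:, 0]
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise ImuCsvError(
            f"{path}: non-monotone timestamp on line {nonmono[0] + header_lines + 2}"
        )
    gyro = data[:, 4:7]
    if gyro_unit == "deg/s":
        gyro = np.deg2rad(gyro)
    return ImuRecording(t, data[:, 1:4], gyro)


def write_ground_truth(gt, csv_path: str | Path, json_path: str | Path) -> None:
    """Ground-truth trajectory/velocity/orientation CSV plus a JSON sidecar
    with events and the true swing plane."""
    t = gt.orientation.timestamps
    frame = pd.DataFrame(
        np.column_stack([t, gt.trajectory, gt.velocity, gt.orientation.quaternions]),
        columns=["t", "X", "Y", "Z", "vX", "vY", "vZ", "qw", "qx", "qy", "qz"],
    )
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "events": dict(zip(["t_ADD", "t_BST", "t_IMP", "t_FIN"], gt.events.as_tuple())),
        "plane": {
            "v_n": gt.plane.v_n.tolist(),
            "c_circ": gt.plane.c_circ.tolist(),
            "r_circ": gt.plane.r_circ,
        },
        "path_length_m": gt.path_length,
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


def write_track(track, csv_path: str | Path, json_path: str | Path,
                extra: dict | None = None) -> None:
    """Per-sample trajectory CSV (uncorrected / Vcal / Tcal) plus a JSON
    sidecar with events, plane, bias and any supplied metrics."""
    t = track.orientation.timestamps
    frame = pd.DataFrame(
        np.column_stack([t, track.traj_ori, track.traj_vcal, track.traj_tcal]),
        columns=["t", "X_ori", "Y_ori", "Z_ori",
                 "X_Vcal", "Y_Vcal", "Z_Vcal", "X_Tcal", "Y_Tcal", "Z_Tcal"],
    )
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "events": dict(zip(["t_ADD", "t_BST", "t_IMP", "t_FIN"],
                           track.events.as_tuple())),
        "plane": {
            "v_n": track.plane.v_n.tolist(),
            "c_circ": track.plane.c_circ.tolist(),
            "r_circ": track.plane.r_circ,
        },
        "a_bias": track.a_bias.tolist(),
        "endpoint": track.ep.tolist(),
    }
    if extra:
        sidecar.update(extra)
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


_CONFIG_FIELDS = {
    "filter_cutoff_hz": float,
    "filter_order": int,
    "filter_mode": str,
    "window_range_mode": str,
    "segmentation_mode": str,
    "orientation_mode": str,
    "eq5_literal": bool,
    "circle_refine": bool,
    "seed": int,
}


@dataclass
class RunConfig:
    """Run-level configuration; every ambiguity of the processing pipeline
    (filter phase handling, Eq.-variant flags, window range) is a key here
    so ablations are runnable from the config file alone."""

    filter_cutoff_hz: float = 20.0
    filter_order: int = 10
    filter_mode: str = "zero-phase"        # or "single"
    window_range_mode: str = "pre_add_to_bst"
    segmentation_mode: str = "model"       # or "provided"
    orientation_mode: str = "cnn"          # or "baseline" | "provided"
    eq5_literal: bool = False
    circle_refine: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            want = _CONFIG_FIELDS[key]
            if want is float and isinstance(value, int):
                continue
            if not isinstance(value, want):
                raise ValueError(f"config key {key!r} must be {want.__name__}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


_CHECKPOINT_VERSION = 1


def save_orientation_model(model, path: str | Path) -> None:
    from .orient import OrientationModel  # noqa: F401  (type reference)

    np.savez(
        path,
        version=_CHECKPOINT_VERSION,
        kind="orientation-cnn",
        w1=model.params.w1, b1=model.params.b1,
        w2=model.params.w2, b2=model.params.b2,
        wf=model.params.wf, bf=model.params.bf,
        config=json.dumps(asdict(model.config)),
        range_mode=model.range_mode.value,
        history=np.asarray(model.history, dtype=float).reshape(-1, 2),
    )


def load_orientation_model(path: str | Path):
    from .orient import OrientationModel, OrientCnnConfig, RangeMode, _CnnParams

    with np.load(path, allow_pickle=False) as data:
        if int(data["version"]) != _CHECKPOINT_VERSION or str(data["kind"]) != "orientation-cnn":
            raise ValueError("not an orientation-cnn checkpoint")
        cfg = OrientCnnConfig(**json.loads(str(data["config"])))
        cfg.channels = tuple(cfg.channels)
        params = _CnnParams(cfg, np.random.default_rng(0))
        params.load_weights([data[k] for k in ["w1", "b1", "w2", "b2", "wf", "bf"]])
        history = [tuple(row) for row in data["history"]]
        return OrientationModel(params, cfg, RangeMode(str(data["range_mode"])), history)


def save_segmenter_model(model, path: str | Path) -> None:
    p = model.params
    np.savez(
        path,
        version=_CHECKPOINT_VERSION,
        kind="segmenter-birnn",
        wx_f=p.wx_f, wh_f=p.wh_f, b_f=p.b_f,
        wx_b=p.wx_b, wh_b=p.wh_b, b_b=p.b_b,
        wo=p.wo, bo=p.bo,
        stats_mean=model.stats.mean, stats_sd=model.stats.sd,
        config=json.dumps(asdict(model.config)),
    )


def load_segmenter_model(path: str | Path):
    from ._nn import BiRnnParams
    from .preprocess import ChannelStats
    from .segment import SegmenterConfig, SegmenterModel

    with np.load(path, allow_pickle=False) as data:
        if int(data["version"]) != _CHECKPOINT_VERSION or str(data["kind"]) != "segmenter-birnn":
            raise ValueError("not a segmenter checkpoint")
        params = BiRnnParams(
            **{k: data[k] for k in
               ["wx_f", "wh_f", "b_f", "wx_b", "wh_b", "b_b", "wo", "bo"]}
        )
        stats = ChannelStats(data["stats_mean"], data["stats_sd"])
        cfg = SegmenterConfig(**json.loads(str(data["config"])))
        return SegmenterModel(params, stats, cfg)
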