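"""File formats and run configuration.

CSV formats (comma-separated, UTF-8, dot decimal, mandatory header; the
readers sniff comma/semicolon/tab delimiters to accommodate exported
variants):

* orientation CSV — ``time_s, segment, qw, qx, qy, qz``, one row per sample
  per segment, 200 Hz nominal;
* GRF CSV — ``time_s, fz_N``;
* angle table CSV — ``participant, task, method, plane, pct_0 ... pct_100``;
* raw angle CSV — ``time_s, flexion_deg, adduction_deg, int_rot_deg``;
* calibration record — JSON (offset quaternions, window, residual motion).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import PLANES, GRFSeries, JointAngleSeries, OrientationStream
from .rotation import CalibrationRecord
from .stats import PCT_COLS

__all__ = [
    "RunConfig",
    "read_orientation_csv",
    "write_orientation_csv",
    "read_grf_csv",
    "write_grf_csv",
    "read_angle_table",
    "write_angle_table",
    "write_raw_angles",
    "read_calibration_json",
    "write_calibration_json",
]

_ORIENTATION_COLS = ["time_s", "segment", "qw", "qx", "qy", "qz"]
_SEGMENTS = ("thigh", "shank", "pelvis", "foot")


def _read_csv(path) -> pd.DataFrame:
    # sniff among comma/semicolon/tab
    return pd.read_csv(path, sep=None, engine="python")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_orientation_csv(path) -> dict[str, OrientationStream]:
    """Read per-segment orientation streams; returns ``{segment: stream}``.

    Quaternions are re-normalized on read; a warning is issued if any norm
    deviates from unity by more than 1e-6.
    """
    import warnings

    df = _read_csv(path)
    _require_columns(df, _ORIENTATION_COLS, path)
    streams: dict[str, OrientationStream] = {}
    for segment, g in df.groupby("segment", sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-monotone timestamps for segment {segment!r}")
        q = g[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
        drift = np.max(np.abs(np.linalg.norm(q, axis=1) - 1.0))
        if drift > 1e-6:
            warnings.warn(
                f"{path}: segment {segment!r} quaternions deviate from unit norm by up to "
                f"{drift:.2e}; re-normalized",
                stacklevel=2,
            )
        rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 else 200.0
        streams[str(segment)] = OrientationStream(
            segment=str(segment), timestamps=t, quaternions=q, sample_rate_hz=float(round(rate))
        )
    return streams


def write_orientation_csv(streams, path) -> None:
    """Write one or more orientation streams to a single CSV."""
    if isinstance(streams, OrientationStream):
        streams = [streams]
    if isinstance(streams, dict):
        streams = list(streams.values())
    frames = []
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.timestamps,
                    "segment": s.segment,
                    "qw": s.quaternions[:, 0],
                    "qx": s.quaternions[:, 1],
                    "qy": s.quaternions[:, 2],
                    "qz": s.quaternions[:, 3],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grf_csv(path) -> GRFSeries:
    df = _read_csv(path)
    _require_columns(df, ["time_s", "fz_N"], path)
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotone timestamps")
    rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 else 1000.0
    return GRFSeries(timestamps=t, force_n=df["fz_N"].to_numpy(dtype=float), sample_rate_hz=float(round(rate)))


def write_grf_csv(grf: GRFSeries, path) -> None:
    pd.DataFrame({"time_s": grf.timestamps, "fz_N": grf.force_n}).to_csv(path, index=False)


def read_angle_table(path) -> pd.DataFrame:
    """Read an S1-style normalized angle table (101 points per row)."""
    df = _read_csv(path)
    _require_columns(df, ["participant", "task", "method", "plane"], path)
    pct = [c for c in df.columns if c.startswith("pct_")]
    if len(pct) != 101:
        raise ValueError(
            f"{path}: expected 101 percent-of-cycle columns (pct_0 ... pct_100), found {len(pct)}"
        )
    bad = set(df["plane"]) - set(PLANES)
    if bad:
        raise ValueError(f"{path}: unknown plane label(s) {sorted(bad)}")
    return df[["participant", "task", "method", "plane"] + PCT_COLS]


def write_angle_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_raw_angles(angles: JointAngleSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": angles.timestamps,
            "flexion_deg": angles.angles_deg[:, 0],
            "adduction_deg": angles.angles_deg[:, 1],
            "int_rot_deg": angles.angles_deg[:, 2],
        }
    ).to_csv(path, index=False)


def write_calibration_json(calib: CalibrationRecord, path) -> None:
    Path(path).write_text(json.dumps(calib.to_dict(), indent=2))


def read_calibration_json(path) -> CalibrationRecord:
    return CalibrationRecord.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunConfig:
    """All tunable pipeline parameters, serializable to/from YAML."""

    kinematic_rate_hz: float = 200.0
    grf_rate_hz: float = 1000.0
    filter_cutoff_hz: float = 6.0
    filter_order: int = 2
    zero_phase: bool = True
    grf_threshold_n: float = 20.0
    grf_hysteresis_s: float = 0.05
    task_speed_threshold_deg_s: float = 5.0
    max_lag_s: float = 0.5
    alpha: float = 0.05
    n_comparisons: int = 3
    mean_center: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.filter_cutoff_hz < self.kinematic_rate_hz / 2:
            raise ValueError("filter cutoff must sit between 0 and the kinematic Nyquist rate")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.grf_threshold_n <= 0 or self.grf_hysteresis_s < 0:
            raise ValueError("GRF threshold must be positive and hysteresis non-negative")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a YAML mapping of config fields")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config field(s) {sorted(unknown)}")
        return cls(**data)
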