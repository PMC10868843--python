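"""Synthetic cohorts of IMU orientation streams, GRF, and reference knee angles.

The generator emulates the study conditions of a wearable-sensor knee
validation experiment: a cohort (default 21 participants) performs five
activities of daily living — walking, squatting, sit-to-stand, stair ascent,
stair descent — with per-participant sagittal range of motion drawn from the
task's cohort distribution.  For each trial it produces

* a ground-truth tri-planar knee angle series (playing the optical motion
  capture reference role),
* thigh and shank orientation streams at 200 Hz that reproduce the truth
  exactly through the angle pipeline (the clean channel), plus corrupted
  copies per simulated IMU method,
* a 1000 Hz vertical ground reaction force channel with stance windows at the
  requested gait events, and
* static neutral-posture calibration recordings.

The corruption model composes the error sources known to degrade skin-mounted
inertial sensing: gyroscopic drift (random-walk rotation), soft-tissue
artifact on the thigh (motion-correlated oscillation), white orientation
noise, a fixed sensor-axis misalignment producing crosstalk, and a flexed
knee during the calibration pose producing a constant offset.  Stair tasks
receive an extra disturbance factor emulating the electromagnetic
interference of an instrumented staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import rotation
from .pipeline import (
    PLANES,
    TASKS,
    GRFSeries,
    JointAngleSeries,
    OrientationStream,
)

__all__ = [
    "TaskTemplate",
    "NoiseConfig",
    "SyntheticTrial",
    "CohortSpec",
    "make_template",
    "truth_to_orientations",
    "apply_sensor_errors",
    "generate_grf",
    "generate_trial",
    "generate_cohort",
    "TASK_DEFAULTS",
    "R_IMU_NOISE",
    "M_IMU_NOISE",
]

SAMPLE_RATE_HZ = 200.0
GRF_RATE_HZ = 1000.0
STATIC_DURATION_S = 1.0
#: Rest inserted before/between squat and sit-to-stand repetitions (s).
REST_GAP_S = 0.75
#: Fraction of a gait cycle spent in stance (walking and stairs).
STANCE_FRACTION = {"walk": 0.62, "stair_ascent": 0.65, "stair_descent": 0.65}

#: Study conditions per task: cohort mean (SD) of sagittal ROM in degrees for
#: the reference channel, and a typical cycle duration in seconds.
TASK_DEFAULTS = {
    "walk": {"rom_mean": 60.40, "rom_sd": 8.77, "duration_s": 1.1},
    "squat": {"rom_mean": 78.85, "rom_sd": 11.73, "duration_s": 3.0},
    "sit_to_stand": {"rom_mean": 77.42, "rom_sd": 23.51, "duration_s": 2.5},
    "stair_ascent": {"rom_mean": 88.56, "rom_sd": 9.72, "duration_s": 1.4},
    "stair_descent": {"rom_mean": 88.90, "rom_sd": 9.63, "duration_s": 1.4},
}

#: Default out-of-plane truth amplitudes (deg of ROM).
FRONTAL_ROM_DEG = 8.0
TRANSVERSE_ROM_DEG = 10.0

#: White orientation noise during quiescent standing relative to motion.
STATIC_NOISE_ATTENUATION = 0.3

#: Cohort body-mass distribution (kg) for GRF scaling.
BODY_MASS_MEAN_KG = 93.89
BODY_MASS_SD_KG = 24.0
GRAVITY = 9.81


def _vm_bump(s: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Periodic (von Mises) bump on the unit phase circle."""
    return np.exp(kappa * (np.cos(2 * np.pi * (s - center)) - 1.0))


def _one_shot(s: np.ndarray) -> np.ndarray:
    """Single smooth excursion, zero value and slope at both ends."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * s))


def _flexion_shape(task: str, s: np.ndarray) -> np.ndarray:
    if task == "walk":
        # small loading-response bump in stance plus the large swing peak
        return 0.28 * _vm_bump(s, 0.15, 18.0) + 1.0 * _vm_bump(s, 0.72, 28.0)
    if task in ("squat", "sit_to_stand"):
        return _one_shot(s)
    if task in ("stair_ascent", "stair_descent"):
        g = _one_shot(s)
        return (1.0 + 0.18) * g / (g + 0.18)  # large excursion with plateau
    raise ValueError(f"unknown task {task!r}")


def _frontal_shape(task: str, s: np.ndarray) -> np.ndarray:
    if task == "walk":
        return np.sin(2 * np.pi * (s - 0.1))
    return np.sin(np.pi * s) ** 2


def _transverse_shape(task: str, s: np.ndarray) -> np.ndarray:
    if task == "walk":
        return np.sin(4 * np.pi * s) * 0.5 + np.sin(2 * np.pi * (s - 0.3)) * 0.5
    return np.sin(2 * np.pi * s) * np.sin(np.pi * s) ** 2


@dataclass(frozen=True)
class TaskTemplate:
    """Parametric single-cycle knee-angle waveform for one task.

    ``angles(t)`` evaluates the tri-planar truth (degrees) at times ``t``
    (seconds); the flexion ROM over one cycle equals ``target_rom_deg``
    exactly by construction, the out-of-plane ROMs are small (< 15 deg).
    """

    task: str
    duration_s: float
    target_rom_deg: float
    frontal_rom_deg: float = FRONTAL_ROM_DEG
    transverse_rom_deg: float = TRANSVERSE_ROM_DEG
    _scales: tuple = field(default=None, repr=False)  # (scale, offset) per plane

    def phase(self, t) -> np.ndarray:
        return (np.asarray(t, dtype=float) / self.duration_s) % 1.0

    def angles(self, t) -> np.ndarray:
        s = self.phase(t)
        sc = self._scales
        flex = _flexion_shape(self.task, s) * sc[0][0] + sc[0][1]
        fro = _frontal_shape(self.task, s) * sc[1][0] + sc[1][1]
        tra = _transverse_shape(self.task, s) * sc[2][0] + sc[2][1]
        return np.stack([flex, fro, tra], axis=-1)


def make_template(
    task: str,
    target_rom_deg: float | None = None,
    duration_s: float | None = None,
    frontal_rom_deg: float = FRONTAL_ROM_DEG,
    transverse_rom_deg: float = TRANSVERSE_ROM_DEG,
) -> TaskTemplate:
    """Build a task waveform template scaled to an exact flexion ROM.

    Walking is a double-bump gait pattern (stance flexion wave plus swing
    peak); squat and sit-to-stand are single smooth excursions; stair tasks a
    single large excursion with a plateau.  Defaults come from the cohort
    study conditions in :data:`TASK_DEFAULTS`.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if target_rom_deg is None:
        target_rom_deg = TASK_DEFAULTS[task]["rom_mean"]
    if duration_s is None:
        duration_s = TASK_DEFAULTS[task]["duration_s"]
    if target_rom_deg <= 0:
        raise ValueError("target ROM must be positive")
    if not 0.5 < duration_s < 10.0:
        raise ValueError(f"cycle duration {duration_s} s outside the plausible (0.5, 10) s range")
    s = np.linspace(0.0, 1.0, 4001)
    scales = []
    for shape_fn, rom, zero_min in (
        (_flexion_shape, target_rom_deg, True),
        (_frontal_shape, frontal_rom_deg, False),
        (_transverse_shape, transverse_rom_deg, False),
    ):
        raw = shape_fn(task, s)
        span = float(raw.max() - raw.min())
        scale = rom / span
        # flexion is kept non-negative; out-of-plane shapes stay centered
        offset = -float(raw.min()) * scale if zero_min else -float(raw.mean()) * scale
        scales.append((scale, offset))
    return TaskTemplate(
        task=task,
        duration_s=float(duration_s),
        target_rom_deg=float(target_rom_deg),
        frontal_rom_deg=float(frontal_rom_deg),
        transverse_rom_deg=float(transverse_rom_deg),
        _scales=tuple(scales),
    )


# ---------------------------------------------------------------------------
# Truth -> orientation streams


def _euler_to_quat(angles_deg: np.ndarray) -> np.ndarray:
    """Intrinsic XYZ Cardan angles (deg) -> quaternion, vectorized."""
    a = np.asarray(angles_deg, dtype=float)
    qx = rotation.quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), a[..., 0])
    qy = rotation.quat_from_axis_angle(np.array([0.0, 1.0, 0.0]), a[..., 1])
    qz = rotation.quat_from_axis_angle(np.array([0.0, 0.0, 1.0]), a[..., 2])
    return rotation.quat_multiply(rotation.quat_multiply(qx, qy), qz)


def _random_static(rng: np.random.Generator, max_deg: float = 20.0) -> np.ndarray:
    axis = rng.normal(size=3)
    return rotation.quat_from_axis_angle(axis, rng.uniform(-max_deg, max_deg))


def truth_to_orientations(
    truth: JointAngleSeries,
    thigh_static: np.ndarray | None = None,
    shank_static: np.ndarray | None = None,
    thigh_gain: float = -0.35,
) -> tuple[OrientationStream, OrientationStream]:
    """Thigh and shank orientation streams consistent with a truth angle series.

    The thigh moves smoothly in the world frame (rotation about the
    mediolateral axis proportional to knee flexion, gain ``thigh_gain``); the
    shank orientation is the thigh's motion composed with the joint rotation
    of the truth angles.  Running the clean output back through the angle
    pipeline recovers the truth to numerical precision; the absolute thigh
    motion only matters for how drift and soft-tissue errors interact with it.
    """
    t = truth.timestamps
    if thigh_static is None:
        thigh_static = np.array([1.0, 0.0, 0.0, 0.0])
    if shank_static is None:
        shank_static = np.array([1.0, 0.0, 0.0, 0.0])
    theta = thigh_gain * truth.flexion
    q_world = rotation.quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), theta)
    q_joint = _euler_to_quat(truth.angles_deg)
    q_thigh = rotation.quat_multiply(q_world, thigh_static)
    q_shank = rotation.quat_multiply(rotation.quat_multiply(q_world, q_joint), shank_static)
    mk = lambda seg, q: OrientationStream(
        segment=seg, timestamps=t, quaternions=q, sample_rate_hz=truth.sample_rate_hz
    )
    return mk("thigh", q_thigh), mk("shank", q_shank)


def _static_stream(segment: str, q_static: np.ndarray, rate: float = SAMPLE_RATE_HZ) -> OrientationStream:
    n = int(STATIC_DURATION_S * rate) + 1
    t = np.arange(n) / rate
    return OrientationStream(
        segment=segment, timestamps=t, quaternions=np.tile(q_static, (n, 1)), sample_rate_hz=rate
    )


# ---------------------------------------------------------------------------
# Sensor error model


@dataclass(frozen=True)
class NoiseConfig:
    """Magnitudes of the simulated IMU error sources (all >= 0, degrees).

    An all-zero configuration leaves streams bitwise unchanged.  The
    documented defaults for the two simulated methods are
    :data:`R_IMU_NOISE` and :data:`M_IMU_NOISE`.
    """

    white_noise_sd_deg: float = 0.0
    drift_sd_deg_per_sqrt_s: float = 0.0
    soft_tissue_amp_deg: float = 0.0
    #: Phase of the soft-tissue oscillation relative to the flexion cycle:
    #: 0 deg tracks flexion, 90 deg tracks flexion velocity.
    soft_tissue_phase_deg: float = 50.0
    calib_offset_deg: float = 0.0
    crosstalk_deg: float = 0.0
    #: Extra multiplier on drift/soft-tissue/crosstalk for stair tasks
    #: (instrumented-staircase electromagnetic disturbance).
    stair_disturbance_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "white_noise_sd_deg",
            "drift_sd_deg_per_sqrt_s",
            "soft_tissue_amp_deg",
            "calib_offset_deg",
            "crosstalk_deg",
            "stair_disturbance_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (
            self.white_noise_sd_deg == 0
            and self.drift_sd_deg_per_sqrt_s == 0
            and self.soft_tissue_amp_deg == 0
            and self.calib_offset_deg == 0
            and self.crosstalk_deg == 0
        )

    def for_task(self, task: str) -> "NoiseConfig":
        if task not in ("stair_ascent", "stair_descent") or self.stair_disturbance_scale == 1.0:
            return self
        k = self.stair_disturbance_scale
        return replace(
            self,
            drift_sd_deg_per_sqrt_s=self.drift_sd_deg_per_sqrt_s * k,
            soft_tissue_amp_deg=self.soft_tissue_amp_deg * k,
            crosstalk_deg=self.crosstalk_deg * k,
        )


#: Documented "paper-like" corruption levels for the raw-quaternion channel.
R_IMU_NOISE = NoiseConfig(
    white_noise_sd_deg=2.2,
    drift_sd_deg_per_sqrt_s=4.0,
    soft_tissue_amp_deg=8.0,
    calib_offset_deg=4.0,
    crosstalk_deg=12.0,
    stair_disturbance_scale=3.0,
)

#: The vendor-model channel: same physics, slightly smoothed magnitudes.
M_IMU_NOISE = NoiseConfig(
    white_noise_sd_deg=2.0,
    drift_sd_deg_per_sqrt_s=3.5,
    soft_tissue_amp_deg=7.5,
    calib_offset_deg=3.0,
    crosstalk_deg=10.0,
    stair_disturbance_scale=3.0,
)


def _random_walk_quat(
    rng: np.random.Generator, t: np.ndarray, sd_deg_sqrt_s: float
) -> np.ndarray:
    axis = rng.normal(size=3)
    dt = np.diff(t, prepend=t[0])
    steps = rng.normal(0.0, sd_deg_sqrt_s, size=len(t)) * np.sqrt(np.maximum(dt, 0.0))
    return rotation.quat_from_axis_angle(axis, np.cumsum(steps))


def _white_noise_quats(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    axes = rng.normal(size=(n, 3))
    angles = rng.normal(0.0, sd_deg, size=n)
    return rotation.quat_from_axis_angle(axes, angles)


def apply_sensor_errors(
    thigh: OrientationStream,
    shank: OrientationStream,
    thigh_static: OrientationStream,
    shank_static: OrientationStream,
    cfg: NoiseConfig,
    rng: np.random.Generator,
    flexion_ref: np.ndarray | None = None,
) -> tuple[OrientationStream, OrientationStream, OrientationStream, OrientationStream]:
    """Corrupt clean orientation streams with the configured error sources.

    Composition per dynamic stream: a fixed sensor-frame misalignment
    (right-multiplied on the motion trial only, so registration cannot cancel
    it — this is what produces axis crosstalk), a world-side random-walk drift
    rotation, a motion-correlated soft-tissue oscillation on the thigh, and
    per-sample white orientation noise.  The calibration-pose offset rotates
    the static shank recording as if the knee were flexed by
    ``calib_offset_deg`` during calibration, biasing subsequent flexion by a
    constant without touching ROM.  Static recordings receive white noise only.
    """
    if cfg.is_zero:
        return thigh, shank, thigh_static, shank_static

    def corrupt_dynamic(stream: OrientationStream, soft: bool) -> OrientationStream:
        q = stream.quaternions
        n = len(q)
        if cfg.crosstalk_deg > 0:
            mis = rotation.quat_from_axis_angle(rng.normal(size=3), cfg.crosstalk_deg)
            q = rotation.quat_multiply(q, mis)
        if cfg.drift_sd_deg_per_sqrt_s > 0:
            q = rotation.quat_multiply(
                _random_walk_quat(rng, stream.timestamps, cfg.drift_sd_deg_per_sqrt_s), q
            )
        if soft and cfg.soft_tissue_amp_deg > 0 and flexion_ref is not None:
            # skin lags the bone: an oscillation about (roughly) the thigh
            # flexion axis tracking the flexion cycle with a phase lag, signed
            # so that peak flexion is underestimated
            peak = np.max(np.abs(flexion_ref)) or 1.0
            fn = flexion_ref / peak
            vel = np.gradient(flexion_ref, stream.timestamps)
            vn = vel / (np.max(np.abs(vel)) or 1.0)
            phi = np.radians(cfg.soft_tissue_phase_deg)
            sta_angle = cfg.soft_tissue_amp_deg * (np.cos(phi) * fn + np.sin(phi) * vn)
            axis = np.array([1.0, 0.0, 0.0]) + 0.3 * rng.normal(size=3)
            sta = rotation.quat_from_axis_angle(axis, sta_angle)
            q = rotation.quat_multiply(q, sta)
        if cfg.white_noise_sd_deg > 0:
            q = rotation.quat_multiply(_white_noise_quats(rng, n, cfg.white_noise_sd_deg), q)
        return OrientationStream(
            segment=stream.segment,
            timestamps=stream.timestamps,
            quaternions=q,
            sample_rate_hz=stream.sample_rate_hz,
        )

    def corrupt_static(stream: OrientationStream, flexed: bool) -> OrientationStream:
        q = stream.quaternions
        if flexed and cfg.calib_offset_deg > 0:
            off = rotation.quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), cfg.calib_offset_deg)
            q = rotation.quat_multiply(off, q)
        if cfg.white_noise_sd_deg > 0:
            # fused orientation output is much quieter at rest than in motion
            q = rotation.quat_multiply(
                _white_noise_quats(rng, len(q), STATIC_NOISE_ATTENUATION * cfg.white_noise_sd_deg), q
            )
        return OrientationStream(
            segment=stream.segment,
            timestamps=stream.timestamps,
            quaternions=q,
            sample_rate_hz=stream.sample_rate_hz,
        )

    return (
        corrupt_dynamic(thigh, soft=True),
        corrupt_dynamic(shank, soft=False),
        corrupt_static(thigh_static, flexed=False),
        corrupt_static(shank_static, flexed=True),
    )


# ---------------------------------------------------------------------------
# Ground reaction force


def generate_grf(
    task: str,
    stance_windows: list[tuple[float, float]],
    body_weight_n: float,
    duration_s: float,
    sample_rate_hz: float = GRF_RATE_HZ,
) -> GRFSeries:
    """Vertical GRF with stance-shaped force inside the requested windows.

    Gait tasks produce a smooth double-hump stance waveform peaking at the
    body-weight parameter, exactly zero in swing, with stance boundaries at
    the requested events.  Squat and sit-to-stand produce body weight with a
    smooth dip during each movement window (the subject never leaves the
    plate), so no gait events arise.
    """
    n = int(round(duration_s * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz
    f = np.zeros(n)
    if task in ("squat", "sit_to_stand"):
        f[:] = body_weight_n
        for t0, t1 in stance_windows:
            s = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
            f -= 0.2 * body_weight_n * np.sin(np.pi * s) ** 2
        return GRFSeries(timestamps=t, force_n=f, sample_rate_hz=sample_rate_hz)
    for t0, t1 in stance_windows:
        if t1 <= t0:
            raise ValueError("stance window end must follow start")
        inside = (t >= t0) & (t <= t1)
        s = (t[inside] - t0) / (t1 - t0)
        # sub-linear exponent steepens foot contact and lift-off so the
        # threshold crossing stays within a millisecond of the true event
        shape = np.sin(np.pi * s) ** 0.7 * (1.0 + 0.25 * np.cos(2.0 * np.pi * s))
        peak = np.max(shape) if np.max(shape) > 0 else 1.0
        f[inside] = np.maximum(f[inside], body_weight_n * shape / peak)
    return GRFSeries(timestamps=t, force_n=f, sample_rate_hz=sample_rate_hz)


# ---------------------------------------------------------------------------
# Trials and cohorts


@dataclass
class SyntheticTrial:
    """One participant x task recording with clean and corrupted channels.

    ``channels`` maps a method label ("clean", "r_IMU", "m_IMU", ...) to a
    dict with keys ``thigh, shank, thigh_static, shank_static``.
    """

    participant: str
    task: str
    truth: JointAngleSeries
    channels: dict
    grf: GRFSeries
    stance_windows: list[tuple[float, float]]
    template: TaskTemplate
    repetitions: int


def _trial_truth(template: TaskTemplate, repetitions: int) -> tuple[JointAngleSeries, list[tuple[float, float]]]:
    """Assemble the full-trial truth series and true stance/movement windows."""
    task, T = template.task, template.duration_s
    rate = SAMPLE_RATE_HZ
    if task in ("walk", "stair_ascent", "stair_descent"):
        # one extra stance so that `repetitions` strike-to-strike cycles
        # exist, plus lead-in/out keeping events off the filter edges
        lead = 0.3
        stance = STANCE_FRACTION[task]
        total = lead + (repetitions + stance) * T + 0.3
        n = int(round(total * rate)) + 1
        t = np.arange(n) / rate
        ang = template.angles(t - lead)
        windows = [(lead + k * T, lead + (k + stance) * T) for k in range(repetitions + 1)]
    else:
        total = REST_GAP_S + repetitions * (T + REST_GAP_S)
        n = int(round(total * rate)) + 1
        t = np.arange(n) / rate
        ang = np.zeros((n, 3))
        windows = []
        for k in range(repetitions):
            t0 = REST_GAP_S + k * (T + REST_GAP_S)
            mask = (t >= t0) & (t <= t0 + T)
            ang[mask] = template.angles(t[mask] - t0)
            windows.append((t0, t0 + T))
    return (
        JointAngleSeries(
            timestamps=t, angles_deg=ang, gimbal=np.zeros(len(t), bool), sample_rate_hz=rate
        ),
        windows,
    )


def generate_trial(
    template: TaskTemplate,
    rng: np.random.Generator,
    participant: str = "P01",
    repetitions: int = 5,
    body_weight_n: float = BODY_MASS_MEAN_KG * GRAVITY,
    noise_configs: dict | None = None,
) -> SyntheticTrial:
    """Generate one trial: truth, clean streams, corrupted channels, GRF.

    ``noise_configs`` maps method labels to :class:`NoiseConfig`; the clean
    channel is always present under the label ``"clean"``.
    """
    truth, windows = _trial_truth(template, repetitions)
    thigh_static_q = _random_static(rng)
    shank_static_q = _random_static(rng)
    thigh, shank = truth_to_orientations(truth, thigh_static_q, shank_static_q)
    thigh_cal = _static_stream("thigh", thigh_static_q)
    shank_cal = _static_stream("shank", shank_static_q)
    channels = {
        "clean": {
            "thigh": thigh,
            "shank": shank,
            "thigh_static": thigh_cal,
            "shank_static": shank_cal,
        }
    }
    for method, cfg in (noise_configs or {}).items():
        th, sh, thc, shc = apply_sensor_errors(
            thigh,
            shank,
            thigh_cal,
            shank_cal,
            cfg.for_task(template.task),
            rng,
            flexion_ref=truth.flexion,
        )
        channels[method] = {"thigh": th, "shank": sh, "thigh_static": thc, "shank_static": shc}
    grf = generate_grf(template.task, windows, body_weight_n, float(truth.timestamps[-1]))
    return SyntheticTrial(
        participant=participant,
        task=template.task,
        truth=truth,
        channels=channels,
        grf=grf,
        stance_windows=windows,
        template=template,
        repetitions=repetitions,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level study conditions: sizes, tasks, and corruption levels."""

    n_participants: int = 21
    tasks: tuple = TASKS
    repetitions: int = 5
    noise_configs: dict = field(
        default_factory=lambda: {"r_IMU": R_IMU_NOISE, "m_IMU": M_IMU_NOISE}
    )
    frontal_rom_deg: float = FRONTAL_ROM_DEG
    transverse_rom_deg: float = TRANSVERSE_ROM_DEG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("cohort needs at least one participant")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown task(s): {sorted(unknown)}")


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[SyntheticTrial]:
    """Generate all trials of a cohort, reproducibly from ``spec.seed``.

    Per participant and task the sagittal ROM is drawn from the task's cohort
    distribution (truncated at 20 deg), the cycle duration jittered ±10%, and
    body weight drawn from the cohort's mass distribution.
    """
    rng = np.random.default_rng(spec.seed)
    trials: list[SyntheticTrial] = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        mass = max(float(rng.normal(BODY_MASS_MEAN_KG, BODY_MASS_SD_KG)), 45.0)
        for task in spec.tasks:
            d = TASK_DEFAULTS[task]
            rom = max(float(rng.normal(d["rom_mean"], d["rom_sd"])), 20.0)
            duration = d["duration_s"] * float(rng.uniform(0.9, 1.1))
            template = make_template(
                task,
                target_rom_deg=rom,
                duration_s=duration,
                frontal_rom_deg=spec.frontal_rom_deg,
                transverse_rom_deg=spec.transverse_rom_deg,
            )
            trials.append(
                generate_trial(
                    template,
                    rng,
                    participant=pid,
                    repetitions=spec.repetitions,
                    body_weight_n=mass * GRAVITY,
                    noise_configs=spec.noise_configs,
                )
            )
    return trials
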