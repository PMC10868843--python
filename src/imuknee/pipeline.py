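"""From orientation streams and ground reaction force to normalized knee-angle cycles.

The processing chain mirrors standard practice in human movement analysis:

1. resample thigh and shank orientation streams onto a common 200 Hz timebase
   and compute the calibrated thigh-to-shank rotation per sample;
2. decompose into Cardan XYZ knee angles (flexion, adduction, internal rotation);
3. identify movement cycles — from vertical ground reaction force threshold
   crossings for gait tasks, from the flexion angular-speed profile for squat
   and sit-to-stand;
4. time-align channels by cross-correlation on the flexion curve, cubic-spline
   resample each cycle to 101 points (0–100 % of cycle), and optionally
   subtract the trial mean so that a mis-calibrated neutral posture does not
   masquerade as joint-angle error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from . import rotation
from .rotation import CalibrationRecord

__all__ = [
    "FilterSpec",
    "OrientationStream",
    "GRFSeries",
    "JointAngleSeries",
    "GaitEvent",
    "MovementCycle",
    "NormalizedCurve",
    "butterworth_lowpass",
    "compute_knee_angles",
    "detect_gait_events",
    "detect_task_bounds",
    "cycles_from_gait_events",
    "time_align",
    "resample_to_101",
    "mean_center",
    "normalize_cycle",
]

TASKS = ("walk", "squat", "sit_to_stand", "stair_ascent", "stair_descent")
PLANES = ("sagittal", "frontal", "transverse")

#: Tasks whose cycles are bounded by force-plate gait events.
GAIT_TASKS = ("walk", "stair_ascent", "stair_descent")

#: Default vertical-force threshold for gait event detection (N).
GRF_THRESHOLD_N = 20.0
#: Minimum spacing between successive gait events (s).
GRF_HYSTERESIS_S = 0.05
#: Flexion angular-speed threshold bounding squat / sit-to-stand cycles (deg/s).
TASK_SPEED_THRESHOLD_DEG_S = 5.0
#: Minimum flexion excursion for a candidate squat / sit-to-stand cycle (deg).
TASK_MIN_EXCURSION_DEG = 20.0
#: Plausibility bounds on cycle duration (s).
CYCLE_DURATION_BOUNDS_S = (0.5, 10.0)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings (6 Hz, 2nd order, zero-phase)."""

    cutoff_hz: float = 6.0
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class OrientationStream:
    """Unit-quaternion orientation time series for one body segment."""

    segment: str
    timestamps: np.ndarray
    quaternions: np.ndarray
    sample_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.timestamps.ndim != 1 or self.quaternions.shape != (len(self.timestamps), 4):
            raise ValueError("timestamps must be (N,) and quaternions (N, 4)")
        if len(self.timestamps) == 0:
            raise ValueError(f"empty orientation stream for segment {self.segment!r}")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError(f"timestamps must be strictly increasing ({self.segment})")
        self.quaternions = rotation.sign_continuous(
            rotation.quat_normalize(self.quaternions, enforce_w_positive=False)
        )
        if len(self.timestamps) > 1:
            actual = (len(self.timestamps) - 1) / (self.timestamps[-1] - self.timestamps[0])
            if abs(actual - self.sample_rate_hz) / self.sample_rate_hz > 0.01:
                warnings.warn(
                    f"{self.segment}: actual rate {actual:.1f} Hz deviates >1% from nominal "
                    f"{self.sample_rate_hz:.1f} Hz",
                    stacklevel=2,
                )

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class GRFSeries:
    """Vertical ground reaction force (N), nominally 1000 Hz."""

    timestamps: np.ndarray
    force_n: np.ndarray
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.timestamps.shape != self.force_n.shape or self.timestamps.ndim != 1:
            raise ValueError("timestamps and force must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.force_n)):
            raise ValueError("force values must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")


@dataclass
class JointAngleSeries:
    """Tri-planar knee angles (degrees) with per-sample gimbal flags.

    ``angles_deg[:, 0]`` is flexion (sagittal), ``[:, 1]`` adduction
    (frontal), ``[:, 2]`` internal rotation (transverse).
    """

    timestamps: np.ndarray
    angles_deg: np.ndarray
    gimbal: np.ndarray
    sample_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.gimbal = np.asarray(self.gimbal, dtype=bool)
        n = len(self.timestamps)
        if self.angles_deg.shape != (n, 3) or self.gimbal.shape != (n,):
            raise ValueError("angles must be (N, 3) and gimbal flags (N,)")
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("angles must be finite")

    def plane(self, name: str) -> np.ndarray:
        return self.angles_deg[:, PLANES.index(name)]

    @property
    def flexion(self) -> np.ndarray:
        return self.angles_deg[:, 0]


@dataclass(frozen=True)
class GaitEvent:
    label: str  # "heel_strike" | "toe_off"
    time_s: float


@dataclass(frozen=True)
class MovementCycle:
    """One movement cycle as an index range into a JointAngleSeries."""

    task: str
    start: int
    end: int
    events: tuple[GaitEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.start < self.end:
            raise ValueError("cycle start must precede end")


@dataclass
class NormalizedCurve:
    """A 101-sample movement-cycle waveform on the 0–100 % cycle grid."""

    values: np.ndarray
    plane: str = "sagittal"
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError(f"normalized curve must have exactly 101 samples, got {self.values.shape}")
        if self.centered and abs(float(self.values.mean())) > 1e-9:
            raise ValueError("curve flagged as centered but mean is nonzero")

    @property
    def percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, 101)


# ---------------------------------------------------------------------------
# Filtering


def butterworth_lowpass(values, sample_rate_hz: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass Butterworth filter; zero-phase (forward-backward) by default.

    Note that forward-backward application squares the magnitude response, so
    the effective attenuation at the cutoff is -6 dB rather than -3 dB.
    """
    values = np.asarray(values, dtype=float)
    nyquist = sample_rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    b, a = butter(spec.order, spec.cutoff_hz / nyquist, btype="low")
    if spec.zero_phase:
        return filtfilt(b, a, values, axis=-1)
    from scipy.signal import lfilter

    return lfilter(b, a, values, axis=-1)


# ---------------------------------------------------------------------------
# Angle computation


def _interp_quat(stream: OrientationStream, t: np.ndarray) -> np.ndarray:
    """Sample a sign-continuous quaternion stream at times ``t`` by
    component-wise linear interpolation + renormalization (adequate for the
    dense 200 Hz streams this pipeline consumes)."""
    qs = stream.quaternions
    out = np.empty((len(t), 4))
    for i in range(4):
        out[:, i] = np.interp(t, stream.timestamps, qs[:, i])
    return rotation.quat_normalize(out, enforce_w_positive=False)


def compute_knee_angles(
    thigh: OrientationStream,
    shank: OrientationStream,
    calib: CalibrationRecord,
    sample_rate_hz: float = 200.0,
) -> JointAngleSeries:
    """Tri-planar knee angles from calibrated thigh and shank orientations.

    Streams are resampled onto a common uniform timebase spanning their
    temporal overlap; the overlap must cover at least half of the shorter
    stream.
    """
    t0 = max(thigh.timestamps[0], shank.timestamps[0])
    t1 = min(thigh.timestamps[-1], shank.timestamps[-1])
    if t1 <= t0:
        raise ValueError("thigh and shank streams have disjoint time ranges")
    shorter = min(thigh.duration, shank.duration)
    if shorter > 0 and (t1 - t0) / shorter < 0.5:
        raise ValueError(
            f"streams overlap only {t1 - t0:.2f} s of {shorter:.2f} s (<50%); "
            "check stream synchronization"
        )
    n = max(int(round((t1 - t0) * sample_rate_hz)) + 1, 2)
    t = t0 + np.arange(n) / sample_rate_hz
    t = t[t <= t1 + 1e-9]
    q_thigh = _interp_quat(thigh, t)
    q_shank = _interp_quat(shank, t)
    J = rotation.relative_knee_rotation(q_thigh, q_shank, calib)
    angles, gimbal = rotation.matrix_to_euler_xyz(J)
    return JointAngleSeries(timestamps=t, angles_deg=angles, gimbal=gimbal, sample_rate_hz=sample_rate_hz)


# ---------------------------------------------------------------------------
# Event detection and segmentation


def detect_gait_events(
    grf: GRFSeries,
    threshold_n: float = GRF_THRESHOLD_N,
    filter_spec: FilterSpec = FilterSpec(),
    hysteresis_s: float = GRF_HYSTERESIS_S,
) -> list[GaitEvent]:
    """Heel-strike / toe-off instants from vertical GRF threshold crossings.

    The force channel is low-pass filtered and upward crossings of the
    threshold are labelled heel-strike, downward crossings toe-off; crossings
    closer than ``hysteresis_s`` to the previous accepted event are discarded,
    which with alternation suppresses chatter around the threshold.  Each
    accepted instant is then refined to the nearest same-direction crossing of
    the *unfiltered* channel, so that event timing does not drift with force
    amplitude (zero-phase smoothing stretches the loading edge, moving the
    threshold crossing of the filtered trace when the force is scaled).
    """
    raw = grf.force_n
    f = butterworth_lowpass(raw, grf.sample_rate_hz, filter_spec)

    def crossings(sig: np.ndarray) -> np.ndarray:
        return np.flatnonzero(np.diff((sig > threshold_n).astype(int)))

    def cross_time(sig: np.ndarray, idx: int) -> float:
        f0, f1 = sig[idx], sig[idx + 1]
        frac = (threshold_n - f0) / (f1 - f0) if f1 != f0 else 0.5
        return float(grf.timestamps[idx] + frac * (grf.timestamps[idx + 1] - grf.timestamps[idx]))

    raw_idx = crossings(raw)
    events: list[GaitEvent] = []
    last_t = -np.inf
    for idx in crossings(f):
        rising = f[idx + 1] > f[idx]
        t_cross = cross_time(f, idx)
        # refine on the raw channel: nearest raw crossing in the same direction
        same_dir = raw_idx[(raw[raw_idx + 1] > raw[raw_idx]) == rising]
        if len(same_dir):
            nearest = same_dir[np.argmin(np.abs(same_dir - idx))]
            if abs(grf.timestamps[nearest] - t_cross) < 0.1:
                t_cross = cross_time(raw, int(nearest))
        label = "heel_strike" if rising else "toe_off"
        if t_cross - last_t < hysteresis_s:
            continue
        if events and events[-1].label == label:
            continue  # enforce strict alternation
        events.append(GaitEvent(label, float(t_cross)))
        last_t = t_cross
    if not events:
        warnings.warn("no gait events found (force never crosses threshold)", stacklevel=2)
    return events


def cycles_from_gait_events(
    angles: JointAngleSeries, events: list[GaitEvent], task: str
) -> list[MovementCycle]:
    """Build movement cycles from gait events on the kinematic timebase.

    Walking cycles span heel-strike to the next ipsilateral heel-strike when
    two or more heel-strikes are present; otherwise (single force plate or
    instrumented stair step) one cycle spans heel-strike to toe-off plus the
    swing until the end of data or the next event.  Event times are mapped to
    the 200 Hz kinematic grid by nearest-sample rounding.
    """
    hs = [e.time_s for e in events if e.label == "heel_strike"]
    to = [e.time_s for e in events if e.label == "toe_off"]
    t = angles.timestamps
    lo, hi = CYCLE_DURATION_BOUNDS_S
    cycles: list[MovementCycle] = []

    def nearest(time_s: float) -> int:
        return int(np.argmin(np.abs(t - time_s)))

    if len(hs) >= 2:
        bounds = list(zip(hs[:-1], hs[1:]))
    elif len(hs) == 1:
        end_time = min(t[-1], hs[0] + hi)
        nxt = [x for x in to if x > hs[0]]
        if nxt:  # extend past toe-off by the stance duration as a swing proxy
            end_time = min(t[-1], nxt[0] + (nxt[0] - hs[0]))
        bounds = [(hs[0], end_time)]
    else:
        bounds = []
    for b0, b1 in bounds:
        i0, i1 = nearest(b0), nearest(b1)
        if i1 <= i0:
            continue
        dur = t[i1] - t[i0]
        if lo <= dur <= hi:
            evs = tuple(e for e in events if b0 - 1e-9 <= e.time_s <= b1 + 1e-9)
            cycles.append(MovementCycle(task=task, start=i0, end=i1, events=evs))
    return cycles


def detect_task_bounds(
    angles: JointAngleSeries,
    task: str,
    velocity_threshold_deg_s: float = TASK_SPEED_THRESHOLD_DEG_S,
    min_excursion_deg: float = TASK_MIN_EXCURSION_DEG,
    filter_spec: FilterSpec = FilterSpec(),
) -> list[MovementCycle]:
    """Bound squat / sit-to-stand cycles from the flexion angular-speed profile.

    Each flexion excursion exceeding ``min_excursion_deg`` yields one cycle
    whose bounds are where the smoothed flexion angular speed last/first
    crosses ``velocity_threshold_deg_s`` on either side of the excursion peak.
    """
    if task not in ("squat", "sit_to_stand"):
        raise ValueError("task-bound detection applies to squat and sit_to_stand only")
    flex = butterworth_lowpass(angles.flexion, angles.sample_rate_hz, filter_spec)
    speed = np.abs(np.gradient(flex, angles.timestamps))
    peaks, _ = find_peaks(flex, prominence=min_excursion_deg)
    if len(peaks) == 0:
        warnings.warn("no movement cycles found (flexion excursion below threshold)", stacklevel=2)
        return []
    slow = speed < velocity_threshold_deg_s
    cycles: list[MovementCycle] = []
    lo, hi = CYCLE_DURATION_BOUNDS_S
    prev_end = 0
    last = len(flex) - 1
    for p in peaks:
        # walk outward from the peak: skip the slow region at the apex, cross
        # the fast rise/fall, and stop where speed drops below threshold again
        i = p
        while i > 0 and slow[i]:
            i -= 1
        while i > 0 and not slow[i]:
            i -= 1
        start = i
        j = p
        while j < last and slow[j]:
            j += 1
        while j < last and not slow[j]:
            j += 1
        end = j
        start = max(start, prev_end)
        dur = angles.timestamps[end] - angles.timestamps[start]
        if start < end and lo <= dur <= hi:
            cycles.append(MovementCycle(task=task, start=start, end=end))
            prev_end = end
    return cycles


# ---------------------------------------------------------------------------
# Alignment and time normalization


def time_align(a, b, max_lag: int | None = None) -> tuple[int, float]:
    """Lag (in samples) of ``b`` relative to ``a`` by normalized cross-correlation.

    Returns ``(lag, peak)``: the lag within ``±max_lag`` maximizing the
    normalized cross-correlation of the mean-removed curves (so that
    ``b[i] ≈ a[i - lag]`` at the optimum; a positive lag means ``b`` is
    delayed).  Ties break toward the smallest ``|lag|``.  A peak below 0.5
    triggers a low-correlation warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("curves must have at least 10 samples to align")
    if max_lag is None:
        max_lag = min(len(a), len(b)) // 2
    a0 = a - a.mean()
    b0 = b - b.mean()
    if np.allclose(a0, 0) or np.allclose(b0, 0):
        raise ValueError("cannot align zero-variance curves")
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a0, b0[lag:]
        else:
            x, y = a0[-lag:], b0
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if n < 2:
            corr[i] = 0.0
            continue
        denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
        corr[i] = np.sum(x * y) / denom if denom > 0 else 0.0
    # argmax with ties broken toward |lag| smallest: sort keys (−corr, |lag|)
    order = np.lexsort((np.abs(lags), -corr))
    best = order[0]
    lag, peak = int(lags[best]), float(corr[best])
    if peak < 0.5:
        warnings.warn(f"low peak cross-correlation ({peak:.2f}); alignment unreliable", stacklevel=2)
    return lag, peak


def resample_to_101(values, plane: str = "sagittal") -> NormalizedCurve:
    """Cubic-spline interpolation of one cycle onto 101 equispaced points
    spanning 0–100 % of the cycle (endpoints inclusive)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise ValueError("need a 1-D curve with at least 4 samples for cubic-spline resampling")
    x = np.linspace(0.0, 1.0, len(values))
    out = CubicSpline(x, values)(np.linspace(0.0, 1.0, 101))
    return NormalizedCurve(values=out, plane=plane, centered=False)


def mean_center(curve: NormalizedCurve) -> NormalizedCurve:
    """Subtract the curve mean (idempotent); sets the ``centered`` flag."""
    return replace(curve, values=curve.values - curve.values.mean(), centered=True)


def normalize_cycle(
    angles: JointAngleSeries, cycle: MovementCycle, center: bool = False
) -> dict[str, NormalizedCurve]:
    """Per-plane 101-point curves for one movement cycle."""
    out: dict[str, NormalizedCurve] = {}
    for plane in PLANES:
        seg = angles.plane(plane)[cycle.start : cycle.end + 1]
        curve = resample_to_101(seg, plane=plane)
        out[plane] = mean_center(curve) if center else curve
    return out
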