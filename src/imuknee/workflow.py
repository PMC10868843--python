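"""End-to-end orchestration: trials in, normalized angle tables and statistics out.

Glue between the synthetic generator (or imported recordings), the kinematics
pipeline, and the agreement statistics.  The central interchange object is the
*angle table*: one row per participant x task x method x plane with 101
percent-of-cycle columns ``pct_0 ... pct_100`` — the layout used by deposited
per-cycle angle datasets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import pipeline, stats
from .pipeline import (
    GAIT_TASKS,
    PLANES,
    JointAngleSeries,
    MovementCycle,
    NormalizedCurve,
)
from .rotation import register_calibration
from .synthetic import SyntheticTrial

__all__ = [
    "compute_channel_angles",
    "segment_trial",
    "process_trial",
    "cohort_to_angle_table",
    "analyze_cohort",
]

#: Methods whose deposited tables carry only the sagittal plane (the vendor
#: kinematic model computes sagittal knee angles only).
SAGITTAL_ONLY_METHODS = ("m_IMU",)


def compute_channel_angles(trial: SyntheticTrial, method: str) -> JointAngleSeries:
    """Calibrate one channel from its static recording and compute knee angles."""
    ch = trial.channels[method]
    calib = register_calibration(ch["thigh_static"], ch["shank_static"])
    return pipeline.compute_knee_angles(ch["thigh"], ch["shank"], calib)


def segment_trial(trial: SyntheticTrial, angles: JointAngleSeries) -> list[MovementCycle]:
    """Movement cycles for a trial: gait events from GRF for walking and stair
    tasks, flexion angular-speed bounds for squat and sit-to-stand."""
    if trial.task in GAIT_TASKS:
        events = pipeline.detect_gait_events(trial.grf)
        return pipeline.cycles_from_gait_events(angles, events, trial.task)
    return pipeline.detect_task_bounds(angles, trial.task)


def _cycle_to_times(angles: JointAngleSeries, cycle: MovementCycle) -> tuple[float, float]:
    return float(angles.timestamps[cycle.start]), float(angles.timestamps[cycle.end])


def _extract(angles: JointAngleSeries, t0: float, t1: float, lag_s: float = 0.0) -> np.ndarray:
    """Index range of ``angles`` covering [t0, t1] shifted by ``lag_s``."""
    t = angles.timestamps
    i0 = int(np.argmin(np.abs(t - (t0 + lag_s))))
    i1 = int(np.argmin(np.abs(t - (t1 + lag_s))))
    return angles.angles_deg[i0 : i1 + 1]


def process_trial(
    trial: SyntheticTrial,
    methods: tuple = ("clean",),
    reference: str = "truth",
    center: bool = False,
    align: bool = True,
) -> dict:
    """Segment one trial and produce per-cycle 101-point curves per channel.

    The reference channel (ground-truth angles, playing the optical-capture
    role) defines the cycle boundaries; each requested method channel is
    cross-correlation aligned to the reference on the flexion trace (the lag
    is applied to all three planes), then each cycle is spline-resampled to
    101 points.

    Returns ``{"cycles": [...], "curves": {method: [ {plane: NormalizedCurve}
    per cycle ]}, "representative": index}`` where the representative cycle is
    the middle repetition (steady-state, mirroring the single representative
    trial analysed per participant and task).
    """
    ref_angles = trial.truth if reference == "truth" else compute_channel_angles(trial, reference)
    cycles = segment_trial(trial, ref_angles)
    if not cycles:
        warnings.warn(f"no cycles found in {trial.participant}/{trial.task}", stacklevel=2)
        return {"cycles": [], "curves": {}, "representative": None}
    curves: dict[str, list[dict[str, NormalizedCurve]]] = {"truth": []}
    for cyc in cycles:
        curves["truth"].append(pipeline.normalize_cycle(ref_angles, cyc, center=center))
    for method in methods:
        ang = compute_channel_angles(trial, method)
        lag_s = 0.0
        if align:
            n = min(len(ref_angles.flexion), len(ang.flexion))
            max_lag = min(n // 4, int(0.5 * ang.sample_rate_hz))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lag, _ = pipeline.time_align(
                        ref_angles.flexion[:n], ang.flexion[:n], max_lag=max_lag
                    )
                lag_s = lag / ang.sample_rate_hz
            except ValueError:
                lag_s = 0.0
        out = []
        for cyc in cycles:
            t0, t1 = _cycle_to_times(ref_angles, cyc)
            seg = _extract(ang, t0, t1, lag_s)
            per_plane = {}
            for k, plane in enumerate(PLANES):
                curve = pipeline.resample_to_101(seg[:, k], plane=plane)
                per_plane[plane] = pipeline.mean_center(curve) if center else curve
            out.append(per_plane)
        curves[method] = out
    return {"cycles": cycles, "curves": curves, "representative": len(cycles) // 2}


METHOD_LABELS = {"truth": "OMC", "clean": "clean"}


def cohort_to_angle_table(
    trials: list[SyntheticTrial],
    methods: tuple = ("r_IMU", "m_IMU"),
    center: bool = False,
) -> pd.DataFrame:
    """Representative-cycle angle table for a cohort (S1-style layout).

    One row per participant x task x method x plane; the truth channel is
    labelled ``OMC`` (it plays the optical reference role) and sagittal-only
    methods contribute only their sagittal row.
    """
    rows = []
    for trial in trials:
        available = tuple(m for m in methods if m in trial.channels)
        res = process_trial(trial, methods=available, center=center)
        rep = res["representative"]
        if rep is None:
            continue
        for method, per_cycle in res["curves"].items():
            label = METHOD_LABELS.get(method, method)
            planes = PLANES if label not in SAGITTAL_ONLY_METHODS else ("sagittal",)
            for plane in planes:
                curve = per_cycle[rep][plane]
                row = {
                    "participant": trial.participant,
                    "task": trial.task,
                    "method": label,
                    "plane": plane,
                }
                row.update({f"pct_{i}": v for i, v in enumerate(curve.values)})
                rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(trials: list[SyntheticTrial], methods: tuple = ("r_IMU", "m_IMU")) -> dict:
    """Full analysis of a cohort: angle table -> agreement + ROM statistics."""
    table = cohort_to_angle_table(trials, methods=methods)
    analysis = stats.analyze_angle_table(table, center=True)
    analysis["angle_table"] = table
    return analysis
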