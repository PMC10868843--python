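"""Rotation algebra and sensor-to-segment calibration.

Quaternions are scalar-first ``(w, x, y, z)``, Hamilton convention, and encode
the rotation from the segment (sensor) frame into the world frame.  Joint
angles use an intrinsic Cardan XYZ sequence: flexion about X (mediolateral
axis), adduction about Y (anteroposterior axis), internal rotation about Z
(longitudinal axis); positive values mean flexion, adduction, and internal
rotation.

All functions are vectorized over a leading batch axis: a "quaternion" is any
array of shape ``(..., 4)`` and a rotation matrix any array ``(..., 3, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateQuaternionError",
    "NonStaticCalibrationError",
    "CalibrationRecord",
    "quat_normalize",
    "quat_conjugate",
    "quat_multiply",
    "quat_rotate_vector",
    "quat_to_matrix",
    "matrix_to_euler_xyz",
    "euler_xyz_to_matrix",
    "quat_from_axis_angle",
    "quat_angle_between",
    "sign_continuous",
    "quat_mean",
    "register_calibration",
    "relative_knee_rotation",
]

#: |adduction| closer than this (degrees) to 90 raises the gimbal flag.
GIMBAL_PROXIMITY_DEG = 0.5

#: Residual static motion above this (degrees) rejects a calibration window.
MAX_STATIC_MOTION_DEG = 5.0


class DegenerateQuaternionError(ValueError):
    """Quaternion norm too small to define a rotation."""


class NonStaticCalibrationError(ValueError):
    """The calibration window contains too much motion to be a static pose."""


def quat_normalize(q, *, enforce_w_positive: bool = True) -> np.ndarray:
    """Normalize to unit length, resolving the double cover with ``w >= 0``.

    ``q`` and ``-q`` encode the same rotation; for isolated quaternions the
    representative with non-negative scalar part is chosen.  For time series
    use :func:`sign_continuous` instead, which preserves continuity.

    Raises
    ------
    DegenerateQuaternionError
        If any norm is below 1e-12.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"expected (..., 4) quaternion array, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("quaternion components must be finite")
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise DegenerateQuaternionError("quaternion norm below 1e-12")
    out = q / norm
    if enforce_w_positive:
        flip = out[..., :1] < 0.0
        out = np.where(flip, -out, out)
    return out


def quat_conjugate(q) -> np.ndarray:
    """Conjugate (inverse for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (apply ``b`` first, then ``a``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
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


def quat_rotate_vector(q, v) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` via ``q v q*``."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return quat_multiply(quat_multiply(q, qv), quat_conjugate(q))[..., 1:]


def _check_unit(q: np.ndarray, tol: float = 1e-6) -> None:
    err = np.abs(np.linalg.norm(q, axis=-1) - 1.0)
    if np.any(err > tol):
        raise ValueError(
            f"quaternion not unit norm (max deviation {float(np.max(err)):.3g} > {tol:g}); "
            "normalize first"
        )


def quat_to_matrix(q) -> np.ndarray:
    """Convert unit quaternion(s) to rotation matrix/matrices.

    The matrix maps segment-frame vectors into the world frame.  Input must be
    unit within 1e-6.
    """
    q = np.asarray(q, dtype=float)
    _check_unit(q)
    w, x, y, z = (q[..., i] for i in range(4))
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1)
    row1 = np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1)
    row2 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def matrix_to_quat(R) -> np.ndarray:
    """Inverse of :func:`quat_to_matrix` (Shepperd's method), ``w >= 0``."""
    R = np.asarray(R, dtype=float)
    _check_rotation(R)
    batch = R.shape[:-2]
    Rf = R.reshape((-1, 3, 3))
    out = np.empty((Rf.shape[0], 4))
    for i, m in enumerate(Rf):
        tr = np.trace(m)
        # pick the largest diagonal element for numerical stability
        choices = np.array([tr, m[0, 0], m[1, 1], m[2, 2]])
        k = int(np.argmax(choices))
        if k == 0:
            s = np.sqrt(tr + 1.0) * 2.0
            q = np.array(
                [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
            )
        elif k == 1:
            s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2.0
            q = np.array(
                [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
            )
        elif k == 2:
            s = np.sqrt(1.0 - m[0, 0] + m[1, 1] - m[2, 2]) * 2.0
            q = np.array(
                [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
            )
        else:
            s = np.sqrt(1.0 - m[0, 0] - m[1, 1] + m[2, 2]) * 2.0
            q = np.array(
                [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
            )
        out[i] = q
    return quat_normalize(out.reshape(batch + (4,)))


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) matrix, got shape {R.shape}")
    eye = np.eye(3)
    ortho = np.abs(np.swapaxes(R, -1, -2) @ R - eye)
    det = np.linalg.det(R)
    if np.any(ortho > tol) or np.any(np.abs(det - 1.0) > tol):
        raise ValueError("matrix is not a proper rotation (orthonormal, det +1)")


def matrix_to_euler_xyz(R) -> tuple[np.ndarray, np.ndarray]:
    """Decompose rotation(s) into intrinsic Cardan XYZ angles, in degrees.

    Returns ``(angles, gimbal)`` where ``angles[..., :]`` is (flexion,
    adduction, internal rotation) and ``gimbal`` is a boolean flag raised when
    the middle (Y) angle is within 0.5 degrees of ±90, i.e. near the Cardan
    singularity where the X and Z axes align and the decomposition degrades.

    For ``R = Rx(a) · Ry(b) · Rz(c)``:
    ``R[0,2] = sin b``, ``a = atan2(-R[1,2], R[2,2])``, ``c = atan2(-R[0,1], R[0,0])``.
    """
    R = np.asarray(R, dtype=float)
    _check_rotation(R)
    sy = np.clip(R[..., 0, 2], -1.0, 1.0)
    b = np.arcsin(sy)
    a = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    c = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    angles = np.degrees(np.stack([a, b, c], axis=-1))
    gimbal = np.abs(np.abs(angles[..., 1]) - 90.0) < GIMBAL_PROXIMITY_DEG
    return angles, gimbal


def euler_xyz_to_matrix(angles_deg) -> np.ndarray:
    """Compose intrinsic XYZ Cardan angles (degrees) into rotation matrices."""
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    a, b, c = (ang[..., i] for i in range(3))
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    # Rx(a) @ Ry(b) @ Rz(c), written out
    row0 = np.stack([cb * cc, -cb * sc, sb], axis=-1)
    row1 = np.stack([ca * sc + sa * sb * cc, ca * cc - sa * sb * sc, -sa * cb], axis=-1)
    row2 = np.stack([sa * sc - ca * sb * cc, sa * cc + ca * sb * sc, ca * cb], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def quat_from_axis_angle(axis, angle_deg) -> np.ndarray:
    """Unit quaternion for rotation(s) of ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("rotation axis must be nonzero")
    axis = axis / n
    half = np.radians(np.asarray(angle_deg, dtype=float)) / 2.0
    w = np.cos(half)[..., None]
    xyz = axis * np.sin(half)[..., None]
    return np.concatenate([w, xyz], axis=-1)


def quat_angle_between(a, b) -> np.ndarray:
    """Geodesic angle (degrees) between two rotations given as quaternions."""
    dot = np.abs(np.sum(np.asarray(a) * np.asarray(b), axis=-1))
    return np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))


def sign_continuous(qs) -> np.ndarray:
    """Resolve the double cover along a stream: flip samples whose dot product
    with the previous (already-fixed) sample is negative."""
    qs = np.asarray(qs, dtype=float).copy()
    if qs.ndim != 2 or qs.shape[1] != 4:
        raise ValueError("expected an (N, 4) quaternion stream")
    dots = np.sum(qs[1:] * qs[:-1], axis=1)
    # cumulative parity of flips: a negative dot toggles the sign state
    flips = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    qs[1:] *= flips[:, None]
    return qs


def quat_mean(qs) -> np.ndarray:
    """Chordal mean of a quaternion stream: sign-align to the first sample,
    average component-wise, normalize.  Adequate for tightly clustered
    orientations such as a static calibration window."""
    qs = sign_continuous(quat_normalize(qs, enforce_w_positive=False))
    return quat_normalize(qs.mean(axis=0))


@dataclass
class CalibrationRecord:
    """Sensor-to-segment registration from a static neutral-posture recording.

    ``*_offset`` is the conjugate of the segment's mean static orientation, so
    that the calibrated orientation ``C(t) = R(t) · R_static^T`` is identity at
    the pose; the knee angle computed from calibrated segments is therefore
    zero in the calibration posture.
    """

    thigh_offset: np.ndarray
    shank_offset: np.ndarray
    window: tuple[float, float]
    residual_motion_deg: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thigh_offset = quat_normalize(self.thigh_offset)
        self.shank_offset = quat_normalize(self.shank_offset)
        if self.residual_motion_deg < 0:
            raise ValueError("residual static motion must be >= 0")

    def to_dict(self) -> dict:
        return {
            "thigh_offset": [float(v) for v in self.thigh_offset],
            "shank_offset": [float(v) for v in self.shank_offset],
            "window": [float(self.window[0]), float(self.window[1])],
            "residual_motion_deg": float(self.residual_motion_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationRecord":
        return cls(
            thigh_offset=np.asarray(d["thigh_offset"], dtype=float),
            shank_offset=np.asarray(d["shank_offset"], dtype=float),
            window=(float(d["window"][0]), float(d["window"][1])),
            residual_motion_deg=float(d.get("residual_motion_deg", 0.0)),
        )


def _static_mean(stream, window: tuple[float, float]) -> tuple[np.ndarray, float]:
    t = np.asarray(stream.timestamps, dtype=float)
    mask = (t >= window[0]) & (t <= window[1])
    if not np.any(mask):
        raise ValueError("calibration window does not overlap the stream")
    qs = np.asarray(stream.quaternions, dtype=float)[mask]
    mean = quat_mean(qs)
    residual = float(np.max(quat_angle_between(quat_normalize(qs, enforce_w_positive=False), mean)))
    return mean, residual


def register_calibration(thigh_static, shank_static, window=None) -> CalibrationRecord:
    """Register thigh and shank sensors to their segments from a static pose.

    Parameters
    ----------
    thigh_static, shank_static
        :class:`~imuknee.pipeline.OrientationStream` covering the window.
    window
        ``(start_s, end_s)``; defaults to the full overlap of the two streams.
        Must span at least 0.5 s.

    Raises
    ------
    NonStaticCalibrationError
        If either segment deviates more than 5 degrees from its mean
        orientation inside the window — the pose was not static.
    """
    if window is None:
        window = (
            max(thigh_static.timestamps[0], shank_static.timestamps[0]),
            min(thigh_static.timestamps[-1], shank_static.timestamps[-1]),
        )
    window = (float(window[0]), float(window[1]))
    if window[1] - window[0] < 0.5:
        raise ValueError(f"calibration window must span >= 0.5 s, got {window[1] - window[0]:.3f} s")
    thigh_mean, thigh_res = _static_mean(thigh_static, window)
    shank_mean, shank_res = _static_mean(shank_static, window)
    residual = max(thigh_res, shank_res)
    if residual > MAX_STATIC_MOTION_DEG:
        raise NonStaticCalibrationError(
            f"residual static motion {residual:.2f} deg exceeds {MAX_STATIC_MOTION_DEG} deg; "
            "the calibration recording is not a static pose"
        )
    return CalibrationRecord(
        thigh_offset=quat_conjugate(thigh_mean),
        shank_offset=quat_conjugate(shank_mean),
        window=window,
        residual_motion_deg=residual,
    )


def relative_knee_rotation(q_thigh, q_shank, calib: CalibrationRecord) -> np.ndarray:
    """Rotation from calibrated thigh frame to calibrated shank frame.

    With calibrated segment orientations ``C_seg(t) = R_seg(t) · R_seg(static)^T``
    the joint rotation is ``J(t) = C_thigh(t)^T · C_shank(t)``; it is the
    identity at the calibration pose and invariant to any common world-frame
    rotation of both segments.
    """
    q_thigh = quat_normalize(q_thigh, enforce_w_positive=False)
    q_shank = quat_normalize(q_shank, enforce_w_positive=False)
    c_thigh = quat_multiply(q_thigh, calib.thigh_offset)
    c_shank = quat_multiply(q_shank, calib.shank_offset)
    j = quat_multiply(quat_conjugate(c_thigh), c_shank)
    return quat_to_matrix(quat_normalize(j, enforce_w_positive=False))
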