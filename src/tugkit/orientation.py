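"""Sensor orientation from accelerometer + gyroscope.

A complementary quaternion filter in the style used for trunk-worn IMUs:
angular velocity is integrated sample by sample and the resulting attitude is
continuously pulled toward the gravity direction measured by the
accelerometer with a small per-sample gain.  Yaw is unobservable from gravity
and drifts slowly with the gyroscope bias; the mobility-test pipeline only
uses yaw differentially (a 180-degree turn over ~2 s), where the drift is
negligible, so no magnetometer is fused.

Quaternions are ``(qw, qx, qy, qz)``, unit norm, mapping body to world
vectors; Euler angles use the aerospace ZYX (yaw-pitch-roll) convention with
yaw in (-pi, pi].  The world frame is gravity-aligned: "down" is (0, 0, -1),
matching a resting cranio-caudal accelerometer reading of -g.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from ._errors import DataError, ParameterError
from .signal_model import BodyFrameSignals, G, IMURecording, map_device_to_body_axes


@dataclass
class OrientationSeries:
    """Per-sample unit quaternions and the Euler angles derived from them."""

    quaternions: np.ndarray  # (n, 4) = (qw, qx, qy, qz)
    euler: np.ndarray  # (n, 3) = (roll, pitch, yaw) in radians
    rate: float

    def __post_init__(self):
        norms = np.linalg.norm(self.quaternions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise DataError("quaternions must be unit norm at every sample")


# -- quaternion primitives ---------------------------------------------------

def _qmul(a, b):
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


def _qnormalize(q):
    w, x, y, z = q
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return (w / n, x / n, y / n, z / n)


def _q_axis_angle(axis, angle):
    ax, ay, az = axis
    n = math.sqrt(ax * ax + ay * ay + az * az)
    if n < 1e-15 or angle == 0.0:
        return (1.0, 0.0, 0.0, 0.0)
    s = math.sin(angle / 2.0) / n
    return (math.cos(angle / 2.0), ax * s, ay * s, az * s)


def _rotate_inverse(q, v):
    """Rotate world vector v into the body frame: R(q)^T v.

    Uses v' = v + 2w (u x v) + 2 u x (u x v) with u = -(qx, qy, qz).
    """
    w, x, y, z = q
    ux, uy, uz = -x, -y, -z
    vx, vy, vz = v
    tx = 2.0 * (uy * vz - uz * vy)
    ty = 2.0 * (uz * vx - ux * vz)
    tz = 2.0 * (ux * vy - uy * vx)
    return (
        vx + w * tx + (uy * tz - uz * ty),
        vy + w * ty + (uz * tx - ux * tz),
        vz + w * tz + (ux * ty - uy * tx),
    )


def quaternion_to_euler(q: Union[np.ndarray, tuple]) -> np.ndarray:
    """Convert unit quaternion(s) to (roll, pitch, yaw), ZYX convention.

    At gimbal lock (|pitch| = 90 deg) the roll axis absorbs the indeterminate
    rotation (yaw and roll become coupled; the returned pair is one valid
    decomposition).
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if not np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-6):
        raise ParameterError("quaternion_to_euler requires unit-norm input")
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    roll = np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    pitch = np.arcsin(np.clip(2.0 * (w * y - z * x), -1.0, 1.0))
    yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    out = np.column_stack([roll, pitch, yaw])
    return out[0] if single else out


def euler_to_quaternion(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Inverse of :func:`quaternion_to_euler` (ZYX convention)."""
    cy, sy = math.cos(yaw / 2), math.sin(yaw / 2)
    cp, sp = math.cos(pitch / 2), math.sin(pitch / 2)
    cr, sr = math.cos(roll / 2), math.sin(roll / 2)
    return np.array(
        [
            cr * cp * cy + sr * sp * sy,
            sr * cp * cy - cr * sp * sy,
            cr * sp * cy + sr * cp * sy,
            cr * cp * sy - sr * sp * cy,
        ]
    )


def _init_from_gravity(acc_mean):
    """Quaternion aligning the measured gravity direction with world down."""
    norm = np.linalg.norm(acc_mean)
    if norm < 1e-9:
        return (1.0, 0.0, 0.0, 0.0)
    d_meas = acc_mean / norm
    d_w = np.array([0.0, 0.0, -1.0])
    axis = np.cross(d_meas, d_w)
    angle = math.atan2(np.linalg.norm(axis), float(np.dot(d_meas, d_w)))
    if np.linalg.norm(axis) < 1e-12:
        # Parallel or anti-parallel; anti-parallel flips about ML.
        return (1.0, 0.0, 0.0, 0.0) if angle < math.pi / 2 else (0.0, 1.0, 0.0, 0.0)
    return _q_axis_angle(tuple(axis), angle)


def estimate_orientation(
    data: Union[IMURecording, BodyFrameSignals],
    rate: float | None = None,
    gain: float = 0.01,
    init_window_s: float = 0.5,
) -> OrientationSeries:
    """Run the complementary filter over a uniform recording.

    ``gain`` is the per-sample fraction of the tilt error corrected toward the
    accelerometer gravity direction (0 -> pure gyro integration, 1 -> snap to
    the accelerometer tilt solution whenever the accelerometer is trustworthy).
    The initial attitude comes from the mean accelerometer vector over the
    first ``init_window_s`` seconds.  Samples whose acceleration norm is far
    from g (outside 0.5g..1.5g) contribute no correction; an all-zero
    accelerometer (free fall) produces a warning and gyro-only integration.
    """
    if isinstance(data, IMURecording):
        body = map_device_to_body_axes(data)
    else:
        body = data
        if body.gyro is None:
            raise DataError("BodyFrameSignals without full gyro cannot drive orientation")
    if rate is None:
        rate = body.rate
    if not 0.0 <= gain <= 1.0:
        raise ParameterError(f"gain must lie in [0, 1], got {gain}")
    acc = body.acc_matrix()
    gyro = body.gyro
    n = len(acc)
    if n == 0:
        raise DataError("empty recording")
    dt = 1.0 / rate

    n_init = max(1, min(n, int(round(init_window_s * rate))))
    q = _qnormalize(_init_from_gravity(acc[:n_init].mean(axis=0)))

    if np.max(np.abs(acc)) < 1e-9:
        warnings.warn(
            "accelerometer is all zero (free fall?); gyro-only integration",
            RuntimeWarning,
            stacklevel=2,
        )

    quats = np.empty((n, 4))
    lo, hi = 0.5 * G, 1.5 * G
    for k in range(n):
        if k > 0:
            wx, wy, wz = gyro[k - 1]
            angle = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
            if angle > 0.0:
                q = _qmul(q, _q_axis_angle((wx, wy, wz), angle))
        ax, ay, az = acc[k]
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        if gain > 0.0 and lo < norm < hi:
            d_meas = (ax / norm, ay / norm, az / norm)
            d_pred = _rotate_inverse(q, (0.0, 0.0, -1.0))
            cx = d_pred[1] * d_meas[2] - d_pred[2] * d_meas[1]
            cy = d_pred[2] * d_meas[0] - d_pred[0] * d_meas[2]
            cz = d_pred[0] * d_meas[1] - d_pred[1] * d_meas[0]
            sin_err = math.sqrt(cx * cx + cy * cy + cz * cz)
            cos_err = (
                d_pred[0] * d_meas[0] + d_pred[1] * d_meas[1] + d_pred[2] * d_meas[2]
            )
            err = math.atan2(sin_err, cos_err)
            if sin_err > 1e-12:
                q = _qmul(q, _q_axis_angle((cx, cy, cz), -gain * err))
        q = _qnormalize(q)
        quats[k] = q

    return OrientationSeries(quaternions=quats, euler=quaternion_to_euler(quats), rate=rate)
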