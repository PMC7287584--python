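"""Orientation fusion and derived acceleration series from IMU streams.

The Madgwick gradient-descent complementary filter integrates the gyroscope
and corrects the quaternion toward gravity alignment by a normalized
gradient step of gain ``beta`` (IMU variant; the magnetometer is not used —
extracting the vertical only requires the gravity direction).  Earth-frame
vertical acceleration is the rotated accelerometer z component minus 1 g;
the resultant acceleration is the plain Euclidean norm of the accelerometer
triplet, invariant to mounting orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .signal_io import ImuRecording

__all__ = [
    "OrientationSeries",
    "ScalarSeries",
    "madgwick_orientation",
    "vertical_acceleration",
    "resultant_acceleration",
]


@dataclass
class OrientationSeries:
    """Unit quaternions (w, x, y, z), sensor→earth, one per IMU sample."""

    q: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError("q must be shaped (n, 4)")
        norms = np.linalg.norm(self.q, axis=1)
        if len(norms) and np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("quaternions must be unit norm")


@dataclass
class ScalarSeries:
    """A derived scalar signal with its rate, start time and semantic kind."""

    values: np.ndarray
    sample_rate: float
    kind: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ScalarSeries values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sample_rate


@njit(cache=True)
def _madgwick_loop(acc: np.ndarray, gyr_rad: np.ndarray, dt: float,
                   beta: float, q0: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = acc.shape[0]
    out = np.empty((n, 4))
    qw, qx, qy, qz = q0[0], q0[1], q0[2], q0[3]
    for i in range(n):
        gx, gy, gz = gyr_rad[i, 0], gyr_rad[i, 1], gyr_rad[i, 2]
        # quaternion rate from gyro: 0.5 * q ⊗ (0, ω)
        dqw = 0.5 * (-qx * gx - qy * gy - qz * gz)
        dqx = 0.5 * (qw * gx + qy * gz - qz * gy)
        dqy = 0.5 * (qw * gy - qx * gz + qz * gx)
        dqz = 0.5 * (qw * gz + qx * gy - qy * gx)

        ax, ay, az = acc[i, 0], acc[i, 1], acc[i, 2]
        anorm = np.sqrt(ax * ax + ay * ay + az * az)
        if anorm > 0.0 and beta > 0.0:
            ax /= anorm
            ay /= anorm
            az /= anorm
            # objective: gravity predicted in sensor frame minus measured
            f1 = 2.0 * (qx * qz - qw * qy) - ax
            f2 = 2.0 * (qw * qx + qy * qz) - ay
            f3 = 2.0 * (0.5 - qx * qx - qy * qy) - az
            s0 = -2.0 * qy * f1 + 2.0 * qx * f2
            s1 = 2.0 * qz * f1 + 2.0 * qw * f2 - 4.0 * qx * f3
            s2 = -2.0 * qw * f1 + 2.0 * qz * f2 - 4.0 * qy * f3
            s3 = 2.0 * qx * f1 + 2.0 * qy * f2
            snorm = np.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
            if snorm > 0.0:
                dqw -= beta * s0 / snorm
                dqx -= beta * s1 / snorm
                dqy -= beta * s2 / snorm
                dqz -= beta * s3 / snorm

        qw += dqw * dt
        qx += dqx * dt
        qy += dqy * dt
        qz += dqz * dt
        qnorm = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw /= qnorm
        qx /= qnorm
        qy /= qnorm
        qz /= qnorm
        out[i, 0] = qw
        out[i, 1] = qx
        out[i, 2] = qy
        out[i, 3] = qz
    return out


def madgwick_orientation(
    imu: ImuRecording,
    beta: float = 0.1,
    init: np.ndarray | None = None,
) -> OrientationSeries:
    """Per-sample sensor→earth quaternion from the Madgwick IMU filter.

    ``beta`` (default 0.1, the filter's conventional gain) sets the
    magnitude of the normalized gravity-alignment gradient step per second;
    ``beta=0`` reduces to pure gyro integration.  A zero-norm accelerometer
    sample skips the correction for that step.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    q0 = np.array([1.0, 0.0, 0.0, 0.0]) if init is None else np.asarray(init, float)
    q0 = q0 / np.linalg.norm(q0)
    gyr_rad = np.deg2rad(imu.gyr)
    q = _madgwick_loop(np.ascontiguousarray(imu.acc), np.ascontiguousarray(gyr_rad),
                       1.0 / imu.sample_rate, float(beta), q0)
    return OrientationSeries(q=q, sample_rate=imu.sample_rate)


def _rotate_to_earth(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame vectors to earth frame, v_e = q ⊗ v ⊗ q*."""
    qw, qx, qy, qz = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    vx, vy, vz = v[:, 0], v[:, 1], v[:, 2]
    # t = 2 q_vec × v ; v' = v + qw t + q_vec × t
    tx = 2.0 * (qy * vz - qz * vy)
    ty = 2.0 * (qz * vx - qx * vz)
    tz = 2.0 * (qx * vy - qy * vx)
    out = np.empty_like(v)
    out[:, 0] = vx + qw * tx + qy * tz - qz * ty
    out[:, 1] = vy + qw * ty + qz * tx - qx * tz
    out[:, 2] = vz + qw * tz + qx * ty - qy * tx
    return out


def vertical_acceleration(imu: ImuRecording, orientation: OrientationSeries) -> ScalarSeries:
    """Earth-frame vertical acceleration in g (gravity removed)."""
    if len(orientation.q) != len(imu):
        raise ValueError("orientation must be aligned with the IMU samples")
    earth = _rotate_to_earth(orientation.q, imu.acc)
    t0 = float(imu.t[0]) if len(imu) else 0.0
    return ScalarSeries(earth[:, 2] - 1.0, imu.sample_rate, "vertical_acc_g", t0)


def resultant_acceleration(imu: ImuRecording) -> ScalarSeries:
    """Euclidean norm of the raw accelerometer triplet, in g (gravity kept)."""
    t0 = float(imu.t[0]) if len(imu) else 0.0
    return ScalarSeries(np.linalg.norm(imu.acc, axis=1), imu.sample_rate,
                        "resultant_acc_g", t0)
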