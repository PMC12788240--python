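"""Kinematic feature engineering: expand 6-DOF streams into 18 channels.

Channel layout (fixed order):

====================  ========================================================
``ax, ay, az``        dynamic linear acceleration, m/s^2 (tremor intensity)
``wx, wy, wz``        angular velocity from the gyroscope, deg/s
``vx, vy, vz``        velocity reconstructed by forward-Euler integration
``jx, jy, jz``        jerk (d/dt of acceleration) — movement smoothness
``alpha_x..alpha_z``  rotational acceleration (backward difference of gyro)
``roll, pitch, yaw``  pen orientation from a complementary filter
====================  ========================================================

The magnetometer is never consulted: indoor electromagnetic interference
makes absolute heading unreliable for fine motor analysis.  All channels are
min-max normalized per recording and padded/truncated to a fixed length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from penkinetics.preprocess import (
    PreprocessedRecording,
    T_FIXED,
    minmax_normalize,
    pad_or_truncate,
)
from penkinetics.recording import FS

CHANNEL_NAMES = (
    "ax", "ay", "az",
    "wx", "wy", "wz",
    "vx", "vy", "vz",
    "jx", "jy", "jz",
    "alpha_x", "alpha_y", "alpha_z",
    "roll", "pitch", "yaw",
)

#: Channels eligible for tremor-noise injection (acceleration + jerk).
NOISE_CHANNELS = ("ax", "ay", "az", "jx", "jy", "jz")

SUMMARY_STATS = ("mean", "std", "min", "max", "rms")

#: Default moving-mean window (seconds) for velocity drift removal.
DEFAULT_DETREND_WINDOW = 2.0


@dataclass
class FeatureTensor:
    """Fixed-length T x 18 kinematic channel matrix with carried metadata."""

    values: np.ndarray            # (T, 18)
    subject_id: str
    task: str
    label: str
    source: str
    valid_length: int
    channel_names: Tuple[str, ...] = CHANNEL_NAMES

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def copy(self, **changes) -> "FeatureTensor":
        base = dict(
            values=self.values.copy(), subject_id=self.subject_id, task=self.task,
            label=self.label, source=self.source, valid_length=self.valid_length,
            channel_names=self.channel_names,
        )
        base.update(changes)
        return FeatureTensor(**base)


def integrate_velocity(
    accel: np.ndarray,
    dt: float = 1.0 / FS,
    v0: float = 0.0,
    detrend_window: Optional[float] = None,
) -> np.ndarray:
    """Forward-Euler velocity reconstruction: v(t) = v(t-1) + a(t)*dt.

    ``v(0) = v0``; works on (n,) or (n, k) arrays along axis 0.  Pure
    integration drifts under sensor noise, so an optional moving-mean
    detrend (window in seconds) subtracts the slow drift component after
    integration; pass ``None`` to disable (exact Euler inverse).
    """
    a = np.asarray(accel, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("integrate_velocity requires finite input")
    v = v0 + dt * (np.cumsum(a, axis=0) - a[:1])
    if detrend_window is not None:
        from scipy.ndimage import uniform_filter1d
        size = max(int(round(detrend_window / dt)), 1)
        v = v - uniform_filter1d(v, size=size, axis=0, mode="nearest")
    return v


def compute_jerk(accel: np.ndarray, dt: float = 1.0 / FS) -> np.ndarray:
    """Jerk J = dA/dt via central differences (one-sided at the endpoints)."""
    a = np.asarray(accel, dtype=float)
    if a.shape[0] < 2:
        raise ValueError("compute_jerk requires >= 2 samples")
    return np.gradient(a, dt, axis=0)


def rotational_acceleration(gyro: np.ndarray, dt: float = 1.0 / FS) -> np.ndarray:
    """Rotational acceleration alpha = (w(t) - w(t-1)) / dt, backward difference.

    The first sample replicates the second so the output length matches the
    input (the backward scheme is undefined at t=0).
    """
    w = np.asarray(gyro, dtype=float)
    if w.shape[0] < 2:
        raise ValueError("rotational_acceleration requires >= 2 samples")
    alpha = np.empty_like(w)
    alpha[1:] = (w[1:] - w[:-1]) / dt
    alpha[0] = alpha[1]
    return alpha


def estimate_euler(
    accel_g: np.ndarray,
    gyro_dps: np.ndarray,
    dt: float = 1.0 / FS,
    blend: float = 0.98,
) -> np.ndarray:
    """Complementary-filter Euler angles (roll, pitch, yaw) in radians.

    Software stand-in for the IMU's on-chip sensor fusion.  Roll and pitch
    fuse gyro integration (weight ``blend``) with the accelerometer tilt
    reference (weight ``1 - blend``); yaw integrates the gyro alone since
    the magnetometer is dropped.  The tilt reference assumes the simulator's
    sign convention (static reading = R^T (0, 0, -1) g):

        roll  = atan2(-ay, -az)
        pitch = atan2(ax, sqrt(ay^2 + az^2))

    For a static pose the estimate converges to the accelerometer tilt.
    Input acceleration must retain gravity (run before compensation).
    """
    a = np.asarray(accel_g, dtype=float)
    w = np.radians(np.asarray(gyro_dps, dtype=float))
    n = a.shape[0]
    tilt_roll = np.arctan2(-a[:, 1], -a[:, 2])
    tilt_pitch = np.arctan2(a[:, 0], np.hypot(a[:, 1], a[:, 2]))
    out = np.zeros((n, 3))
    out[0, 0] = tilt_roll[0]
    out[0, 1] = tilt_pitch[0]
    roll, pitch, yaw = out[0]
    for i in range(1, n):
        roll = blend * (roll + w[i, 0] * dt) + (1.0 - blend) * tilt_roll[i]
        pitch = blend * (pitch + w[i, 1] * dt) + (1.0 - blend) * tilt_pitch[i]
        yaw = yaw + w[i, 2] * dt
        out[i] = (roll, pitch, yaw)
    return out


def assemble_feature_tensor(
    pre: PreprocessedRecording,
    T: int = T_FIXED,
    normalize: bool = True,
    detrend_window: Optional[float] = DEFAULT_DETREND_WINDOW,
) -> FeatureTensor:
    """Expand a preprocessed recording into the T x 18 feature tensor.

    Derived channels are computed from the physical-unit streams, then all
    18 channels are min-max normalized per channel and padded/truncated to
    length ``T``.  Pass ``normalize=False`` to keep physical units (used by
    diagnostic tests).
    """
    dt = 1.0 / FS
    vel = integrate_velocity(pre.accel_dyn, dt, detrend_window=detrend_window)
    jerk = compute_jerk(pre.accel_dyn, dt)
    alpha = rotational_acceleration(pre.gyro, dt)
    euler = estimate_euler(pre.accel_g, pre.gyro, dt)
    stacked = np.concatenate([pre.accel_dyn, pre.gyro, vel, jerk, alpha, euler], axis=1)
    if stacked.shape[1] != len(CHANNEL_NAMES):
        raise AssertionError("channel assembly does not match the declared layout")
    if not np.all(np.isfinite(stacked)):
        raise ValueError("non-finite values in assembled channels")
    if normalize:
        stacked = minmax_normalize(stacked, axis=0)
    values, valid_length = pad_or_truncate(stacked, T)
    return FeatureTensor(
        values=values, subject_id=pre.subject_id, task=pre.task, label=pre.label,
        source=pre.source, valid_length=valid_length,
    )


def summary_feature_names() -> list:
    """Names of the 90 summary statistics, channel-major."""
    return [f"{ch}_{stat}" for ch in CHANNEL_NAMES for stat in SUMMARY_STATS]


def summarize(ft: FeatureTensor) -> np.ndarray:
    """Collapse a feature tensor to 90 scalars: 5 statistics per channel.

    Statistics (mean, population std, min, max, RMS) are computed over the
    unpadded region only.  These are the aggregated descriptors consumed by
    the classical baselines.
    """
    if ft.valid_length < 2:
        raise ValueError("summarize requires valid_length >= 2")
    x = ft.values[: ft.valid_length]
    stats = np.stack([
        x.mean(axis=0),
        x.std(axis=0),          # population std (ddof=0)
        x.min(axis=0),
        x.max(axis=0),
        np.sqrt(np.mean(x**2, axis=0)),
    ], axis=1)                   # (18, 5), channel-major to match names
    return stats.reshape(-1)
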