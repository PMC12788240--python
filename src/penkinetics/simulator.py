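"""Parametric pen-tip trajectory simulator and inverse sensor model.

Generates clean, healthy 6-DOF handwriting recordings for three graphomotor
tasks and converts them into IMU streams via an inverse sensor model:

* ``spiral`` — Archimedean spiral ``r = a + b*theta`` swept at a constant
  angular rate, drawn from the centre outward.
* ``loops``  — continuous cursive loops: steady horizontal drift plus a
  sinusoidal vertical oscillation at the loop rate.
* ``sentence`` — a seeded sequence of smooth minimum-jerk strokes emulating
  over-learned cursive writing.

Every trajectory starts with a quiescent rest prefix (pen held still on the
desk) that the preprocessing stage uses to estimate the static gravity
component.  Recordings are emitted in device units: specific force in g,
angular rate in deg/s, at a fixed 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from penkinetics.recording import (
    FS,
    GRAVITY_MS2,
    LABELS,
    TASKS,
    RawRecording,
)

#: Default per-axis sensor noise floor: (accel std in g, gyro std in deg/s).
DEFAULT_NOISE_FLOOR = (0.005, 0.5)

#: Default gravity vector in the desk frame (z up), m/s^2.
DEFAULT_GRAVITY = (0.0, 0.0, -GRAVITY_MS2)


@dataclass
class TaskParams:
    """Parameters of a single simulated graphomotor task.

    ``duration`` is the total recording length in seconds and includes the
    initial ``rest_duration`` of quiescence; the active drawing phase spans
    ``[rest_duration, duration]``.  Amplitudes are in metres, rates in their
    natural units; ``scale`` and ``tempo`` are dimensionless per-subject
    multipliers on amplitude and speed.
    """

    task: str
    duration: float = 12.0
    rest_duration: float = 1.0
    seed: int = 0
    # Archimedean spiral r = a + b*theta, swept at omega rad/s.
    spiral_a: float = 0.002
    spiral_b: float = 0.0015
    spiral_omega: float = float(np.pi)
    # Oscillating loops: horizontal advance per loop and loop height (peak), loop rate in Hz.
    loop_advance: float = 0.004
    loop_height: float = 0.008
    loop_rate: float = 2.0
    # Sentence writing: number of smooth strokes and their characteristic size.
    n_strokes: int = 14
    stroke_scale: float = 0.01
    # Gentle wrist-orientation oscillation (radians, Hz).
    orient_amp: float = 0.08
    orient_freq: float = 1.2
    # Smooth onset: task time is ramped up over this many seconds so motion
    # starts with zero velocity (writers accelerate, they do not jump).
    onset_ramp: float = 0.5
    # Per-subject variability multipliers.
    scale: float = 1.0
    tempo: float = 1.0

    def validate(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.rest_duration < self.duration:
            raise ValueError("rest_duration must satisfy 0 <= rest < duration")
        for name in ("spiral_a", "spiral_b", "loop_advance", "loop_height",
                     "loop_rate", "stroke_scale", "scale", "tempo", "onset_ramp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.scale == 0 or self.tempo == 0:
            raise ValueError("scale and tempo must be positive")


@dataclass
class Trajectory:
    """Pen-tip trajectory sampled at 100 Hz in the desk frame.

    ``position`` is the pen tip in metres (z up), ``orientation`` the pen
    body's intrinsic roll-pitch-yaw Euler angles (phi, theta, psi) in radians.
    """

    t: np.ndarray
    position: np.ndarray
    orientation: np.ndarray
    task: str = "spiral"

    @property
    def n_samples(self) -> int:
        return len(self.t)


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(u) = 10u^3 - 15u^4 + 6u^5 on [0, 1]."""
    return u**3 * (10.0 + u * (-15.0 + 6.0 * u))


def _ramped_time(s: np.ndarray, ramp: float) -> np.ndarray:
    """Task time with a C1 smooth-start: rate ramps 0 -> 1 over ``ramp`` s.

    Integral of the smoothstep rate 3u^2 - 2u^3; beyond the ramp the clock
    runs at unit rate with a constant offset of ramp/2.
    """
    if ramp <= 0:
        return s
    u = np.clip(s / ramp, 0.0, 1.0)
    ramped = ramp * (u**3 - 0.5 * u**4)
    return np.where(s <= ramp, ramped, s - 0.5 * ramp)


def _sentence_position(s: np.ndarray, params: TaskParams, rng: np.random.Generator) -> np.ndarray:
    """Seeded sequence of minimum-jerk strokes with a slow rightward drift."""
    active = s[-1] if len(s) else 0.0
    pos = np.zeros((len(s), 3))
    cursor = np.zeros(2)
    t0 = 0.0
    k = 0
    while t0 < active:
        dur = rng.uniform(0.25, 0.5)
        pause = rng.uniform(0.05, 0.15)
        ang = rng.uniform(0, 2 * np.pi)
        length = abs(rng.normal(params.stroke_scale, params.stroke_scale / 3.0))
        delta = length * np.array([np.cos(ang), np.sin(ang)])
        # rightward writing drift dominates the x component
        delta[0] = abs(delta[0]) * 0.5 + 0.3 * params.stroke_scale
        mask = (s >= t0) & (s < t0 + dur)
        u = (s[mask] - t0) / dur
        prof = _minimum_jerk(u)
        pos[mask, 0] = cursor[0] + delta[0] * prof
        pos[mask, 1] = cursor[1] + delta[1] * prof
        after = s >= t0 + dur
        cursor = cursor + delta
        pos[after, 0] = cursor[0]
        pos[after, 1] = cursor[1]
        t0 += dur + pause
        k += 1
        if k >= params.n_strokes:
            # recycle stroke budget: keep writing until time runs out
            k = 0
    return pos


def generate_trajectory(params: TaskParams) -> Trajectory:
    """Generate a pen-tip trajectory for one task at 100 Hz.

    Returns ``duration * 100`` samples.  The first ``rest_duration`` seconds
    are quiescent (constant position and zero orientation); the task profile
    then unfolds over the remaining time, sped up by ``tempo`` and scaled in
    amplitude by ``scale``.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * FS))
    t = np.arange(n) / FS
    # active task time, clamped at zero during the rest prefix
    s = np.clip(t - params.rest_duration, 0.0, None) * params.tempo

    pos = np.zeros((n, 3))
    st = _ramped_time(s, params.onset_ramp * params.tempo)
    if params.task == "spiral":
        theta = params.spiral_omega * st
        r = params.spiral_a + params.spiral_b * theta
        pos[:, 0] = r * np.cos(theta)
        pos[:, 1] = r * np.sin(theta)
    elif params.task == "loops":
        drift = params.loop_advance * params.loop_rate
        pos[:, 0] = drift * st
        pos[:, 1] = params.loop_height * np.sin(2 * np.pi * params.loop_rate * st)
    elif params.task == "sentence":
        pos = _sentence_position(s, params, rng)
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown task {params.task!r}")
    pos *= params.scale

    orient = np.zeros((n, 3))
    if params.orient_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        w = 2 * np.pi * params.orient_freq
        orient[:, 0] = params.orient_amp * np.sin(w * s)            # roll
        orient[:, 1] = 0.75 * params.orient_amp * np.sin(w * s + phase)  # pitch
        orient[:, 2] = 0.5 * params.orient_amp * np.sin(0.25 * w * s)    # yaw
    return Trajectory(t=t, position=pos, orientation=orient, task=params.task)


def _body_rotations(orientation: np.ndarray) -> Rotation:
    """Body-to-world rotations R = Rz(psi) Ry(theta) Rx(phi) per sample."""
    # scipy intrinsic 'ZYX' consumes angles in (yaw, pitch, roll) order
    return Rotation.from_euler("ZYX", orientation[:, ::-1])


def trajectory_to_imu(
    traj: Trajectory,
    noise_floor: Sequence[float] = DEFAULT_NOISE_FLOOR,
    gravity_vector: Sequence[float] = DEFAULT_GRAVITY,
    seed: int = 0,
    *,
    subject_id: str = "synthetic-0000",
    label: str = "CN",
) -> RawRecording:
    """Inverse sensor model: trajectory -> 9-axis IMU recording.

    The accelerometer channel is the body-frame projection of the pen-tip
    acceleration (second central difference of position) plus the gravity
    vector, expressed in g units, with additive white noise at the per-axis
    ``noise_floor``.  The gyroscope channel is the first derivative of the
    Euler angles in deg/s plus noise (for the small attitude excursions
    simulated here, Euler rates stand in for true body rates).  A constant
    Earth-like magnetic field rotated into the body frame fills the optional
    magnetometer channel, which downstream stages drop.
    """
    if traj.n_samples < 3:
        raise ValueError("trajectory_to_imu requires >= 3 samples for second differences")
    rng = np.random.default_rng(seed)
    dt = 1.0 / FS
    g_vec = np.asarray(gravity_vector, dtype=float)

    vel = np.gradient(traj.position, dt, axis=0)
    acc_world = np.gradient(vel, dt, axis=0)
    rot = _body_rotations(traj.orientation)
    specific = rot.apply(acc_world + g_vec, inverse=True)  # body frame, m/s^2
    accel_g = specific / GRAVITY_MS2
    accel_g = accel_g + rng.normal(0.0, noise_floor[0], size=accel_g.shape)

    gyro_dps = np.degrees(np.gradient(traj.orientation, dt, axis=0))
    gyro_dps = gyro_dps + rng.normal(0.0, noise_floor[1], size=gyro_dps.shape)

    # constant Earth-like field (uT) in the desk frame, rotated into the body
    mag_world = np.array([22.0, 0.0, -42.0])
    mag = rot.apply(np.tile(mag_world, (traj.n_samples, 1)), inverse=True)
    mag = mag + rng.normal(0.0, 0.3, size=mag.shape)

    return RawRecording(
        subject_id=subject_id, task=traj.task, label=label, source="synthetic",
        t=traj.t.copy(), accel=accel_g, gyro=gyro_dps, mag=mag,
    )


def _task_allocation(n: int, task_mix, rng: np.random.Generator) -> list:
    """Deterministically allocate n recordings across tasks per the mix."""
    if isinstance(task_mix, dict):
        fracs = np.array([task_mix.get(task, 0.0) for task in TASKS], dtype=float)
    else:
        fracs = np.asarray(task_mix, dtype=float)
        if len(fracs) != len(TASKS):
            raise ValueError(f"task_mix must have {len(TASKS)} entries (order {TASKS})")
    if fracs.min() < 0 or not np.isclose(fracs.sum(), 1.0, atol=1e-6):
        raise ValueError("task_mix proportions must be non-negative and sum to 1")
    counts = np.floor(fracs * n).astype(int)
    # hand remaining slots to the largest fractional parts
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    for i in range(rem):
        counts[order[i % len(TASKS)]] += 1
    tasks = [task for task, c in zip(TASKS, counts) for _ in range(c)]
    rng.shuffle(tasks)
    return tasks


def generate_cohort(
    n_per_class: int,
    task_mix: Union[Sequence[float], dict] = (1 / 3, 1 / 3, 1 / 3),
    pathology: Optional["AugmentationParams"] = None,
    seed: int = 0,
    *,
    noise_floor: Sequence[float] = DEFAULT_NOISE_FLOOR,
    mean_duration: float = 12.0,
    id_prefix: str = "syn",
) -> list:
    """Generate a balanced synthetic cohort of CN and AD recordings.

    Produces exactly ``n_per_class`` recordings per class with unique subject
    ids.  AD recordings carry tremor noise (sigma drawn uniformly from the
    pathology sigma range, applied to the acceleration channels) plus strong
    bradykinesia time-warping; CN recordings receive mild random warping only,
    so the classifier cannot key on the mere presence of warp artifacts.
    Per-subject amplitude/tempo/duration variability emulates natural
    differences in writing style.  Fully reproducible per ``seed``.
    """
    from penkinetics.augment import AugmentationParams, augment_recording

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if pathology is None:
        pathology = AugmentationParams()
    pathology.validate()

    master = np.random.default_rng(seed)
    cohort = []
    for label in LABELS:
        rng = np.random.default_rng(master.integers(2**31))
        tasks = _task_allocation(n_per_class, task_mix, rng)
        for i, task in enumerate(tasks):
            duration = float(np.clip(rng.normal(mean_duration, 1.0), 9.0, 15.0))
            params = TaskParams(
                task=task,
                duration=round(duration, 2),
                seed=int(rng.integers(2**31)),
                scale=float(rng.lognormal(0.0, 0.15)),
                tempo=float(rng.lognormal(0.0, 0.10)),
            )
            traj = generate_trajectory(params)
            rec = trajectory_to_imu(
                traj,
                noise_floor=noise_floor,
                seed=int(rng.integers(2**31)),
                subject_id=f"{id_prefix}-{label}-{i:04d}",
                label=label,
            )
            rec = augment_recording(rec, pathology, rng=np.random.default_rng(rng.integers(2**31)))
            rec.validate()
            cohort.append(rec)
    return cohort
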