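"""Raw 9-axis pen-motion recording container and sensor constants.

A recording mirrors what a pen-mounted MPU-9250-class IMU streams over a
serial link: a 100 Hz time base, 3-axis specific force (in units of g,
full scale +/-16 g), 3-axis angular rate (deg/s, full scale +/-2000 deg/s)
and an optional 3-axis magnetic field that downstream stages parse and drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Sampling rate of the pen sensor stream, Hz.
FS = 100.0

#: Conversion constant between g units and m/s^2 used throughout.
GRAVITY_MS2 = 9.8

#: Accelerometer full-scale range, g.
ACCEL_RANGE_G = 16.0

#: Gyroscope full-scale range, deg/s.
GYRO_RANGE_DPS = 2000.0

TASKS = ("sentence", "spiral", "loops")
LABELS = ("CN", "AD")
SOURCES = ("real", "synthetic")


@dataclass
class RawRecording:
    """Timestamped 9-axis sensor streams with subject/task/label metadata.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier; unique within a cohort.
    task : {"sentence", "spiral", "loops"}
        Graphomotor task performed.
    label : {"CN", "AD"}
        Binary class label (cognitively normal vs. impaired).
    source : {"real", "synthetic"}
        Provenance of the recording.
    t : ndarray, shape (n,)
        Sample timestamps in seconds, strictly increasing at 100 Hz.
    accel : ndarray, shape (n, 3)
        Specific force per axis in g units.
    gyro : ndarray, shape (n, 3)
        Angular rate per axis in deg/s.
    mag : ndarray, shape (n, 3), optional
        Magnetic field per axis (arbitrary units); parsed then dropped by
        the feature stage.
    """

    subject_id: str
    task: str
    label: str
    source: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples else 0.0

    def validate(self, *, check_ranges: bool = True, rate_tol: float = 0.01) -> None:
        """Raise ``ValueError`` if the recording violates its invariants.

        Checks sample count >= 2, equal channel lengths, strictly increasing
        timestamps at a uniform 100 Hz rate (within ``rate_tol`` relative
        jitter), and optionally the sensor full-scale ranges.
        """
        n = self.n_samples
        if n < 2:
            raise ValueError(f"recording must contain >= 2 samples, got {n}")
        for name, arr, width in (("accel", self.accel, 3), ("gyro", self.gyro, 3)):
            if arr.shape != (n, width):
                raise ValueError(f"{name} shape {arr.shape} does not match ({n}, {width})")
        if self.mag is not None and self.mag.shape != (n, 3):
            raise ValueError(f"mag shape {self.mag.shape} does not match ({n}, 3)")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        nominal = 1.0 / FS
        if np.any(np.abs(dt - nominal) > rate_tol * nominal):
            raise ValueError(
                f"non-uniform sampling: intervals deviate more than {rate_tol:.0%} from {nominal} s"
            )
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if check_ranges:
            if np.any(np.abs(self.accel) > ACCEL_RANGE_G):
                raise ValueError(
                    f"accelerometer sample exceeds the +/-{ACCEL_RANGE_G:g} g full-scale range"
                )
            if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS):
                raise ValueError(
                    f"gyroscope sample exceeds the +/-{GYRO_RANGE_DPS:g} deg/s full-scale range"
                )

    def copy(self, **changes) -> "RawRecording":
        """Return a deep copy, optionally replacing fields."""
        base = dict(
            subject_id=self.subject_id, task=self.task, label=self.label,
            source=self.source, t=self.t.copy(), accel=self.accel.copy(),
            gyro=self.gyro.copy(), mag=None if self.mag is None else self.mag.copy(),
        )
        base.update(changes)
        return RawRecording(**base)
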