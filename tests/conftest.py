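import numpy as np
import pytest

from penkinetics import (
    assemble_feature_tensor,
    generate_cohort,
    generate_trajectory,
    preprocess_recording,
    trajectory_to_imu,
)
from penkinetics.simulator import TaskParams


@pytest.fixture(scope="session")
def spiral_recording():
    """One clean synthetic spiral recording with default sensor noise."""
    params = TaskParams(task="spiral", duration=12.0, seed=3)
    return trajectory_to_imu(generate_trajectory(params), seed=3, subject_id="fix-spiral")


@pytest.fixture(scope="session")
def feature_tensor(spiral_recording):
    return assemble_feature_tensor(preprocess_recording(spiral_recording))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(5, seed=0)


def static_recording(duration=3.0, orientation=None, noise=(0.0, 0.0), seed=0):
    """A motionless pen recording (optionally at a fixed attitude)."""
    params = TaskParams(task="loops", duration=duration, rest_duration=0.0,
                        loop_height=0.0, loop_advance=0.0, orient_amp=0.0,
                        onset_ramp=0.0, seed=seed)
    traj = generate_trajectory(params)
    if orientation is not None:
        traj.orientation[:] = np.asarray(orientation)
    return trajectory_to_imu(traj, noise_floor=noise, seed=seed)


def circular_recording(radius=0.01, omega=2 * np.pi, duration=10.0, noise=(0.0, 0.0)):
    """Uniform circular pen-tip motion at a level attitude (no noise)."""
    params = TaskParams(task="spiral", duration=duration, rest_duration=0.0,
                        spiral_a=radius, spiral_b=0.0, spiral_omega=omega,
                        orient_amp=0.0, onset_ramp=0.0, seed=0)
    return trajectory_to_imu(generate_trajectory(params), noise_floor=noise, seed=0)
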