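"""Feature engineering: the 18 kinematic channels and summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from penkinetics import (
    CHANNEL_NAMES,
    assemble_feature_tensor,
    compute_jerk,
    estimate_euler,
    integrate_velocity,
    preprocess_recording,
    rotational_acceleration,
    summarize,
)
from penkinetics.features import FeatureTensor, SUMMARY_STATS, summary_feature_names
from penkinetics.recording import FS, GRAVITY_MS2
from penkinetics.simulator import TaskParams, generate_trajectory, trajectory_to_imu

from conftest import circular_recording, static_recording

DT = 1.0 / FS


class TestIntegrateVelocity:
    def test_zero_accel_zero_velocity(self):
        np.testing.assert_array_equal(
            integrate_velocity(np.zeros(50)), np.zeros(50))

    def test_constant_accel_euler_sum(self):
        """v(t) = v(t-1) + a(t) dt with a = 2 m/s^2: after 100 steps v = 2."""
        v = integrate_velocity(np.full(101, 2.0), dt=0.01)
        assert v[0] == 0.0
        assert v[100] == pytest.approx(2.0, abs=1e-12)

    def test_recovers_circular_speed(self):
        """After gravity removal, integrating the simulated centripetal
        acceleration recovers a peak speed of R*Omega within 1%."""
        R, omega = 0.01, 2 * np.pi
        rec = circular_recording(radius=R, omega=omega, duration=10.0)
        dyn = rec.accel.copy() * GRAVITY_MS2
        dyn[:, 2] += GRAVITY_MS2
        v = integrate_velocity(dyn, detrend_window=None)
        # half-range of the vx oscillation cancels the small integration
        # constant contributed by the one-sided endpoint differences
        amplitude = (v[:, 0].max() - v[:, 0].min()) / 2
        assert amplitude == pytest.approx(R * omega, rel=0.01)

    def test_euler_scheme_inverse(self):
        """Differencing the integral recovers the acceleration exactly."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=300)
        v = integrate_velocity(a, dt=DT, detrend_window=None)
        np.testing.assert_allclose(np.diff(v) / DT, a[1:], rtol=1e-9)


class TestDerivatives:
    def test_jerk_of_linear_accel_is_constant(self):
        t = np.arange(200) * DT
        jerk = compute_jerk(3.5 * t, dt=DT)
        np.testing.assert_allclose(jerk, 3.5, rtol=1e-9)

    def test_jerk_of_constant_accel_is_zero(self):
        np.testing.assert_array_equal(compute_jerk(np.full(100, 7.0)), 0.0)

    def test_jerk_second_order_error_bound(self):
        """Central differences on a(t) = sin(2*pi*2*t): the interior error
        is bounded by max|a'''| dt^2 / 6 (Taylor remainder)."""
        t = np.arange(500) * DT
        w = 2 * np.pi * 2.0
        jerk = compute_jerk(np.sin(w * t), dt=DT)
        true = w * np.cos(w * t)
        bound = w**3 * DT**2 / 6.0
        assert np.abs(jerk[1:-1] - true[1:-1]).max() <= bound * 1.01

    def test_rotational_acceleration_backward_difference(self):
        """alpha = (w_t - w_{t-1}) / dt, literally; linear ramp -> constant."""
        t = np.arange(100) * DT
        w = np.column_stack([t * 0, t * 0, 10.0 * t])
        alpha = rotational_acceleration(w, dt=DT)
        np.testing.assert_allclose(alpha[:, 2], 10.0, rtol=1e-9)
        np.testing.assert_array_equal(alpha[:, 0], 0.0)

    def test_rotational_acceleration_constant_rate(self):
        np.testing.assert_array_equal(
            rotational_acceleration(np.full((50, 3), 30.0)), 0.0)

    def test_schemes_agree_on_smooth_input(self):
        """Backward and central differences agree to first order in dt."""
        t = np.arange(400) * DT
        x = np.sin(2 * np.pi * 1.5 * t)
        backward = rotational_acceleration(x[:, None], dt=DT)[:, 0]
        central = compute_jerk(x, dt=DT)
        # half-step offset between schemes: |x''| * dt / 2
        bound = (2 * np.pi * 1.5) ** 2 * DT / 2
        assert np.abs(backward[1:-1] - central[1:-1]).max() <= bound * 1.05

    def test_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_jerk(np.array([1.0]))
        with pytest.raises(ValueError):
            rotational_acceleration(np.array([[1.0, 2.0, 3.0]]))


class TestEstimateEuler:
    def test_static_level_pose(self):
        rec = static_recording()
        euler = estimate_euler(rec.accel, rec.gyro)
        assert np.abs(euler[-1]).max() < 1e-9

    def test_static_roll_converges_to_tilt(self):
        """A pen held at 30 deg roll: the accelerometer tilt reference pulls
        the estimate to 30 +/- 0.5 deg."""
        phi = np.radians(30.0)
        rec = static_recording(duration=5.0, orientation=(phi, 0.0, 0.0))
        euler = estimate_euler(rec.accel, rec.gyro)
        assert np.degrees(euler[-1, 0]) == pytest.approx(30.0, abs=0.5)
        assert np.degrees(euler[-1, 1]) == pytest.approx(0.0, abs=0.5)

    def test_pure_yaw_integration(self):
        """90 deg/s about z for 1 s integrates to 90 deg (no tilt reference)."""
        n = 101
        accel = np.tile([0.0, 0.0, -1.0], (n, 1))
        gyro = np.tile([0.0, 0.0, 90.0], (n, 1))
        euler = estimate_euler(accel, gyro)
        assert np.degrees(euler[-1, 2]) == pytest.approx(90.0, abs=1e-6)


class TestAssembleFeatureTensor:
    def test_channel_contract(self, feature_tensor):
        assert feature_tensor.values.shape == (1084, 18)
        assert feature_tensor.n_channels == 18
        assert feature_tensor.channel_names == CHANNEL_NAMES
        assert np.all(feature_tensor.values >= 0.0)
        assert np.all(feature_tensor.values <= 1.0)
        assert np.all(np.isfinite(feature_tensor.values))

    def test_zero_motion_derived_channels_zero(self):
        """A static pen yields identically zero velocity, jerk and
        rotational acceleration before normalization."""
        pre = preprocess_recording(static_recording(duration=12.0))
        ft = assemble_feature_tensor(pre, normalize=False)
        idx = {name: i for i, name in enumerate(CHANNEL_NAMES)}
        for ch in ("vx", "vy", "vz", "jx", "jy", "jz", "alpha_x", "alpha_y", "alpha_z"):
            np.testing.assert_allclose(ft.values[: ft.valid_length, idx[ch]], 0.0,
                                       atol=1e-7)

    def test_truncation_and_padding_metadata(self, spiral_recording):
        pre = preprocess_recording(spiral_recording)
        short = assemble_feature_tensor(pre, T=2000)
        assert short.values.shape == (2000, 18)
        assert short.valid_length == spiral_recording.n_samples
        np.testing.assert_array_equal(short.values[short.valid_length:], 0.0)

    @given(st.floats(0.5, 20.0))
    @settings(max_examples=10, deadline=None)
    def test_linearity_of_derived_channels(self, c):
        """Scaling the input scales velocity/jerk/alpha by the same factor."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(100, 3))
        np.testing.assert_allclose(
            integrate_velocity(c * a, detrend_window=None),
            c * integrate_velocity(a, detrend_window=None), rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(compute_jerk(c * a), c * compute_jerk(a),
                                   rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(rotational_acceleration(c * a),
                                   c * rotational_acceleration(a), rtol=1e-9, atol=1e-9)


class TestSummarize:
    def _tensor(self, values, valid=None):
        v = np.asarray(values, dtype=float)
        return FeatureTensor(values=v, subject_id="s", task="spiral", label="CN",
                             source="synthetic", valid_length=valid or len(v),
                             channel_names=tuple(f"c{i}" for i in range(v.shape[1])))

    def test_constant_channel(self):
        ft = self._tensor(np.full((10, 18), 3.0))
        out = summarize(ft).reshape(18, 5)
        # order: mean, std, min, max, rms
        np.testing.assert_allclose(out[:, 0], 3.0)
        np.testing.assert_allclose(out[:, 1], 0.0)
        np.testing.assert_allclose(out[:, 4], 3.0)

    def test_two_point_channel(self):
        ft = self._tensor(np.array([[0.0], [1.0]]))
        mean, std, mn, mx, rms = summarize(ft)
        assert (mean, mn, mx) == (0.5, 0.0, 1.0)
        assert std == pytest.approx(0.5)          # population std
        assert rms == pytest.approx(np.sqrt(0.5))

    def test_matches_brute_force(self, feature_tensor):
        """Independent per-channel loop reproduces every statistic."""
        vec = summarize(feature_tensor)
        assert vec.shape == (90,)
        x = feature_tensor.values[: feature_tensor.valid_length]
        brute = []
        for ch in range(18):
            col = x[:, ch]
            brute += [col.mean(), col.std(), col.min(), col.max(),
                      np.sqrt((col**2).mean())]
        np.testing.assert_allclose(vec, brute, rtol=1e-12)

    def test_names_align(self):
        names = summary_feature_names()
        assert len(names) == 90
        assert names[0] == "ax_mean"
        assert names[-1] == "yaw_rms"
        assert all(any(s in n for s in SUMMARY_STATS) for n in names)

    def test_too_short_rejected(self):
        ft = self._tensor(np.zeros((5, 2)), valid=1)
        with pytest.raises(ValueError, match="valid_length"):
            summarize(ft)
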