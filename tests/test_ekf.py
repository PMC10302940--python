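"""Error-state EKF: propagation arithmetic, covariance algebra, ZUPT behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from armimu.config import RunConfig
from armimu.ekf import (
    ErrorState,
    FilterParams,
    NominalState,
    error_transition_matrix,
    initial_state_from_stationary,
    propagate,
    propagate_error_covariance,
    propagate_pair,
    quat_from_rotation_vector,
    quat_multiply,
    quat_to_rotation_matrix,
    run_filter,
    zupt_update,
)
from armimu.errors import StateError
from armimu.synthgen import ImuTrace, hold, imu_from_trajectory, simulate_arm
from armimu.zvd import DetectorParams, detect_zero_velocity

IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def _stationary_trace(n, dt=0.01, g=9.81):
    return ImuTrace(
        t=np.arange(n) * dt,
        accel=np.tile([0.0, 0.0, g], (n, 1)),
        gyro=np.zeros((n, 3)),
    )


class TestQuaternionAlgebra:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_rotation(self, seed):
        rng = np.random.default_rng(seed)
        rv = rng.uniform(-2, 2, 3)
        q = quat_from_rotation_vector(rv)
        expected = Rotation.from_rotvec(rv).as_matrix()
        np.testing.assert_allclose(quat_to_rotation_matrix(q), expected, atol=1e-12)
        rv2 = rng.uniform(-2, 2, 3)
        q2 = quat_from_rotation_vector(rv2)
        R12 = quat_to_rotation_matrix(quat_multiply(q, q2))
        np.testing.assert_allclose(
            R12, expected @ Rotation.from_rotvec(rv2).as_matrix(), atol=1e-12
        )


class TestPropagate:
    def test_stationary_level_state_is_fixed_point(self):
        params = FilterParams(dt=0.01, g=9.81)
        s0 = NominalState()
        s1 = propagate(s0, np.array([0.0, 0.0, 9.81]), np.zeros(3), params)
        np.testing.assert_allclose(s1.p, 0.0, atol=1e-15)
        np.testing.assert_allclose(s1.v, 0.0, atol=1e-15)
        np.testing.assert_allclose(s1.q, IDENTITY_Q, atol=1e-15)

    def test_single_step_arithmetic(self):
        # a_world = (1,0,0): p gains 0.5*1*0.1^2 = 0.005, v gains 0.1
        params = FilterParams(dt=0.1, g=9.81)
        s1 = propagate(NominalState(), np.array([1.0, 0.0, 9.81]), np.zeros(3), params)
        np.testing.assert_allclose(s1.p, [0.005, 0.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(s1.v, [0.1, 0.0, 0.0], atol=1e-15)

    def test_constant_yaw_rate_full_revolution(self):
        params = FilterParams(dt=1e-3, g=9.81)
        state = NominalState()
        gyro = np.array([0.0, 0.0, 1.0])
        accel = np.array([0.0, 0.0, 9.81])
        n = int(round(2 * np.pi / 1e-3))
        for _ in range(n):
            state = propagate(state, accel, gyro, params)
        rv = Rotation.from_quat(np.roll(state.q, -1)).as_rotvec()
        assert np.linalg.norm(rv) == pytest.approx(0.0, abs=1e-3)

    def test_quaternion_norm_preserved(self):
        params = FilterParams(dt=0.01)
        rng = np.random.default_rng(0)
        state = NominalState()
        for _ in range(500):
            state = propagate(state, rng.normal(0, 3, 3), rng.normal(0, 2, 3), params)
            assert abs(np.linalg.norm(state.q) - 1.0) < 1e-9

    def test_non_unit_quaternion_rejected(self):
        bad = NominalState(q=np.array([1.0, 0.5, 0.0, 0.0]))
        with pytest.raises(StateError):
            propagate(bad, np.zeros(3), np.zeros(3), FilterParams())


class TestErrorCovariance:
    def test_identity_transition_keeps_covariance(self):
        # zero dt limit: F -> I and Q -> 0
        params = FilterParams(dt=1e-12, accel_noise_std=0.0, gyro_noise_std=0.0)
        cov = np.diag(np.arange(1.0, 10.0))
        out = propagate_error_covariance(ErrorState(cov=cov), NominalState(), np.zeros(3), params)
        np.testing.assert_allclose(out.cov, cov, atol=1e-9)

    def test_matches_dense_matrix_oracle(self):
        params = FilterParams(dt=0.02, accel_noise_std=0.1, gyro_noise_std=0.01)
        rng = np.random.default_rng(5)
        A = rng.standard_normal((9, 9))
        cov = A @ A.T  # random PSD
        state = NominalState(q=quat_from_rotation_vector([0.1, -0.2, 0.3]))
        accel = np.array([1.0, -2.0, 9.0])
        F = error_transition_matrix(state, accel, params)
        expected = F @ cov @ F.T + params.process_noise()
        expected = 0.5 * (expected + expected.T)
        out = propagate_error_covariance(ErrorState(cov=cov), state, accel, params)
        np.testing.assert_allclose(out.cov, expected, atol=1e-12)

    def test_trace_never_decreases_under_propagation(self):
        params = FilterParams(dt=0.01, accel_noise_std=0.05, gyro_noise_std=0.005)
        err = ErrorState(cov=np.eye(9) * 1e-4)
        state = NominalState()
        for _ in range(100):
            new = propagate_error_covariance(err, state, np.array([0.5, 0.0, 9.81]), params)
            assert np.trace(new.cov) >= np.trace(err.cov) - 1e-15
            err = new

    def test_non_psd_covariance_rejected(self):
        bad = np.eye(9)
        bad[0, 0] = -1.0
        with pytest.raises(StateError):
            propagate_error_covariance(
                ErrorState(cov=bad), NominalState(), np.zeros(3), FilterParams()
            )


class TestZuptUpdate:
    def test_zero_velocity_state_unchanged_but_covariance_shrinks(self):
        params = FilterParams()
        err = ErrorState(cov=np.eye(9) * 0.1)
        state = NominalState()  # v already exactly zero
        new_state, new_err = zupt_update(state, err, params)
        np.testing.assert_allclose(new_state.p, state.p, atol=1e-15)
        np.testing.assert_allclose(new_state.v, state.v, atol=1e-15)
        vel_block = slice(3, 6)
        assert np.trace(new_err.cov[vel_block, vel_block]) < np.trace(err.cov[vel_block, vel_block])

    def test_large_prior_small_noise_zeroes_velocity(self):
        params = FilterParams(zupt_noise_std=1e-9)
        err = ErrorState(cov=np.eye(9) * 10.0)
        state = NominalState(v=np.array([1.0, 0.0, 0.0]))
        new_state, _ = zupt_update(state, err, params)
        assert np.linalg.norm(new_state.v) < 1e-6

    def test_velocity_covariance_strictly_decreases(self):
        params = FilterParams()
        rng = np.random.default_rng(2)
        A = rng.standard_normal((9, 9)) * 0.1
        err = ErrorState(cov=A @ A.T + np.eye(9) * 1e-3)
        state = NominalState(v=np.array([0.1, -0.2, 0.05]))
        for _ in range(5):
            state, new_err = zupt_update(state, err, params)
            v = slice(3, 6)
            assert np.trace(new_err.cov[v, v]) < np.trace(err.cov[v, v])
            err = new_err


class TestRunFilter:
    def test_empty_trace_gives_empty_result(self):
        trace = ImuTrace(t=np.zeros(0), accel=np.zeros((0, 3)), gyro=np.zeros((0, 3)))
        res = run_filter(trace, None, NominalState(), FilterParams())
        assert res.n == 0

    def test_stationary_run_drifts_below_one_centimetre(self):
        """60 s of stationary data with default noise: ZUPT pins the position."""
        cfg = RunConfig()
        traj = simulate_arm(cfg.geometry(), (hold(0.5), hold(0.4)), 60.0, 0.01, 0.0, seed=7)
        trace = imu_from_trajectory(
            traj,
            bias_a=cfg.synth.bias_a,
            bias_g=cfg.synth.bias_g,
            noise_std_a=cfg.synth.noise_std_a,
            noise_std_g=cfg.synth.noise_std_g,
            seed=7,
        )
        mask = detect_zero_velocity(trace, cfg.detector_params())
        p0 = np.array([traj.p_wrist[0, 0] / 100, traj.p_wrist[0, 1] / 100, 0.0])
        init = NominalState(p=p0, q=quat_from_rotation_vector([0, 0, float(traj.yaw[0])]))
        res = run_filter(trace, mask, init, cfg.filter_params())
        drift_cm = np.linalg.norm(res.p[-1] - p0) * 100
        assert drift_cm < 1.0

    def test_dead_reckoning_consistency_zero_noise(self, gait_trajectory, clean_trace):
        """Mask all-false, clean IMU: integration reproduces the wrist path."""
        cfg = RunConfig()
        traj = gait_trajectory
        p0 = np.array([traj.p_wrist[0, 0] / 100, traj.p_wrist[0, 1] / 100, 0.0])
        init = NominalState(p=p0, q=quat_from_rotation_vector([0, 0, float(traj.yaw[0])]))
        res = run_filter(clean_trace, None, init, cfg.filter_params())
        err_cm = np.linalg.norm(res.p[:, :2] * 100 - traj.p_wrist, axis=1)
        assert err_cm.max() < 0.5  # first-order integration error over 10 s

    def test_zupt_halves_drift_on_gait_suite(self, geometry):
        """Median final-position error with ZUPT <= 0.5x pure integration, 20 seeds."""
        from armimu.synthgen import stance_swing_profile

        cfg = RunConfig()
        s = cfg.synth
        with_z, without_z = [], []
        for seed in range(20):
            profiles = (
                stance_swing_profile(s.shoulder.lo, s.shoulder.hi, s.period, s.stance_fraction),
                stance_swing_profile(s.elbow.lo, s.elbow.hi, s.period, s.stance_fraction),
            )
            traj = simulate_arm(geometry, profiles, 10.0, s.dt, 0.0, seed)
            trace = imu_from_trajectory(
                traj,
                bias_a=s.bias_a,
                bias_g=s.bias_g,
                noise_std_a=s.noise_std_a,
                noise_std_g=s.noise_std_g,
                seed=seed + 1000,
            )
            p0 = np.array([traj.p_wrist[0, 0] / 100, traj.p_wrist[0, 1] / 100, 0.0])
            init = NominalState(p=p0, q=quat_from_rotation_vector([0, 0, float(traj.yaw[0])]))
            params = cfg.filter_params()
            mask = detect_zero_velocity(trace, cfg.detector_params())
            truth_final = np.array([traj.p_wrist[-1, 0] / 100, traj.p_wrist[-1, 1] / 100, 0.0])
            rz = run_filter(trace, mask, init, params)
            rn = run_filter(trace, None, init, params)
            with_z.append(np.linalg.norm(rz.p[-1] - truth_final))
            without_z.append(np.linalg.norm(rn.p[-1] - truth_final))
        assert np.median(with_z) <= 0.5 * np.median(without_z)

    def test_two_sample_update_refines_single_sample(self):
        """With constant samples and no rotation the two-sample step collapses
        to the plain single-sample transcription."""
        params = FilterParams(dt=0.01)
        state = NominalState(v=np.array([0.1, 0.0, 0.0]))
        accel = np.array([0.5, -0.2, 9.7])
        gyro = np.zeros(3)
        a = propagate(state, accel, gyro, params)
        b = propagate_pair(state, accel, gyro, accel, gyro, params)
        np.testing.assert_allclose(a.p, b.p, atol=1e-15)
        np.testing.assert_allclose(a.v, b.v, atol=1e-15)
        np.testing.assert_allclose(a.q, b.q, atol=1e-15)


class TestInitialAlignment:
    def test_level_sensor_gives_identity_tilt(self):
        trace = _stationary_trace(100)
        init = initial_state_from_stationary(trace)
        np.testing.assert_allclose(init.q, IDENTITY_Q, atol=1e-12)

    def test_tilted_sensor_recovers_gravity_direction(self):
        # body tilted 30 degrees about x: accel reads R^T (0,0,g)
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        f = R.T @ np.array([0.0, 0.0, 9.81])
        trace = ImuTrace(t=np.arange(50) * 0.01, accel=np.tile(f, (50, 1)), gyro=np.zeros((50, 3)))
        init = initial_state_from_stationary(trace)
        R_est = quat_to_rotation_matrix(init.q)
        np.testing.assert_allclose(R_est @ f, [0.0, 0.0, 9.81], atol=1e-9)
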