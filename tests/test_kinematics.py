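"""Forward/inverse kinematics, aperture, grasp events and angle utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachkin import kinematics as K
from reachkin.preprocess import gaussian_smooth


def _random_angles(rng, n, lim=K.SAFE_ANGLE_RANGE):
    return rng.uniform(-lim, lim, size=(n, K.N_ANGLES))


class TestRoundTrip:
    def test_neutral_posture_gives_zero_angles(self, template):
        angles = K.inverse_kinematics(template.neutral_keypoints, template)
        assert np.abs(angles).max() < 1e-12

    def test_forward_of_zeros_is_neutral(self, template):
        kp = K.forward_kinematics(np.zeros(K.N_ANGLES), template)
        assert np.allclose(kp, template.neutral_keypoints, atol=1e-12)

    def test_roundtrip_on_random_in_range_angles(self, template, rng):
        theta = _random_angles(rng, 1000)
        kp = K.forward_kinematics(theta, template)
        back = K.inverse_kinematics(kp, template)
        assert np.abs(back - theta).max() < 1e-6

    def test_link_lengths_preserved_by_forward_kinematics(self, template, rng):
        theta = _random_angles(rng, 200)
        kp = K.forward_kinematics(theta, template)
        for (a, b), length in template.segment_lengths().items():
            found = np.linalg.norm(kp[:, b] - kp[:, a], axis=-1)
            assert np.abs(found - length).max() < 1e-9

    def test_single_axis_rotation_recovers_that_angle_only(self, template):
        for idx, name in enumerate(K.ANGLE_NAMES):
            theta = np.zeros(K.N_ANGLES)
            theta[idx] = 30.0
            kp = K.forward_kinematics(theta, template)
            back = K.inverse_kinematics(kp, template)
            assert abs(back[idx] - 30.0) < 1e-9, name
            others = np.delete(back, idx)
            assert np.abs(others).max() < 1e-9, name

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_roundtrip_property(self, template, seed):
        r = np.random.default_rng(seed)
        theta = _random_angles(r, 5)
        back = K.inverse_kinematics(K.forward_kinematics(theta, template), template)
        assert np.abs(back - theta).max() < 1e-6


class TestRigidInvariance:
    def test_translation_invariance(self, template, rng):
        theta = _random_angles(rng, 50)
        kp = K.forward_kinematics(theta, template)
        shift = np.array([13.0, -7.0, 4.2])
        a0 = K.inverse_kinematics(kp, template)
        a1 = K.inverse_kinematics(kp + shift, template)
        assert np.abs(a1 - a0).max() < 1e-9

    def test_distal_angles_invariant_to_global_rotation(self, template, rng):
        from scipy.spatial.transform import Rotation

        theta = _random_angles(rng, 50, lim=40.0)
        kp = K.forward_kinematics(theta, template)
        rot = Rotation.from_euler("xyz", [17.0, -9.0, 23.0], degrees=True)
        kpr = kp @ rot.as_matrix().T
        a0 = K.inverse_kinematics(kp, template)
        a1 = K.inverse_kinematics(kpr, template)
        pip = [K.ANGLE_NAMES.index(f"PIP_flex_{d}") for d in range(1, 5)]
        assert np.abs(a1[:, pip] - a0[:, pip]).max() < 1e-9

    def test_frame_wise_computation_time_reversal(self, template, rng):
        theta = _random_angles(rng, 20, lim=40.0)
        kp = K.forward_kinematics(theta, template)
        fwd = K.inverse_kinematics(kp, template)
        rev = K.inverse_kinematics(kp[::-1], template)
        assert np.allclose(rev[::-1], fwd)
        assert np.allclose(K.paw_aperture(kp[::-1])[::-1], K.paw_aperture(kp))


class TestErrorsAndFlags:
    def test_degenerate_segment_raises(self, template):
        kp = template.neutral_keypoints.copy()
        kp[K.ELBOW] = kp[K.SHOULDER]
        with pytest.raises(K.DegenerateSegmentError):
            K.inverse_kinematics(kp, template)

    def test_nonfinite_keypoints_rejected(self, template):
        kp = template.neutral_keypoints.copy()
        kp[0, 0] = np.nan
        with pytest.raises(ValueError):
            K.inverse_kinematics(kp, template)

    def test_nonfinite_angles_rejected(self, template):
        theta = np.zeros(K.N_ANGLES)
        theta[3] = np.inf
        with pytest.raises(ValueError):
            K.forward_kinematics(theta, template)

    def test_unwrap_keeps_traces_continuous(self, template):
        # smooth trajectory passing through large shoulder excursions
        t = np.linspace(0, 1, 120)
        theta = np.zeros((1, t.size, K.N_ANGLES))
        theta[0, :, 0] = 70 * np.sin(2 * np.pi * t)
        theta[0, :, 2] = 60 * np.cos(2 * np.pi * t)
        kp = K.forward_kinematics(theta, template)
        session = K.KeypointSession(positions=kp, frame_times=t)
        tensor, _ = K.inverse_kinematics_trials(session, template)
        assert np.abs(np.diff(tensor.angles, axis=1)).max() < 90.0


class TestAperture:
    def test_tips_at_digit_centroid_give_zero(self, template):
        # placing all tips at the mean of the other 8 digit markers makes
        # the tips coincide with the 12-marker centroid exactly
        kp = template.neutral_keypoints.copy()
        kp[K.TIP] = kp[K.PIP + K.MCP].mean(axis=0)
        assert K.paw_aperture(kp) < 1e-12

    def test_rigid_translation_leaves_aperture_unchanged(self, template):
        kp = template.neutral_keypoints
        assert np.isclose(K.paw_aperture(kp + 11.0), K.paw_aperture(kp))

    def test_scaling_digits_about_centroid_doubles_aperture(self, template):
        kp = template.neutral_keypoints.copy()
        c = kp[K.DIGIT_MARKERS].mean(axis=0)
        kp2 = kp.copy()
        kp2[K.DIGIT_MARKERS] = c + 2.0 * (kp[K.DIGIT_MARKERS] - c)
        assert np.isclose(K.paw_aperture(kp2), 2.0 * K.paw_aperture(kp))

    def test_missing_digit_marker_flags_frame(self, template):
        kp = template.neutral_keypoints.copy()
        kp[K.TIP[0]] = np.nan
        assert np.isnan(K.paw_aperture(kp))


class TestGraspEvents:
    def test_constructed_minimum_then_maximum(self):
        t = np.arange(0, 0.4, 0.01)
        lift = 0.05
        ap = np.where(t < 0.13, 10 - 40 * t, 10 - 40 * 0.13 + 50 * (t - 0.13))
        ap = np.where(t > 0.20, ap[t > 0.20].max() - 30 * (t - 0.20), ap)
        zv = np.exp(-((t - 0.08) ** 2) / (2 * 0.02**2))
        ge = K.detect_grasp_events(ap, t, lift, zv)
        assert np.isclose(ge.collect_time[0], 0.13, atol=0.011)
        assert np.isclose(ge.extend_time[0], 0.20, atol=0.011)
        assert np.isclose(ge.max_z_velocity_time[0], 0.08, atol=0.011)
        assert ge.collect_time[0] < ge.extend_time[0]

    def test_monotonic_aperture_leaves_collect_undefined(self):
        t = np.arange(0, 0.3, 0.01)
        ge = K.detect_grasp_events(1.0 + t, t, 0.05, np.ones_like(t))
        assert np.isnan(ge.collect_time[0])
        assert np.isnan(ge.extend_time[0])

    def test_velocity_peak_precedes_collect_in_generated_sessions(self, small_session):
        ses = small_session
        kp, t = ses.keypoints.positions, ses.keypoints.frame_times
        dt = t[1] - t[0]
        ap = gaussian_smooth(K.paw_aperture(kp), 15.0, bin_ms=1000 * dt, axis=1)
        zv = gaussian_smooth(
            np.gradient(K.paw_centroid(kp)[..., 2], dt, axis=1),
            15.0, bin_ms=1000 * dt, axis=1)
        ge = K.detect_grasp_events(ap, t, ses.events.lift_time, zv)
        lag = ge.collect_time - ge.max_z_velocity_time
        assert np.nanmedian(lag) > 0


class TestCorrelationsAndVelocities:
    def test_identical_series_correlate_perfectly(self, rng):
        x = rng.standard_normal(500)
        a = np.tile(x[:, None], (1, 24))
        corr, flags = K.joint_correlations(a)
        assert not flags.any()
        assert np.allclose(corr, 1.0)

    def test_independent_noise_correlations_vanish(self, rng):
        a = rng.standard_normal((20000, 24))
        corr, _ = K.joint_correlations(a)
        off = corr[~np.eye(24, dtype=bool)]
        assert np.abs(off).max() < 5.0 / np.sqrt(20000) * 2

    def test_matrix_symmetric_unit_diagonal(self, rng):
        a = rng.standard_normal((300, 24))
        corr, _ = K.joint_correlations(a)
        assert np.abs(corr - corr.T).max() < 1e-12
        assert np.allclose(np.diag(corr), 1.0)
        assert np.abs(corr).max() <= 1.0 + 1e-12

    def test_contact_frames_excluded(self, rng):
        a = rng.standard_normal((100, 24))
        mask = np.zeros(100, dtype=bool)
        mask[50:] = True
        corr, _ = K.joint_correlations(a, mask)
        ref, _ = K.joint_correlations(a[:50])
        assert np.allclose(corr, ref)

    def test_constant_angle_flagged(self, rng):
        a = rng.standard_normal((200, 24))
        a[:, 3] = 5.0
        corr, flags = K.joint_correlations(a)
        assert flags[3] and not flags[4]
        assert np.isnan(corr[3]).all()

    def test_velocity_of_constant_and_ramp(self):
        t = np.arange(50) * 0.01
        const = np.full((1, 50, 24), 3.0)
        assert np.allclose(K.joint_velocities(const, 0.01), 0.0)
        ramp = np.tile((7.0 * t)[None, :, None], (1, 1, 24))
        assert np.allclose(K.joint_velocities(ramp, 0.01), 7.0)

    def test_integrating_velocity_recovers_smooth_angle(self):
        t = np.arange(400) * 0.01
        a = 20 * np.sin(2 * np.pi * 0.7 * t) + 5 * np.cos(2 * np.pi * 0.3 * t)
        a = np.tile(a[None, :, None], (1, 1, 24))
        v = K.joint_velocities(a, 0.01)
        rec = a[0, 0, 0] + np.concatenate(
            [[0.0], np.cumsum(0.5 * (v[0, 1:, 0] + v[0, :-1, 0]) * 0.01)])
        # trapezoid integral of central differences: O(dt^2) on smooth traces
        assert np.abs(rec - a[0, :, 0]).max() < 0.05
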