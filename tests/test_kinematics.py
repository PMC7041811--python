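"""Geometry and signal-processing oracles for the kinematics layer.

Expected values are closed-form: Butterworth magnitude response, hand
trigonometry for projection/back angles, exact circle kinematics.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from equispine.kinematics import (
    DegenerateGeometryError,
    FilterParameterError,
    HorseFrame,
    back_angle,
    body_tracking_angle,
    head_swivel_angle,
    heading_frame,
    lean_correct,
    lowpass_filter,
    pelvic_angles,
    projection_angle,
    speed_from_marker,
)

RATE = 100.0


def identity_frame(n: int) -> HorseFrame:
    return HorseFrame(
        xhat=np.tile([1.0, 0, 0], (n, 1)),
        yhat=np.tile([0, 1.0, 0], (n, 1)),
        zhat=np.tile([0, 0, 1.0], (n, 1)),
    )


def sine_gain(freq, cutoff, order=4, rate=RATE, seconds=10.0):
    """Measured amplitude ratio of a filtered pure sine (middle section)."""
    t = np.arange(int(seconds * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    y = lowpass_filter(x, cutoff, rate, order)
    mid = slice(int(2 * rate), int(8 * rate))
    return np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full(200, 7.0)
        np.testing.assert_allclose(lowpass_filter(x, 30.0, RATE), 7.0)

    def test_stopband_gain_matches_squared_butterworth(self):
        # Digital 4th-order Butterworth (bilinear transform, prewarped
        # cutoff): |H(f)|^2 = 1 / (1 + (tan(pi f/fs)/tan(pi fc/fs))^8);
        # forward-backward application squares it again.
        warp = np.tan(np.pi * 45.0 / RATE) / np.tan(np.pi * 30.0 / RATE)
        expected = 1.0 / (1.0 + warp ** 8)
        assert sine_gain(45.0, 30.0) == pytest.approx(expected, rel=0.02)

    def test_passband_preserved_within_one_percent(self):
        assert sine_gain(2.0, 30.0) == pytest.approx(1.0, abs=0.01)
        # stride-band energy (<= 5 Hz) essentially untouched
        assert sine_gain(5.0, 30.0) >= 0.99

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(FilterParameterError):
            lowpass_filter(np.zeros(100), 50.0, RATE)


class TestHeadingFrame:
    def test_straight_motion_along_x(self):
        track = np.column_stack([np.linspace(0, 5000, 200), np.zeros(200)])
        f = heading_frame(track, RATE)
        np.testing.assert_allclose(f.xhat, np.tile([1, 0, 0], (200, 1)), atol=1e-9)
        np.testing.assert_allclose(f.yhat, np.tile([0, 1, 0], (200, 1)), atol=1e-9)

    def test_motion_along_y(self):
        track = np.column_stack([np.zeros(200), np.linspace(0, 5000, 200)])
        f = heading_frame(track, RATE)
        np.testing.assert_allclose(f.xhat[:, :2], np.tile([0, 1], (200, 1)), atol=1e-9)
        np.testing.assert_allclose(f.yhat[:, :2], np.tile([-1, 0], (200, 1)), atol=1e-9)

    def test_ccw_circle_yhat_points_to_centre(self):
        t = np.arange(800) / RATE
        r = 5000.0
        track = np.column_stack([r * np.cos(0.7 * t), r * np.sin(0.7 * t)])
        f = heading_frame(track, RATE)
        mid = slice(100, 700)
        to_centre = -track[mid]
        to_centre /= np.linalg.norm(to_centre, axis=1)[:, None]
        cosang = np.einsum("ij,ij->i", f.yhat[mid, :2], to_centre)
        assert cosang.min() > 0.999

    def test_stationary_track_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            heading_frame(np.zeros((200, 2)), RATE)


class TestProjectionAngle:
    def test_parallel_to_reference_is_zero(self):
        f = identity_frame(4)
        v = np.tile([3.0, 0, 0], (4, 1))
        np.testing.assert_allclose(projection_angle(v, f, "sagittal"), 0.0, atol=1e-12)

    def test_frontal_hand_trigonometry(self):
        # left->right tuber coxae line, 0.2 height change over 2.0 lateral
        # span: |angle| = atan(0.2 / 2.0) = 5.71 deg.
        f = identity_frame(1)
        v = np.array([[0.0, -2.0, -0.2]])
        ref = np.array([[0.0, -1.0, 0.0]])
        ang = projection_angle(v, f, "frontal", reference=ref)
        assert abs(ang[0]) == pytest.approx(np.degrees(np.arctan2(0.2, 2.0)),
                                            abs=1e-9)
        assert abs(ang[0]) == pytest.approx(5.711, abs=1e-3)

    def test_orthogonal_vector_degenerate(self):
        f = identity_frame(1)
        with pytest.raises(DegenerateGeometryError):
            projection_angle(np.array([[0.0, 1.0, 0.0]]), f, "sagittal")

    @given(st.floats(-179, 179), st.floats(0.1, 10), st.floats(-1, 1))
    def test_rotation_equivariance_about_vertical(self, rot_deg, scale, vz):
        """Rotating vector and frame jointly about z leaves the angle fixed."""
        v = np.array([[scale, 0.4 * scale, vz]])
        f = identity_frame(1)
        base = projection_angle(v, f, "dorsal")
        c, s = np.cos(np.deg2rad(rot_deg)), np.sin(np.deg2rad(rot_deg))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        f_rot = HorseFrame(xhat=f.xhat @ R.T, yhat=f.yhat @ R.T, zhat=f.zhat @ R.T)
        rotated = projection_angle(v @ R.T, f_rot, "dorsal")
        np.testing.assert_allclose(rotated, base, atol=1e-8)


class TestPelvicAngles:
    def test_level_square_pelvis(self):
        n = 3
        f = identity_frame(n)
        ts = np.tile([0.0, 0, 1400.0], (n, 1))
        ltc = np.tile([150.0, 260.0, 1300.0], (n, 1))
        rtc = np.tile([150.0, -260.0, 1300.0], (n, 1))
        roll, pitch, yaw = pelvic_angles(ts, ltc, rtc, f)
        np.testing.assert_allclose(roll, 0.0, atol=1e-9)
        np.testing.assert_allclose(yaw, 0.0, atol=1e-9)
        # pitch is the constant anatomical inclination of ts -> midpoint
        np.testing.assert_allclose(
            pitch, np.degrees(np.arctan2(-100.0, 150.0)), atol=1e-9)

    def test_raised_coxae_hand_trigonometry(self):
        # left tuber coxae raised by 0.2 with lateral span 2.0:
        # roll (positive right-down) = +atan(0.2/2.0) = +5.71 deg
        f = identity_frame(1)
        ts = np.array([[0.0, 0.0, 0.0]])
        ltc = np.array([[0.5, 1.0, 0.2]])
        rtc = np.array([[0.5, -1.0, 0.0]])
        roll, _, _ = pelvic_angles(ts, ltc, rtc, f)
        assert roll[0] == pytest.approx(5.7106, abs=1e-3)
        # and the mirror case (right raised) negates it
        roll2, _, _ = pelvic_angles(ts, ltc * [1, 1, 0], rtc + [0, 0, 0.2], f)
        assert roll2[0] == pytest.approx(-5.7106, abs=1e-3)


class TestLeanCorrect:
    def test_zero_is_identity(self):
        f = identity_frame(5)
        g = lean_correct(f, 0.0)
        np.testing.assert_allclose(g.yhat, f.yhat)
        np.testing.assert_allclose(g.zhat, f.zhat)

    def test_plus_then_minus_restores_frame(self):
        f = identity_frame(5)
        g = lean_correct(lean_correct(f, 9.5), -9.5)
        np.testing.assert_allclose(g.yhat, f.yhat, atol=1e-12)
        np.testing.assert_allclose(g.zhat, f.zhat, atol=1e-12)
        np.testing.assert_allclose(g.lean_deg, 0.0, atol=1e-12)

    def test_correction_zeroes_measured_roll(self):
        """A pelvis rolled by lambda reads zero in the lambda-corrected frame."""
        lam = 12.0
        f = identity_frame(1)
        rad = np.deg2rad(lam)
        # roll the coxae line right-down by lam
        ltc = np.array([[0.0, np.cos(rad), np.sin(rad)]])
        rtc = -ltc
        ts = np.array([[-0.5, 0.0, 0.0]])
        roll_before, _, _ = pelvic_angles(ts, ltc, rtc, f)
        assert roll_before[0] == pytest.approx(lam, abs=1e-9)
        roll_after, _, _ = pelvic_angles(ts, ltc, rtc, lean_correct(f, lam))
        assert roll_after[0] == pytest.approx(0.0, abs=1e-9)


class TestBackAngle:
    def test_collinear_markers_zero_everywhere(self):
        n = 50
        f = identity_frame(n)
        t = np.linspace(0, 1, n)
        cranial = np.column_stack([1000 + 50 * t, 10 * t, 1400 + 30 * t])
        apex = np.column_stack([500 + 50 * t, 10 * t, 1400 + 30 * t])
        caudal = np.column_stack([0 + 50 * t, 10 * t, 1400 + 30 * t])
        for plane in ("sagittal", "dorsal"):
            np.testing.assert_allclose(
                back_angle(cranial, apex, caudal, f, plane), 0.0, atol=1e-9)

    @pytest.mark.parametrize("plane,offset,sign", [
        ("sagittal", np.array([0, 0, -30.0]), +1),  # apex below chord
        ("sagittal", np.array([0, 0, +30.0]), -1),
        ("dorsal", np.array([0, 40.0, 0]), +1),     # apex left of chord
        ("dorsal", np.array([0, -40.0, 0]), -1),
    ])
    def test_isoceles_geometry(self, plane, offset, sign):
        """Apex displaced by h perpendicular to the chord: angle 2*atan(h/c)."""
        c = 500.0
        f = identity_frame(1)
        cranial = np.array([[c, 0, 1400.0]])
        caudal = np.array([[-c, 0, 1400.0]])
        apex = np.array([[0, 0, 1400.0]]) + offset
        h = np.abs(offset).max()
        expected = sign * 2 * np.degrees(np.arctan(h / c))
        ang = back_angle(cranial, apex, caudal, f, plane)
        assert ang[0] == pytest.approx(expected, abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        n = 20
        f = identity_frame(n)
        cranial = rng.normal(size=(n, 3)) + [1000, 0, 1400]
        apex = rng.normal(size=(n, 3)) + [500, 0, 1400]
        caudal = rng.normal(size=(n, 3)) + [0, 0, 1400]
        shift = np.array([123.4, -56.7, 89.0])
        for plane in ("sagittal", "dorsal"):
            base = back_angle(cranial, apex, caudal, f, plane)
            moved = back_angle(cranial + shift, apex + shift, caudal + shift,
                               f, plane)
            np.testing.assert_allclose(moved, base, atol=1e-9)


class TestBodyTrackingAndHeadSwivel:
    def _frame_and_bodies(self, track_deg=0.0, swivel_deg=0.0, n=4):
        f = identity_frame(n)
        ts = np.tile([0.0, 0, 1400], (n, 1))
        rad = np.deg2rad(track_deg)
        withers = ts + 1000 * np.array([np.cos(rad), -np.sin(rad), 0.0])
        srad = np.deg2rad(track_deg + swivel_deg)
        head = withers + 900 * np.array([np.cos(srad), -np.sin(srad), 0.0])
        return f, head, withers, ts

    def test_aligned_body_zero(self):
        f, head, withers, ts = self._frame_and_bodies()
        np.testing.assert_allclose(body_tracking_angle(withers, ts, f), 0, atol=1e-9)
        np.testing.assert_allclose(head_swivel_angle(head, withers, ts, f), 0,
                                   atol=1e-9)

    def test_forehand_ten_right_positive(self):
        f, _, withers, ts = self._frame_and_bodies(track_deg=10.0)
        np.testing.assert_allclose(body_tracking_angle(withers, ts, f), 10.0,
                                   atol=1e-9)

    def test_head_eight_right_positive(self):
        f, head, withers, ts = self._frame_and_bodies(swivel_deg=8.0)
        np.testing.assert_allclose(head_swivel_angle(head, withers, ts, f), 8.0,
                                   atol=1e-9)

    def test_mirror_antisymmetry(self):
        f, head, withers, ts = self._frame_and_bodies(track_deg=7.0, swivel_deg=-4.0)
        flip = np.array([1.0, -1.0, 1.0])
        bt = body_tracking_angle(withers, ts, f)
        hs = head_swivel_angle(head, withers, ts, f)
        np.testing.assert_allclose(
            body_tracking_angle(withers * flip, ts * flip, f), -bt, atol=1e-9)
        np.testing.assert_allclose(
            head_swivel_angle(head * flip, withers * flip, ts * flip, f), -hs,
            atol=1e-9)


class TestSpeed:
    def test_uniform_motion(self):
        t = np.arange(400) / RATE
        track = np.column_stack([3350.0 * t, np.zeros_like(t)])  # 3.35 m/s
        speed = speed_from_marker(track, RATE)
        np.testing.assert_allclose(speed, 3.35, atol=1e-9)

    def test_circular_motion_r_omega(self):
        t = np.arange(1500) / RATE
        r, omega = 4850.0, 0.68  # mm, rad/s
        track = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t)])
        speed = speed_from_marker(track, RATE)
        expected = r * omega / 1000.0
        mid = slice(100, 1400)
        np.testing.assert_allclose(speed[mid], expected, rtol=0.01)

    def test_stationary_marker_zero(self):
        track = np.full((300, 2), 1234.5)
        np.testing.assert_allclose(speed_from_marker(track, RATE), 0.0, atol=1e-12)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            speed_from_marker(np.zeros((2, 2)), RATE)
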