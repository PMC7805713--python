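"""Effort-feature oracles: shoelace areas, finite-difference kinematics."""

import numpy as np
import pytest

from engagekit.errors import MissingKeypointError, TooShortError
from engagekit.laban import (
    JOINTS,
    JointKinematics,
    arm_geometry,
    joint_kinematics,
    laban_series,
    space,
    time_feature,
    weight,
)
from engagekit.pose_io import L_SHOULDER, L_WRIST, R_SHOULDER, R_WRIST

from conftest import (
    UNIT_SQUARE_ARMS,
    body_from_points,
    make_elbow_track,
    make_frame,
    make_track,
    static_arm_bodies,
)


def shoelace(pts: np.ndarray) -> float:
    """Independent polygon-area oracle (vertices in order)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _is_strictly_convex(quad: np.ndarray, min_cross: float = 1.0) -> bool:
    crosses = []
    for i in range(4):
        u = quad[(i + 1) % 4] - quad[i]
        v = quad[(i + 2) % 4] - quad[(i + 1) % 4]
        crosses.append(u[0] * v[1] - u[1] * v[0])
    crosses = np.array(crosses)
    return bool((crosses > min_cross).all() or (crosses < -min_cross).all())


def random_convex_quad(rng) -> np.ndarray:
    """Strictly convex quadrilateral LS-RS-RH-LH in consistent cyclic order."""
    while True:
        center = rng.uniform(-200, 200, 2)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 4))
        r = rng.uniform(10, 150, 4)
        quad = center + np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        if _is_strictly_convex(quad):
            return quad


class TestArmGeometry:
    def test_unit_square_angles_are_right(self):
        g = arm_geometry(make_frame(UNIT_SQUARE_ARMS))
        # dot-product oracle: all four vectors are axis-aligned unit vectors
        assert g.theta1 == pytest.approx(np.pi / 2)
        assert g.theta2 == pytest.approx(np.pi / 2)
        assert not g.degenerate

    def test_all_points_identical_is_degenerate(self):
        frame = make_frame({k: (3.0, 3.0) for k in UNIT_SQUARE_ARMS})
        assert arm_geometry(frame).degenerate

    def test_partial_degeneracy_keeps_other_angle(self):
        pts = dict(UNIT_SQUARE_ARMS)
        pts[L_WRIST] = pts[L_SHOULDER]  # a-vector collapses
        g = arm_geometry(make_frame(pts))
        assert g.degenerate and np.isnan(g.theta1)
        assert g.theta2 == pytest.approx(np.pi / 2)

    def test_missing_keypoint_names_joint(self):
        pts = {k: v for k, v in UNIT_SQUARE_ARMS.items() if k != R_WRIST}
        with pytest.raises(MissingKeypointError, match="right_hand"):
            arm_geometry(make_frame(pts))


class TestSpace:
    def test_unit_square_area(self):
        assert space(make_frame(UNIT_SQUARE_ARMS)) == pytest.approx(1.0)

    def test_scaled_square_area_quadratic(self):
        pts = {k: (2 * x, 2 * y) for k, (x, y) in UNIT_SQUARE_ARMS.items()}
        assert space(make_frame(pts)) == pytest.approx(4.0)

    def test_collinear_points_give_zero(self):
        pts = {L_SHOULDER: (0.0, 0.0), R_SHOULDER: (1.0, 0.0),
               L_WRIST: (2.0, 0.0), R_WRIST: (3.0, 0.0)}
        assert space(make_frame(pts)) == 0.0

    def test_matches_shoelace_on_random_convex_quadrilaterals(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            quad = random_convex_quad(rng)  # LS, RS, RH, LH in order
            pts = {L_SHOULDER: tuple(quad[0]), R_SHOULDER: tuple(quad[1]),
                   R_WRIST: tuple(quad[2]), L_WRIST: tuple(quad[3])}
            expected = shoelace(quad)
            got = space(make_frame(pts))
            assert got == pytest.approx(expected, rel=1e-9)

    def test_rigid_motion_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(7)
        quad = random_convex_quad(rng)
        def sp(q):
            return space(make_frame({L_SHOULDER: tuple(q[0]), R_SHOULDER: tuple(q[1]),
                                     R_WRIST: tuple(q[2]), L_WRIST: tuple(q[3])}))
        base = sp(quad)
        assert sp(quad + np.array([37.0, -11.0])) == pytest.approx(base, rel=1e-12)
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert sp(quad @ R.T) == pytest.approx(base, rel=1e-9)
        assert sp(quad * 3.0) == pytest.approx(9.0 * base, rel=1e-12)


class TestJointKinematics:
    def test_static_pose_has_zero_velocity(self):
        track = make_track(static_arm_bodies(10))
        for j in JOINTS:
            k = joint_kinematics(track, j)
            np.testing.assert_allclose(k.omega, 0.0, atol=1e-12)
            np.testing.assert_allclose(k.omega_dot, 0.0, atol=1e-12)

    def test_linear_angle_recovers_constant_velocity(self):
        fps = 30.0
        t = np.arange(60) / fps
        theta = 0.5 + 0.2 * t
        k = joint_kinematics(make_elbow_track(theta, fps), "left_elbow")
        np.testing.assert_allclose(k.omega[1:-1], 0.2, atol=1e-9)

    def test_quadratic_angle_recovers_constant_acceleration(self):
        # duration capped so theta stays below pi: a planar joint angle is
        # measured in [0, pi] and would fold back beyond it
        fps = 30.0
        t = np.arange(45) / fps
        theta = 0.3 + t**2
        k = joint_kinematics(make_elbow_track(theta, fps), "left_elbow")
        np.testing.assert_allclose(k.omega_dot[2:-2], 2.0, atol=1e-6)

    def test_sinusoid_matches_closed_form_to_second_order(self):
        fps = 30.0
        t = np.arange(150) / fps
        A, w0 = 0.4, 2 * np.pi * 1.0
        theta = 1.0 + A * np.sin(w0 * t)
        k = joint_kinematics(make_elbow_track(theta, fps), "left_elbow")
        dt = 1 / fps
        tol = A * w0**3 * dt**2  # O(dt^2) truncation bound
        np.testing.assert_allclose(k.omega[1:-1], A * w0 * np.cos(w0 * t[1:-1]), atol=tol)
        np.testing.assert_allclose(
            k.omega_dot[2:-2], -A * w0**2 * np.sin(w0 * t[2:-2]), atol=5 * w0 * tol
        )

    def test_short_segment_raises(self):
        with pytest.raises(TooShortError):
            joint_kinematics(make_track(static_arm_bodies(2)), "left_elbow")


def _kin(omega=0.0, omega_dot=0.0, theta=np.pi / 2, L=1.0, n=3, joint="left_elbow"):
    return JointKinematics(
        joint, np.full(n, theta), np.full(n, omega), np.full(n, omega_dot), np.full(n, L)
    )


class TestWeightAndTime:
    def test_static_weight_is_zero(self):
        assert weight([_kin(omega=0.0)], 1) == 0.0

    def test_single_joint_direct_evaluation(self):
        # independent scalar check: L^2 * omega^2 * sin(theta) * mass = 4*9*1*1
        assert weight([_kin(omega=3.0, L=2.0)], 1) == pytest.approx(36.0)

    def test_weight_is_additive_over_joints(self):
        a, b = _kin(omega=3.0, L=2.0), _kin(omega=1.0, L=5.0, theta=0.3)
        assert weight([a, b], 1) == pytest.approx(weight([a], 1) + weight([b], 1))

    def test_constant_velocity_time_is_zero(self):
        assert time_feature([_kin(omega=2.0, omega_dot=0.0)] * 4, 1) == 0.0

    def test_time_uses_magnitudes(self):
        # +2 and -2 accelerations must add to 4, not cancel
        assert time_feature([_kin(omega_dot=2.0), _kin(omega_dot=-2.0)], 1) == pytest.approx(4.0)

    def test_two_quadratic_joints_give_four(self):
        fps = 30.0
        t = np.arange(60) / fps
        k = joint_kinematics(make_elbow_track(0.3 + t**2, fps), "left_elbow")
        assert time_feature([k, k], 10) == pytest.approx(4.0, abs=1e-6)


class TestLabanSeries:
    def test_constant_pose_series_are_constant(self):
        track = make_track(static_arm_bodies(40, scale=100.0))
        ls = laban_series(track, window_frames=30)
        np.testing.assert_allclose(ls.space, 100.0**2, rtol=1e-12)
        np.testing.assert_allclose(ls.weight, 0.0, atol=1e-12)
        np.testing.assert_allclose(ls.time, 0.0, atol=1e-12)

    def test_window_one_equals_instantaneous(self, synthetic_subject):
        _, track, _, _, _ = synthetic_subject
        from engagekit.pose_io import fill_gaps

        track = fill_gaps(track)
        inst = laban_series(track, window_frames=1)
        seg = track.segments()[0]
        frames = [track.frame(i) for i in range(seg.start, min(seg.stop, seg.start + 50))]
        per_frame = np.array([space(f) for f in frames])
        np.testing.assert_allclose(inst.space[seg.start : seg.start + len(frames)], per_frame, rtol=1e-12)

    def test_windowing_is_the_trailing_moving_average(self, synthetic_subject):
        _, track, _, _, _ = synthetic_subject
        from engagekit.pose_io import fill_gaps

        track = fill_gaps(track)
        w = 30
        inst = laban_series(track, window_frames=1)
        win = laban_series(track, window_frames=w)
        seg = track.segments()[0]
        x = inst.space[seg]
        # moving-average oracle with growing window at the segment start
        expect = np.array([np.nanmean(x[max(0, i - w + 1) : i + 1]) for i in range(len(x))])
        np.testing.assert_allclose(win.space[seg], expect, rtol=1e-9)

    def test_weight_series_nonnegative(self, synthetic_subject):
        _, track, _, _, _ = synthetic_subject
        from engagekit.pose_io import fill_gaps

        ls = laban_series(fill_gaps(track), window_frames=30)
        ok = ~np.isnan(ls.weight)
        assert (ls.weight[ok] >= 0).all()
        assert (ls.space[ok & ~np.isnan(ls.space)] >= 0).all()

    def test_too_short_track_raises(self):
        with pytest.raises(TooShortError):
            laban_series(make_track(static_arm_bodies(2)))
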