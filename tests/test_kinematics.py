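"""Cardan-joint kinematics, muscle lengths, moment arms, generalized load."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wristsim import (
    CardanWristJoint,
    Muscle,
    PathPoint,
    RangeError,
    ValidationError,
    WristModel,
    build_default_model,
    forward_kinematics,
    generalized_load,
    moment_arms,
    muscle_length,
)
from wristsim.model import MUSCLE_NAMES


def rot_x(deg):
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(deg):
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


class TestForwardKinematics:
    def test_neutral_is_identity(self, default_model):
        segs = forward_kinematics(default_model, 0.0, 0.0)
        np.testing.assert_allclose(segs["hand"].rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(segs["hand"].translation, 0.0, atol=1e-12)

    def test_fe_rotation_inverts(self, default_model):
        r1 = forward_kinematics(default_model, 60.0, 0.0)["hand"].rotation
        r2 = forward_kinematics(default_model, -60.0, 0.0)["hand"].rotation
        np.testing.assert_allclose(r1 @ r2, np.eye(3), atol=1e-12)

    def test_landmark_against_matrix_product(self, default_model):
        """Hand pose equals the hand-written RUD*FE rotation product.

        FE is about +x (flexion positive), RUD about -y (ulnar positive);
        the oracle composes the elementary matrices directly.
        """
        p = np.array([0.01, -0.02, 0.06])
        segs = forward_kinematics(default_model, 30.0, 10.0)
        posed = segs["hand"].pose_point(p)
        oracle = rot_y(-10.0) @ rot_x(30.0) @ p
        np.testing.assert_allclose(posed, oracle, atol=1e-12)

    def test_out_of_range_raises(self, default_model):
        with pytest.raises(RangeError):
            forward_kinematics(default_model, 81.0, 0.0)
        with pytest.raises(RangeError):
            forward_kinematics(default_model, 0.0, -21.0)


class TestMuscleLength:
    def test_two_point_path_is_euclidean(self):
        m = Muscle(
            "FLEX",
            (PathPoint((0.0, -0.01, -0.2), "forearm"), PathPoint((0.0, -0.01, 0.05), "hand")),
            100.0,
        )
        model = WristModel(joint=CardanWristJoint(), muscles=(m,))
        assert muscle_length(model, 0.0, 0.0)[0] == pytest.approx(0.25, rel=1e-12)

    def test_three_point_path_sums_segments(self):
        pts = [(0.0, -0.02, -0.2), (0.01, -0.015, -0.01), (0.0, -0.01, 0.04)]
        m = Muscle(
            "FLEX",
            (
                PathPoint(pts[0], "forearm"),
                PathPoint(pts[1], "forearm"),
                PathPoint(pts[2], "hand"),
            ),
            100.0,
        )
        model = WristModel(joint=CardanWristJoint(), muscles=(m,))
        expected = sum(
            np.linalg.norm(np.subtract(b, a)) for a, b in zip(pts, pts[1:])
        )
        assert muscle_length(model, 0.0, 0.0)[0] == pytest.approx(expected, rel=1e-12)

    @given(
        fe=st.floats(-60.0, 80.0),
        rud=st.floats(-20.0, 40.0),
    )
    def test_length_at_least_chord(self, fe, rud):
        """Polyline length never beats the straight origin-insertion line."""
        model = build_default_model()
        lengths = muscle_length(model, fe, rud)
        segs = forward_kinematics(model, fe, rud)
        for m, length in zip(model.muscles, lengths):
            a = segs[m.path[0].segment].pose_point(m.path[0].point)
            b = segs[m.path[-1].segment].pose_point(m.path[-1].point)
            assert length >= np.linalg.norm(b - a) - 1e-12


class TestMomentArms:
    def test_straight_line_arm_is_perpendicular_distance(self):
        """A line parallel to the forearm at palmar offset d has FE arm d."""
        d = 0.013
        m = Muscle(
            "FLEX",
            (PathPoint((0.0, -d, -0.3), "forearm"), PathPoint((0.0, -d, 0.08), "hand")),
            100.0,
        )
        model = WristModel(joint=CardanWristJoint(), muscles=(m,))
        arms = moment_arms(model, 0.0, 0.0)
        assert arms[0, 0] == pytest.approx(d, rel=1e-6)

    def test_sign_convention(self, default_model):
        """Flexors positive / extensors negative about FE; ulnar deviators
        positive / radial deviators negative about RUD."""
        arms = moment_arms(default_model, 0.0, 0.0)
        by_name = dict(zip(default_model.muscle_names, arms))
        for name in ("FCR", "FCU"):
            assert by_name[name][0] > 0, f"{name} should be a flexor"
        for name in ("ECU", "ECRB", "ECRL"):
            assert by_name[name][0] < 0, f"{name} should be an extensor"
        for name in ("ECU", "FCU"):
            assert by_name[name][1] > 0, f"{name} should deviate ulnarly"
        for name in ("ECRL", "ECRB", "FCR"):
            assert by_name[name][1] < 0, f"{name} should deviate radially"

    @pytest.mark.parametrize("fe,rud", [(0.0, 0.0), (45.0, 0.0), (-30.0, 20.0)])
    def test_finite_difference_convergence(self, default_model, fe, rud):
        """Halving the step changes no arm by more than 1e-4 m."""
        coarse = moment_arms(default_model, fe, rud, step_rad=1e-3)
        fine = moment_arms(default_model, fe, rud, step_rad=1e-4)
        assert np.abs(coarse - fine).max() < 1e-4


class TestGeneralizedLoad:
    def test_zero_load(self, default_model):
        np.testing.assert_allclose(
            generalized_load(default_model, 10.0, 5.0, force_N=(0, 0, 0)), 0.0
        )

    def test_vertical_load_neutral_hand(self, default_model):
        """100 N at 0.08 m distal on the neutral hand gives |tau_FE| = 8 N*m."""
        tau = generalized_load(
            default_model, 0.0, 0.0, force_N=(0.0, 100.0, 0.0), point=(0.0, 0.0, 0.08)
        )
        assert abs(tau[0]) == pytest.approx(8.0, rel=1e-12)
        assert tau[1] == pytest.approx(0.0, abs=1e-12)

    def test_load_through_joint_center(self, default_model):
        tau = generalized_load(
            default_model, 20.0, -10.0, force_N=(30.0, -40.0, 50.0), point=(0, 0, 0)
        )
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)


class TestModelValidation:
    def test_default_has_five_muscles(self, default_model):
        assert default_model.muscle_names == MUSCLE_NAMES

    def test_zero_strength_rejected(self):
        with pytest.raises(ValidationError):
            build_default_model({"strengths": {"ECU": 0.0}})

    def test_non_perpendicular_axes_rejected(self):
        with pytest.raises(ValidationError):
            CardanWristJoint(fe_axis=(1.0, 0.0, 0.0), rud_axis=(1.0, 0.0, 0.0))

    def test_seeded_build_is_deterministic(self):
        a = build_default_model({"perturb_mm": 0.5, "seed": 1})
        b = build_default_model({"perturb_mm": 0.5, "seed": 1})
        for ma, mb in zip(a.muscles, b.muscles):
            for pa, pb in zip(ma.path, mb.path):
                np.testing.assert_array_equal(pa.point, pb.point)
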