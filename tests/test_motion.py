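"""Joint reactions, motion protocol and quasi-static motion sweeps."""

import numpy as np
import pytest

from wristsim import (
    CardanWristJoint,
    Muscle,
    PathPoint,
    RecruitmentSolution,
    ValidationError,
    WristModel,
    joint_reaction,
    make_motion_cycle,
    recruit,
    simulate_motion,
    summarized_muscle_force,
)


def single_muscle_model(path_pts, strength=5000.0):
    m = Muscle(
        "FLEX",
        tuple(
            PathPoint(p, "forearm" if i < len(path_pts) - 1 else "hand")
            for i, p in enumerate(path_pts)
        ),
        strength,
    )
    return WristModel(joint=CardanWristJoint(), muscles=(m,))


class TestJointReaction:
    def test_no_muscles_reaction_balances_load(self, default_model):
        silent = RecruitmentSolution(
            default_model.muscle_names, np.zeros(5), 0.0, 0.0
        )
        r = joint_reaction(
            default_model, (0.0, 0.0), silent, external_force_N=(0.0, 100.0, 0.0)
        )
        assert np.linalg.norm(r) == pytest.approx(100.0, rel=1e-12)

    def test_linearity_in_forces_and_load(self, default_model):
        sol = recruit(default_model, (0.0, 0.0), (5.0, 0.0))
        doubled = RecruitmentSolution(
            sol.muscles, 2.0 * sol.forces_N, sol.objective, sol.residual_Nm
        )
        r1 = joint_reaction(default_model, (0.0, 0.0), sol,
                            external_force_N=(0.0, 100.0, 0.0))
        r2 = joint_reaction(default_model, (0.0, 0.0), doubled,
                            external_force_N=(0.0, 200.0, 0.0))
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-12)

    def test_single_flexor_vector_sum(self):
        """Reaction equals the hand-computed sum of load + tendon pull."""
        model = single_muscle_model([(0.0, -0.013, -0.3), (0.0, -0.013, 0.06)])
        f = 250.0
        sol = RecruitmentSolution(("FLEX",), np.array([f]), 0.0, 0.0)
        load = np.array([0.0, 100.0, 0.0])
        r = joint_reaction(model, (0.0, 0.0), sol, external_force_N=load)
        pull = f * np.array([0.0, 0.0, -1.0])  # straight path along -z
        np.testing.assert_allclose(r, -(load + pull), atol=1e-12)


class TestMotionCycle:
    def test_fe_protocol_extrema(self):
        cyc = make_motion_cycle("FE", 41)
        assert cyc.angles_deg.max() == 80.0  # peak flexion
        assert cyc.angles_deg.min() == -60.0  # peak extension

    def test_rud_protocol_extrema(self):
        cyc = make_motion_cycle("RUD", 41)
        assert cyc.angles_deg.min() == -20.0  # peak radial deviation
        assert cyc.angles_deg.max() == 40.0  # peak ulnar deviation

    @pytest.mark.parametrize("plane", ["FE", "RUD"])
    @pytest.mark.parametrize("n", [3, 10, 121])
    def test_cycle_starts_and_ends_neutral(self, plane, n):
        cyc = make_motion_cycle(plane, n)
        assert cyc.angles_deg[0] == 0.0 and cyc.angles_deg[-1] == 0.0
        lo, hi = (-60.0, 80.0) if plane == "FE" else (-20.0, 40.0)
        assert cyc.angles_deg.min() == lo and cyc.angles_deg.max() == hi

    def test_invalid_plane_and_samples(self):
        with pytest.raises(ValidationError):
            make_motion_cycle("circumduction")
        with pytest.raises(ValidationError):
            make_motion_cycle("FE", 2)


class TestSimulateMotion:
    def test_zero_load_all_silent(self, default_model):
        cyc = make_motion_cycle("FE", 9)
        df = simulate_motion(default_model, cyc, external_force_N=(0.0, 0.0, 0.0))
        for name in default_model.muscle_names:
            np.testing.assert_array_equal(df[f"{name}_N"], 0.0)

    def test_flexors_peak_at_peak_extension(self, fe_simulation):
        """Under the dorsal 100 N load the flexor group force is maximal
        where the flexor lever arms collapse: at full extension."""
        flexor = fe_simulation.FCR_N + fe_simulation.FCU_N
        peak_angle = fe_simulation.fe_deg[flexor.idxmax()]
        assert peak_angle == -60.0

    def test_reversed_cycle_reverses_series(self, default_model):
        cyc = make_motion_cycle("FE", 11)
        fwd = simulate_motion(default_model, cyc)
        bwd = simulate_motion(default_model, cyc.reversed())
        for col in ("FCR_N", "ECU_N", "reaction_y_N"):
            np.testing.assert_allclose(
                bwd[col].to_numpy(), fwd[col].to_numpy()[::-1], atol=1e-9
            )

    def test_per_sample_invariants(self, default_model, fe_simulation):
        strengths = dict(zip(default_model.muscle_names, default_model.strengths))
        for name in default_model.muscle_names:
            col = fe_simulation[f"{name}_N"]
            assert (col >= -1e-9).all()
            assert (col <= strengths[name] + 1e-6).all()


class TestPlanarEquivalence:
    def test_degenerate_model_reproduces_planar_force(self):
        """One straight flexor on one revolute axis matches the planar
        closed form tau / (A cos alpha) within 0.1% over 0-60 deg.

        The muscle runs parallel to the forearm axis from far proximal to
        an insertion at palmar offset A, so its FE moment arm is A cos
        alpha up to a O(A/L) direction error.
        """
        A = 0.010
        model = single_muscle_model([(0.0, -A, -50.0), (0.0, -A, 0.0)])
        torque = 10.0
        for alpha in np.linspace(0.0, 60.0, 25):
            sol = recruit(model, (-alpha, 0.0), (torque, 0.0))
            expected = summarized_muscle_force(torque, A, alpha)
            assert sol.forces_N[0] == pytest.approx(expected, rel=1e-3)
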