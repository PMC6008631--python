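"""Mobility, forward chain, closure constraints, and the inverse solver."""

import numpy as np
import pytest

from shoulderkin.girdle_kinematics import (
    ConvergenceError,
    GirdleInputs,
    HumerusPose,
    JointState,
    SolverSettings,
    constraint_residual,
    forward_chain,
    humerus_transform,
    mobility,
    scapula_isb_posture,
    solve_girdle,
    solve_trajectory,
)
from shoulderkin.model_geometry import ellipsoid_point
from shoulderkin.transforms import translation_of

from conftest import make_feasible_state


@pytest.mark.parametrize(
    "n, dofs, expected",
    [
        (3, [3, 3, 4], 4),  # closed girdle loop: SC + AC spherical, ST cylinder-plane
        (4, [3, 3, 4, 3], 7),  # plus the 3-DoF GH joint: whole shoulder
        (1, [], 0),
        (2, [3], 3),
    ],
)
def test_mobility(n, dofs, expected):
    assert mobility(n, dofs) == expected


def test_mobility_validates_joint_freedoms():
    with pytest.raises(ValueError):
        mobility(3, [0, 3, 4])
    with pytest.raises(ValueError):
        mobility(0, [])


class TestForwardChain:
    def test_straight_chain(self, garner_geometry):
        g, _, _ = garner_geometry
        state = JointState(0, 0, 0, 0, 0, 0, 0, 0, 0)
        T10, T21, pc0, _ = forward_chain(state, g)
        assert np.allclose(T10, np.eye(4), atol=1e-15)
        assert pc0 == pytest.approx([0.0, 0.0, g.l1 + g.l2])

    def test_matches_symbolic_expansion(self, garner_geometry, rng):
        """Entrywise agreement with an independent sympy expansion of the chain."""
        sympy = pytest.importorskip("sympy")
        sp = sympy
        t = sp.symbols("t1 t2 t3 t4 t5 t6")
        l1 = sp.symbols("l1")

        def Rz(a):
            return sp.Matrix([[sp.cos(a), -sp.sin(a), 0], [sp.sin(a), sp.cos(a), 0], [0, 0, 1]])

        def Ry(a):
            return sp.Matrix([[sp.cos(a), 0, sp.sin(a)], [0, 1, 0], [-sp.sin(a), 0, sp.cos(a)]])

        def Rx(a):
            return sp.Matrix([[1, 0, 0], [0, sp.cos(a), -sp.sin(a)], [0, sp.sin(a), sp.cos(a)]])

        def hom(R, p):
            return R.row_join(sp.Matrix(p)).col_join(sp.Matrix([[0, 0, 0, 1]]))

        T10s = hom(Rz(t[0]) * Rx(t[1]) * Rz(t[2]), [0, 0, 0])
        T21s = hom(sp.eye(3), [0, 0, l1]) * hom(Ry(t[3]) * Rx(t[4]) * Ry(t[5]), [0, 0, 0])
        f10 = sp.lambdify(t[:3], T10s, "numpy")
        f21 = sp.lambdify((l1, *t[3:]), T21s, "numpy")

        g, _, _ = garner_geometry
        for _ in range(20):
            angles = rng.uniform(-np.pi, np.pi, 6)
            state = JointState(*angles[:2], *angles[3:6], 0, 0, 0, 0, theta3=angles[2])
            T10, T21, pc0, pd0 = forward_chain(state, g)
            assert np.allclose(T10, f10(*angles[:3]), atol=1e-10)
            assert np.allclose(T21, f21(g.l1, *angles[3:]), atol=1e-10)

    def test_scapula_rigidity_along_chain(self, garner_geometry, rng):
        """|AC->c| = l2, |AC->d| = l3 and the gamma angle hold for any state."""
        g, _, _ = garner_geometry
        for _ in range(100):
            angles = rng.uniform(-np.pi, np.pi, 6)
            state = JointState(*angles[:2], *angles[3:6], 0, 0, 0, 0, theta3=angles[2])
            T10, T21, pc0, pd0 = forward_chain(state, g)
            b = (T10 @ T21 @ [0, 0, 0, 1])[:3]
            assert np.linalg.norm(pc0 - b) == pytest.approx(g.l2, abs=1e-9)
            assert np.linalg.norm(pd0 - b) == pytest.approx(g.l3, abs=1e-9)
            cosang = (pc0 - b) @ (pd0 - b) / (g.l2 * g.l3)
            assert np.arccos(np.clip(cosang, -1, 1)) == pytest.approx(g.gamma, abs=1e-9)


class TestConstraintResidual:
    def test_constructed_state_closes_loop(self, feasible_state, garner_geometry):
        g, e, _ = garner_geometry
        state, _ = feasible_state
        assert np.linalg.norm(constraint_residual(state, g, e)) < 1e-9

    def test_perturbation_detected(self, feasible_state, garner_geometry):
        import dataclasses

        g, e, _ = garner_geometry
        state, _ = feasible_state
        perturbed = dataclasses.replace(state, theta4=state.theta4 + 0.1)
        assert np.linalg.norm(constraint_residual(perturbed, g, e)) > 1.0

    def test_residual_periodic_in_angles(self, feasible_state, garner_geometry):
        import dataclasses

        g, e, _ = garner_geometry
        state, _ = feasible_state
        base = constraint_residual(state, g, e)
        shifted = dataclasses.replace(state, theta5=state.theta5 + 2 * np.pi)
        assert np.allclose(constraint_residual(shifted, g, e), base, atol=1e-8)


class TestSolveGirdle:
    def test_round_trip_from_constructed_states(self, garner_geometry, rng):
        """Forward-constructed states are recovered from (theta1, theta2, psi_d)."""
        g, e, _ = garner_geometry
        for _ in range(10):
            state, _ = make_feasible_state(g, e, rng)
            inputs = GirdleInputs(state.theta1, state.theta2, state.psi_d)
            solved = solve_girdle(inputs, g, e)
            for name in ("theta4", "theta5", "theta6", "phi_c", "psi_c", "phi_d"):
                assert getattr(solved, name) == pytest.approx(getattr(state, name), abs=1e-6)
            assert np.linalg.norm(constraint_residual(solved, g, e)) < 1e-8

    def test_solution_on_ellipsoid_and_rigid(self, garner_geometry, rng):
        g, e, _ = garner_geometry
        state, _ = make_feasible_state(g, e, rng)
        solved = solve_girdle(GirdleInputs(state.theta1, state.theta2, state.psi_d), g, e)
        center = e.center_in_s0()
        _, _, pc0, pd0 = forward_chain(solved, g)
        assert abs(e.implicit(pc0 - center)) < 1e-9
        assert abs(e.implicit(pd0 - center)) < 1e-9

    def test_no_grid_point_beats_converged_solution(self, garner_geometry, rng):
        """Brute-force 6-D grid around the solution: no smaller residual."""
        g, e, _ = garner_geometry
        state, _ = make_feasible_state(g, e, rng)
        inputs = GirdleInputs(state.theta1, state.theta2, state.psi_d)
        solved = solve_girdle(inputs, g, e)
        best = np.linalg.norm(constraint_residual(solved, g, e))
        x0 = np.array(
            [solved.theta4, solved.theta5, solved.theta6, solved.phi_c, solved.psi_c, solved.phi_d]
        )
        import dataclasses
        from itertools import product

        for offsets in product((-0.05, 0.0, 0.05), repeat=6):
            if all(o == 0.0 for o in offsets):
                continue
            x = x0 + np.array(offsets)
            cand = dataclasses.replace(
                state, theta4=x[0], theta5=x[1], theta6=x[2], phi_c=x[3], psi_c=x[4], phi_d=x[5]
            )
            assert np.linalg.norm(constraint_residual(cand, g, e)) > best

    def test_nonconvergence_reports_residual(self, garner_geometry):
        from shoulderkin.model_geometry import ThoraxEllipsoid

        g, _, _ = garner_geometry
        # an ellipsoid far beyond the chain's reach: the loop cannot close
        e_far = ThoraxEllipsoid(m=10.0, n=10.0, p=10.0, center=(1000.0, 0.0, 0.0))
        inputs = GirdleInputs(1.3, 1.4, -0.9)
        with pytest.raises(ConvergenceError) as err:
            solve_girdle(inputs, g, e_far, settings=SolverSettings(max_iterations=20))
        assert err.value.residual > 0


class TestSolveTrajectory:
    def test_constant_inputs_constant_outputs(self, garner_geometry, rng):
        g, e, _ = garner_geometry
        state, _ = make_feasible_state(g, e, rng)
        inputs = GirdleInputs(state.theta1, state.theta2, state.psi_d)
        frames = solve_trajectory([inputs] * 5, g, e)
        assert all(f.converged for f in frames)
        th4 = [f.state.theta4 for f in frames]
        assert np.ptp(th4) < 1e-9

    def test_time_reversal_symmetry(self, garner_geometry, rng):
        g, e, _ = garner_geometry
        state, _ = make_feasible_state(g, e, rng)
        base = GirdleInputs(state.theta1, state.theta2, state.psi_d)
        series = [
            GirdleInputs(base.theta1 + 0.01 * k, base.theta2 - 0.005 * k, base.psi_d + 0.01 * k)
            for k in range(8)
        ]
        # seed both directions on the same assembly branch
        fwd = solve_trajectory(series, g, e, guess=state)
        bwd = solve_trajectory(series[::-1], g, e, guess=fwd[-1].state)
        assert all(f.converged for f in fwd + bwd)
        for f, b in zip(fwd, bwd[::-1]):
            assert f.state.theta4 == pytest.approx(b.state.theta4, abs=1e-6)
            assert f.state.phi_d == pytest.approx(b.state.phi_d, abs=1e-6)


class TestHumerusPose:
    def test_identity(self):
        T = humerus_transform(HumerusPose(0, 0, 0))
        assert np.allclose(T, np.eye(4), atol=1e-15)

    def test_translation_column_is_pe(self, rng):
        pe = rng.uniform(-100, 100, 3)
        T = humerus_transform(HumerusPose(0.3, -0.2, 0.5, pe=pe))
        assert np.allclose(translation_of(T), pe)

    def test_isb_round_trip(self, rng):
        for _ in range(25):
            y1, x, y2 = rng.uniform(-80, 80), rng.uniform(10, 160), rng.uniform(-80, 80)
            pose = HumerusPose.from_isb_degrees(y1, x, y2)
            got = pose.isb_degrees()
            assert got == pytest.approx((y1, x, y2), abs=1e-9)


def test_scapula_isb_posture_is_finite(feasible_state, garner_geometry):
    g, _, _ = garner_geometry
    state, _ = feasible_state
    eul = scapula_isb_posture(state, g)
    assert np.all(np.isfinite(eul.angles))
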