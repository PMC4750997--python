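"""Feasible activation segments and energy extremization.

The one-joint three-muscle limb with moment arms (1, 2, -1), unit maximal
forces and desired joint stiffness 1 has equality solutions
``a(t) = (0.5 - 3t, t, 0.5 - t)`` whose box intersection is ``t in [0, 1/6]``;
the energy along it is ``E(t) = 11 t^2 - 4 t + 0.5`` with the unconstrained
stationary point at t = 2/11 outside the interval, so the minimum sits at the
boundary: e_min = E(1/6) = 5/36 at a = (0, 1/6, 1/3) and e_max = E(0) = 0.5
at a = (0.5, 0, 0.5).  These hand-derived values anchor the segment algebra.
"""

import numpy as np
import pytest
import scipy.linalg
from scipy.optimize import LinearConstraint, minimize

from stiffsynth import (
    ArmModel,
    FixtureSpec,
    assemble_constraints,
    auto_scale,
    desired_stiffness,
    energy_range,
    energy_reduction_pct,
    feasible_segment,
    is_realizable,
    make_random_arm,
    max_energy,
    min_energy,
    oracle_energy_bracket,
    realizable_fraction,
)
from stiffsynth.feasibility import scaled

from .conftest import random_posture


class TestAssembly:
    def test_default_arm_shapes(self, arm, posture01):
        c = assemble_constraints(arm, posture01, desired_stiffness(2.0, 30.0))
        assert c.A_eq.shape == (5, 6)
        assert np.all(c.b_eq[:2] == 0.0)
        assert c.n_equilibrium == 2

    def test_single_joint_shapes(self, single_joint):
        c = assemble_constraints(single_joint, None, [1.0])
        assert c.A_eq.shape == (2, 3)
        assert c.b_eq == pytest.approx([0.0, 1.0])
        # torque row is the moment arms, stiffness row their squares
        assert c.A_eq[0] == pytest.approx([1.0, 2.0, -1.0])
        assert c.A_eq[1] == pytest.approx([1.0, 4.0, 1.0])

    def test_zero_desired_feasible_at_origin(self, arm, posture01):
        c = assemble_constraints(arm, posture01, np.zeros(3))
        seg = feasible_segment(c)
        assert not seg.empty
        a, e = min_energy(c, seg)
        assert e == pytest.approx(0.0, abs=1e-16)
        assert a == pytest.approx(np.zeros(6), abs=1e-9)


class TestSingleJointSegment:
    def test_segment_matches_hand_elimination(self, single_joint):
        c = assemble_constraints(single_joint, None, [1.0])
        seg = feasible_segment(c)
        assert not seg.empty and seg.null_dim == 1
        # every segment point satisfies the hand-derived parametrization:
        # a2 free, a1 = 0.5 - 3 a2, a3 = 0.5 - a2
        for t in np.linspace(*seg.t_range, 7):
            a = seg.point(t)
            assert a[0] == pytest.approx(0.5 - 3 * a[1], abs=1e-9)
            assert a[2] == pytest.approx(0.5 - a[1], abs=1e-9)
        ends = {tuple(np.round(np.clip(a, 0, 1), 6)) for a in seg.endpoints}
        assert ends == {(0.5, 0.0, 0.5), (0.0, round(1 / 6, 6), round(1 / 3, 6))}

    def test_energy_extremes_exact(self, single_joint):
        c = assemble_constraints(single_joint, None, [1.0])
        a_min, e_min = min_energy(c)
        a_max, e_max = max_energy(c)
        assert e_min == pytest.approx(5 / 36, abs=1e-8)
        assert a_min == pytest.approx([0.0, 1 / 6, 1 / 3], abs=1e-7)
        assert e_max == pytest.approx(0.5, abs=1e-8)
        assert a_max == pytest.approx([0.5, 0.0, 0.5], abs=1e-7)
        er = energy_range(c)
        assert er.reduction_pct == pytest.approx(100 * 13 / 18, abs=1e-5)

    def test_minimum_invariant_to_parametrization(self, single_joint):
        """Shifting the particular solution along the null space must not
        change the energy extremes."""
        c = assemble_constraints(single_joint, None, [1.0])
        seg = feasible_segment(c)
        d = seg.direction
        shifted = type(seg)(
            a0=seg.a0 + 0.01 * d,
            direction=d,
            t_range=(seg.t_range[0] - 0.01, seg.t_range[1] - 0.01),
            empty=False,
            null_dim=1,
        )
        _, e1 = min_energy(c, seg)
        _, e2 = min_energy(c, shifted)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_grid_confirms_boundary_minimum(self, single_joint):
        """Dense sampling over the segment brackets the analytic extremes;
        with the stationary point outside the interval the boundary wins."""
        c = assemble_constraints(single_joint, None, [1.0])
        lo, hi = oracle_energy_bracket(c, n_samples=100_000, seed=7)
        assert lo == pytest.approx(5 / 36, abs=1e-6)
        assert hi == pytest.approx(0.5, abs=1e-9)
        _, e_min = min_energy(c)
        _, e_max = max_energy(c)
        assert lo >= e_min - 1e-9 and hi <= e_max + 1e-9

    def test_oracle_deterministic_under_seed(self, single_joint):
        c = assemble_constraints(single_joint, None, [1.0])
        assert oracle_energy_bracket(c, 500, seed=3) == oracle_energy_bracket(c, 500, seed=3)

    def test_oversized_demand_is_empty(self, single_joint):
        c = assemble_constraints(single_joint, None, [1000.0])
        assert feasible_segment(c).empty

    def test_same_sign_moment_arms_cannot_hold_stiffness(self):
        from stiffsynth import make_single_joint_limb

        with pytest.warns(UserWarning, match="one sign"):
            limb = make_single_joint_limb((1.0, 1.0, 1.0))
        c = assemble_constraints(limb, None, [1.0])
        assert feasible_segment(c).empty


class TestRankStructure:
    def test_generic_null_space_is_one_dimensional(self, arm, rng):
        """Six muscles minus two equilibrium and three stiffness constraints
        leave one free dimension at generic postures."""
        for _ in range(100):
            p = random_posture(rng)
            c = assemble_constraints(arm, p, desired_stiffness(2.0, 30.0))
            assert np.linalg.matrix_rank(c.A_eq) == 5
            assert scipy.linalg.null_space(c.A_eq).shape[1] == 1

    def test_underactuated_arm_flagged_not_crashed(self):
        """Three muscles cannot generically satisfy five constraints."""
        ra = make_random_arm(FixtureSpec(seed=1, muscle_count=4))
        p = random_posture(np.random.default_rng(0))
        c = assemble_constraints(ra, p, desired_stiffness(2.0, 30.0, 1e-3))
        seg = feasible_segment(c)
        assert seg.empty or seg.null_dim == 0


class TestRealizability:
    def test_circle_realizable_at_reference_posture(self, arm, posture01):
        assert is_realizable(arm, posture01, 1.0, 0.0)

    def test_scale_invariance_below_saturation(self, arm, rng):
        """The realizability verdict is a property of shape and orientation
        alone once the size is below saturation."""
        for _ in range(10):
            p = random_posture(rng)
            shape = rng.uniform(1.2, 6.0)
            orient = rng.uniform(0.0, 180.0)
            verdicts = {
                is_realizable(arm, p, shape, orient, scale=s) for s in (1e-4, 1e-3, 1e-2)
            }
            assert len(verdicts) == 1
            assert is_realizable(arm, p, shape, orient, scale="auto") in verdicts

    def test_fraction_step_must_divide_180(self, arm, posture01):
        with pytest.raises(ValueError):
            realizable_fraction(arm, posture01, 2.0, step_deg=7.0)
        with pytest.raises(ValueError):
            realizable_fraction(arm, posture01, 1.0)

    def test_fraction_zero_at_absurd_scale(self, arm, posture01):
        assert realizable_fraction(arm, posture01, 2.0, scale=1e6) == 0.0

    def test_moderate_shapes_fully_orientable_at_reference_posture(self, arm, posture01):
        for shape in (1.5, 2.9):
            assert realizable_fraction(arm, posture01, shape) == 1.0


class TestEnergyRange:
    def test_worked_percentage_example(self):
        assert energy_reduction_pct(0.35, 0.5) == pytest.approx(30.0)

    def test_reduction_edge_cases(self):
        assert energy_reduction_pct(0.2, 0.2) == 0.0
        with pytest.raises(ValueError):
            energy_reduction_pct(0.0, 0.0)
        with pytest.raises(ValueError):
            energy_reduction_pct(0.6, 0.5)

    def test_point_segment_has_no_headroom(self, arm, posture01):
        """A desired stiffness the arm can meet exactly one way leaves
        e_min = e_max."""
        c = assemble_constraints(arm, posture01, np.zeros(3))
        seg = feasible_segment(c)
        # force a single-point feasible set by collapsing the interval
        pt = type(seg)(a0=seg.a0, direction=seg.direction, t_range=(0.0, 0.0),
                       empty=False, null_dim=1)
        _, e1 = min_energy(c, pt)
        _, e2 = max_energy(c, pt)
        assert e1 == pytest.approx(e2)

    def test_reduction_invariant_to_stiffness_scale(self, arm, rng):
        """Both extremes scale as s^2 below saturation, so the percent
        reduction is scale-free."""
        checked = 0
        for _ in range(20):
            p = random_posture(rng)
            base = assemble_constraints(arm, p, desired_stiffness(2.0, rng.uniform(0, 180)))
            s = auto_scale(base)
            reds = []
            for f in (1.0, 0.5):
                er = energy_range(scaled(base, s * f))
                if er is None:
                    break
                reds.append(er.reduction_pct)
                assert er.e_max > 0
            if len(reds) == 2:
                assert reds[0] == pytest.approx(reds[1], abs=1e-6)
                checked += 1
        assert checked >= 5

    def test_segment_extremes_match_generic_qp(self, arm, rng):
        """The closed-form 1-D extremization agrees with an independent
        constrained solver on randomized feasible tasks."""
        checked = 0
        for _ in range(30):
            p = random_posture(rng)
            c0 = assemble_constraints(arm, p, desired_stiffness(rng.uniform(1.1, 3.0), rng.uniform(0, 180)))
            c = scaled(c0, auto_scale(c0))
            seg = feasible_segment(c)
            if seg.empty:
                continue
            _, e_min = min_energy(c, seg)
            res = minimize(
                lambda a: a @ a,
                np.clip(seg.point(np.mean(seg.t_range)), 0, 1),
                jac=lambda a: 2 * a,
                constraints=[LinearConstraint(c.A_eq, c.b_eq, c.b_eq)],
                bounds=[(0.0, 1.0)] * 6,
                method="SLSQP",
            )
            assert res.success
            assert e_min == pytest.approx(res.fun, abs=1e-6)
            checked += 1
        assert checked >= 10

    def test_min_energy_solution_audits_constraints(self, arm, rng):
        for _ in range(20):
            p = random_posture(rng)
            c0 = assemble_constraints(arm, p, desired_stiffness(2.0, rng.uniform(0, 180)))
            c = scaled(c0, auto_scale(c0))
            a, e = min_energy(c)
            if a is None:
                continue
            assert np.all(a >= 0) and np.all(a <= 1)
            assert np.linalg.norm(c.A_eq @ a - c.b_eq) < 1e-8

    def test_infeasible_returns_none_not_exception(self, single_joint):
        c = assemble_constraints(single_joint, None, [1000.0])
        assert min_energy(c) == (None, None)
        assert max_energy(c) == (None, None)
        assert energy_range(c) is None


class TestDegeneratePolytope:
    def test_duplicated_muscles_fall_back_to_vertices(self, posture01):
        """Doubling every muscle makes the null space 7-dimensional; the
        vertex fallback must agree with an independent bounded QP."""
        R6 = ArmModel().moment_arms
        arm12 = ArmModel(moment_arms=np.hstack([R6, R6]))
        c0 = assemble_constraints(arm12, posture01, desired_stiffness(1.5, 90.0))
        c = scaled(c0, auto_scale(c0))
        seg = feasible_segment(c)
        assert seg.degenerate and seg.null_dim == 7 and not seg.empty
        assert len(seg.vertices) > 0
        a_min, e_min = min_energy(c, seg)
        a_max, e_max = max_energy(c, seg)
        assert e_max >= e_min
        res = minimize(
            lambda a: a @ a,
            np.full(12, 0.25),
            jac=lambda a: 2 * a,
            constraints=[LinearConstraint(c.A_eq, c.b_eq, c.b_eq)],
            bounds=[(0.0, 1.0)] * 12,
            method="SLSQP",
        )
        assert e_min == pytest.approx(res.fun, abs=1e-6)
        # the max over vertices dominates random feasible samples
        rng = np.random.default_rng(0)
        N = scipy.linalg.null_space(c.A_eq)
        a0 = np.linalg.lstsq(c.A_eq, c.b_eq, rcond=None)[0]
        for _ in range(200):
            t = rng.normal(size=N.shape[1]) * 0.2
            a = a0 + N @ t
            if np.all(a >= 0) and np.all(a <= 1):
                assert a @ a <= e_max + 1e-9
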