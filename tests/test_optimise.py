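"""QP solver: exactness, KKT verification, oracle agreement, degeneracy."""

import numpy as np
import pandas as pd
import pytest

from dietshift.optimise import (
    LinearConstraint,
    QPProblem,
    _Dense,
    _polish_from_point,
    _trust_constr_solve,
    brute_force_oracle,
    solve,
    verify_kkt,
)

from conftest import random_feasible_problem


def two_food_problem() -> QPProblem:
    """Energy equality + binding emission cap force x* = (50, 150), f* = 0.5."""
    idx = pd.Index(["a", "b"], name="food_id")
    anchor = pd.Series([100.0, 100.0], index=idx)
    cons = [
        LinearConstraint(pd.Series([1.0, 1.0], index=idx), "=", 200.0, "energy"),
        LinearConstraint(pd.Series([2.0, 1.0], index=idx), "<=", 250.0, "ghge_cap"),
    ]
    return QPProblem(
        anchor=anchor,
        lower=pd.Series([0.0, 0.0], index=idx),
        upper=pd.Series([1000.0, 1000.0], index=idx),
        constraints=cons,
    )


class TestSolve:
    def test_analytically_forced_solution(self):
        sol = solve(two_food_problem())
        assert sol.optimal
        assert sol.x["a"] == pytest.approx(50.0, abs=1e-8)
        assert sol.x["b"] == pytest.approx(150.0, abs=1e-8)
        assert sol.objective == pytest.approx(0.5, abs=1e-8)
        assert sol.kkt["max_residual"] <= 1e-6
        # both constraints binding, cap dual strictly positive
        assert sol.active.all()
        assert sol.duals["ghge_cap"] > 0

    def test_feasible_anchor_is_returned_unchanged(self):
        p = two_food_problem()
        # loosen the cap so the anchor (GHGE 300) is feasible
        p.constraints[1] = LinearConstraint(
            p.constraints[1].coeffs, "<=", 400.0, "ghge_cap"
        )
        sol = solve(p)
        assert sol.optimal
        np.testing.assert_allclose(sol.x.to_numpy()[:2], [100.0, 100.0], atol=1e-9)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)
        assert abs(sol.duals["ghge_cap"]) <= 1e-9  # non-binding => zero dual

    def test_oracle_agreement_on_random_problems(self):
        """>= 100 random small problems: objective gap to the brute-force oracle <= 1e-6."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 100:
            p = random_feasible_problem(rng)
            sol = solve(p)
            assert sol.optimal, sol.diagnosis
            assert sol.kkt["max_residual"] <= 1e-6
            ref = brute_force_oracle(p)
            assert ref.optimal
            # face enumeration is exact up to its feasibility tolerance
            assert abs(ref.objective - sol.objective) <= 1e-6
            n_checked += 1

    def test_box_only_problem_clips_anchor(self):
        idx = pd.Index(["a"], name="food_id")
        p = QPProblem(
            anchor=pd.Series([100.0], index=idx),
            lower=pd.Series([120.0], index=idx),
            upper=pd.Series([200.0], index=idx),
            constraints=[],
        )
        sol = solve(p)
        assert sol.optimal
        assert sol.x["a"] == pytest.approx(120.0, abs=1e-9)
        assert sol.bound_duals.loc["a", "lower"] > 0

    def test_infeasible_reports_diagnosis(self):
        p = two_food_problem()
        p.constraints.append(
            LinearConstraint(pd.Series([1.0, 1.0], index=p.foods), ">=", 5000.0, "impossible")
        )
        sol = solve(p)
        assert sol.status == "infeasible"
        assert sol.x is None
        assert "impossible" in sol.diagnosis

    def test_scaling_units_leaves_objective_invariant(self):
        """Expressing one food in units of 10 g does not change the optimum."""
        p = two_food_problem()
        sol = solve(p)
        idx = p.foods
        scale = pd.Series([0.1, 1.0], index=idx)  # food a counted in 10 g units
        cons = [
            LinearConstraint(c.coeffs / scale, c.sense, c.rhs, c.label)
            for c in p.constraints
        ]
        p2 = QPProblem(
            anchor=p.anchor * scale,
            lower=p.lower * scale,
            upper=p.upper * scale,
            constraints=cons,
        )
        sol2 = solve(p2)
        assert sol2.objective == pytest.approx(sol.objective, abs=1e-10)
        assert sol2.x["a"] == pytest.approx(sol.x["a"] * 0.1, abs=1e-8)

    def test_agrees_with_interior_point_route(self, synth_bundle):
        """Uniqueness: the active-set path and scipy's trust-constr agree to 1e-6."""
        from dietshift import ScenarioSpec, assemble

        p = assemble(
            synth_bundle.group("male/all"),
            ScenarioSpec("x", ghge_reduction=1.0 / 3.0),
            synth_bundle,
        )
        sol = solve(p)
        assert sol.optimal
        dense = _Dense(p)
        z0 = _trust_constr_solve(dense)
        z, mu_eq, mu_w, work, ok = _polish_from_point(dense, z0, 1e-9)
        assert ok
        x_alt = z * p.anchor.to_numpy()
        np.testing.assert_allclose(
            sol.x.reindex(p.foods).to_numpy(), x_alt, atol=1e-6, rtol=1e-6
        )


class TestVerifyKKT:
    def test_optimal_solution_passes(self):
        sol = solve(two_food_problem())
        report = verify_kkt(two_food_problem(), sol, tol=1e-6)
        assert report["ok"]
        assert report["max_residual"] <= 1e-8

    def test_perturbed_solution_fails_stationarity(self):
        p = two_food_problem()
        sol = solve(p)
        # move along the energy equality to stay primal-feasible but suboptimal
        sol.x["a"] += 1.0
        sol.x["b"] -= 1.0
        report = verify_kkt(p, sol, tol=1e-6)
        assert not report["ok"]
        assert report["stationarity"] > 1e-6

    def test_nonbinding_dual_is_zero(self):
        p = two_food_problem()
        p.constraints[1] = LinearConstraint(
            p.constraints[1].coeffs, "<=", 400.0, "ghge_cap"
        )
        sol = solve(p)
        assert abs(sol.duals["ghge_cap"]) <= 1e-10
        assert sol.kkt["complementary_slackness"] <= 1e-10


class TestOracle:
    def test_two_food_example(self):
        ref = brute_force_oracle(two_food_problem())
        assert ref.optimal
        assert ref.objective == pytest.approx(0.5, abs=1e-7)
        assert ref.x["a"] == pytest.approx(50.0, abs=1e-3)

    def test_unconstrained_within_box_returns_anchor(self):
        idx = pd.Index(["a", "b"], name="food_id")
        p = QPProblem(
            anchor=pd.Series([100.0, 50.0], index=idx),
            lower=pd.Series([0.0, 0.0], index=idx),
            upper=pd.Series([200.0, 200.0], index=idx),
            constraints=[],
        )
        ref = brute_force_oracle(p)
        assert ref.objective == pytest.approx(0.0, abs=1e-10)

    def test_dimension_guard(self):
        idx = pd.Index([f"f{i}" for i in range(6)], name="food_id")
        p = QPProblem(
            anchor=pd.Series(np.ones(6) * 10, index=idx),
            lower=pd.Series(np.zeros(6), index=idx),
            upper=pd.Series(np.ones(6) * 20, index=idx),
            constraints=[],
        )
        with pytest.raises(ValueError, match="<= 5"):
            brute_force_oracle(p)


class TestProblemValidation:
    def test_zero_anchor_rejected(self):
        idx = pd.Index(["a"], name="food_id")
        with pytest.raises(ValueError, match="strictly positive"):
            QPProblem(
                anchor=pd.Series([0.0], index=idx),
                lower=pd.Series([0.0], index=idx),
                upper=pd.Series([1.0], index=idx),
                constraints=[],
            )

    def test_inverted_box_rejected(self):
        idx = pd.Index(["a"], name="food_id")
        with pytest.raises(ValueError, match="lower bound exceeds"):
            QPProblem(
                anchor=pd.Series([1.0], index=idx),
                lower=pd.Series([2.0], index=idx),
                upper=pd.Series([1.0], index=idx),
                constraints=[],
            )

    def test_weights_are_inverse_square_anchor(self):
        p = two_food_problem()
        np.testing.assert_allclose(p.weights.to_numpy(), 1e-4)
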