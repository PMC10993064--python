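"""Constraint builders and problem assembly."""

import numpy as np
import pandas as pd
import pytest

from dietshift import (
    RecommendationSet,
    ScenarioSpec,
    assemble,
    build_beef_dairy_constraint,
    build_energy_constraint,
    build_food_habit_bounds,
    build_ghge_cap,
    build_nutrient_constraints,
    compute_energy,
    compute_ghge,
)
from dietshift.foods import FoodCategory, FoodTable


class TestEnergyConstraint:
    def test_coefficients_and_rhs(self, toy_bundle):
        g = toy_bundle.group("toy/all")
        c = build_energy_constraint(g, toy_bundle.composition)
        assert c.sense == "=" and c.rhs == 200.0
        assert list(c.coeffs) == [1.0, 1.0, 0.0]

    def test_observed_diet_satisfies_itself(self, synth_bundle):
        g = synth_bundle.group("female/Educ3")
        c = build_energy_constraint(g, synth_bundle.composition)
        assert c.value(g.mean) == pytest.approx(g.energy_obs, rel=1e-9)

    def test_stored_energy_matches_recomputation(self, synth_bundle):
        # the generator closes energy exactly; 1 % is the documented data contract
        for gid in synth_bundle.group_ids:
            g = synth_bundle.group(gid)
            assert compute_energy(g.mean, synth_bundle.composition) == pytest.approx(
                g.energy_obs, rel=0.01
            )

    def test_nonpositive_energy_rejected(self, synth_bundle):
        g = synth_bundle.group("male/all")
        bad = type(g)(g.group_id, g.mean, g.p10, g.p90, energy_obs=0.0)
        with pytest.raises(ValueError, match="positive"):
            build_energy_constraint(bad, synth_bundle.composition)


class TestNutrientConstraints:
    def test_absolute_fibre_minimum(self, synth_bundle):
        cons = build_nutrient_constraints(
            synth_bundle.recommendations, synth_bundle.composition, 9400.0, "male"
        )
        fib = next(c for c in cons if c.label == "nut:fibre:min")
        assert fib.sense == ">=" and fib.rhs == 35.0
        pd.testing.assert_series_equal(
            fib.coeffs, synth_bundle.composition.density("fibre"), check_names=False
        )

    def test_energy_percent_sfa_maximum(self, synth_bundle):
        comp = synth_bundle.composition
        e0 = 9000.0
        cons = build_nutrient_constraints(
            synth_bundle.recommendations, comp, e0, "male"
        )
        sfa = next(c for c in cons if c.label == "nut:sfa:max")
        assert sfa.sense == "<="
        # k_j * sum a x <= 0.10 * E0  <=>  sum a x <= 0.10 * E0 / k_fat
        assert sfa.rhs == pytest.approx(0.10 * e0)
        pd.testing.assert_series_equal(
            sfa.coeffs, comp.energy_factor("sfa") * comp.density("sfa"),
            check_names=False,
        )

    def test_unbounded_nutrient_produces_no_constraint(self, synth_bundle):
        cons = build_nutrient_constraints(
            synth_bundle.recommendations, synth_bundle.composition, 9000.0, "male"
        )
        # b12 has only a minimum: exactly one constraint, no max
        labels = [c.label for c in cons]
        assert "nut:b12:min" in labels and "nut:b12:max" not in labels

    def test_epercent_and_absolute_forms_define_same_halfspace(self, synth_bundle):
        """An E% bound pre-converted to absolute units gives the same feasible set."""
        comp = synth_bundle.composition
        e0 = 8000.0
        recs_ep = RecommendationSet(pd.DataFrame(
            [["carb", "male", "min", "energy_percent", 45.0, "", ""]],
            columns=["nutrient_id", "sex", "bound_type", "form", "value", "source", "policy"],
        ))
        recs_abs = RecommendationSet(pd.DataFrame(
            [["carb", "male", "min", "absolute", 0.45 * e0 / comp.energy_factor("carb"), "", ""]],
            columns=["nutrient_id", "sex", "bound_type", "form", "value", "source", "policy"],
        ))
        (c_ep,) = build_nutrient_constraints(recs_ep, comp, e0, "male")
        (c_abs,) = build_nutrient_constraints(recs_abs, comp, e0, "male")
        # same halfspace up to a positive scale factor
        k = comp.energy_factor("carb")
        np.testing.assert_allclose(c_ep.coeffs, k * c_abs.coeffs, rtol=1e-12)
        assert c_ep.rhs == pytest.approx(k * c_abs.rhs)
        assert c_ep.sense == c_abs.sense

    def test_fe_policy_switches_female_bound(self, synth_bundle):
        comp = synth_bundle.composition
        lo = build_nutrient_constraints(
            synth_bundle.recommendations, comp, 7400.0, "female", "observed"
        )
        hi = build_nutrient_constraints(
            synth_bundle.recommendations, comp, 7400.0, "female", "recommended"
        )
        fe_lo = next(c for c in lo if c.label == "nut:iron:min")
        fe_hi = next(c for c in hi if c.label == "nut:iron:min")
        assert (fe_lo.rhs, fe_hi.rhs) == (10.0, 15.0)


class TestHabitBounds:
    def test_box(self, synth_bundle):
        g = synth_bundle.group("male/all")
        lo, hi = build_food_habit_bounds(g)
        pd.testing.assert_series_equal(lo, g.p10)
        pd.testing.assert_series_equal(hi, g.p90)

    def test_degenerate_box_fixes_food(self, toy_bundle):
        p = assemble(toy_bundle.group("toy/all"), ScenarioSpec("n"), toy_bundle)
        assert "food_c" not in p.foods
        assert p.fixed["food_c"] == 50.0


class TestGHGECap:
    def test_r_zero_keeps_baseline(self, synth_bundle):
        g = synth_bundle.group("male/all")
        cap = build_ghge_cap(synth_bundle.ghge["lca"], g, 0.0)
        assert cap.rhs == pytest.approx(compute_ghge(g.mean, synth_bundle.ghge["lca"]))
        assert cap.satisfied(g.mean)

    @pytest.mark.parametrize("r,frac", [(1.0 / 3.0, 2.0 / 3.0), (0.5, 0.5)])
    def test_reduction_scales_rhs(self, synth_bundle, r, frac):
        g = synth_bundle.group("male/all")
        base = compute_ghge(g.mean, synth_bundle.ghge["lca"])
        cap = build_ghge_cap(synth_bundle.ghge["lca"], g, r)
        assert cap.rhs == pytest.approx(frac * base)

    def test_invalid_reduction(self, synth_bundle):
        g = synth_bundle.group("male/all")
        with pytest.raises(ValueError):
            build_ghge_cap(synth_bundle.ghge["lca"], g, 1.0)


class TestBeefDairy:
    @pytest.fixture
    def table(self):
        return FoodTable(
            [
                FoodCategory("milk", "milk", "milk", milk_eq=1.0),
                FoodCategory("beef", "beef", "meat", beef_content=1.0),
                FoodCategory("sausage", "sausage", "meat", beef_content=0.075),
            ]
        )

    def test_exactly_binding_at_ratio(self, table):
        c = build_beef_dairy_constraint(table, 33.9)
        diet = pd.Series({"milk": 339.0, "beef": 10.0, "sausage": 0.0})
        # 33.9 g milk per g beef: 10 g beef supports exactly 339 g milk-eq
        assert c.value(diet.reindex(c.coeffs.index)) == pytest.approx(0.0, abs=1e-9)
        assert c.sense == ">="

    def test_no_dairy_any_beef_satisfied(self, table):
        c = build_beef_dairy_constraint(table)
        assert c.satisfied(pd.Series({"milk": 0.0, "beef": 5.0, "sausage": 0.0}))

    def test_sausage_counts_fractionally(self, table):
        c = build_beef_dairy_constraint(table, 33.9)
        assert c.coeffs["sausage"] == pytest.approx(33.9 * 0.075)

    def test_all_dairy_no_beef_warns(self):
        t = FoodTable([FoodCategory("milk", "milk", "milk", milk_eq=1.0)])
        with pytest.warns(UserWarning, match="beef"):
            build_beef_dairy_constraint(t)


class TestAssemble:
    def test_nutrition_only_has_no_cap(self, synth_bundle):
        p = assemble(synth_bundle.group("male/all"), ScenarioSpec("nutrition_only"),
                     synth_bundle)
        assert "ghge_cap" not in p.labels()
        assert "beef_dairy" in p.labels()

    def test_beef_dairy_can_be_dropped(self, synth_bundle):
        p = assemble(
            synth_bundle.group("male/all"),
            ScenarioSpec("x", ghge_reduction=0.5, include_beef_dairy=False),
            synth_bundle,
        )
        assert "beef_dairy" not in p.labels()
        assert "ghge_cap" in p.labels()

    def test_constraint_count(self, synth_bundle):
        spec = ScenarioSpec("x", ghge_reduction=0.5)
        p = assemble(synth_bundle.group("male/all"), spec, synth_bundle)
        n_nutrients = len(synth_bundle.recommendations.bounds_for("male"))
        assert len(p.constraints) == 1 + n_nutrients + 1 + 1

    def test_constraints_invariant_to_food_order(self, synth_bundle):
        spec = ScenarioSpec("x", ghge_reduction=0.5)
        p = assemble(synth_bundle.group("male/all"), spec, synth_bundle)
        for c in p.constraints:
            perm = c.coeffs.sample(frac=1.0, random_state=1)
            assert c.value(perm) == pytest.approx(c.value(c.coeffs), rel=1e-12)


class TestScenarioSpec:
    def test_invalid_reduction(self):
        with pytest.raises(ValueError):
            ScenarioSpec("x", ghge_reduction=1.5)

    def test_invalid_fe_policy(self):
        with pytest.raises(ValueError):
            ScenarioSpec("x", fe_policy="maximal")


class TestRecommendationSet:
    def test_min_above_max_rejected(self):
        df = pd.DataFrame(
            [
                ["fibre", "male", "min", "absolute", 40.0, "", ""],
                ["fibre", "male", "max", "absolute", 30.0, "", ""],
            ],
            columns=["nutrient_id", "sex", "bound_type", "form", "value", "source", "policy"],
        )
        with pytest.raises(ValueError, match="min bound exceeds max"):
            RecommendationSet(df)

    def test_energy_percent_range(self):
        df = pd.DataFrame(
            [["sfa", "male", "max", "energy_percent", 150.0, "", ""]],
            columns=["nutrient_id", "sex", "bound_type", "form", "value", "source", "policy"],
        )
        with pytest.raises(ValueError, match="energy_percent"):
            RecommendationSet(df)
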