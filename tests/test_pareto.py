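"""Trade-off sweeps, binding-nutrient diagnostics and transition points."""

import pytest
from hypothesis import given, strategies as st

import fluxcompare as fc
from fluxcompare.errors import FrontError, StateError
from fluxcompare.fba import SolverStatus
from fluxcompare.pareto import ParetoSettings

from oracles import vertex_optimum_for_model


class TestParetoFront:
    def test_branch_front_is_conservation_line(self, branch_model):
        front = fc.pareto_front(
            branch_model, ParetoSettings("export_1", "export_2", n=10)
        )
        assert front.f1_max == pytest.approx(10.0)
        for i, pt in enumerate(front.points):
            fraction = 1.0 - i / 10
            assert pt.fraction == pytest.approx(fraction)
            # v2 = U - v1 along the whole sweep
            assert pt.objective2_value == pytest.approx(
                10.0 - 10.0 * fraction, abs=1e-6
            )

    def test_disjoint_resources_make_flat_front(self):
        model = fc.fixtures.make_disjoint_pair(uptake1=10.0, uptake2=7.0)
        front = fc.pareto_front(model, ParetoSettings("export_a", "export_b", n=8))
        for pt in front.points:
            assert pt.objective2_value == pytest.approx(7.0, abs=1e-6)

    def test_point_count_and_fraction_order(self, branch_model):
        front = fc.pareto_front(branch_model, ParetoSettings("export_1", "export_2", n=7))
        fractions = [pt.fraction for pt in front.points]
        assert len(fractions) == 8
        assert fractions[0] == 1.0 and fractions[-1] == 0.0
        assert all(a > b for a, b in zip(fractions, fractions[1:]))

    def test_endpoint_consistency(self, branch_model):
        front = fc.pareto_front(branch_model, ParetoSettings("export_1", "export_2", n=5))
        at_max = fc.solve_fba_with_fixed_flux(
            branch_model, "export_2", [("export_1", front.f1_max, fc.DEFAULT_BIG)]
        )
        unconstrained = fc.solve_fba(branch_model, "export_2")
        assert front.points[0].objective2_value == pytest.approx(
            at_max.objective_value, abs=1e-6
        )
        assert front.points[-1].objective2_value == pytest.approx(
            unconstrained.objective_value, abs=1e-6
        )

    def test_monotone_relaxation(self, two_nutrient):
        model, medium = two_nutrient
        front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=12), medium)
        values = [pt.objective2_value for pt in front.points]
        for earlier, later in zip(values, values[1:]):
            assert later >= earlier - 1e-9

    def test_resolution_refinement(self, branch_model):
        coarse = fc.pareto_front(branch_model, ParetoSettings("export_1", "export_2", n=5))
        fine = fc.pareto_front(branch_model, ParetoSettings("export_1", "export_2", n=10))
        fine_by_fraction = {round(pt.fraction, 9): pt.objective2_value for pt in fine.points}
        for pt in coarse.points:
            assert fine_by_fraction[round(pt.fraction, 9)] == pytest.approx(
                pt.objective2_value, abs=1e-6
            )

    def test_front_matches_vertex_oracle_pointwise(self, two_nutrient):
        model, medium = two_nutrient
        prepared = fc.apply_medium(model, medium)
        front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=6), medium)
        ub = prepared.get_reaction("biomass").upper_bound
        for pt in front.points:
            oracle = vertex_optimum_for_model(
                prepared, "product", overrides=[("biomass", pt.objective1_floor, ub)]
            )
            assert pt.objective2_value == pytest.approx(oracle, abs=1e-6)

    def test_infeasible_base_raises_front_error(self, chain_model):
        broken = chain_model.copy()
        # force a positive flux through a reaction nothing can supply
        broken.get_reaction("uptake").lower_bound = 1.0
        broken.get_reaction("EX_glc").upper_bound = 0.0
        broken.get_reaction("EX_glc").lower_bound = 0.0
        constrained = fc.apply_medium(broken, fc.Medium(entries={}))
        with pytest.raises(FrontError):
            fc.pareto_front(constrained, ParetoSettings("export", "uptake", n=3))

    def test_invalid_settings_rejected(self, chain_model):
        with pytest.raises(ValueError):
            fc.pareto_front(chain_model, ParetoSettings("export", "export", n=3))
        with pytest.raises(ValueError):
            fc.pareto_front(chain_model, ParetoSettings("export", "uptake", n=0))


class TestTwoNutrientTradeoff:
    """Structural twin of the biomass/product nutrient-limitation analysis."""

    def test_plateau_exists_and_extent_is_analytic(self, two_nutrient):
        model, medium = two_nutrient
        front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=12), medium)
        f2_max = front.f2_max
        plateau = [
            pt for pt in front.points
            if abs(pt.objective2_value - f2_max) <= 1e-6
        ]
        expected_fraction = fc.fixtures.plateau_fraction()
        # plateau spans exactly the fractions <= (capacity - po4)/f1_max
        assert {round(pt.fraction, 6) for pt in plateau} == {
            round(i / 12, 6) for i in range(0, int(expected_fraction * 12) + 1)
        }

    def test_binding_nutrients_differ_at_the_two_ends(self, two_nutrient):
        model, medium = two_nutrient
        front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=10), medium)
        top = fc.binding_medium_constraints(front.points[0].result, front.model, medium)
        bottom = fc.binding_medium_constraints(front.points[-1].result, front.model, medium)
        assert top == ["nh3_e"]  # biomass end: nitrogen-limited
        assert bottom == ["po4_e"]  # product end: phosphate-limited

    def test_doubling_nutrient_bounds_removes_plateau(self):
        model, medium = fc.fixtures.make_two_nutrient(
            nh3_bound=12.0, po4_bound=8.0
        )
        front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=12), medium)
        f2_max = front.f2_max
        plateau = [
            pt for pt in front.points
            if abs(pt.objective2_value - f2_max) <= 1e-6
        ]
        assert len(plateau) == 1  # only the unconstrained endpoint remains


class TestBindingMediumConstraints:
    def test_single_uptake_at_bound_is_listed(self):
        model = fc.fixtures.make_chain(k=2, uptake=fc.DEFAULT_BIG)
        medium = fc.Medium(entries={"glc_e": 10.0})
        prepared = fc.apply_medium(model, medium)
        result = fc.solve_fba(prepared, "export")
        assert fc.binding_medium_constraints(result, prepared, medium) == ["glc_e"]

    def test_interior_optimum_gives_empty_list(self):
        model = fc.fixtures.make_chain(k=2, uptake=4.0)  # reaction bound binds first
        medium = fc.Medium(entries={"glc_e": 10.0})
        prepared = fc.apply_medium(model, medium)
        result = fc.solve_fba(prepared, "export")
        assert fc.binding_medium_constraints(result, prepared, medium) == []

    def test_non_optimal_result_raises(self, chain_model):
        medium = fc.Medium(entries={"glc_e": 1.0})
        prepared = fc.apply_medium(chain_model, medium)
        result = fc.solve_fba_with_fixed_flux(
            prepared, "export", [("export", 99.0, 99.0)]
        )
        assert result.status is SolverStatus.INFEASIBLE
        with pytest.raises(StateError):
            fc.binding_medium_constraints(result, prepared, medium)


class TestTransitionPoints:
    def test_straight_line_front_has_none(self, branch_model):
        front = fc.pareto_front(branch_model, ParetoSettings("export_1", "export_2", n=10))
        assert fc.transition_points(front) == []

    def test_plateau_edge_detected_exactly_once(self, two_nutrient):
        model, medium = two_nutrient
        # n=12 puts the analytic kink (fraction 2/3) on the sweep grid
        front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=12), medium)
        transitions = fc.transition_points(front)
        assert len(transitions) == 1
        assert transitions[0] == pytest.approx(fc.fixtures.plateau_fraction())

    def test_flat_front_has_none(self):
        model = fc.fixtures.make_disjoint_pair()
        front = fc.pareto_front(model, ParetoSettings("export_a", "export_b", n=6))
        assert fc.transition_points(front) == []


class TestRandomFrontInvariants:
    @given(st.integers(0, 99))
    def test_endpoints_and_monotonicity_on_random_networks(self, seed):
        model = fc.fixtures.make_random_network(seed, n_reactions=6, n_metabolites=3)
        front = fc.pareto_front(model, ParetoSettings("r0", "r1", n=5))
        values = [pt.objective2_value for pt in front.points]
        assert all(v is not None for v in values)
        for earlier, later in zip(values, values[1:]):
            assert later >= earlier - 1e-7
        unconstrained = fc.solve_fba(model, "r1").objective_value
        assert values[-1] == pytest.approx(unconstrained, abs=1e-6)
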