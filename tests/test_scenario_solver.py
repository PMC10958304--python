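import numpy as np
import pytest

from wptaxsim.market_model import TaxPolicy
from wptaxsim.scenario_solver import (
    NoSolutionError,
    PolicyTarget,
    evaluate_baseline,
    evaluate_policy,
    solve_specific,
    sweep,
)
from wptaxsim.synthetic_data import SynthConfig, generate

from conftest import build_scenario


class TestEvaluatePolicy:
    def test_same_tax_is_a_no_op(self, toy_scenario):
        s0 = toy_scenario.tax.specific_excise
        result = evaluate_policy(toy_scenario, s0)
        stats, rev = evaluate_baseline(toy_scenario)
        assert result.policy_stats.total_units == pytest.approx(stats.total_units)
        assert result.policy_revenue.total == pytest.approx(rev.total)
        assert result.deaths_averted == pytest.approx(0.0, abs=1e-6)

    def test_higher_tax_reduces_units_and_averts_deaths(self, toy_scenario):
        result = evaluate_policy(toy_scenario, 1.5)
        assert result.policy_stats.total_units < toy_scenario.total_units
        assert result.deaths_averted > 0

    def test_remove_ad_valorem_zeroes_component(self, toy_scenario):
        result = evaluate_policy(toy_scenario, 1.0, remove_ad_valorem=True)
        assert result.policy_revenue.ad_valorem_rev == 0.0
        assert all(o.policy.ad_valorem == 0.0 for o in result.shares)

    def test_baseline_weights_flag_freezes_quantities(self, toy_scenario):
        moved = evaluate_policy(toy_scenario, 1.5)
        frozen = evaluate_policy(toy_scenario, 1.5, baseline_weights=True)
        assert frozen.policy_stats.total_units == pytest.approx(toy_scenario.total_units)
        # demand shifts toward cheaper relative rises, so the weighted price differs
        assert moved.policy_stats.weighted_price != pytest.approx(
            frozen.policy_stats.weighted_price
        )


class TestSolveSpecific:
    def test_baseline_burden_is_a_fixed_point(self, toy_scenario):
        stats, _ = evaluate_baseline(toy_scenario)
        target = PolicyTarget("burden_target", stats.weighted_burden)
        s_star, _ = solve_specific(toy_scenario, target, bracket=(0.0, 5.0))
        assert s_star == pytest.approx(toy_scenario.tax.specific_excise, abs=1e-5)

    def test_inelastic_specific_only_revenue_doubling(self):
        """With zero elasticity and only a specific tax, doubling excise
        revenue means exactly doubling the specific rate."""
        s0 = 0.4
        sc = build_scenario(
            tax=TaxPolicy(specific_excise=s0),
            elasticities=(0, 0, 0, 0),
            cif=0.2,
        )
        target = PolicyTarget("excise_revenue_multiple", 2.0)
        s_star, result = solve_specific(sc, target, bracket=(0.0, 5.0))
        assert s_star == pytest.approx(2 * s0, abs=1e-5)
        assert result.policy_stats.total_units == pytest.approx(sc.total_units)

    def test_solver_agrees_with_grid_search(self):
        """The bisection result matches a 10,000-point grid search."""
        sc = generate(SynthConfig(seed=7))
        baseline_burden = evaluate_baseline(sc)[0].weighted_burden
        goal = min(0.9 * baseline_burden + 0.1 * 0.9, baseline_burden + 0.2)
        target = PolicyTarget("burden_target", goal)
        lo, hi = 0.0, 10.0
        s_star, result = solve_specific(sc, target, bracket=(lo, hi))

        grid = np.linspace(lo, hi, 10_000)
        step = grid[1] - grid[0]
        objective = [
            abs(
                evaluate_policy(sc, s, on_negative_margin="warn")
                .policy_stats.weighted_burden
                - goal
            )
            for s in grid
        ]
        s_grid = grid[int(np.argmin(objective))]
        assert abs(s_star - s_grid) <= step
        assert result.policy_stats.weighted_burden == pytest.approx(goal, abs=1e-6)

    def test_solution_meets_target_post_hoc(self, jordan):
        target = PolicyTarget("burden_target", 0.359)
        s_star, result = solve_specific(jordan, target)
        assert result.policy_stats.weighted_burden == pytest.approx(0.359, abs=1e-6)
        assert s_star > jordan.tax.specific_excise

    def test_unattainable_target_reports_attainable_range(self, toy_scenario):
        target = PolicyTarget("excise_revenue_multiple", 500.0)
        with pytest.raises(NoSolutionError, match="attainable range"):
            solve_specific(toy_scenario, target, bracket=(0.0, 10.0))

    def test_revenue_multiple_returns_smallest_root(self):
        """Past the Laffer peak a revenue level is hit twice; the solver
        must return the cheaper (smaller) excise."""
        sc = build_scenario(elasticities=(-2.5, -2.5, -2.5, -2.5),
                            tax=TaxPolicy(specific_excise=0.1, vat_rate=0.1))
        target = PolicyTarget("excise_revenue_multiple", 1.5)
        s_star, _ = solve_specific(sc, target, bracket=(0.0, 50.0))
        points = sweep(sc, np.linspace(0.0, 50.0, 2000))
        rev = np.array([p.excise_revenue for p in points])
        peak = points[int(np.argmax(rev))].specific_excise
        assert s_star < peak


class TestSweep:
    def test_single_point_equals_baseline_evaluation(self, toy_scenario):
        s0 = toy_scenario.tax.specific_excise
        [point] = sweep(toy_scenario, [s0])
        stats, rev = evaluate_baseline(toy_scenario)
        assert point.total_units == pytest.approx(stats.total_units)
        assert point.excise_revenue == pytest.approx(rev.excise)

    def test_units_non_increasing_and_revenue_unimodal(self):
        sc = generate(SynthConfig(seed=3))
        points = sweep(sc, np.linspace(0.0, 15.0, 200))
        units = np.array([p.total_units for p in points])
        assert np.all(np.diff(units) <= 1e-9 * units[0])
        rev = np.array([p.excise_revenue for p in points])
        signs = np.sign(np.diff(rev))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes <= 1  # single-peaked Laffer curve

    def test_burden_monotone_along_grid(self, toy_scenario):
        points = sweep(toy_scenario, np.linspace(0.0, 5.0, 50))
        burdens = [p.weighted_burden for p in points]
        assert all(b2 > b1 for b1, b2 in zip(burdens, burdens[1:]))

    def test_unsorted_grid_rejected(self, toy_scenario):
        with pytest.raises(ValueError):
            sweep(toy_scenario, [1.0, 0.5])
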