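"""Scenario evaluation, policy goal-seeking and incremental tax sweeps.

``evaluate_policy`` runs the full pipeline for one candidate specific-excise
level: recompose each share's retail price under the new tax (CIF and margin
fixed, full pass-through unless shifted), project each share's demand with
its constant elasticity, and aggregate revenue and market-weighted
statistics from the post-response quantities.

``solve_specific`` finds the specific excise that meets a policy target —
either a market-weighted tax burden (e.g. the 35.9% global average for
waterpipe tobacco) or a multiple of baseline excise revenue.  Excise revenue
along a specific-tax sweep is a Laffer curve (single-peaked), so a revenue
target may have two roots; the solver returns the smallest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from . import demand_health, price_engine, revenue_burden
from .market_model import CountryScenario, TaxPolicy
from .price_engine import PriceDecomposition
from .revenue_burden import AggregateStats, RevenueBreakdown

__all__ = [
    "PolicyTarget",
    "ShareOutcome",
    "ScenarioResult",
    "SweepPoint",
    "NoSolutionError",
    "evaluate_baseline",
    "evaluate_policy",
    "solve_specific",
    "sweep",
]


class NoSolutionError(ValueError):
    """The policy target is unattainable within the search bracket."""


@dataclass(frozen=True)
class PolicyTarget:
    """A goal for the specific-excise solver.

    ``mode="burden_target"``: reach a market-weighted tax burden of
    ``value`` (a fraction, e.g. 0.359).  ``mode="excise_revenue_multiple"``:
    make excise revenue (specific + ad valorem) equal ``value`` times its
    baseline level.  ``remove_ad_valorem`` zeroes the ad valorem rate in the
    policy scenario (simplifying the tax structure) before solving.
    """

    mode: str
    value: float
    remove_ad_valorem: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("burden_target", "excise_revenue_multiple"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if not (self.value > 0):
            raise ValueError(f"target value must be > 0, got {self.value}")


@dataclass(frozen=True)
class ShareOutcome:
    """Baseline/policy pair for one market share."""

    label: str
    baseline: PriceDecomposition
    policy: PriceDecomposition
    q0: float
    q1: float
    elasticity_used: float


@dataclass(frozen=True)
class ScenarioResult:
    """Per-share and aggregate outputs for a baseline/policy pair."""

    scenario_name: str
    specific_excise: float
    policy_tax: TaxPolicy
    shares: Tuple[ShareOutcome, ...]
    baseline_stats: AggregateStats
    policy_stats: AggregateStats
    baseline_revenue: RevenueBreakdown
    policy_revenue: RevenueBreakdown
    deaths_averted: float

    @property
    def consumption_change(self) -> float:
        """Relative change in total units (negative for a reduction)."""
        return self.policy_stats.total_units / self.baseline_stats.total_units - 1.0

    @property
    def revenue_change(self) -> float:
        """Relative change in total tax revenue."""
        return self.policy_revenue.total / self.baseline_revenue.total - 1.0


@dataclass(frozen=True)
class SweepPoint:
    """One point of an incremental specific-tax sweep."""

    specific_excise: float
    total_units: float
    excise_revenue: float
    total_revenue: float
    weighted_burden: float
    weighted_price: float


def _baseline_decompositions(
    scenario: CountryScenario, cif_factor: float, on_negative_margin: str
) -> List[Tuple[PriceDecomposition, float]]:
    tax = scenario.effective_tax()
    cif = scenario.cif_price * cif_factor
    return [
        (
            price_engine.decompose(
                s.retail_price, cif, tax, label=s.label, on_negative_margin=on_negative_margin
            ),
            s.annual_units,
        )
        for s in scenario.market_shares
    ]


def evaluate_baseline(
    scenario: CountryScenario,
    *,
    cif_factor: float = 1.0,
    on_negative_margin: str = "raise",
) -> Tuple[AggregateStats, RevenueBreakdown]:
    """Aggregate statistics and revenue of the base (current-tax) scenario."""
    entries = _baseline_decompositions(scenario, cif_factor, on_negative_margin)
    return revenue_burden.weighted_stats(entries), revenue_burden.revenue(entries)


def evaluate_policy(
    scenario: CountryScenario,
    specific_excise: float,
    *,
    remove_ad_valorem: bool = False,
    pass_through: float = 1.0,
    cif_factor: float = 1.0,
    elasticity_variant: str = "point",
    baseline_weights: bool = False,
    include_illicit_in_health: bool = False,
    on_negative_margin: str = "raise",
) -> ScenarioResult:
    """Evaluate the scenario under a new specific-excise level.

    Pipeline per market share: recompose price under the new tax ->
    project demand with the share's constant elasticity -> aggregate.

    Parameters
    ----------
    specific_excise : float
        Candidate specific excise, USD per 20 g unit.
    remove_ad_valorem : bool
        Zero the ad valorem rate in the policy tax.
    pass_through : float
        Scale on the retail-price change (1.0 = full pass-through;
        1.1 / 0.9 model a 10% industry over/undershift).
    cif_factor : float
        Scale on the CIF price, applied before the baseline decomposition
        (used by sensitivity analysis).
    elasticity_variant : {"point", "low", "high"}
        Use the point estimate or a 95% CI bound of each share's elasticity.
    baseline_weights : bool
        Weight policy aggregates by baseline rather than post-response
        quantities (for comparison; the default uses the policy scenario's
        own quantities).
    include_illicit_in_health : bool
        Scale the quantities fed to the deaths computation back up to total
        (legal + illicit) consumption.  Note the deaths formula depends only
        on the *relative* consumption drop and the smoker count, so a joint
        rescaling leaves it unchanged; the flag is kept for explicitness.
    on_negative_margin : {"raise", "warn"}
        Forwarded to the price engine (sweeps use ``"warn"``).
    """
    if specific_excise < 0:
        raise ValueError(f"specific_excise must be >= 0, got {specific_excise}")

    base_tax = scenario.effective_tax()
    new_tax = base_tax.with_specific(specific_excise)
    if remove_ad_valorem:
        new_tax = new_tax.without_ad_valorem()

    baseline_entries = _baseline_decompositions(scenario, cif_factor, on_negative_margin)

    outcomes: List[ShareOutcome] = []
    for share, (base_dec, q0) in zip(scenario.market_shares, baseline_entries):
        policy_dec = price_engine.recompose(
            base_dec,
            new_tax,
            pass_through,
            label=share.label,
            on_negative_margin=on_negative_margin,
        )
        eps = share.elasticity.value(elasticity_variant)
        q1 = demand_health.project_demand(q0, base_dec.retail, policy_dec.retail, eps)
        outcomes.append(
            ShareOutcome(
                label=share.label,
                baseline=base_dec,
                policy=policy_dec,
                q0=q0,
                q1=q1,
                elasticity_used=eps,
            )
        )

    baseline_stats = revenue_burden.weighted_stats(baseline_entries)
    baseline_rev = revenue_burden.revenue(baseline_entries)

    policy_entries = [(o.policy, o.q0 if baseline_weights else o.q1) for o in outcomes]
    policy_stats = revenue_burden.weighted_stats(policy_entries)
    policy_rev = revenue_burden.revenue(policy_entries)

    q0_total = sum(o.q0 for o in outcomes)
    q1_total = sum(o.q1 for o in outcomes)
    if include_illicit_in_health:
        upscale = 1.0 / (1.0 - scenario.illicit_share)
        q0_total, q1_total = q0_total * upscale, q1_total * upscale
    deaths = (
        demand_health.deaths_averted(q0_total, min(q1_total, q0_total), scenario.smokers)
        if q0_total > 0
        else 0.0
    )

    return ScenarioResult(
        scenario_name=scenario.name,
        specific_excise=specific_excise,
        policy_tax=new_tax,
        shares=tuple(outcomes),
        baseline_stats=baseline_stats,
        policy_stats=policy_stats,
        baseline_revenue=baseline_rev,
        policy_revenue=policy_rev,
        deaths_averted=deaths,
    )


def solve_specific(
    scenario: CountryScenario,
    target: PolicyTarget,
    bracket: Tuple[float, float] = (0.0, 50.0),
    tol: float = 1e-6,
    *,
    scan_points: int = 257,
    **eval_kwargs,
) -> Tuple[float, ScenarioResult]:
    """Specific excise meeting a policy target, with the resulting scenario.

    The objective is evaluated on a coarse scan of the bracket to locate the
    first sign change (the smallest root when excise revenue is non-monotone
    past its Laffer peak), then refined by Brent's method to ``tol`` USD.

    Raises
    ------
    NoSolutionError
        If the objective never crosses zero in the bracket; the message
        reports the attainable range of the targeted quantity.
    """
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ValueError(f"invalid bracket {bracket}")

    eval_kwargs.setdefault("on_negative_margin", "warn")
    baseline_excise = evaluate_baseline(
        scenario, cif_factor=eval_kwargs.get("cif_factor", 1.0), on_negative_margin="warn"
    )[1].excise

    def measure(s: float) -> float:
        result = evaluate_policy(
            scenario, s, remove_ad_valorem=target.remove_ad_valorem, **eval_kwargs
        )
        if target.mode == "burden_target":
            return result.policy_stats.weighted_burden
        return result.policy_revenue.excise

    goal = (
        target.value
        if target.mode == "burden_target"
        else target.value * baseline_excise
    )

    def objective(s: float) -> float:
        return measure(s) - goal

    grid = np.linspace(lo, hi, scan_points)
    values = np.array([objective(s) for s in grid])

    # exact hit on a grid node (e.g. the fixed-point target)
    hit = np.flatnonzero(np.abs(values) == 0.0)
    if hit.size:
        s_star = float(grid[hit[0]])
    else:
        crossings = np.flatnonzero(np.sign(values[:-1]) * np.sign(values[1:]) < 0)
        if crossings.size == 0:
            attained = values + goal
            raise NoSolutionError(
                f"target {target.mode}={target.value} unattainable in bracket "
                f"[{lo}, {hi}]: attainable range is "
                f"[{attained.min():.6g}, {attained.max():.6g}]"
            )
        i = int(crossings[0])
        s_star = float(brentq(objective, grid[i], grid[i + 1], xtol=tol))

    result = evaluate_policy(
        scenario, s_star, remove_ad_valorem=target.remove_ad_valorem, **eval_kwargs
    )
    return s_star, result


def sweep(
    scenario: CountryScenario,
    specific_grid: Sequence[float],
    remove_ad_valorem: bool = False,
    **eval_kwargs,
) -> List[SweepPoint]:
    """Evaluate the scenario at each specific-excise level of a sorted grid.

    Each point runs recompose -> demand projection -> revenue.  Tax levels
    that push a share's margin negative produce a warning, not an error, so
    the sweep documents where the current retail price can no longer absorb
    the tax.
    """
    grid = list(specific_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("specific_grid must be sorted ascending")
    eval_kwargs.setdefault("on_negative_margin", "warn")

    points = []
    for s in grid:
        r = evaluate_policy(scenario, s, remove_ad_valorem=remove_ad_valorem, **eval_kwargs)
        points.append(
            SweepPoint(
                specific_excise=s,
                total_units=r.policy_stats.total_units,
                excise_revenue=r.policy_revenue.excise,
                total_revenue=r.policy_revenue.total,
                weighted_burden=r.policy_stats.weighted_burden,
                weighted_price=r.policy_stats.weighted_price,
            )
        )
    return points
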