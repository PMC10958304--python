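"""Revenue calibration and one-at-a-time sensitivity analysis.

Calibration scales all market-share quantities by a single factor so the
baseline model revenue matches (or stays below) an externally reported
tobacco tax revenue.  Because revenue is linear in quantities while the
market-weighted price and burden are scale-free, calibration changes levels
only, never the structure of the market.

The sensitivity grid perturbs, one at a time: the CIF price (+-50%, probing
the assumption that the CIF price equals the ex-factory price), the industry
pricing response (a 10% over- or undershift of the retail price change), and
the elasticities (swapped to their 95% CI bounds).  Outcomes are reported as
relative percentage differences from the main scenario.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .market_model import CountryScenario
from .scenario_solver import (
    NoSolutionError,
    PolicyTarget,
    ScenarioResult,
    evaluate_baseline,
    evaluate_policy,
    solve_specific,
)

__all__ = [
    "SensitivitySpec",
    "SensitivityResult",
    "calibrate",
    "revenue_plausible",
    "run_sensitivity",
    "one_at_a_time_grid",
    "full_grid",
]

CIF_FACTORS = (0.5, 1.0, 1.5)
SHIFTS = (0.9, 1.0, 1.1)
ELASTICITY_VARIANTS = ("low", "point", "high")


@dataclass(frozen=True)
class SensitivitySpec:
    """One cell of the sensitivity grid.

    ``cif_factor`` scales the CIF price before decomposition; ``shift``
    scales the pass-through of the retail-price change; ``elasticity_variant``
    selects the point estimate or a 95% CI bound ("low" = more negative).
    """

    cif_factor: float = 1.0
    shift: float = 1.0
    elasticity_variant: str = "point"

    @property
    def is_identity(self) -> bool:
        return (
            self.cif_factor == 1.0
            and self.shift == 1.0
            and self.elasticity_variant == "point"
        )


@dataclass(frozen=True)
class SensitivityResult:
    """Percentage deltas of one spec's outcomes vs the main scenario."""

    spec: SensitivitySpec
    consumption_delta: float  # % relative to main scenario
    revenue_delta: float  # %
    deaths_delta: float  # %
    solved_specific: float = float("nan")
    error: Optional[str] = None


def one_at_a_time_grid() -> List[SensitivitySpec]:
    """The identity spec plus each single-parameter perturbation."""
    specs = [SensitivitySpec()]
    specs += [SensitivitySpec(cif_factor=f) for f in CIF_FACTORS if f != 1.0]
    specs += [SensitivitySpec(shift=s) for s in SHIFTS if s != 1.0]
    specs += [SensitivitySpec(elasticity_variant=v) for v in ELASTICITY_VARIANTS if v != "point"]
    return specs


def full_grid() -> List[SensitivitySpec]:
    """The full 3 x 3 x 3 factorial grid (27 specs, identity included once)."""
    return [
        SensitivitySpec(cif_factor=f, shift=s, elasticity_variant=v)
        for f, s, v in itertools.product(CIF_FACTORS, SHIFTS, ELASTICITY_VARIANTS)
    ]


def calibrate(
    scenario: CountryScenario, anchor: float, mode: str = "match"
) -> Tuple[CountryScenario, float]:
    """Scale quantities so baseline revenue relates to an external anchor.

    ``mode="match"`` multiplies every share's annual units by
    ``k = anchor / baseline_revenue`` so modelled revenue equals the anchor
    (revenue is linear in quantities).  ``mode="cap"`` only scales *down*
    (``k = min(1, anchor / baseline_revenue)``), enforcing that modelled
    waterpipe revenue not exceed a reported all-tobacco revenue.  Prices,
    elasticities, burden and weighted price are unchanged.

    Returns the scaled scenario and the factor ``k``.
    """
    if anchor <= 0:
        raise ValueError(f"anchor must be > 0, got {anchor}")
    _, rev = evaluate_baseline(scenario)
    if rev.total <= 0:
        raise ValueError("baseline revenue must be > 0 to calibrate")
    k = anchor / rev.total
    if mode == "cap":
        k = min(1.0, k)
    elif mode != "match":
        raise ValueError(f"unknown calibration mode {mode!r}")
    if k == 1.0:
        return scenario, 1.0
    return scenario.scale_quantities(k), k


def revenue_plausible(scenario: CountryScenario, anchor: Optional[float] = None) -> bool:
    """Check modelled waterpipe revenue against a reported all-tobacco revenue.

    Waterpipe tobacco is a subset of all tobacco products, so its modelled
    tax take should not exceed the country's reported total tobacco tax
    revenue.  Uses ``scenario.revenue_anchor`` when ``anchor`` is omitted.
    """
    if anchor is None:
        anchor = scenario.revenue_anchor
    if anchor is None:
        raise ValueError("no revenue anchor available")
    _, rev = evaluate_baseline(scenario)
    return rev.total <= anchor


def _outcomes(result: ScenarioResult) -> Tuple[float, float, float]:
    return (
        result.policy_stats.total_units,
        result.policy_revenue.total,
        result.deaths_averted,
    )


def run_sensitivity(
    scenario: CountryScenario,
    target: PolicyTarget,
    grid: Optional[Sequence[SensitivitySpec]] = None,
    *,
    resolve_target: bool = True,
    bracket: Tuple[float, float] = (0.0, 50.0),
) -> List[SensitivityResult]:
    """Re-run the policy under each sensitivity spec and report % deltas.

    With ``resolve_target=True`` (default) each perturbed scenario re-solves
    the policy target, so the solved specific excise adapts to the
    perturbation; ``resolve_target=False`` freezes the main scenario's
    solved excise and only re-evaluates outcomes under it.  Per-spec solver
    failures are recorded on the result rather than raised.
    """
    if grid is None:
        grid = one_at_a_time_grid()

    s_main, main = solve_specific(scenario, target, bracket=bracket)
    main_outcomes = _outcomes(main)

    results: List[SensitivityResult] = []
    for spec in grid:
        kwargs = dict(
            cif_factor=spec.cif_factor,
            pass_through=spec.shift,
            elasticity_variant=spec.elasticity_variant,
        )
        try:
            if resolve_target:
                s_star, res = solve_specific(scenario, target, bracket=bracket, **kwargs)
            else:
                s_star = s_main
                res = evaluate_policy(
                    scenario,
                    s_main,
                    remove_ad_valorem=target.remove_ad_valorem,
                    on_negative_margin="warn",
                    **kwargs,
                )
        except (NoSolutionError, ValueError) as exc:
            results.append(
                SensitivityResult(
                    spec=spec,
                    consumption_delta=float("nan"),
                    revenue_delta=float("nan"),
                    deaths_delta=float("nan"),
                    error=str(exc),
                )
            )
            continue

        deltas = []
        for new, ref in zip(_outcomes(res), main_outcomes):
            deltas.append(100.0 * (new / ref - 1.0) if ref != 0 else float("nan"))
        results.append(
            SensitivityResult(
                spec=spec,
                consumption_delta=deltas[0],
                revenue_delta=deltas[1],
                deaths_delta=deltas[2],
                solved_specific=s_star,
            )
        )
    return results
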