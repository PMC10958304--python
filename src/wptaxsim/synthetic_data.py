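"""Synthetic country scenarios with realistic waterpipe-market structure.

The per-market-share survey inputs behind published country analyses
(prices, quantities and elasticities for each of the four segments) are
generally not public; only country-level aggregates are.  This module fills
the gap in two ways:

* :func:`generate` draws a random but structurally valid market: ordered
  prices (discount < premium within each location, café above home —
  café retail carries a large service margin, at least 60% of price by
  default), negative constant elasticities, Dirichlet share weights, and a
  tax structure guaranteed to leave every share a non-negative margin.

* :func:`anchor_fit` reconstructs a four-share market whose *aggregates*
  match a set of published country-level anchors (market-weighted price and
  tax burden, total units, and one revenue component) to within a stated
  tolerance, by constrained least squares over share prices and weights
  followed by a closed-form solve for the VAT and ad valorem rates.  The
  result is a synthetic stand-in: its aggregates are pinned, its per-share
  detail is not.

``ANCHORS`` holds published aggregate anchors for the three markets this
model was designed around (Jordan, Lebanon, Palestine/West Bank).  The
per-country elasticities there are single values implied by the published
aggregate price and consumption responses, used uniformly across shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .market_model import (
    LABELS,
    CountryScenario,
    ElasticityEstimate,
    MarketShare,
    TaxPolicy,
    downscale_illicit,
    effective_tax,
)
from .price_engine import InfeasiblePriceError, decompose
from .scenario_solver import evaluate_baseline

__all__ = [
    "SynthConfig",
    "AnchorTargets",
    "ANCHORS",
    "GenerationError",
    "AnchorFitError",
    "generate",
    "anchor_fit",
    "anchor_residuals",
]


class GenerationError(ValueError):
    """The configuration cannot yield a feasible market."""


class AnchorFitError(ValueError):
    """The anchor targets are mutually infeasible."""


_DEFAULT_PRICE_RANGES: Dict[str, Tuple[float, float]] = {
    "discount_home": (0.5, 1.2),
    "premium_home": (0.9, 3.0),
    "discount_cafe": (2.0, 5.0),
    "premium_cafe": (5.0, 9.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for :func:`generate`.

    Defaults describe an Eastern-Mediterranean-style waterpipe market: home
    prices around a dollar per 20 g, café prices several-fold higher with a
    service margin of at least ``cafe_margin_floor`` of the retail price,
    elasticities spanning very inelastic to elastic demand, and an illicit
    trade share between 5% and 30% of consumption.
    """

    seed: int = 0
    name: str = "synthetic"
    price_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PRICE_RANGES)
    )
    cafe_margin_floor: float = 0.60  # fraction of café retail price
    home_margin_floor: float = 0.02  # fraction of home retail price
    elasticity_range: Tuple[float, float] = (-2.0, -0.2)
    ci_rel_halfwidth: float = 0.25
    illicit_range: Tuple[float, float] = (0.05, 0.30)
    total_units_range: Tuple[float, float] = (50e6, 250e6)
    vat_range: Tuple[float, float] = (0.08, 0.20)
    specific_range: Tuple[float, float] = (0.0, 0.5)
    ad_valorem_range: Tuple[float, float] = (0.0, 0.30)
    import_duty_range: Tuple[float, float] = (0.0, 0.10)
    prevalence_range: Tuple[float, float] = (0.05, 0.40)
    adult_population_range: Tuple[float, float] = (2e6, 1e7)
    anchor_country: Optional[str] = None  # {"jordan", "lebanon", "palestine"}

    def __post_init__(self) -> None:
        for label in LABELS:
            lo, hi = self.price_ranges[label]
            if not (0 < lo <= hi):
                raise ValueError(f"invalid price range for {label}: ({lo}, {hi})")
        if not (0 <= self.cafe_margin_floor < 1):
            raise ValueError("cafe_margin_floor must be in [0, 1)")
        if not (self.elasticity_range[0] <= self.elasticity_range[1] < 0):
            raise ValueError("elasticity_range must be a negative interval")
        if self.anchor_country is not None and self.anchor_country not in ANCHORS:
            raise ValueError(
                f"anchor_country must be one of {sorted(ANCHORS)}, got {self.anchor_country!r}"
            )


@dataclass(frozen=True)
class AnchorTargets:
    """Published aggregate anchors for one country.

    ``vat_revenue`` or ``excise_revenue`` (exactly one) pins the split of
    the total tax take, from which the VAT and ad valorem rates are derived.
    ``price_anchors`` and ``unit_shares`` are per-label hints: unit shares
    listed here are held fixed, price anchors are soft targets.
    ``elasticity`` is a single own-price elasticity applied to every share.
    """

    name: str
    weighted_price: float  # USD per 20 g unit
    weighted_burden: float  # fraction of retail price
    total_units: float  # legal units/yr
    specific_excise: float  # baseline USD per unit
    vat_revenue: Optional[float] = None  # USD/yr
    excise_revenue: Optional[float] = None  # USD/yr
    price_anchors: Mapping[str, float] = field(default_factory=dict)
    unit_shares: Mapping[str, float] = field(default_factory=dict)
    import_duty_rate: float = 0.0
    fully_imported: bool = False
    cif_fraction: float = 0.15  # CIF as a fraction of the lowest retail price
    illicit_share: float = 0.0
    prevalence: float = 0.1
    adult_population: float = 1e6
    revenue_anchor: Optional[float] = None
    elasticity: float = -0.8
    elasticity_rel_halfwidth: float = 0.25

    def __post_init__(self) -> None:
        if (self.vat_revenue is None) == (self.excise_revenue is None):
            raise ValueError("exactly one of vat_revenue / excise_revenue must be given")
        fixed = sum(self.unit_shares.values())
        if fixed > 1 + 1e-9:
            raise ValueError(f"fixed unit shares sum to {fixed} > 1")
        for label in list(self.price_anchors) + list(self.unit_shares):
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r}")

    @classmethod
    def from_scenario(cls, scenario: CountryScenario) -> "AnchorTargets":
        """Targets equal to an existing scenario's own aggregates."""
        stats, rev = evaluate_baseline(scenario)
        prices = {s.label: s.retail_price for s in scenario.market_shares}
        shares = {
            s.label: s.annual_units / stats.total_units for s in scenario.market_shares
        }
        p_min = min(prices.values())
        eps = [s.elasticity.point for s in scenario.market_shares]
        return cls(
            name=scenario.name,
            weighted_price=stats.weighted_price,
            weighted_burden=stats.weighted_burden,
            total_units=stats.total_units,
            specific_excise=scenario.effective_tax().specific_excise,
            vat_revenue=rev.vat_rev,
            price_anchors=prices,
            unit_shares=shares,
            import_duty_rate=scenario.tax.import_duty_rate,
            fully_imported=scenario.fully_imported,
            cif_fraction=scenario.cif_price / p_min,
            illicit_share=scenario.illicit_share,
            prevalence=scenario.prevalence,
            adult_population=scenario.adult_population,
            revenue_anchor=scenario.revenue_anchor,
            elasticity=float(np.mean(eps)),
        )


# Published country-level aggregates used as fixture anchors; elasticities
# are the single values implied by each country's aggregate price and
# consumption response (Palestine very inelastic, Lebanon elastic).
ANCHORS: Dict[str, AnchorTargets] = {
    "jordan": AnchorTargets(
        name="jordan",
        weighted_price=3.43,
        weighted_burden=0.175,
        total_units=168.0e6,
        specific_excise=0.18,
        vat_revenue=69.7e6,
        price_anchors={"discount_home": 0.64, "premium_cafe": 7.38},
        unit_shares={"premium_home": 0.367, "premium_cafe": 0.377},
        import_duty_rate=0.0,
        fully_imported=False,
        cif_fraction=0.15,
        illicit_share=0.07,
        prevalence=0.110,
        adult_population=6.7e6,
        revenue_anchor=996e6,
        elasticity=-0.80,
    ),
    "lebanon": AnchorTargets(
        name="lebanon",
        weighted_price=3.82,
        weighted_burden=0.173,
        total_units=198.5e6,
        specific_excise=0.03,
        excise_revenue=61.9e6,
        price_anchors={"discount_home": 0.64, "premium_cafe": 7.92},
        unit_shares={"premium_home": 0.285, "premium_cafe": 0.414},
        import_duty_rate=0.05,
        fully_imported=True,
        cif_fraction=0.30,
        illicit_share=0.259,
        prevalence=0.395,
        adult_population=5.3e6,
        revenue_anchor=64e6,
        elasticity=-1.45,
    ),
    "palestine": AnchorTargets(
        name="palestine",
        weighted_price=5.34,
        weighted_burden=0.444,
        total_units=68.6e6,
        specific_excise=1.72,
        excise_revenue=118.1e6,
        price_anchors={
            "discount_home": 2.40,
            "premium_home": 5.00,
            "discount_cafe": 2.40,
            "premium_cafe": 7.62,
        },
        unit_shares={"discount_cafe": 0.481},
        import_duty_rate=0.0,
        fully_imported=False,
        cif_fraction=0.08,
        illicit_share=0.25,
        prevalence=0.129,
        adult_population=1.9e6,
        revenue_anchor=282e6,
        elasticity=-0.43,
    ),
}


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

def _ordered_price(rng, lo: float, hi: float, floor: float, what: str) -> float:
    lo = max(lo, floor)
    if lo >= hi:
        raise GenerationError(
            f"cannot draw {what} price above {floor:.3f} within range ({lo}, {hi})"
        )
    return float(rng.uniform(lo, hi))


def generate(config: SynthConfig) -> CountryScenario:
    """Generate one country scenario; deterministic given ``config.seed``.

    With ``anchor_country`` set, delegates to :func:`anchor_fit` on the
    stored published anchors for that country (a deterministic fit).
    """
    if config.anchor_country is not None:
        return anchor_fit(ANCHORS[config.anchor_country])

    rng = np.random.default_rng(config.seed)

    # ordered prices: discount < premium within location, cafe above home
    pr = config.price_ranges
    p_dh = float(rng.uniform(*pr["discount_home"]))
    p_ph = _ordered_price(rng, *pr["premium_home"], floor=p_dh * 1.05, what="premium_home")
    p_dc = _ordered_price(rng, *pr["discount_cafe"], floor=p_ph * 1.05, what="discount_cafe")
    p_pc = _ordered_price(rng, *pr["premium_cafe"], floor=p_dc * 1.05, what="premium_cafe")
    prices = dict(zip(LABELS, (p_dh, p_ph, p_dc, p_pc)))

    vat = float(rng.uniform(*config.vat_range))
    specific = float(rng.uniform(*config.specific_range))
    ad_valorem = float(rng.uniform(*config.ad_valorem_range))
    duty = float(rng.uniform(*config.import_duty_range))
    fully_imported = bool(rng.random() < 0.5)
    duty_eff = duty if fully_imported else 0.0

    # CIF bounded so every share keeps its margin floor:
    # margin = p/(1+v) - cif*(1+d)*(1+a) - specific >= floor_frac * p
    cif_caps = []
    for label, p in prices.items():
        floor_frac = config.cafe_margin_floor if label.endswith("cafe") else config.home_margin_floor
        cap = (p / (1 + vat) - specific - floor_frac * p) / ((1 + duty_eff) * (1 + ad_valorem))
        cif_caps.append((cap, label))
    cap, binding = min(cif_caps)
    if cap <= 0:
        raise GenerationError(
            f"tax structure forces a negative margin in share {binding!r} "
            f"(specific={specific:.3f}, vat={vat:.3f})"
        )
    cif = cap * float(rng.uniform(0.3, 0.9))

    weights = rng.dirichlet(np.full(4, 2.0))
    total = float(rng.uniform(*config.total_units_range))
    illicit = float(rng.uniform(*config.illicit_range))
    legal_total = downscale_illicit(total, illicit)

    lo_e, hi_e = config.elasticity_range
    shares = tuple(
        MarketShare(
            label=label,
            retail_price=prices[label],
            annual_units=float(w) * legal_total,
            elasticity=ElasticityEstimate.symmetric(
                float(rng.uniform(lo_e, hi_e)), config.ci_rel_halfwidth
            ),
        )
        for label, w in zip(LABELS, weights)
    )

    scenario = CountryScenario(
        name=f"{config.name}-{config.seed}",
        market_shares=shares,
        tax=TaxPolicy(
            import_duty_rate=duty,
            specific_excise=specific,
            ad_valorem_rate=ad_valorem,
            vat_rate=vat,
        ),
        cif_price=cif,
        illicit_share=illicit,
        prevalence=float(rng.uniform(*config.prevalence_range)),
        adult_population=float(rng.uniform(*config.adult_population_range)),
        fully_imported=fully_imported,
    )
    # every generated scenario must admit a feasible decomposition
    for s in scenario.market_shares:
        decompose(s.retail_price, cif, scenario.effective_tax(), label=s.label)
    return scenario


# ---------------------------------------------------------------------------
# anchored fitting
# ---------------------------------------------------------------------------

_WPRICE_WEIGHT = 50.0  # the weighted-price anchor is hard; price hints are soft


def _fit_prices_weights(t: AnchorTargets) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Share prices and unit-share weights matching the weighted price.

    Prices are parametrised with positive increments enforcing the
    within-location orderings (discount < premium); weights not fixed by the
    targets share the residual mass through a softmax.  The market-weighted
    price is a heavily weighted residual; per-label price anchors are soft.
    """
    free_labels = [l for l in LABELS if l not in t.unit_shares]
    residual_mass = 1.0 - sum(t.unit_shares.values())
    if free_labels and residual_mass <= 0:
        raise AnchorFitError("fixed unit shares leave no mass for the free labels")
    if not free_labels and abs(residual_mass) > 1e-6:
        raise AnchorFitError("fixed unit shares do not sum to 1")

    n_logit = len(free_labels)

    def unpack(x):
        p_dh = math.exp(x[0])
        p_ph = p_dh + math.exp(x[1])
        p_dc = math.exp(x[2])
        p_pc = p_dc + math.exp(x[3])
        prices = dict(zip(LABELS, (p_dh, p_ph, p_dc, p_pc)))
        weights = dict(t.unit_shares)
        if n_logit:
            logits = np.asarray(x[4:4 + n_logit], dtype=float)
            soft = np.exp(logits - logits.max())
            soft = soft / soft.sum() * residual_mass
            weights.update(dict(zip(free_labels, soft)))
        return prices, weights

    def residuals(x):
        prices, weights = unpack(x)
        wprice = sum(prices[l] * weights[l] for l in LABELS)
        res = [_WPRICE_WEIGHT * (wprice / t.weighted_price - 1.0)]
        for label, anchor in t.price_anchors.items():
            res.append(prices[label] / anchor - 1.0)
        if n_logit:
            res.extend(0.01 * np.asarray(x[4:4 + n_logit]))
        return np.asarray(res)

    # start from the price anchors where given, mid-market otherwise
    p0 = {
        "discount_home": t.price_anchors.get("discount_home", 0.3 * t.weighted_price),
        "premium_cafe": t.price_anchors.get("premium_cafe", 2.0 * t.weighted_price),
    }
    p0["premium_home"] = t.price_anchors.get("premium_home", 1.8 * p0["discount_home"])
    p0["discount_cafe"] = t.price_anchors.get("discount_cafe", 0.6 * p0["premium_cafe"])
    x0 = [
        math.log(p0["discount_home"]),
        math.log(max(p0["premium_home"] - p0["discount_home"], 1e-3)),
        math.log(p0["discount_cafe"]),
        math.log(max(p0["premium_cafe"] - p0["discount_cafe"], 1e-3)),
    ] + [0.0] * n_logit

    sol = least_squares(residuals, x0, method="trf", max_nfev=5000)
    prices, weights = unpack(sol.x)

    wprice = sum(prices[l] * weights[l] for l in LABELS)
    if abs(wprice / t.weighted_price - 1.0) > 1e-4:
        raise AnchorFitError(
            f"cannot match weighted price {t.weighted_price} with the given "
            f"price/share constraints (best: {wprice:.4f})"
        )
    return prices, weights


def anchor_fit(t: AnchorTargets, tol: float = 0.01) -> CountryScenario:
    """Build a synthetic scenario whose aggregates match published anchors.

    Share prices and weights come from a constrained least-squares fit to
    the market-weighted price (with soft per-label price hints); the VAT and
    ad valorem rates are then solved in closed form so the total tax take
    equals ``weighted_burden x expenditure`` and the given revenue component
    (VAT or excise) matches exactly.  Verifies every hard target to within
    ``tol`` (relative) and raises :class:`AnchorFitError` naming the first
    violated constraint otherwise.
    """
    prices, weights = _fit_prices_weights(t)
    quantities = {l: weights[l] * t.total_units for l in LABELS}

    expenditure = sum(prices[l] * quantities[l] for l in LABELS)
    tax_total = t.weighted_burden * expenditure
    specific_rev = t.specific_excise * t.total_units

    p_min = min(prices.values())
    duty_applies = t.fully_imported and t.import_duty_rate > 0

    last_err: Optional[str] = None
    for shrink in (1.0, 0.5, 0.25, 0.125):
        cif = t.cif_fraction * p_min * shrink
        duty_per_unit = t.import_duty_rate * cif if duty_applies else 0.0
        duty_rev = duty_per_unit * t.total_units

        if t.vat_revenue is not None:
            vat_rev = t.vat_revenue
            adval_rev = tax_total - specific_rev - vat_rev - duty_rev
        else:
            adval_rev = t.excise_revenue - specific_rev
            vat_rev = tax_total - t.excise_revenue - duty_rev

        if adval_rev < -tol * tax_total or vat_rev < -tol * tax_total:
            raise AnchorFitError(
                f"revenue split infeasible: implied ad valorem revenue "
                f"{adval_rev:.3g}, VAT revenue {vat_rev:.3g}"
            )
        adval_rev = max(adval_rev, 0.0)
        vat_rev = max(vat_rev, 0.0)

        vat_frac = vat_rev / expenditure  # v / (1 + v)
        if vat_frac >= 0.5:
            raise AnchorFitError(f"implied VAT rate >= 100% (v/(1+v) = {vat_frac:.3f})")
        vat_rate = vat_frac / (1.0 - vat_frac)
        adval_base = cif + duty_per_unit
        adval_rate = adval_rev / (t.total_units * adval_base) if adval_base > 0 else 0.0

        tax = TaxPolicy(
            import_duty_rate=t.import_duty_rate,
            specific_excise=t.specific_excise,
            ad_valorem_rate=adval_rate,
            vat_rate=vat_rate,
        )
        # feasibility check on every share; shrink CIF if one fails
        eff = effective_tax(tax, t.fully_imported)
        try:
            for label in LABELS:
                decompose(prices[label], cif, eff, label=label)
        except InfeasiblePriceError as exc:
            last_err = str(exc)
            continue
        break
    else:
        raise AnchorFitError(f"no feasible CIF found: {last_err}")

    elasticity = ElasticityEstimate.symmetric(t.elasticity, t.elasticity_rel_halfwidth)
    shares = tuple(
        MarketShare(
            label=label,
            retail_price=prices[label],
            annual_units=quantities[label],
            elasticity=elasticity,
        )
        for label in LABELS
    )
    scenario = CountryScenario(
        name=t.name,
        market_shares=shares,
        tax=tax,
        cif_price=cif,
        illicit_share=t.illicit_share,
        prevalence=t.prevalence,
        adult_population=t.adult_population,
        fully_imported=t.fully_imported,
        revenue_anchor=t.revenue_anchor,
    )

    residuals = anchor_residuals(scenario, t)
    for name, rel in residuals.items():
        if abs(rel) > tol:
            raise AnchorFitError(
                f"fitted scenario misses target {name!r} by {100 * rel:.2f}%"
            )
    return scenario


def anchor_residuals(scenario: CountryScenario, t: AnchorTargets) -> Dict[str, float]:
    """Relative residuals of the scenario's aggregates vs the hard targets."""
    stats, rev = evaluate_baseline(scenario)
    res = {
        "weighted_price": stats.weighted_price / t.weighted_price - 1.0,
        "weighted_burden": stats.weighted_burden / t.weighted_burden - 1.0,
        "total_units": stats.total_units / t.total_units - 1.0,
    }
    if t.vat_revenue is not None:
        res["vat_revenue"] = rev.vat_rev / t.vat_revenue - 1.0
    else:
        res["excise_revenue"] = rev.excise / t.excise_revenue - 1.0
    return res
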