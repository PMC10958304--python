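"""Domain types for a national waterpipe-tobacco market.

A country's market is split into four price/consumption segments ("market
shares") defined by smoking location (home vs café) and price tier (discount
vs premium, split at the median price within each location).  Each segment
carries a retail price per 20 g unit of tobacco (one waterpipe "head"), an
annual number of units consumed, and an own-price elasticity of demand.

Quantities stored on a :class:`CountryScenario` are *legal* (taxed)
quantities: consumption estimated from household surveys captures both licit
and illicit purchases, so survey-derived totals are downscaled once, at
scenario construction, by the illicit-trade share.  The same quantities then
feed both revenue and consumption outputs, keeping the two mutually
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

__all__ = [
    "LABELS",
    "TaxPolicy",
    "ElasticityEstimate",
    "MarketShare",
    "CountryScenario",
    "ConsumptionInputs",
    "annual_consumption",
    "downscale_illicit",
    "effective_tax",
]

#: Canonical market-share labels, in conventional order.
LABELS: Tuple[str, str, str, str] = (
    "discount_home",
    "premium_home",
    "discount_cafe",
    "premium_cafe",
)


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class TaxPolicy:
    """A country's indirect-tax rates on waterpipe tobacco.

    The tax-base chain is: import duty on the CIF price; specific excise per
    20 g unit; ad valorem excise on (CIF + import duty); VAT on the full
    pre-VAT price (CIF + duty + excises + industry margin).

    Parameters
    ----------
    import_duty_rate : float
        Fraction of the CIF price (e.g. ``0.05`` for 5%).
    specific_excise : float
        USD per 20 g unit.
    ad_valorem_rate : float
        Fraction of (CIF + import duty).
    vat_rate : float
        Fraction of the pre-VAT price; must be below 1.
    """

    import_duty_rate: float = 0.0
    specific_excise: float = 0.0
    ad_valorem_rate: float = 0.0
    vat_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("import_duty_rate", "specific_excise", "ad_valorem_rate", "vat_rate"):
            value = getattr(self, name)
            _require_finite(name, value)
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.vat_rate >= 1:
            raise ValueError(f"vat_rate must be < 1, got {self.vat_rate}")

    def with_specific(self, specific_excise: float) -> "TaxPolicy":
        """Return a copy with a different specific excise."""
        return replace(self, specific_excise=specific_excise)

    def without_ad_valorem(self) -> "TaxPolicy":
        """Return a copy with the ad valorem excise removed."""
        return replace(self, ad_valorem_rate=0.0)


def effective_tax(tax: TaxPolicy, fully_imported: bool) -> TaxPolicy:
    """Tax policy as it applies to a market.

    Import duty is only collected on imported product; for a country whose
    waterpipe market is not (fully) imported the duty rate is dropped.
    """
    if fully_imported:
        return tax
    return replace(tax, import_duty_rate=0.0)


@dataclass(frozen=True)
class ElasticityEstimate:
    """Own-price elasticity of demand with its 95% CI.

    Point estimates for waterpipe tobacco are negative (demand falls when
    price rises); ``ci_low`` is the more negative bound.
    """

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        for name in ("point", "ci_low", "ci_high"):
            _require_finite(name, getattr(self, name))
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"require ci_low <= point <= ci_high, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )

    @classmethod
    def symmetric(cls, point: float, rel_halfwidth: float = 0.25) -> "ElasticityEstimate":
        """CI as a symmetric relative band around the point estimate."""
        hw = abs(point) * rel_halfwidth
        return cls(point=point, ci_low=point - hw, ci_high=point + hw)

    def value(self, variant: str = "point") -> float:
        """Select the point estimate or a CI bound.

        ``"low"`` is the lower (more negative) bound, ``"high"`` the upper.
        """
        if variant == "point":
            return self.point
        if variant == "low":
            return self.ci_low
        if variant == "high":
            return self.ci_high
        raise ValueError(f"unknown elasticity variant {variant!r}")


@dataclass(frozen=True)
class MarketShare:
    """One of the four price/consumption segments of a country's market."""

    label: str
    retail_price: float  # USD per 20 g unit
    annual_units: float  # 20 g units per year (legal consumption)
    elasticity: ElasticityEstimate

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        _require_finite("retail_price", self.retail_price)
        _require_finite("annual_units", self.annual_units)
        if self.retail_price <= 0:
            raise ValueError(f"retail_price must be > 0, got {self.retail_price}")
        if self.annual_units < 0:
            raise ValueError(f"annual_units must be >= 0, got {self.annual_units}")


@dataclass(frozen=True)
class CountryScenario:
    """Baseline description of one country's waterpipe-tobacco market.

    ``market_shares`` must contain exactly four records with distinct labels.
    Quantities are legal (taxed) consumption; ``illicit_share`` records the
    fraction of total consumption that escaped taxation and was removed
    before construction (see :func:`downscale_illicit`).
    """

    name: str
    market_shares: Tuple[MarketShare, ...]
    tax: TaxPolicy
    cif_price: float  # USD per 20 g; assumed equal to the ex-factory price
    illicit_share: float = 0.0
    prevalence: float = 0.1
    adult_population: float = 1_000_000.0
    fully_imported: bool = True
    revenue_anchor: Optional[float] = None  # USD/yr reported tobacco tax revenue

    def __post_init__(self) -> None:
        shares = tuple(self.market_shares)
        object.__setattr__(self, "market_shares", shares)
        if len(shares) != 4:
            raise ValueError(f"expected exactly 4 market shares, got {len(shares)}")
        labels = [s.label for s in shares]
        if len(set(labels)) != 4:
            raise ValueError(f"market share labels must be distinct, got {labels}")
        _require_finite("cif_price", self.cif_price)
        if self.cif_price < 0:
            raise ValueError("cif_price must be >= 0")
        if not (0 <= self.illicit_share < 1):
            raise ValueError(f"illicit_share must be in [0, 1), got {self.illicit_share}")
        if not (0 < self.prevalence < 1):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.adult_population <= 0:
            raise ValueError("adult_population must be > 0")
        if self.revenue_anchor is not None and self.revenue_anchor <= 0:
            raise ValueError("revenue_anchor must be > 0 when given")

    # -- derived quantities ------------------------------------------------

    @property
    def smokers(self) -> float:
        """Current waterpipe smokers: prevalence x adult (15+) population."""
        return self.prevalence * self.adult_population

    @property
    def total_units(self) -> float:
        """Total legal annual consumption across shares, 20 g units."""
        return sum(s.annual_units for s in self.market_shares)

    def share(self, label: str) -> MarketShare:
        for s in self.market_shares:
            if s.label == label:
                return s
        raise KeyError(label)

    def effective_tax(self) -> TaxPolicy:
        return effective_tax(self.tax, self.fully_imported)

    def scale_quantities(self, factor: float) -> "CountryScenario":
        """Multiply every share's annual units by ``factor``."""
        if factor <= 0:
            raise ValueError("factor must be > 0")
        shares = tuple(replace(s, annual_units=s.annual_units * factor) for s in self.market_shares)
        return replace(self, market_shares=shares)


@dataclass(frozen=True)
class ConsumptionInputs:
    """Survey-style inputs for building national annual consumption."""

    sessions_per_day: float  # mean waterpipe sessions per day among smokers
    heads_per_session: float  # mean 20 g servings per session
    prevalence: float
    adult_population: float

    def __post_init__(self) -> None:
        for name in ("sessions_per_day", "heads_per_session", "prevalence", "adult_population"):
            value = getattr(self, name)
            _require_finite(name, value)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")


def annual_consumption(c: ConsumptionInputs, days_per_year: float = 365) -> float:
    """Country-level annual number of 20 g waterpipe units smoked.

    The product sessions/day x heads/session x prevalence x adult population
    x days/year.  Multilinear in every argument.
    """
    if days_per_year <= 0:
        raise ValueError(f"days_per_year must be > 0, got {days_per_year}")
    return (
        c.sessions_per_day
        * c.heads_per_session
        * c.prevalence
        * c.adult_population
        * days_per_year
    )


def downscale_illicit(q: float, illicit_share: float) -> float:
    """Remove the untaxed (illicit) fraction from a consumption estimate.

    Survey-based consumption captures both legal and illicit purchases;
    revenue accounting must only see the taxed share, so estimates are
    scaled by ``1 - illicit_share``.
    """
    if not (0 <= illicit_share < 1):
        raise ValueError(f"illicit_share must be in [0, 1), got {illicit_share}")
    if q < 0:
        raise ValueError(f"quantity must be >= 0, got {q}")
    return q * (1.0 - illicit_share)
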