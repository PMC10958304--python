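"""Aggregation of per-market-share decompositions into revenue and
market-weighted statistics.

Government revenue by tax component is the per-unit component times annual
legal units, summed over market shares.  The market-weighted tax burden is
defined as the total tax take over total retail expenditure (expenditure
weighting), which makes the burden and the revenue mutually consistent:
``burden * expenditure == revenue.total`` exactly.  The market-weighted
average price uses quantity weights (the average price per unit sold) by
default, with expenditure weighting available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .price_engine import PriceDecomposition

__all__ = ["RevenueBreakdown", "AggregateStats", "revenue", "weighted_stats"]

ShareEntry = Tuple[PriceDecomposition, float]  # (decomposition, annual units)


@dataclass(frozen=True)
class RevenueBreakdown:
    """Annual government revenue by tax component, USD/yr."""

    import_duty_rev: float
    specific_rev: float
    ad_valorem_rev: float
    vat_rev: float

    @property
    def excise(self) -> float:
        """Excise-only take (specific + ad valorem), USD/yr."""
        return self.specific_rev + self.ad_valorem_rev

    @property
    def total(self) -> float:
        return self.import_duty_rev + self.specific_rev + self.ad_valorem_rev + self.vat_rev


@dataclass(frozen=True)
class AggregateStats:
    """Market-weighted aggregates over the four shares."""

    weighted_price: float  # USD per 20 g unit
    weighted_burden: float  # fraction of retail price
    total_units: float  # units/yr
    total_expenditure: float  # USD/yr

    def __post_init__(self) -> None:
        if not (0 <= self.weighted_burden < 1):
            raise ValueError(f"weighted_burden must be in [0, 1), got {self.weighted_burden}")


def revenue(shares: Sequence[ShareEntry]) -> RevenueBreakdown:
    """Revenue by component: per-unit components x units, summed over shares."""
    duty = spec = adval = vat = 0.0
    for p, units in shares:
        if units < 0:
            raise ValueError(f"units must be >= 0, got {units}")
        duty += p.import_duty * units
        spec += p.specific * units
        adval += p.ad_valorem * units
        vat += p.vat * units
    return RevenueBreakdown(
        import_duty_rev=duty, specific_rev=spec, ad_valorem_rev=adval, vat_rev=vat
    )


def weighted_stats(
    shares: Sequence[ShareEntry], *, price_weighting: str = "quantity"
) -> AggregateStats:
    """Market-weighted price and burden over the shares.

    ``weighted_price`` uses quantity weights ``w_m = units_m / total_units``
    by default (``price_weighting="expenditure"`` weights by retail
    expenditure instead).  ``weighted_burden`` is total tax revenue over
    total retail expenditure.
    """
    total_units = sum(units for _, units in shares)
    if total_units <= 0:
        raise ValueError("total units must be > 0 to compute weighted statistics")
    expenditure = sum(p.retail * units for p, units in shares)
    tax_take = sum(p.total_tax * units for p, units in shares)

    if price_weighting == "quantity":
        weighted_price = expenditure / total_units
    elif price_weighting == "expenditure":
        weighted_price = sum(p.retail**2 * units for p, units in shares) / expenditure
    else:
        raise ValueError(f"unknown price_weighting {price_weighting!r}")

    return AggregateStats(
        weighted_price=weighted_price,
        weighted_burden=tax_take / expenditure,
        total_units=total_units,
        total_expenditure=expenditure,
    )
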