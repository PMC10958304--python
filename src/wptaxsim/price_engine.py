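"""Retail-price decomposition and recomposition under the indirect-tax chain.

A retail price of 20 g of waterpipe tobacco is split into six additive
components: CIF (ex-factory) price, import duty, specific excise, ad valorem
excise, VAT, and industry margin.  The tax bases are:

* import duty ``= d * cif``
* specific excise: a fixed USD amount per unit
* ad valorem excise ``= a * (cif + duty)``
* VAT ``= v * B`` where ``B = retail / (1 + v)`` is the pre-VAT price
* margin ``= B - cif - duty - specific - ad_valorem`` (the residual)

A policy change is evaluated by holding CIF and margin fixed (constant
production costs, full pass-through of the tax to the consumer) and
recomputing the tax components, optionally scaling the induced retail-price
change to model industry over- or undershifting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .market_model import TaxPolicy

__all__ = [
    "PriceDecomposition",
    "InfeasiblePriceError",
    "NegativeMarginWarning",
    "decompose",
    "recompose",
    "tax_burden",
]

#: Absolute tolerance (USD) for the additive identity of a decomposition.
ADDITIVE_TOL = 1e-9


class InfeasiblePriceError(ValueError):
    """The retail price cannot cover CIF plus taxes (negative margin)."""


class NegativeMarginWarning(UserWarning):
    """A swept tax level exceeds what the current retail price can absorb."""


@dataclass(frozen=True)
class PriceDecomposition:
    """The six additive components of one retail price, USD per 20 g unit."""

    cif: float
    import_duty: float
    specific: float
    ad_valorem: float
    vat: float
    margin: float
    retail: float

    def __post_init__(self) -> None:
        total = self.cif + self.import_duty + self.specific + self.ad_valorem + self.vat + self.margin
        if not math.isclose(total, self.retail, abs_tol=1e-6, rel_tol=1e-9):
            raise ValueError(
                f"components sum to {total!r}, not retail {self.retail!r}"
            )

    @property
    def total_tax(self) -> float:
        """Sum of all per-unit indirect taxes, USD."""
        return self.import_duty + self.specific + self.ad_valorem + self.vat

    @property
    def excise(self) -> float:
        """Per-unit excise take (specific + ad valorem), USD."""
        return self.specific + self.ad_valorem


def decompose(
    retail_price: float,
    cif: float,
    tax: TaxPolicy,
    *,
    label: str | None = None,
    on_negative_margin: str = "raise",
) -> PriceDecomposition:
    """Split a retail price into its six components under a tax policy.

    Parameters
    ----------
    retail_price : float
        Observed retail price, USD per 20 g unit; must be positive.
    cif : float
        CIF / ex-factory price, USD per unit.
    tax : TaxPolicy
        The rates and their bases (see module docstring).
    label : str, optional
        Market-share label used in diagnostics.
    on_negative_margin : {"raise", "warn"}
        A negative residual margin signals a price below tax-inclusive cost.
        ``"raise"`` (the default, for baseline construction) raises
        :class:`InfeasiblePriceError`; ``"warn"`` (for tax sweeps) emits a
        :class:`NegativeMarginWarning` and keeps the negative margin so the
        additive identity still holds.
    """
    if retail_price <= 0:
        raise ValueError(f"retail_price must be > 0, got {retail_price}")
    if cif < 0:
        raise ValueError(f"cif must be >= 0, got {cif}")

    duty = tax.import_duty_rate * cif
    ad_valorem = tax.ad_valorem_rate * (cif + duty)
    pre_vat = retail_price / (1.0 + tax.vat_rate)
    vat = retail_price - pre_vat
    margin = pre_vat - cif - duty - tax.specific_excise - ad_valorem

    if margin < -ADDITIVE_TOL:
        where = f" in share {label!r}" if label else ""
        msg = (
            f"retail price {retail_price:.4f}{where} is below tax-inclusive cost: "
            f"margin would be {margin:.4f} USD"
        )
        if on_negative_margin == "raise":
            raise InfeasiblePriceError(msg)
        elif on_negative_margin == "warn":
            warnings.warn(msg, NegativeMarginWarning, stacklevel=2)
        else:
            raise ValueError(f"unknown on_negative_margin={on_negative_margin!r}")

    return PriceDecomposition(
        cif=cif,
        import_duty=duty,
        specific=tax.specific_excise,
        ad_valorem=ad_valorem,
        vat=vat,
        margin=margin,
        retail=retail_price,
    )


def recompose(
    base: PriceDecomposition,
    new_tax: TaxPolicy,
    pass_through: float = 1.0,
    *,
    label: str | None = None,
    on_negative_margin: str = "raise",
) -> PriceDecomposition:
    """New retail price after a tax change, with CIF and margin held fixed.

    With full pass-through the new price is

    ``R* = (1 + v) * (cif + duty + specific + ad_valorem + margin)``

    evaluated under ``new_tax``.  ``pass_through`` scales the retail-price
    *change*: the shifted price is ``base.retail + s * (R* - base.retail)``
    (``s = 1`` is full pass-through; ``s = 1.1`` a 10% overshift, ``s = 0.9``
    a 10% undershift).  The returned VAT and margin are re-derived from the
    shifted retail price so the additive identity holds exactly; under over-
    or undershifting the residual margin therefore differs from ``base.margin``.
    """
    if pass_through <= 0:
        raise ValueError(f"pass_through must be > 0, got {pass_through}")

    cif = base.cif
    duty = new_tax.import_duty_rate * cif
    ad_valorem = new_tax.ad_valorem_rate * (cif + duty)
    full = (1.0 + new_tax.vat_rate) * (
        cif + duty + new_tax.specific_excise + ad_valorem + base.margin
    )
    retail = base.retail + pass_through * (full - base.retail)
    if retail <= 0:
        raise InfeasiblePriceError(
            f"recomposed retail price is non-positive ({retail:.4f} USD)"
        )
    return decompose(
        retail, cif, new_tax, label=label, on_negative_margin=on_negative_margin
    )


def tax_burden(p: PriceDecomposition) -> float:
    """Total indirect taxes as a fraction of the retail price."""
    return p.total_tax / p.retail
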