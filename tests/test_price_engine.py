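import math

import pytest
from hypothesis import given, settings, strategies as st

from wptaxsim.market_model import TaxPolicy
from wptaxsim.price_engine import (
    ADDITIVE_TOL,
    InfeasiblePriceError,
    NegativeMarginWarning,
    decompose,
    recompose,
    tax_burden,
)


def components(p):
    return (p.cif, p.import_duty, p.specific, p.ad_valorem, p.vat, p.margin)


class TestDecompose:
    def test_zero_tax_identity(self):
        p = decompose(1.0, 1.0, TaxPolicy())
        assert p.import_duty == p.specific == p.ad_valorem == p.vat == 0.0
        assert p.margin == pytest.approx(0.0, abs=ADDITIVE_TOL)

    def test_worked_example_against_symbolic_solution(self):
        """Cross-check the tax-base chain against an independent sympy solve."""
        sympy = pytest.importorskip("sympy")
        retail, cif, d, s, a, v = 2.0, 0.5, 0.1, 0.2, 0.2, 0.1

        duty, adval, vat, margin = sympy.symbols("duty adval vat margin")
        B = sympy.Rational(2) / (1 + sympy.Rational(1, 10))
        sol = sympy.solve(
            [
                duty - sympy.Rational(1, 10) * sympy.Rational(1, 2),
                adval - sympy.Rational(1, 5) * (sympy.Rational(1, 2) + duty),
                vat - (2 - B),
                margin - (B - sympy.Rational(1, 2) - duty - sympy.Rational(1, 5) - adval),
            ],
            [duty, adval, vat, margin],
        )

        p = decompose(retail, cif, TaxPolicy(d, s, a, v))
        assert p.import_duty == pytest.approx(float(sol[duty]))  # 0.05
        assert p.ad_valorem == pytest.approx(float(sol[adval]))  # 0.11
        assert p.vat == pytest.approx(float(sol[vat]))  # 0.181818...
        assert p.margin == pytest.approx(float(sol[margin]))  # 0.958181...
        assert sum(components(p)) == pytest.approx(2.0, abs=ADDITIVE_TOL)

    def test_negative_margin_raises_and_names_share(self):
        with pytest.raises(InfeasiblePriceError, match="premium_cafe"):
            decompose(0.3, 0.5, TaxPolicy(), label="premium_cafe")

    def test_negative_margin_warns_when_sweeping(self):
        with pytest.warns(NegativeMarginWarning):
            p = decompose(0.3, 0.5, TaxPolicy(), on_negative_margin="warn")
        assert p.margin < 0
        assert sum(components(p)) == pytest.approx(0.3, abs=ADDITIVE_TOL)

    @given(
        retail=st.floats(0.5, 50),
        cif_frac=st.floats(0.0, 0.3),
        d=st.floats(0, 0.5),
        s_frac=st.floats(0, 0.3),
        a=st.floats(0, 0.5),
        v=st.floats(0, 0.4),
    )
    def test_additive_identity(self, retail, cif_frac, d, s_frac, a, v):
        """Components of every decomposition sum to retail within 1e-9 USD."""
        tax = TaxPolicy(d, s_frac * retail, a, v)
        p = decompose(retail, cif_frac * retail, tax, on_negative_margin="warn")
        assert abs(sum(components(p)) - retail) < ADDITIVE_TOL


class TestRecompose:
    @given(
        retail=st.floats(1.0, 20),
        cif=st.floats(0.01, 0.25),
        d=st.floats(0, 0.2),
        s=st.floats(0, 0.2),
        a=st.floats(0, 0.3),
        v=st.floats(0, 0.3),
    )
    def test_round_trip_with_identical_tax(self, retail, cif, d, s, a, v):
        tax = TaxPolicy(d, s, a, v)
        base = decompose(retail, cif, tax, on_negative_margin="warn")
        again = recompose(base, tax, 1.0, on_negative_margin="warn")
        for x, y in zip(components(base), components(again)):
            assert x == pytest.approx(y, abs=1e-9)
        assert again.retail == pytest.approx(retail, abs=1e-9)

    def test_larger_specific_raises_retail_and_burden(self):
        tax = TaxPolicy(0.05, 0.2, 0.1, 0.15)
        base = decompose(3.0, 0.4, tax)
        prev_retail, prev_burden = base.retail, tax_burden(base)
        for s in (0.3, 0.5, 1.0, 2.0):
            new = recompose(base, tax.with_specific(s))
            assert new.retail > prev_retail
            assert tax_burden(new) > prev_burden
            prev_retail, prev_burden = new.retail, tax_burden(new)

    def test_margin_and_cif_held_fixed_under_full_pass_through(self):
        tax = TaxPolicy(0.05, 0.2, 0.1, 0.15)
        base = decompose(3.0, 0.4, tax)
        new = recompose(base, tax.with_specific(1.5))
        assert new.margin == pytest.approx(base.margin, abs=1e-9)
        assert new.cif == base.cif

    def test_pass_through_scales_the_retail_change(self):
        tax = TaxPolicy(0.0, 0.1, 0.0, 0.2)
        base = decompose(4.0, 0.5, tax)
        new_tax = tax.with_specific(1.0)
        full = recompose(base, new_tax, 1.0)
        for s in (0.9, 1.1):
            shifted = recompose(base, new_tax, s)
            assert shifted.retail - base.retail == pytest.approx(
                s * (full.retail - base.retail), rel=1e-12
            )

    def test_rejects_non_positive_pass_through(self):
        base = decompose(2.0, 0.5, TaxPolicy())
        with pytest.raises(ValueError):
            recompose(base, TaxPolicy(), 0.0)


class TestTaxBurden:
    def test_zero_tax_burden_is_zero(self):
        assert tax_burden(decompose(1.0, 0.5, TaxPolicy())) == 0.0

    def test_vat_only_burden_is_v_over_one_plus_v(self):
        v = 0.16
        p = decompose(5.0, 0.5, TaxPolicy(vat_rate=v))
        assert tax_burden(p) == pytest.approx(v / (1 + v), rel=1e-12)

    @given(retail=st.floats(0.5, 30), v=st.floats(0, 0.5))
    def test_burden_in_unit_interval(self, retail, v):
        p = decompose(retail, 0.1, TaxPolicy(vat_rate=v, specific_excise=0.05),
                      on_negative_margin="warn")
        assert 0 <= tax_burden(p) < 1
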