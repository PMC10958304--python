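import pytest

from wptaxsim.market_model import (
    CountryScenario,
    ElasticityEstimate,
    MarketShare,
    TaxPolicy,
)
from wptaxsim.synthetic_data import ANCHORS, anchor_fit


def build_scenario(
    prices=(1.0, 2.0, 4.0, 8.0),
    units=(40e6, 30e6, 20e6, 10e6),
    elasticities=(-0.5, -0.8, -1.2, -1.5),
    tax=None,
    cif=0.3,
    name="toy",
    **kwargs,
):
    """Small four-share market with hand-readable numbers."""
    labels = ("discount_home", "premium_home", "discount_cafe", "premium_cafe")
    if tax is None:
        tax = TaxPolicy(import_duty_rate=0.05, specific_excise=0.2,
                        ad_valorem_rate=0.1, vat_rate=0.1)
    shares = tuple(
        MarketShare(
            label=l,
            retail_price=p,
            annual_units=q,
            elasticity=ElasticityEstimate.symmetric(e) if e != 0
            else ElasticityEstimate(0.0, 0.0, 0.0),
        )
        for l, p, q, e in zip(labels, prices, units, elasticities)
    )
    kwargs.setdefault("prevalence", 0.2)
    kwargs.setdefault("adult_population", 5e6)
    return CountryScenario(
        name=name, market_shares=shares, tax=tax, cif_price=cif, **kwargs
    )


@pytest.fixture
def toy_scenario():
    return build_scenario()


@pytest.fixture(scope="session")
def jordan():
    return anchor_fit(ANCHORS["jordan"])


@pytest.fixture(scope="session")
def lebanon():
    return anchor_fit(ANCHORS["lebanon"])


@pytest.fixture(scope="session")
def palestine():
    return anchor_fit(ANCHORS["palestine"])
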