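import pytest

from itnvalue.records import (
    CountryProfile,
    DistributionSpec,
    FibreType,
    NetType,
    Region,
    TransactionRecord,
)


@pytest.fixture
def rec():
    """Factory for transaction records with sensible defaults."""

    def make(**kw) -> TransactionRecord:
        defaults = dict(
            year=2018,
            supplier="Acme",
            brand="Acme-B1",
            buyer="GLOBAL_FUND",
            unit_price_nominal=2.0,
            quantity=1_000_000,
            net_type=NetType.PYRETHROID,
            fibre_type=FibreType.POLYESTER,
            area_m2=15.0,
            region=Region.SSA,
            oil_price_nominal=60.0,
            unit_price_real=2.0,
            oil_price_real=60.0,
        )
        defaults.update(kw)
        return TransactionRecord(**defaults)

    return make


@pytest.fixture
def point_profile():
    """Country profile whose four uncertain inputs are all degenerate."""

    def make(price=2.0, b=2.0, persons=1.0, rate=0.03, country="Pointland"):
        return CountryProfile(
            country=country,
            retention_median_b=b,
            retention_interval=(b, b),
            price_by_class={"pyrethroid": DistributionSpec.point(price)},
            persons_per_net=DistributionSpec.point(persons),
            discount_rate_r=rate,
        )

    return make
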