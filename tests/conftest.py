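import dataclasses

import pytest

import vegchain as vc
from vegchain.core import (RETAILER, VILLAGE, WHOLESALE, Location,
                           NetworkSpec, OrderingPolicy, Route)


def toy_chain() -> NetworkSpec:
    """Minimal valid chain: 1 village, 1 tier-1 wholesale, 1 retailer."""
    locs = [
        Location(id="v0", level=VILLAGE, lat=20.0, lon=85.0,
                 catchment_population=8000, direct_sale_fraction=0.05,
                 mean_consumer_arrival_time=10.0),
        Location(id="w0", level=WHOLESALE, tier=1, lat=20.1, lon=85.1,
                 catchment_population=8000, direct_sale_fraction=0.05),
        Location(id="r0", level=RETAILER, lat=20.2, lon=85.2,
                 catchment_population=7200, direct_sale_fraction=1.0,
                 mean_consumer_arrival_time=17.0),
    ]
    routes = [
        Route(origin="v0", destination="w0", vehicle_volume=40.0,
              travel_time=0.45),
        Route(origin="w0", destination="r0", vehicle_volume=12.0,
              travel_time=0.4,
              policy=OrderingPolicy(initiator="recipient_fetches")),
    ]
    return NetworkSpec(locations=locs, routes=routes)


@pytest.fixture
def toy_network():
    return toy_chain()


@pytest.fixture(scope="session")
def default_crops():
    return vc.default_crops()


@pytest.fixture(scope="session")
def small_network():
    """A small but fully featured network (villages, 3 tiers, retailers)."""
    return vc.generate_network(vc.GeneratorParams(
        n_village=10, n_tier1=1, n_tier2=1, n_tier3=3,
        retailers_per_wholesale=4, seed=42))


@pytest.fixture(scope="session")
def small_run(small_network, default_crops):
    """One short seeded run on the small network, shared across tests."""
    cfg = vc.ScenarioConfig(burn_in=7, horizon=30, seed=11)
    return vc.run(small_network, default_crops, cfg,
                  production_ratio=vc.default_production_ratios())


def ample_crops():
    """Long-lived, season-free variants of the default crops.

    Used where perishability and seasonality must not confound the quantity
    under test (demand allocation, fulfillment contracts).
    """
    return [dataclasses.replace(c, ambient_lifespan=400.0,
                                season_weights=(1.0,) * 12)
            for c in vc.default_crops()]
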