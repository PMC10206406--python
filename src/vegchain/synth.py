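"""Synthetic networks, default crop parameters, and scenario suites.

The generator emulates the structural statistics of an eastern-India
vegetable market system at a configurable, scaled-down size: three supply
chain levels; wholesale tiers in the ratio 4 : 8 : 395 (a few high-volume
Tier-1/2 aggregators, many single-partner Tier-3 *mandis*); direct sales to
5% of the local population at village and wholesale markets with the
remaining 90% of purchases at retail; lognormal catchment populations; and
five crops spanning ambient lifespans from 4 days (brinjal) to 21 days
(potato) whose per-capita demands sum to 266 g/person/day.

The crop parameter set is a synthetic default anchored to printed ranges —
only the brinjal lifespan and the 266 g total are point values; lifespans
sit inside the 4–7 / 15–21 day ranges, the demand split, bulk densities and
monthly season profiles (2–3 harvest months for potato and onion,
near-year-round for tomato and brinjal) are labelled assumptions stored in
``data/default_crops.csv``, not hard-coded in logic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (RETAILER, VILLAGE, WHOLESALE, Crop, Location, NetworkSpec,
                   ScenarioConfig)
from .trade import RouteDefaults, assign_nearest_partners

#: production-to-demand ratios of the default crops (annual mean); the
#: brinjal surplus of 5.2x typical expenditures is the anchoring point,
#: potato is mostly procured from other states.
DEFAULT_PRODUCTION_RATIOS: Dict[str, float] = {}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic network generator.

    Defaults give the test-scale network: 50 villages, 1/2/10 wholesale
    tiers, 12 retailers per wholesale market, inside a ~3-degree bounding
    box. Village and wholesale catchment populations are lognormal
    (median, sigma); retail consumer counts are derived so that retail
    carries 90% of expected purchases.
    """

    n_village: int = 50
    n_tier1: int = 1
    n_tier2: int = 2
    n_tier3: int = 10
    retailers_per_wholesale: int = 12
    lat_range: Tuple[float, float] = (19.0, 22.0)
    lon_range: Tuple[float, float] = (84.0, 87.0)
    village_pop_median: float = 5500.0
    village_pop_sigma: float = 0.8
    wholesale_pop_median: float = 79000.0
    wholesale_pop_sigma: float = 0.8
    direct_sale_fraction: float = 0.05
    retail_share: float = 0.9
    seed: int = 0
    route_defaults: RouteDefaults = field(default_factory=RouteDefaults)

    def __post_init__(self):
        if self.n_tier1 < 1:
            raise ValueError("need at least one tier-1 market")
        if not (0.0 <= self.direct_sale_fraction <= 1.0):
            raise ValueError("direct_sale_fraction must be in [0, 1]")
        if not (0.0 < self.retail_share < 1.0):
            raise ValueError("retail_share must be in (0, 1)")
        if (self.lat_range[0] >= self.lat_range[1]
                or self.lon_range[0] >= self.lon_range[1]):
            raise ValueError("degenerate bounding box")


def generate_network(params: Optional[GeneratorParams] = None) -> NetworkSpec:
    """Generate a synthetic three-level market network.

    Locations are placed uniformly in the bounding box; routes and the
    tiered wholesale partner graph are built by geographic proximity
    (:func:`vegchain.trade.assign_nearest_partners`). Regeneration with the
    same parameters is bit-identical, and the result always passes
    :func:`vegchain.core.validate_network`.
    """
    p = params or GeneratorParams()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(p.seed)))

    def place(n: int) -> np.ndarray:
        lat = rng.uniform(*p.lat_range, size=n)
        lon = rng.uniform(*p.lon_range, size=n)
        return np.column_stack([lat, lon])

    locations: List[Location] = []

    v_xy = place(p.n_village)
    v_pop = rng.lognormal(np.log(p.village_pop_median),
                          p.village_pop_sigma, size=p.n_village)
    for i in range(p.n_village):
        locations.append(Location(
            id=f"v{i:04d}", level=VILLAGE, lat=float(v_xy[i, 0]),
            lon=float(v_xy[i, 1]), catchment_population=float(v_pop[i]),
            direct_sale_fraction=p.direct_sale_fraction,
            mean_consumer_arrival_time=10.0))

    n_wh = p.n_tier1 + p.n_tier2 + p.n_tier3
    w_xy = place(n_wh)
    w_pop = rng.lognormal(np.log(p.wholesale_pop_median),
                          p.wholesale_pop_sigma, size=n_wh)
    tiers = [1] * p.n_tier1 + [2] * p.n_tier2 + [3] * p.n_tier3
    for i in range(n_wh):
        locations.append(Location(
            id=f"w{i:03d}", level=WHOLESALE, tier=tiers[i],
            lat=float(w_xy[i, 0]), lon=float(w_xy[i, 1]),
            catchment_population=float(w_pop[i]),
            direct_sale_fraction=p.direct_sale_fraction,
            mean_consumer_arrival_time=12.0))

    # retail consumer counts chosen so retail carries `retail_share` of
    # expected daily purchase visits
    direct_visits = (p.direct_sale_fraction
                     * (float(v_pop.sum()) + float(w_pop.sum())))
    retail_visits = direct_visits * p.retail_share / (1.0 - p.retail_share)
    n_ret = n_wh * p.retailers_per_wholesale
    per_ret = retail_visits / max(1, n_ret)
    r_xy = place(n_ret)
    for i in range(n_ret):
        locations.append(Location(
            id=f"r{i:04d}", level=RETAILER, lat=float(r_xy[i, 0]),
            lon=float(r_xy[i, 1]), catchment_population=per_ret,
            direct_sale_fraction=1.0, mean_consumer_arrival_time=17.0))

    routes, partner_edges = assign_nearest_partners(locations,
                                                    p.route_defaults)
    return NetworkSpec(locations=locations, routes=routes,
                       wholesale_partner_graph=partner_edges)


def default_crops() -> List[Crop]:
    """The five default crops, loaded from the packaged parameter table.

    Lifespans: potato 21 d, onion 15 d, cabbage 7 d, tomato 6 d,
    brinjal 4 d. Per-capita demands sum to 266 g/person/day.
    """
    crops = []
    ratios: Dict[str, float] = {}
    with resources.files("vegchain").joinpath(
            "data/default_crops.csv").open("r") as fh:
        for row in csv.DictReader(fh):
            crops.append(Crop(
                name=row["name"],
                ambient_lifespan=float(row["lifespan_d"]),
                bulk_density=float(row["density_kg_m3"]),
                per_capita_demand=float(row["demand_g_capita_d"]),
                season_weights=tuple(float(row[f"m{i}"]) for i in range(1, 13)),
                cold_aging_factor=float(row["cold_factor"])))
            ratios[row["name"]] = float(row["production_demand_ratio"])
    DEFAULT_PRODUCTION_RATIOS.clear()
    DEFAULT_PRODUCTION_RATIOS.update(ratios)
    return crops


def default_production_ratios() -> Dict[str, float]:
    """Production-to-demand ratio per default crop (see the data file)."""
    if not DEFAULT_PRODUCTION_RATIOS:
        default_crops()
    return dict(DEFAULT_PRODUCTION_RATIOS)


def minimal_chain(leg_breakage: float = 0.0,
                  lifespan_days: float = 400.0,
                  population: float = 8000.0,
                  direct_sale_fraction: float = 0.05
                  ) -> Tuple[NetworkSpec, List[Crop]]:
    """The simplest possible chain: one village, one wholesale, one retailer.

    With ample supply, zero breakage and a lifespan exceeding the horizon,
    this structure should fulfil 100% of retail demand — losses and
    accumulation only appear once the chain grows more complex. Returns the
    network and a single long-lived crop (100 g/person/day).
    """
    locs = [
        Location(id="v0", level=VILLAGE, lat=20.0, lon=85.0,
                 catchment_population=population,
                 direct_sale_fraction=direct_sale_fraction,
                 mean_consumer_arrival_time=10.0),
        Location(id="w0", level=WHOLESALE, tier=1, lat=20.1, lon=85.1,
                 catchment_population=population,
                 direct_sale_fraction=direct_sale_fraction,
                 mean_consumer_arrival_time=12.0),
        Location(id="r0", level=RETAILER, lat=20.2, lon=85.2,
                 catchment_population=(9.0 * 2 * population
                                       * direct_sale_fraction),
                 direct_sale_fraction=1.0,
                 mean_consumer_arrival_time=17.0),
    ]
    defaults = RouteDefaults(leg_breakage_mean=leg_breakage)
    routes, partners = assign_nearest_partners(locs, defaults)
    crop = Crop(name="greens", ambient_lifespan=lifespan_days,
                bulk_density=500.0, per_capita_demand=100.0)
    return NetworkSpec(locations=locs, routes=routes,
                       wholesale_partner_graph=partners), [crop]


def scenario_suite(base: Optional[ScenarioConfig] = None,
                   horizon: float = 90.0) -> List[ScenarioConfig]:
    """The production-multiplier experiment: x{1, 1.25, 1.5, 2, 3, 5}.

    Each scenario keeps the base configuration but sets the multiplier, a
    7-day burn-in and the requested horizon (90 days at test scale, 365 for
    a full year).
    """
    base = base or ScenarioConfig()
    multipliers = [1.0, 1.25, 1.5, 2.0, 3.0, 5.0]
    out = []
    for m in multipliers:
        out.append(ScenarioConfig(
            production_multiplier=m, burn_in=7.0, horizon=horizon,
            iterations=base.iterations, seed=base.seed,
            stage_breakage_mean=base.stage_breakage_mean,
            unit_mass_kg=base.unit_mass_kg,
            supply_noise_sigma=base.supply_noise_sigma,
            scale_imports=base.scale_imports,
            departure_jitter_lambda=base.departure_jitter_lambda))
    return out
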