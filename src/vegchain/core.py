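"""Domain types for the market-network simulator, plus structural validation.

The model world is a three-level supply chain: village markets where produce
enters, a tiered network of wholesale markets (*mandis*) that aggregate and
trade laterally, and retail locations where most consumer purchases happen.
Produce is tracked in age-stamped lots; losses occur through expiration
(a lot's effective age reaching its crop's ambient lifespan) and breakage
(Poisson-distributed handling loss per stage or transport leg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

# Location levels
VILLAGE = "village_market"
WHOLESALE = "wholesale_market"
RETAILER = "retailer"
SURROGATE_RETAIL = "surrogate_retail"
EXTERNAL = "external"

LEVELS = (VILLAGE, WHOLESALE, RETAILER, SURROGATE_RETAIL, EXTERNAL)

#: levels at which consumers buy directly
SELLING_LEVELS = (VILLAGE, WHOLESALE, RETAILER, SURROGATE_RETAIL)

#: retail-type levels (the "remaining 90%" of purchases)
RETAIL_LEVELS = (RETAILER, SURROGATE_RETAIL)

# Loss stages
STAGE_VILLAGE_STORAGE = "village_storage"
STAGE_VILLAGE_TO_WHOLESALE = "village_to_wholesale"
STAGE_WHOLESALE_STORAGE = "wholesale_storage"
STAGE_WHOLESALE_TO_WHOLESALE = "wholesale_to_wholesale"
STAGE_WHOLESALE_TO_RETAIL = "wholesale_to_retail"
STAGE_RETAIL_STORAGE = "retail_storage"

STORAGE_STAGES = (STAGE_VILLAGE_STORAGE, STAGE_WHOLESALE_STORAGE,
                  STAGE_RETAIL_STORAGE)
TRANSPORT_STAGES = (STAGE_VILLAGE_TO_WHOLESALE, STAGE_WHOLESALE_TO_WHOLESALE,
                    STAGE_WHOLESALE_TO_RETAIL)
ALL_STAGES = STORAGE_STAGES + TRANSPORT_STAGES

MECHANISM_EXPIRED = "expired"
MECHANISM_BROKEN = "broken"


def storage_stage_for_level(level: str) -> str:
    """Loss stage charged while produce sits in storage at a location."""
    if level == VILLAGE:
        return STAGE_VILLAGE_STORAGE
    if level == WHOLESALE:
        return STAGE_WHOLESALE_STORAGE
    if level in (RETAILER, SURROGATE_RETAIL):
        return STAGE_RETAIL_STORAGE
    raise ValueError(f"no storage stage for level {level!r}")


def leg_stage(origin_level: str, dest_level: str) -> str:
    """Loss stage charged on a transport leg between two levels."""
    if origin_level == VILLAGE and dest_level == WHOLESALE:
        return STAGE_VILLAGE_TO_WHOLESALE
    if origin_level == WHOLESALE and dest_level == WHOLESALE:
        return STAGE_WHOLESALE_TO_WHOLESALE
    if origin_level == WHOLESALE and dest_level in RETAIL_LEVELS:
        return STAGE_WHOLESALE_TO_RETAIL
    raise ValueError(f"no leg stage for {origin_level} -> {dest_level}")


@dataclass(frozen=True)
class Crop:
    """Perishability, density, demand and seasonality parameters for one crop.

    Parameters
    ----------
    name : str
        Crop identifier (e.g. ``"brinjal"``).
    ambient_lifespan : float
        Maximum lifespan in days at ambient temperature; a lot whose
        effective age reaches this expires.
    bulk_density : float
        kg per cubic metre, used to convert mass to vehicle volume.
    per_capita_demand : float
        Grams requested per consumer arrival per day.
    season_weights : tuple of 12 floats
        Relative monthly production weights (peak / lean / off season);
        normalised to mean 1 when applied.
    cold_aging_factor : float
        Aging-rate multiplier in cold storage, in [0, 1]; 1 means cold
        storage confers no benefit.
    """

    name: str
    ambient_lifespan: float
    bulk_density: float
    per_capita_demand: float
    season_weights: tuple = (1.0,) * 12
    cold_aging_factor: float = 1.0

    def __post_init__(self):
        if self.ambient_lifespan <= 0:
            raise ValueError(f"{self.name}: ambient_lifespan must be > 0")
        if self.bulk_density <= 0:
            raise ValueError(f"{self.name}: bulk_density must be > 0")
        if self.per_capita_demand < 0:
            raise ValueError(f"{self.name}: per_capita_demand must be >= 0")
        w = tuple(float(x) for x in self.season_weights)
        if len(w) != 12 or any(x < 0 for x in w):
            raise ValueError(f"{self.name}: need 12 non-negative season weights")
        if not any(x > 0 for x in w):
            raise ValueError(f"{self.name}: at least one season weight must be > 0")
        object.__setattr__(self, "season_weights", w)
        if not (0.0 <= self.cold_aging_factor <= 1.0):
            raise ValueError(f"{self.name}: cold_aging_factor must be in [0, 1]")


@dataclass(frozen=True)
class Location:
    """A market node in the network.

    ``catchment_population`` is the population the node serves;
    ``direct_sale_fraction`` is the share of that population purchasing
    directly at the node each day (0.05 at village and wholesale markets by
    default, 1.0 at retail nodes whose catchment is already a consumer count).
    """

    id: str
    level: str
    lat: float
    lon: float
    catchment_population: float = 0.0
    direct_sale_fraction: float = 0.0
    tier: Optional[int] = None
    storage_volume: float = math.inf
    mean_consumer_arrival_time: float = 12.0  # hour of day

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"{self.id}: unknown level {self.level!r}")
        if self.catchment_population < 0:
            raise ValueError(f"{self.id}: catchment_population must be >= 0")

    @property
    def expected_daily_visits(self) -> float:
        return self.catchment_population * self.direct_sale_fraction


@dataclass
class Lot:
    """An age-tracked quantity of one crop moving through the chain.

    ``effective_age`` is in days and advances at the storage-dependent aging
    rate; the lot is expired once it reaches ``crop.ambient_lifespan``
    (closed boundary).
    """

    crop: str
    mass: float
    effective_age: float = 0.0
    entry_time: float = 0.0    # hours since simulation start
    entry_location: str = ""

    def __post_init__(self):
        if self.mass < 0:
            raise ValueError("lot mass must be >= 0")
        if self.effective_age < 0:
            raise ValueError("lot effective_age must be >= 0")

    def is_expired(self, crop: Crop) -> bool:
        return self.effective_age >= crop.ambient_lifespan


@dataclass(frozen=True)
class OrderingPolicy:
    """Replenishment rule for a route.

    quantity_mode : "fixed" or "variable"
        Variable quantity is an order-up-to (base-stock) rule targeting
        ``(review_period + safety_stock)`` days of demand; fixed quantity
        ships ``fixed_quantity_kg`` whenever projected coverage drops below
        ``safety_stock`` days.
    initiator : "supplier_delivers" or "recipient_fetches"
    persistence : "single" or "persistent"
        Persistent orders are recomputed daily until filled.
    """

    quantity_mode: str = "variable"
    frequency_mode: str = "fixed"
    initiator: str = "supplier_delivers"
    persistence: str = "persistent"
    review_period: float = 1.0
    safety_stock: float = 2.0
    fixed_quantity_kg: float = 0.0

    def __post_init__(self):
        if self.quantity_mode not in ("fixed", "variable"):
            raise ValueError(f"bad quantity_mode {self.quantity_mode!r}")
        if self.frequency_mode not in ("fixed", "variable"):
            raise ValueError(f"bad frequency_mode {self.frequency_mode!r}")
        if self.initiator not in ("supplier_delivers", "recipient_fetches"):
            raise ValueError(f"bad initiator {self.initiator!r}")
        if self.persistence not in ("single", "persistent"):
            raise ValueError(f"bad persistence {self.persistence!r}")
        if self.review_period <= 0:
            raise ValueError("review_period must be > 0")
        if self.safety_stock < 0:
            raise ValueError("safety_stock must be >= 0")


@dataclass(frozen=True)
class Route:
    """A transport link with vehicle capacity, timing and replenishment rule."""

    origin: str
    destination: str
    vehicle_volume: float        # m^3
    travel_time: float           # hours
    mean_departure_time: float = 6.0   # hour of day
    policy: OrderingPolicy = field(default_factory=OrderingPolicy)
    leg_breakage_mean: float = 0.02

    def __post_init__(self):
        if self.origin == self.destination:
            raise ValueError(f"route {self.origin}: origin == destination")
        if self.travel_time <= 0:
            raise ValueError(f"route {self.origin}->{self.destination}: "
                             "travel_time must be > 0")
        if self.vehicle_volume <= 0:
            raise ValueError(f"route {self.origin}->{self.destination}: "
                             "vehicle_volume must be > 0")
        if not (0.0 <= self.leg_breakage_mean < 1.0):
            raise ValueError("leg_breakage_mean must be in [0, 1)")


@dataclass
class NetworkSpec:
    """Locations, directed transport routes, and the undirected lateral-trade
    graph among wholesale markets."""

    locations: list
    routes: list
    wholesale_partner_graph: list = field(default_factory=list)  # (id, id) pairs

    def location_map(self) -> dict:
        return {loc.id: loc for loc in self.locations}


@dataclass(frozen=True)
class ScenarioConfig:
    """Experiment configuration for one scenario.

    ``production_multiplier`` scales in-state village-market production
    (imports held fixed unless ``scale_imports``). Tallies accumulate only
    after the ``burn_in`` days that fill the initially empty chain.
    """

    production_multiplier: float = 1.0
    burn_in: float = 7.0          # days
    horizon: float = 365.0        # days
    iterations: int = 1
    seed: int = 0
    stage_breakage_mean: float = 0.02
    unit_mass_kg: float = 1.0
    supply_noise_sigma: float = 0.1
    scale_imports: bool = False
    departure_jitter_lambda: float = 2.0
    production_hour: float = 5.0
    review_hour: float = 15.0
    export_hour: float = 18.0
    sweep_hour: float = 23.5

    def __post_init__(self):
        if self.production_multiplier <= 0:
            raise ValueError("production_multiplier must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 <= self.stage_breakage_mean < 1.0):
            raise ValueError("stage_breakage_mean must be in [0, 1)")
        if self.unit_mass_kg <= 0:
            raise ValueError("unit_mass_kg must be > 0")


def validate_network(spec: NetworkSpec) -> list:
    """Check the structural invariants of a network specification.

    Returns a list of human-readable violation strings (empty when valid).
    Violations are data, not exceptions: readers report them, the engine
    refuses to run until they are fixed. The result is independent of the
    ordering of the input records.
    """
    violations = []
    seen = set()
    for loc in spec.locations:
        if loc.id in seen:
            violations.append(f"location {loc.id}: duplicate id")
        seen.add(loc.id)
        if loc.level == WHOLESALE:
            if loc.tier not in (1, 2, 3):
                violations.append(
                    f"location {loc.id}: wholesale market needs tier in {{1,2,3}}")
        elif loc.tier is not None:
            violations.append(
                f"location {loc.id}: tier set on non-wholesale level {loc.level}")
        if not (0.0 <= loc.direct_sale_fraction <= 1.0):
            violations.append(
                f"location {loc.id}: direct_sale_fraction outside [0, 1]")
        if not (-90.0 <= loc.lat <= 90.0):
            violations.append(f"location {loc.id}: latitude outside [-90, 90]")
        if not (-180.0 <= loc.lon <= 180.0):
            violations.append(f"location {loc.id}: longitude outside [-180, 180]")

    locmap = {loc.id: loc for loc in spec.locations}

    for r in spec.routes:
        for end in (r.origin, r.destination):
            if end not in locmap:
                violations.append(
                    f"route {r.origin}->{r.destination}: dangling reference "
                    f"to unknown location {end}")

    wholesale_ids = {loc.id for loc in spec.locations if loc.level == WHOLESALE}
    partner_count: dict = {wid: 0 for wid in wholesale_ids}
    upper = {loc.id for loc in spec.locations
             if loc.level == WHOLESALE and loc.tier in (1, 2)}
    g_upper = nx.Graph()
    g_upper.add_nodes_from(sorted(upper))
    for a, b in spec.wholesale_partner_graph:
        for end in (a, b):
            if end not in wholesale_ids:
                violations.append(
                    f"partner edge {a}--{b}: {end} is not a wholesale market")
        if a in partner_count:
            partner_count[a] += 1
        if b in partner_count:
            partner_count[b] += 1
        if a in upper and b in upper:
            g_upper.add_edge(a, b)

    for loc in sorted(spec.locations, key=lambda x: x.id):
        if loc.level == WHOLESALE and loc.tier == 3:
            n = partner_count.get(loc.id, 0)
            if n != 1:
                violations.append(
                    f"location {loc.id}: tier-3 wholesale market must have "
                    f"exactly one trading partner (has {n})")

    if len(g_upper) > 1 and not nx.is_connected(g_upper):
        violations.append("tier-1/2 wholesale partner subgraph is not connected")

    # village -> exactly one wholesale supply route; retailer <- exactly one
    vill_out: dict = {}
    ret_in: dict = {}
    for r in spec.routes:
        o = locmap.get(r.origin)
        d = locmap.get(r.destination)
        if o is None or d is None:
            continue
        if o.level == VILLAGE and d.level == WHOLESALE:
            vill_out[o.id] = vill_out.get(o.id, 0) + 1
        if o.level == WHOLESALE and d.level in RETAIL_LEVELS:
            ret_in[d.id] = ret_in.get(d.id, 0) + 1
    for loc in sorted(spec.locations, key=lambda x: x.id):
        if loc.level == VILLAGE and vill_out.get(loc.id, 0) != 1:
            violations.append(
                f"location {loc.id}: village market must have a route to "
                f"exactly one wholesale market (has {vill_out.get(loc.id, 0)})")
        if loc.level in RETAIL_LEVELS and ret_in.get(loc.id, 0) != 1:
            violations.append(
                f"location {loc.id}: retail location must fetch from exactly "
                f"one wholesale market (has {ret_in.get(loc.id, 0)})")

    return violations
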