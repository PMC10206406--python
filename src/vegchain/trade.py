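"""Replenishment and movement between markets.

Routes follow geographic proximity: villages ship to the closest wholesale
market and retail locations fetch from the closest wholesale market.
Wholesale markets trade laterally in a tiered structure — Tier-3 markets
have a single trading partner (the nearest Tier-1/2 market) while Tier-1/2
markets are high-volume aggregators fully interconnected among themselves.
Information is shared daily and is local: a market sees only its own state
and its direct partners' estimates, and no new trading relationships form.

Vehicle loading prioritises perishability — when space is limited, less
perishable items are left behind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (RETAIL_LEVELS, VILLAGE, WHOLESALE, Crop, Location, Lot,
                   OrderingPolicy, Route)
from .perish import age_lots, draw_breakage, remove_expired

EARTH_RADIUS_KM = 6371.0


def haversine_km(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (math.sin(dlat / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass(frozen=True)
class RouteDefaults:
    """Default vehicle capacities, timings and breakage for generated routes.

    Travel times default to the field-typical averages: about half an hour
    between villages (or retailers) and their wholesale market, five hours
    between wholesale markets.
    """

    village_vehicle_m3: float = 40.0
    retail_vehicle_m3: float = 12.0
    lateral_vehicle_m3: float = 150.0
    village_travel_h: float = 0.45
    retail_travel_h: float = 0.4
    lateral_travel_h: float = 5.0
    village_depart_hour: float = 6.0
    retail_depart_hour: float = 6.0
    lateral_depart_hour: float = 6.0
    leg_breakage_mean: float = 0.02
    retail_safety_stock_days: float = 2.0


def assign_nearest_partners(locations: Sequence[Location],
                            defaults: Optional[RouteDefaults] = None
                            ) -> Tuple[List[Route], List[Tuple[str, str]]]:
    """Build routes and the wholesale partner graph by geographic proximity.

    - each village market ships to its nearest wholesale market
      (supplier delivers, daily);
    - each retail location fetches from its nearest wholesale market
      (recipient fetches, order-up-to policy);
    - each Tier-3 wholesale market partners with its nearest Tier-1/2
      market; Tier-1/2 markets are fully interconnected.

    Distance ties are broken by the lower location id.
    """
    d = defaults or RouteDefaults()
    wholesale = sorted((l for l in locations if l.level == WHOLESALE),
                       key=lambda x: x.id)
    if not wholesale:
        raise ValueError("no wholesale markets in the network")
    upper = [w for w in wholesale if w.tier in (1, 2)]

    def nearest(loc: Location, candidates: Sequence[Location]) -> Location:
        return min(candidates,
                   key=lambda w: (haversine_km((loc.lat, loc.lon),
                                               (w.lat, w.lon)), w.id))

    routes: List[Route] = []
    partner_edges: List[Tuple[str, str]] = []

    push = OrderingPolicy(quantity_mode="variable", frequency_mode="fixed",
                          initiator="supplier_delivers", persistence="persistent")
    fetch = OrderingPolicy(quantity_mode="variable", frequency_mode="fixed",
                           initiator="recipient_fetches", persistence="persistent",
                           review_period=1.0,
                           safety_stock=d.retail_safety_stock_days)
    lateral = OrderingPolicy(quantity_mode="variable", frequency_mode="variable",
                             initiator="supplier_delivers", persistence="single")

    for loc in sorted(locations, key=lambda x: x.id):
        if loc.level == VILLAGE:
            w = nearest(loc, wholesale)
            routes.append(Route(origin=loc.id, destination=w.id,
                                vehicle_volume=d.village_vehicle_m3,
                                travel_time=d.village_travel_h,
                                mean_departure_time=d.village_depart_hour,
                                policy=push,
                                leg_breakage_mean=d.leg_breakage_mean))
        elif loc.level in RETAIL_LEVELS:
            w = nearest(loc, wholesale)
            routes.append(Route(origin=w.id, destination=loc.id,
                                vehicle_volume=d.retail_vehicle_m3,
                                travel_time=d.retail_travel_h,
                                mean_departure_time=d.retail_depart_hour,
                                policy=fetch,
                                leg_breakage_mean=d.leg_breakage_mean))

    def lateral_route(a: str, b: str) -> Route:
        return Route(origin=a, destination=b,
                     vehicle_volume=d.lateral_vehicle_m3,
                     travel_time=d.lateral_travel_h,
                     mean_departure_time=d.lateral_depart_hour,
                     policy=lateral, leg_breakage_mean=d.leg_breakage_mean)

    for w in wholesale:
        if w.tier == 3:
            if not upper:
                raise ValueError("tier-3 markets present but no tier-1/2 market")
            p = nearest(w, upper)
            partner_edges.append((w.id, p.id))
            routes.append(lateral_route(w.id, p.id))
            routes.append(lateral_route(p.id, w.id))
    for i, a in enumerate(upper):
        for b in upper[i + 1:]:
            partner_edges.append((a.id, b.id))
            routes.append(lateral_route(a.id, b.id))
            routes.append(lateral_route(b.id, a.id))

    return routes, partner_edges


@dataclass
class DemandEstimate:
    """A market's shared daily snapshot for one crop.

    ``daily_demand`` is the estimated total downstream demand (local direct
    sales + attached retail + any export quota); ``local_daily_demand`` is
    the local direct-sale part, which a sender never ships below one day of.
    """

    daily_demand: float
    on_hand: float
    in_transit: float
    local_daily_demand: float = 0.0

    def __post_init__(self):
        for name in ("daily_demand", "on_hand", "in_transit",
                     "local_daily_demand"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def compute_order(policy: OrderingPolicy, estimate: DemandEstimate) -> float:
    """Replenishment quantity in kg for one crop under an ordering policy.

    Variable-quantity mode is order-up-to (base stock): bring projected
    inventory position up to ``(review_period + safety_stock)`` days of
    demand. Fixed-quantity mode ships the configured constant whenever
    projected coverage drops below ``safety_stock`` days.
    """
    position = estimate.on_hand + estimate.in_transit
    if policy.quantity_mode == "variable":
        target = (policy.review_period + policy.safety_stock) * estimate.daily_demand
        return max(0.0, target - position)
    trigger = policy.safety_stock * estimate.daily_demand
    if position < trigger:
        return policy.fixed_quantity_kg
    return 0.0


def lateral_transfers(partner_graph: Iterable[Tuple[str, str]],
                      estimates: Dict[str, Dict[str, DemandEstimate]],
                      trigger_days: float = 1.0,
                      target_days: float = 3.0
                      ) -> List[Tuple[str, str, str, float]]:
    """Compute lateral wholesale-to-wholesale transfer orders.

    For each crop, a market whose projected position (on hand + inbound)
    falls below ``trigger_days`` of downstream demand requests enough to
    reach ``target_days`` of coverage from the direct partner with the
    largest projected surplus. A transfer never exceeds the sender's surplus
    and never drives the sender's on-hand stock below one day of its own
    local demand. Information is restricted to direct partners: no other
    market's state is consulted and no new edges are used.

    Returns (from, to, crop, kg) tuples.
    """
    partners: Dict[str, set] = {}
    for a, b in partner_graph:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    crops = sorted({c for est in estimates.values() for c in est})
    transfers: List[Tuple[str, str, str, float]] = []

    for crop in crops:
        # remaining shippable surplus per market for this crop
        surplus: Dict[str, float] = {}
        for m, est in estimates.items():
            e = est.get(crop)
            if e is None:
                continue
            surplus[m] = min(e.on_hand - e.local_daily_demand,
                             e.on_hand + e.in_transit - e.daily_demand)
        for m in sorted(estimates):
            e = estimates[m].get(crop)
            if e is None:
                continue
            position = e.on_hand + e.in_transit
            if position >= trigger_days * e.daily_demand:
                continue
            deficit = target_days * e.daily_demand - position
            if deficit <= 0:
                continue
            cands = [p for p in partners.get(m, ())
                     if surplus.get(p, 0.0) > 0]
            if not cands:
                continue
            donor = max(cands, key=lambda p: (surplus[p], p))
            qty = min(deficit, surplus[donor])
            if qty <= 0:
                continue
            surplus[donor] -= qty
            transfers.append((donor, m, crop, qty))
    return transfers


def load_vehicle(lots: Sequence[Lot], vehicle_volume: float,
                 crops: Dict[str, Crop]) -> Tuple[List[Lot], List[Lot]]:
    """Pack lots into a vehicle, most perishable first.

    Lot volume is ``mass / bulk_density``. Lots are sorted by (crop ambient
    lifespan ascending, effective age descending) and packed greedily until
    the volume is exhausted; the boundary lot is split so the vehicle is
    filled exactly. Mass is conserved between the two outputs.
    """
    if vehicle_volume <= 0:
        raise ValueError("vehicle_volume must be > 0")
    order = sorted(lots, key=lambda l: (crops[l.crop].ambient_lifespan,
                                        -l.effective_age))
    loaded: List[Lot] = []
    left: List[Lot] = []
    remaining = vehicle_volume
    for lot in order:
        if lot.mass <= 0:
            continue
        density = crops[lot.crop].bulk_density
        vol = lot.mass / density
        if vol <= remaining + 1e-12:
            loaded.append(lot)
            remaining -= vol
        elif remaining > 1e-12:
            take_mass = remaining * density
            loaded.append(Lot(crop=lot.crop, mass=take_mass,
                              effective_age=lot.effective_age,
                              entry_time=lot.entry_time,
                              entry_location=lot.entry_location))
            left.append(Lot(crop=lot.crop, mass=lot.mass - take_mass,
                            effective_age=lot.effective_age,
                            entry_time=lot.entry_time,
                            entry_location=lot.entry_location))
            remaining = 0.0
        else:
            left.append(lot)
    return loaded, left


def transit(lots: List[Lot], route: Route, crops: Dict[str, Crop],
            rng: np.random.Generator, unit_mass: float = 1.0
            ) -> Tuple[List[Lot], Dict[str, float], Dict[str, float]]:
    """Apply one transport leg to a shipment.

    Lots age by the travel time at the ambient rate; lots expiring
    mid-transit are removed; one Poisson breakage draw per crop is applied
    to the surviving arriving mass, removed FEFO. Returns
    (arriving lots, expired kg per crop, broken kg per crop).
    """
    age_lots(lots, route.travel_time, "transit", crops)
    survivors, expired = remove_expired(lots, crops)
    broken: Dict[str, float] = {}
    if route.leg_breakage_mean > 0:
        by_crop: Dict[str, List[Lot]] = {}
        for lot in survivors:
            by_crop.setdefault(lot.crop, []).append(lot)
        survivors = []
        for crop_name in sorted(by_crop):
            crop_lots = sorted(by_crop[crop_name], key=lambda l: l.effective_age)
            mass = sum(l.mass for l in crop_lots)
            b = draw_breakage(mass, route.leg_breakage_mean, unit_mass, rng)
            if b > 0:
                from .demand import take_fefo
                got, _ = take_fefo(crop_lots, b)
                broken[crop_name] = got
            survivors.extend(crop_lots)
    return survivors, expired, broken
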