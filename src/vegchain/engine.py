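"""Discrete event scheduler and the top-level simulation loop.

The clock is continuous, in hours from the start of the run. Daily cycles
fire at configurable hours of day: produce enters village markets in the
early morning (05:00), vehicles depart around 06:00 with Poisson jitter,
consumers arrive around each market's mean hour, demand information is
shared and orders placed at the afternoon review (15:00), exports are drawn
in the evening, and a nightly sweep ages inventory and removes expired lots.
Tallies accumulate only after the burn-in period that fills the initially
empty chain.

Same-time events are processed in a fixed kind priority (arrivals before
departures before reviews before consumer arrivals) so that stock arriving
at an instant is available for sale at that instant; remaining ties fall
back to insertion order. A run is a pure function of
(network, crops, config, seed).
"""

from __future__ import annotations

import heapq
import itertools
import math
import zlib
from bisect import insort
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import demand as demand_mod
from . import perish, supply, trade
from .core import (RETAIL_LEVELS, SELLING_LEVELS, VILLAGE, WHOLESALE,
                   Crop, Location, Lot, NetworkSpec, Route, ScenarioConfig,
                   leg_stage, storage_stage_for_level, validate_network,
                   MECHANISM_BROKEN, MECHANISM_EXPIRED)
from .results import SimulationResult

# fixed same-time processing order
EVENT_PRIORITY = {
    "measure_start": 0,
    "vehicle_arrival": 1,
    "production_entry": 2,
    "import_entry": 3,
    "vehicle_departure": 4,
    "daily_review": 5,
    "consumer_arrival": 6,
    "export_draw": 7,
    "expiration_sweep": 8,
    "end_of_run": 9,
}


@dataclass(order=False)
class Event:
    time: float
    kind: str
    payload: tuple = ()


class EventQueue:
    """Future-event list ordered by (time, kind priority, insertion order)."""

    def __init__(self) -> None:
        self._heap: list = []
        self._seq = itertools.count()

    def schedule(self, event: Event, clock: float = -math.inf) -> None:
        if event.time < clock - 1e-9:
            raise ValueError(
                f"cannot schedule {event.kind} at t={event.time} in the past "
                f"(clock={clock})")
        if event.kind not in EVENT_PRIORITY:
            raise ValueError(f"unknown event kind {event.kind!r}")
        heapq.heappush(self._heap,
                       (event.time, EVENT_PRIORITY[event.kind],
                        next(self._seq), event))

    def pop(self) -> Optional[Event]:
        if not self._heap:
            return None
        return heapq.heappop(self._heap)[3]

    def __len__(self) -> int:
        return len(self._heap)


def make_rng_streams(seed: int, labels: Sequence[str]
                     ) -> Dict[str, np.random.Generator]:
    """One independent, reproducible random stream per label.

    Each stream is seeded from (seed, CRC32(label)), so it is a
    deterministic function of the pair and statistically independent across
    labels.
    """
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    streams = {}
    for label in labels:
        key = zlib.crc32(label.encode("utf-8"))
        ss = np.random.SeedSequence(entropy=(int(seed) & 0x7FFFFFFF, key))
        streams[label] = np.random.Generator(np.random.PCG64(ss))
    return streams


def departure_jitter(rng: np.random.Generator, lam: float) -> float:
    """Mean-zero integer-hour departure offset, (K - lam) with K ~ Poisson(lam)."""
    if lam <= 0:
        return 0.0
    return float(rng.poisson(lam)) - lam


class _Shipment:
    __slots__ = ("route", "lots", "depart_time", "mass_by_crop")

    def __init__(self, route: Route, lots: List[Lot], depart_time: float):
        self.route = route
        self.lots = lots
        self.depart_time = depart_time
        self.mass_by_crop: Dict[str, float] = {}
        for lot in lots:
            self.mass_by_crop[lot.crop] = (
                self.mass_by_crop.get(lot.crop, 0.0) + lot.mass)


class _Simulation:
    """State and event handlers for one iteration."""

    def __init__(self, network: NetworkSpec, crops: Sequence[Crop],
                 config: ScenarioConfig, seed: int,
                 plan: Optional[supply.SupplyPlan] = None,
                 production_ratio: Optional[Dict[str, float]] = None):
        violations = validate_network(network)
        if violations:
            raise ValueError("invalid network:\n" + "\n".join(violations))
        self.network = network
        self.crops = {c.name: c for c in crops}
        self.crop_list = list(crops)
        self.config = config
        self.seed = int(seed)
        self.locmap = network.location_map()
        if plan is None:
            sd = supply.statewide_daily_demand(network, self.crop_list)
            plan = supply.build_supply_plan(network, self.crop_list, sd,
                                            production_ratio)
        self.plan = plan

        self.rng = make_rng_streams(self.seed,
                                    ["supply", "arrivals", "breakage",
                                     "departures"])

        # inventory[loc][crop] -> lots sorted by effective_age ascending
        self.inventory: Dict[str, Dict[str, List[Lot]]] = {
            loc.id: {c.name: [] for c in crops} for loc in network.locations}
        self.last_aged: Dict[str, float] = {loc.id: 0.0
                                            for loc in network.locations}

        # route indices
        self.village_route: Dict[str, Route] = {}
        self.retail_route: Dict[str, Route] = {}
        self.lateral_route: Dict[Tuple[str, str], Route] = {}
        for r in network.routes:
            o = self.locmap[r.origin]
            d = self.locmap[r.destination]
            if o.level == VILLAGE and d.level == WHOLESALE:
                self.village_route[o.id] = r
            elif o.level == WHOLESALE and d.level in RETAIL_LEVELS:
                self.retail_route[d.id] = r
            elif o.level == WHOLESALE and d.level == WHOLESALE:
                self.lateral_route[(o.id, d.id)] = r

        self.wholesales = sorted((l for l in network.locations
                                  if l.level == WHOLESALE), key=lambda x: x.id)
        self.tier1 = [w for w in self.wholesales if w.tier == 1]
        self.tier12 = [w for w in self.wholesales if w.tier in (1, 2)]
        self.villages = sorted((l for l in network.locations
                                if l.level == VILLAGE), key=lambda x: x.id)
        self.retailers = sorted((l for l in network.locations
                                 if l.level in RETAIL_LEVELS),
                                key=lambda x: x.id)
        self.selling = sorted((l for l in network.locations
                               if l.level in SELLING_LEVELS and
                               l.expected_daily_visits > 0),
                              key=lambda x: x.id)

        # expected local direct-sale demand kg/day per (loc, crop)
        self.local_demand: Dict[str, Dict[str, float]] = {}
        for loc in network.locations:
            self.local_demand[loc.id] = {
                c.name: loc.expected_daily_visits * c.per_capita_demand / 1000.0
                for c in crops}

        self.retailers_of: Dict[str, List[str]] = {w.id: []
                                                   for w in self.wholesales}
        for r in self.retailers:
            route = self.retail_route.get(r.id)
            if route is not None:
                self.retailers_of[route.origin].append(r.id)

        # downstream (non-export) daily demand per wholesale per crop
        self.downstream_demand: Dict[str, Dict[str, float]] = {}
        for w in self.wholesales:
            dd = dict(self.local_demand[w.id])
            for rid in self.retailers_of[w.id]:
                for c, v in self.local_demand[rid].items():
                    dd[c] += v
            self.downstream_demand[w.id] = dd

        self.in_transit_to: Dict[Tuple[str, str], float] = {}
        self.in_flight: List[_Shipment] = []

        self.result = SimulationResult(
            config=config, seed=self.seed,
            loc_levels={loc.id: loc.level for loc in network.locations})
        for c in crops:
            self.result.entered[c.name] = 0.0
            self.result.carried_in[c.name] = 0.0
            self.result.exported[c.name] = 0.0

        self.measure_start = config.burn_in * 24.0
        self.measuring = self.measure_start <= 0.0
        self.clock = 0.0
        self.queue = EventQueue()

    # ---- helpers -------------------------------------------------------

    def _insert_lot(self, loc_id: str, lot: Lot) -> None:
        insort(self.inventory[loc_id][lot.crop], lot,
               key=lambda l: l.effective_age)

    def touch(self, loc_id: str, now: float) -> None:
        """Age a location's inventory to ``now`` and remove expired lots."""
        elapsed = now - self.last_aged[loc_id]
        if elapsed <= 0:
            return
        self.last_aged[loc_id] = now
        days = elapsed / 24.0
        level = self.locmap[loc_id].level
        for crop_name, lots in self.inventory[loc_id].items():
            if not lots:
                continue
            lifespan = self.crops[crop_name].ambient_lifespan
            for lot in lots:
                lot.effective_age += days
            # expired lots sit at the tail (largest age)
            while lots and lots[-1].effective_age >= lifespan:
                lot = lots.pop()
                if self.measuring:
                    stage = storage_stage_for_level(level)
                    self.result.add_loss(crop_name, stage, MECHANISM_EXPIRED,
                                         lot.mass)
                    self.result.add_exit_sample(
                        crop_name, (now - lot.entry_time) / 24.0, lot.mass)

    def _stage_breakage(self, loc_id: str, crop_name: str, mass: float,
                        now: float) -> float:
        """One per-level handling-breakage draw on mass entering storage."""
        b = perish.draw_breakage(mass, self.config.stage_breakage_mean,
                                 self.config.unit_mass_kg, self.rng["breakage"])
        if b > 0 and self.measuring:
            stage = storage_stage_for_level(self.locmap[loc_id].level)
            self.result.add_loss(crop_name, stage, MECHANISM_BROKEN, b)
        return b

    def _ship(self, route: Route, requests: Optional[Dict[str, float]],
              now: float) -> None:
        """Load a vehicle at route.origin and dispatch it.

        ``requests`` maps crop -> kg (an order); ``None`` means push all
        stock above the origin's one-day local reserve. Senders always keep
        one day of local direct-sale demand on hand.
        """
        origin = route.origin
        self.touch(origin, now)
        candidates: List[Lot] = []
        for crop_name in sorted(self.crops):
            lots = self.inventory[origin][crop_name]
            on_hand = sum(l.mass for l in lots)
            reserve = self.local_demand[origin][crop_name]
            avail = on_hand - reserve
            if requests is not None:
                avail = min(avail, requests.get(crop_name, 0.0))
            if avail <= 1e-9:
                continue
            _, pieces = demand_mod.take_fefo(lots, avail)
            candidates.extend(pieces)
        if not candidates:
            return
        loaded, left = trade.load_vehicle(candidates, route.vehicle_volume,
                                          self.crops)
        for lot in left:
            self._insert_lot(origin, lot)
        if not loaded:
            return
        shipment = _Shipment(route, loaded, now)
        self.in_flight.append(shipment)
        for crop_name, kg in shipment.mass_by_crop.items():
            key = (route.destination, crop_name)
            self.in_transit_to[key] = self.in_transit_to.get(key, 0.0) + kg
        self.queue.schedule(Event(now + route.travel_time, "vehicle_arrival",
                                  (shipment,)), self.clock)

    def _snapshot_stock(self) -> Dict[str, float]:
        stock = {c: 0.0 for c in self.crops}
        for inv in self.inventory.values():
            for crop_name, lots in inv.items():
                for lot in lots:
                    stock[crop_name] += lot.mass
        return stock

    # ---- event handlers ------------------------------------------------

    def _on_measure_start(self, now: float) -> None:
        self.measuring = True
        stock = self._snapshot_stock()
        for s in self.in_flight:
            for crop_name, kg in s.mass_by_crop.items():
                stock[crop_name] += kg
        # in-flight mass is recorded at departure; expired/broken-in-transit
        # portions of straddling shipments are tallied on arrival, so the
        # carried-in snapshot uses the departed mass.
        for crop_name, kg in stock.items():
            self.result.carried_in[crop_name] = kg

    def _on_production(self, now: float) -> None:
        day = int(now // 24.0)
        for crop in self.crop_list:
            entries = supply.daily_entries(
                self.plan, self.network, crop, day,
                self.config.production_multiplier, self.rng["supply"],
                sigma=self.config.supply_noise_sigma)
            for vid, mass in entries:
                if mass <= 0:
                    continue
                self.touch(vid, now)
                if self.measuring:
                    self.result.entered[crop.name] += mass
                broken = self._stage_breakage(vid, crop.name, mass, now)
                if broken > 0 and self.measuring:
                    self.result.add_exit_sample(crop.name, 0.0, broken)
                net = mass - broken
                if net > 0:
                    self._insert_lot(vid, Lot(crop=crop.name, mass=net,
                                              effective_age=0.0,
                                              entry_time=now,
                                              entry_location=vid))

    def _on_imports(self, now: float) -> None:
        if not self.tier1:
            return
        day = int(now // 24.0)
        month = supply.month_of_day(day)
        mult = (self.config.production_multiplier
                if self.config.scale_imports else 1.0)
        for crop in self.crop_list:
            rate = self.plan.imports.get(crop.name, {}).get(month, 0.0) * mult
            per_market = rate / len(self.tier1)
            if per_market <= 0:
                continue
            for w in self.tier1:
                self.touch(w.id, now)
                if self.measuring:
                    self.result.entered[crop.name] += per_market
                broken = self._stage_breakage(w.id, crop.name, per_market, now)
                if broken > 0 and self.measuring:
                    self.result.add_exit_sample(crop.name, 0.0, broken)
                net = per_market - broken
                if net > 0:
                    self._insert_lot(w.id, Lot(crop=crop.name, mass=net,
                                               effective_age=0.0,
                                               entry_time=now,
                                               entry_location=w.id))

    def _on_departure(self, now: float, route: Route,
                      requests: Optional[Dict[str, float]]) -> None:
        self._ship(route, requests, now)

    def _on_arrival(self, now: float, shipment: _Shipment) -> None:
        route = shipment.route
        self.in_flight.remove(shipment)
        for crop_name, kg in shipment.mass_by_crop.items():
            key = (route.destination, crop_name)
            self.in_transit_to[key] = max(
                0.0, self.in_transit_to.get(key, 0.0) - kg)
        o_level = self.locmap[route.origin].level
        d_level = self.locmap[route.destination].level
        stage = leg_stage(o_level, d_level)
        arrived, expired, broken = trade.transit(
            shipment.lots, route, self.crops, self.rng["breakage"],
            self.config.unit_mass_kg)
        if self.measuring:
            for crop_name, kg in expired.items():
                self.result.add_loss(crop_name, stage, MECHANISM_EXPIRED, kg)
            for crop_name, kg in broken.items():
                self.result.add_loss(crop_name, stage, MECHANISM_BROKEN, kg)
        # exit samples for transit losses: use the shipment's mass-weighted
        # mean entry time for the crop (individual lot identity is lost in
        # the per-crop breakage draw)
        if self.measuring:
            for losses in (expired, broken):
                for crop_name, kg in losses.items():
                    if kg > 0:
                        days = (now - self._mean_entry(shipment, crop_name)) / 24.0
                        self.result.add_exit_sample(crop_name, days, kg)
        self.touch(route.destination, now)
        by_crop: Dict[str, List[Lot]] = {}
        for lot in arrived:
            by_crop.setdefault(lot.crop, []).append(lot)
        for crop_name in sorted(by_crop):
            lots = sorted(by_crop[crop_name], key=lambda l: l.effective_age)
            mass = sum(l.mass for l in lots)
            b = self._stage_breakage(route.destination, crop_name, mass, now)
            if b > 0:
                got, _ = demand_mod.take_fefo(lots, b)
                if self.measuring:
                    self.result.add_exit_sample(crop_name, 0.0, got)
            for lot in lots:
                if lot.mass > 0:
                    self._insert_lot(route.destination, lot)

    @staticmethod
    def _mean_entry(shipment: _Shipment, crop_name: str) -> float:
        tm = [(l.entry_time, l.mass) for l in shipment.lots
              if l.crop == crop_name]
        total = sum(m for _t, m in tm)
        if total <= 0:
            return shipment.depart_time
        return sum(t * m for t, m in tm) / total

    def _on_consumer(self, now: float, loc: Location) -> None:
        self.touch(loc.id, now)
        day = int(now // 24.0)
        n = demand_mod.consumer_arrival_count(loc, self.rng["arrivals"])
        for crop in self.crop_list:
            lots = self.inventory[loc.id][crop.name]
            n_full, sold, pieces = demand_mod.serve_batch(
                lots, n, crop.per_capita_demand)
            if self.measuring:
                self.result.tally.record(crop.name, loc.id, day, n, n_full,
                                         sold)
                for piece in pieces:
                    self.result.add_exit_sample(
                        crop.name, (now - piece.entry_time) / 24.0, piece.mass)

    def _on_export(self, now: float, w: Location) -> None:
        day = int(now // 24.0)
        month = supply.month_of_day(day)
        self.touch(w.id, now)
        for crop in self.crop_list:
            rate = self.plan.exports.get(crop.name, {}).get(month, 0.0)
            quota = rate / max(1, len(self.tier12))
            if quota <= 0:
                continue
            lots = self.inventory[w.id][crop.name]
            avail = sum(l.mass for l in lots)
            # exports are served last: keep one day of downstream
            # (local + retail) demand on hand for tomorrow morning
            reserve = self.downstream_demand[w.id][crop.name]
            take = min(quota, avail - reserve)
            if take <= 0:
                continue
            got, pieces = demand_mod.take_fefo(lots, take)
            if self.measuring:
                self.result.exported[crop.name] += got
                for piece in pieces:
                    self.result.add_exit_sample(
                        crop.name, (now - piece.entry_time) / 24.0, piece.mass)

    def _usable_on_hand(self, loc_id: str, crop: Crop) -> float:
        """Stock that will still be sellable one day from now.

        Order and trade estimates ignore lots within a day of expiring:
        a market counts only inventory it can realistically sell tomorrow.
        """
        horizon = crop.ambient_lifespan - 1.0
        return sum(l.mass for l in self.inventory[loc_id][crop.name]
                   if l.effective_age < horizon)

    def _on_review(self, now: float) -> None:
        day = int(now // 24.0)
        month = supply.month_of_day(day)
        cfg = self.config
        # shared daily estimates at wholesale markets
        estimates: Dict[str, Dict[str, trade.DemandEstimate]] = {}
        n_t12 = max(1, len(self.tier12))
        for w in self.wholesales:
            self.touch(w.id, now)
            est: Dict[str, trade.DemandEstimate] = {}
            for crop in self.crop_list:
                on_hand = self._usable_on_hand(w.id, crop)
                inbound = self.in_transit_to.get((w.id, crop.name), 0.0)
                dd = self.downstream_demand[w.id][crop.name]
                if w.tier in (1, 2):
                    dd += (self.plan.exports.get(crop.name, {})
                           .get(month, 0.0) / n_t12)
                est[crop.name] = trade.DemandEstimate(
                    daily_demand=dd, on_hand=on_hand, in_transit=inbound,
                    local_daily_demand=self.local_demand[w.id][crop.name])
            estimates[w.id] = est

        # retail orders -> fetch trips tomorrow morning
        for r in self.retailers:
            route = self.retail_route.get(r.id)
            if route is None:
                continue
            self.touch(r.id, now)
            orders: Dict[str, float] = {}
            for crop in self.crop_list:
                on_hand = self._usable_on_hand(r.id, crop)
                inbound = self.in_transit_to.get((r.id, crop.name), 0.0)
                est = trade.DemandEstimate(
                    daily_demand=self.local_demand[r.id][crop.name],
                    on_hand=on_hand, in_transit=inbound)
                qty = trade.compute_order(route.policy, est)
                if qty > 0:
                    orders[crop.name] = qty
            if orders:
                hour = (route.mean_departure_time +
                        departure_jitter(self.rng["departures"],
                                         cfg.departure_jitter_lambda))
                hour = min(23.5, max(0.5, hour))
                t = (day + 1) * 24.0 + hour
                self.queue.schedule(Event(t, "vehicle_departure",
                                          (route, orders)), self.clock)

        # lateral wholesale trade
        transfers = trade.lateral_transfers(
            self.network.wholesale_partner_graph, estimates)
        grouped: Dict[Tuple[str, str], Dict[str, float]] = {}
        for donor, recip, crop_name, kg in transfers:
            grouped.setdefault((donor, recip), {})[crop_name] = kg
        for (donor, recip), orders in sorted(grouped.items()):
            route = self.lateral_route.get((donor, recip))
            if route is None:
                d = trade.RouteDefaults()
                route = Route(origin=donor, destination=recip,
                              vehicle_volume=d.lateral_vehicle_m3,
                              travel_time=d.lateral_travel_h,
                              mean_departure_time=d.lateral_depart_hour,
                              leg_breakage_mean=d.leg_breakage_mean)
                self.lateral_route[(donor, recip)] = route
            hour = (route.mean_departure_time +
                    departure_jitter(self.rng["departures"],
                                     cfg.departure_jitter_lambda))
            hour = min(23.5, max(0.5, hour))
            t = (day + 1) * 24.0 + hour
            self.queue.schedule(Event(t, "vehicle_departure",
                                      (route, orders)), self.clock)

    def _on_sweep(self, now: float) -> None:
        for loc in self.network.locations:
            self.touch(loc.id, now)

    # ---- run -----------------------------------------------------------

    def run(self) -> SimulationResult:
        cfg = self.config
        total_days = int(math.ceil(cfg.burn_in + cfg.horizon))
        t_end = (cfg.burn_in + cfg.horizon) * 24.0
        q = self.queue

        if self.measure_start > 0:
            q.schedule(Event(self.measure_start, "measure_start"))
        for day in range(total_days):
            base = day * 24.0
            q.schedule(Event(base + cfg.production_hour, "production_entry"))
            q.schedule(Event(base + cfg.production_hour, "import_entry"))
            q.schedule(Event(base + cfg.review_hour, "daily_review"))
            for w in self.tier12:
                q.schedule(Event(base + cfg.export_hour, "export_draw", (w,)))
            q.schedule(Event(base + cfg.sweep_hour, "expiration_sweep"))
            for loc in self.selling:
                q.schedule(Event(base + loc.mean_consumer_arrival_time,
                                 "consumer_arrival", (loc,)))
            for v in self.villages:
                route = self.village_route.get(v.id)
                if route is None:
                    continue
                hour = (route.mean_departure_time +
                        departure_jitter(self.rng["departures"],
                                         cfg.departure_jitter_lambda))
                hour = min(23.5, max(0.5, hour))
                q.schedule(Event(base + hour, "vehicle_departure",
                                 (route, None)))

        while True:
            evt = q.pop()
            if evt is None or evt.time > t_end + 1e-9:
                break
            if evt.time < self.clock - 1e-9:
                raise RuntimeError("clock went backwards")
            self.clock = evt.time
            kind = evt.kind
            if kind == "measure_start":
                self._on_measure_start(evt.time)
            elif kind == "vehicle_arrival":
                self._on_arrival(evt.time, evt.payload[0])
            elif kind == "production_entry":
                self._on_production(evt.time)
            elif kind == "import_entry":
                self._on_imports(evt.time)
            elif kind == "vehicle_departure":
                self._on_departure(evt.time, evt.payload[0], evt.payload[1])
            elif kind == "daily_review":
                self._on_review(evt.time)
            elif kind == "consumer_arrival":
                self._on_consumer(evt.time, evt.payload[0])
            elif kind == "export_draw":
                self._on_export(evt.time, evt.payload[0])
            elif kind == "expiration_sweep":
                self._on_sweep(evt.time)

        # final aging/expiration pass, then snapshot what remains
        for loc in self.network.locations:
            self.touch(loc.id, t_end)
        self.result.ending_stock = self._snapshot_stock()
        ending_transit = {c: 0.0 for c in self.crops}
        for s in self.in_flight:
            for crop_name, kg in s.mass_by_crop.items():
                ending_transit[crop_name] += kg
        self.result.ending_transit = ending_transit
        return self.result


def run(network: NetworkSpec, crops: Sequence[Crop], config: ScenarioConfig,
        seed: Optional[int] = None,
        plan: Optional[supply.SupplyPlan] = None,
        production_ratio: Optional[Dict[str, float]] = None
        ) -> SimulationResult:
    """Run one iteration and return its :class:`SimulationResult`.

    ``seed`` defaults to ``config.seed``. ``plan`` (or ``production_ratio``,
    passed to :func:`vegchain.supply.build_supply_plan`) controls how much
    produce enters relative to consumer demand.
    """
    if seed is None:
        seed = config.seed
    sim = _Simulation(network, crops, config, seed, plan=plan,
                      production_ratio=production_ratio)
    return sim.run()


def run_iterations(network: NetworkSpec, crops: Sequence[Crop],
                   config: ScenarioConfig,
                   plan: Optional[supply.SupplyPlan] = None,
                   production_ratio: Optional[Dict[str, float]] = None
                   ) -> List[SimulationResult]:
    """Run ``config.iterations`` iterations with seeds seed, seed+1, ...

    Scenario metrics are reported as arithmetic means across iterations.
    """
    return [run(network, crops, config, seed=config.seed + i, plan=plan,
                production_ratio=production_ratio)
            for i in range(config.iterations)]
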