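"""Consumer arrivals, purchases and fulfillment accounting.

Each consumer arrival at a selling location requests the crop's per-capita
daily demand in grams, per crop. Inventory is dispatched first-expire-first-
out (FEFO: the lot with the highest effective age sells first). Fulfillment
is binary per crop per arrival: partial quantities are sold but the arrival
counts as unfulfilled. Demand fulfillment is the proportion of arrival
instances at which the requested crop was fully available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import Crop, Location, Lot


class NoArrivalsError(ValueError):
    """A fulfillment query whose filter scope contains no arrivals."""


@dataclass
class ArrivalTally:
    """Per (crop, location, day) arrival / fulfillment / purchase counts."""

    #: (crop, location_id, day) -> [arrivals, fulfilled, purchased_kg]
    data: Dict[Tuple[str, str, int], List[float]] = field(default_factory=dict)

    def record(self, crop: str, location: str, day: int,
               arrivals: int, fulfilled: int, purchased_kg: float) -> None:
        if fulfilled > arrivals:
            raise ValueError("fulfilled cannot exceed arrivals")
        key = (crop, location, day)
        row = self.data.setdefault(key, [0, 0, 0.0])
        row[0] += arrivals
        row[1] += fulfilled
        row[2] += purchased_kg


def consumer_arrival_count(location: Location, rng: np.random.Generator) -> int:
    """Number of consumer arrivals at a location on one day.

    Poisson with mean ``catchment_population * direct_sale_fraction``
    (one consumer visit per served person per day).
    """
    mean = location.expected_daily_visits
    if mean <= 0:
        return 0
    return int(rng.poisson(mean))


def arrival_times(count: int, mean_hour: float, rng: np.random.Generator,
                  half_width_hours: float = 3.0) -> np.ndarray:
    """Clock hours for a day's arrivals, uniform around the mean market hour."""
    if count <= 0:
        return np.empty(0)
    return np.sort(rng.uniform(mean_hour - half_width_hours,
                               mean_hour + half_width_hours, size=count))


def take_fefo(lots: List[Lot], mass: float) -> Tuple[float, List[Lot]]:
    """Remove up to ``mass`` kg from an inventory, oldest effective age first.

    ``lots`` must be sorted by effective_age ascending (the engine maintains
    this); removal pops from the end. Returns (mass removed, removed pieces);
    a boundary lot is split.
    """
    taken = 0.0
    pieces: List[Lot] = []
    while lots and taken < mass - 1e-12:
        lot = lots[-1]
        need = mass - taken
        if lot.mass <= need + 1e-12:
            pieces.append(lots.pop())
            taken += pieces[-1].mass
        else:
            piece = Lot(crop=lot.crop, mass=need, effective_age=lot.effective_age,
                        entry_time=lot.entry_time, entry_location=lot.entry_location)
            lot.mass -= need
            pieces.append(piece)
            taken += need
    return taken, pieces


def serve_arrival(inventory: Dict[str, List[Lot]],
                  requested_grams: Dict[str, float],
                  partial: bool = True
                  ) -> Tuple[Dict[str, float], Dict[str, bool]]:
    """Serve one consumer arrival requesting several crops.

    Inventory lots (sorted by effective_age ascending per crop) are drawn
    FEFO. The fulfilled flag is true only when the full requested quantity
    was served; with ``partial`` (the default) whatever is available is
    still sold.
    """
    served: Dict[str, float] = {}
    fulfilled: Dict[str, bool] = {}
    for crop, grams in requested_grams.items():
        if grams < 0:
            raise ValueError("requested quantity must be >= 0")
        want_kg = grams / 1000.0
        lots = inventory.get(crop, [])
        available = sum(l.mass for l in lots)
        if want_kg == 0:
            served[crop] = 0.0
            fulfilled[crop] = True
            continue
        if available + 1e-12 >= want_kg:
            got, _ = take_fefo(lots, want_kg)
            served[crop] = got
            fulfilled[crop] = True
        elif partial:
            got, _ = take_fefo(lots, available)
            served[crop] = got
            fulfilled[crop] = False
        else:
            served[crop] = 0.0
            fulfilled[crop] = False
    return served, fulfilled


def serve_batch(lots: List[Lot], arrivals: int, per_arrival_grams: float
                ) -> Tuple[int, float, List[Lot]]:
    """Serve a day's batch of identical arrivals for one crop, FEFO.

    Equivalent to serving ``arrivals`` consumers sequentially at one
    instant: the first ``floor(available / request)`` are fully served, at
    most one receives a partial quantity (counted unfulfilled).

    Returns (fulfilled count, mass sold kg, the lot pieces sold).
    """
    if arrivals <= 0 or per_arrival_grams <= 0:
        return (arrivals if per_arrival_grams <= 0 else 0), 0.0, []
    req_kg = per_arrival_grams / 1000.0
    available = sum(l.mass for l in lots)
    want_total = arrivals * req_kg
    sell = min(want_total, available)
    n_full = min(arrivals, int((available + 1e-9) / req_kg))
    got, pieces = take_fefo(lots, sell)
    return n_full, got, pieces


def fulfillment_fraction(tally: ArrivalTally,
                         crop: Optional[str] = None,
                         level: Optional[str] = None,
                         locations: Optional[Iterable[str]] = None,
                         days: Optional[Tuple[int, int]] = None,
                         loc_levels: Optional[Dict[str, str]] = None) -> float:
    """Fulfilled / arrivals over a filtered scope of the tally.

    ``days`` is an inclusive (first, last) range. Filtering by ``level``
    requires ``loc_levels`` (location id -> level). Raises
    :class:`NoArrivalsError` when the scope contains no arrivals (undefined,
    distinct from a fulfillment of zero).
    """
    if level is not None and loc_levels is None:
        raise ValueError("filtering by level requires loc_levels")
    locset = set(locations) if locations is not None else None
    arr = 0.0
    ful = 0.0
    for (c, loc, day), (a, f, _m) in tally.data.items():
        if crop is not None and c != crop:
            continue
        if locset is not None and loc not in locset:
            continue
        if level is not None and loc_levels.get(loc) != level:
            continue
        if days is not None and not (days[0] <= day <= days[1]):
            continue
        arr += a
        ful += f
    if arr == 0:
        raise NoArrivalsError("no arrivals in the filtered scope")
    return ful / arr
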