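"""Aging, expiration and breakage — the two loss mechanisms.

Produce degrades at a linear rate until it reaches its maximum ambient
lifespan; time in cold storage slows the aging rate by a crop-specific
factor. Breakage (bruising, spills, mishandling) is Poisson-distributed
with a configurable mean fraction per storage stage or transport leg.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

from .core import Crop, Lot

AMBIENT = "ambient"
COLD = "cold"
TRANSIT = "transit"


def effective_aging_rate(storage_kind: str, crop: Crop) -> float:
    """Days of effective age accrued per elapsed day in the given storage.

    Ambient storage and transit age at rate 1; cold storage ages at the
    crop's ``cold_aging_factor``.
    """
    if storage_kind in (AMBIENT, TRANSIT):
        return 1.0
    if storage_kind == COLD:
        return crop.cold_aging_factor
    raise ValueError(f"unknown storage kind {storage_kind!r}")


def age_lots(lots: Iterable[Lot], elapsed_hours: float, storage_kind: str,
             crops: Dict[str, Crop]) -> None:
    """Advance each lot's effective age by ``elapsed_hours`` of storage.

    Mass is unchanged. Mutates the lots in place.
    """
    if elapsed_hours < 0:
        raise ValueError("elapsed time must be >= 0")
    if elapsed_hours == 0:
        return
    days = elapsed_hours / 24.0
    for lot in lots:
        rate = effective_aging_rate(storage_kind, crops[lot.crop])
        lot.effective_age += days * rate


def remove_expired(lots: Iterable[Lot],
                   crops: Dict[str, Crop]) -> Tuple[List[Lot], Dict[str, float]]:
    """Split an inventory into survivors and expired mass per crop.

    A lot expires once its effective age reaches the crop lifespan (closed
    boundary: age == lifespan is expired). Mass is conserved between the
    two outputs.
    """
    survivors: List[Lot] = []
    expired: Dict[str, float] = {}
    for lot in lots:
        if lot.effective_age >= crops[lot.crop].ambient_lifespan:
            expired[lot.crop] = expired.get(lot.crop, 0.0) + lot.mass
        else:
            survivors.append(lot)
    return survivors, expired


def draw_breakage(mass: float, mean_rate: float, unit_mass: float,
                  rng: np.random.Generator) -> float:
    """Draw the broken mass for one handling stage or transport leg.

    Mass is discretised into units of ``unit_mass`` kg; the number of broken
    units is Poisson with mean ``mean_rate * mass / unit_mass``, capped so
    breakage never exceeds the mass handled.
    """
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if not (0.0 <= mean_rate < 1.0):
        raise ValueError("mean_rate must be in [0, 1)")
    if unit_mass <= 0:
        raise ValueError("unit_mass must be > 0")
    if mass == 0 or mean_rate == 0:
        return 0.0
    units_handled = mass / unit_mass
    broken_units = rng.poisson(mean_rate * units_handled)
    broken = min(broken_units * unit_mass, mass)
    return float(broken)
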