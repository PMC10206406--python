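"""Outcome metrics: demand fulfillment, loss accounting, time through chain.

Three outcome families are computed from a :class:`SimulationResult`:

* **demand fulfillment** — the proportion of consumer-arrival instances at
  which the requested crop was fully available (see
  :func:`vegchain.demand.fulfillment_fraction`);
* **total loss** — mass lost (expired + broken) as a fraction of the mass
  that entered the chain, disaggregated by mechanism, by supply chain
  stage, and by storage versus transport;
* **time through chain** — mass-weighted statistics of the days between a
  unit of mass entering and exiting the chain (consumption, export or loss).

All fractions are mass-based; exports count as successful exits, not
losses. The master invariant is mass conservation: everything that entered
(plus stock carried in at the burn-in boundary) is accounted for by
purchases, exports, losses, ending stock and ending in-transit mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (ALL_STAGES, MECHANISM_BROKEN, MECHANISM_EXPIRED,
                   RETAIL_LEVELS, STORAGE_STAGES, TRANSPORT_STAGES)
from .demand import NoArrivalsError, fulfillment_fraction
from .results import SimulationResult


@dataclass
class LossBreakdown:
    """Per-crop loss fractions of the mass that entered the chain."""

    crop: str
    total: float
    by_mechanism: Dict[str, float]
    by_stage: Dict[str, float]
    storage: float
    transport: float
    entered_kg: float

    def __post_init__(self):
        for frac in [self.total, self.storage, self.transport,
                     *self.by_mechanism.values(), *self.by_stage.values()]:
            if not (-1e-9 <= frac <= 1.0 + 1e-9):
                raise ValueError("loss fraction outside [0, 1]")


def _denominator(result: SimulationResult, crop: str) -> float:
    # carried-in stock can still be lost inside the measured window, so it
    # belongs in the denominator alongside newly entered mass
    return result.entered.get(crop, 0.0) + result.carried_in.get(crop, 0.0)


def loss_breakdown(result: SimulationResult, crop: str) -> LossBreakdown:
    """Disaggregate a crop's losses by mechanism, stage and storage/transport."""
    denom = _denominator(result, crop)
    if denom <= 0:
        raise ValueError(f"{crop}: no mass entered the supply chain")
    by_stage = {s: 0.0 for s in ALL_STAGES}
    by_mech = {MECHANISM_EXPIRED: 0.0, MECHANISM_BROKEN: 0.0}
    for (c, stage, mech), kg in result.losses.items():
        if c != crop:
            continue
        by_stage[stage] += kg / denom
        by_mech[mech] += kg / denom
    storage = sum(by_stage[s] for s in STORAGE_STAGES)
    transport = sum(by_stage[s] for s in TRANSPORT_STAGES)
    return LossBreakdown(crop=crop, total=storage + transport,
                         by_mechanism=by_mech, by_stage=by_stage,
                         storage=storage, transport=transport,
                         entered_kg=denom)


def mass_balance_residual(result: SimulationResult, crop: str) -> float:
    """Conservation audit in kg; ~0 (|residual| <= 1e-6 x entered) on any run.

    entered + carried_in = purchased + exported + expired + broken
                           + ending stock + ending in-transit
    """
    inflow = result.entered.get(crop, 0.0) + result.carried_in.get(crop, 0.0)
    losses = result.total_loss_kg(crop)
    outflow = (result.purchased_kg(crop) + result.exported.get(crop, 0.0)
               + losses + result.ending_stock.get(crop, 0.0)
               + result.ending_transit.get(crop, 0.0))
    return inflow - outflow


@dataclass
class ChainTimeStats:
    """Mass-weighted time-through-chain statistics for one crop, in days."""

    crop: str
    mean: float
    max: float
    quantiles: Dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.mean <= self.max + 1e-12):
            raise ValueError("need 0 <= mean <= max")


def time_in_chain_stats(result: SimulationResult, crop: str,
                        quantiles: Sequence[float] = (0.5, 0.9)
                        ) -> ChainTimeStats:
    """Mass-weighted mean, max and quantiles of days between entry and exit."""
    samples = result.chain_time.get(crop, [])
    if not samples:
        raise ValueError(f"{crop}: no exit samples")
    days = np.array([t for t, _m in samples])
    mass = np.array([m for _t, m in samples])
    mean = float(np.average(days, weights=mass))
    order = np.argsort(days)
    days_s, mass_s = days[order], mass[order]
    cum = np.cumsum(mass_s) / mass_s.sum()
    qs = {q: float(days_s[np.searchsorted(cum, q)])
          if q <= cum[-1] else float(days_s[-1]) for q in quantiles}
    return ChainTimeStats(crop=crop, mean=mean, max=float(days.max()),
                          quantiles=qs)


def retail_fulfillment(result: SimulationResult, crop: str) -> float:
    """Demand fulfillment at the retail level for one crop."""
    levels = result.loc_levels
    locs = [lid for lid, lev in levels.items() if lev in RETAIL_LEVELS]
    return fulfillment_fraction(result.tally, crop=crop, locations=locs)


def scenario_summary(results_by_multiplier: Mapping[float,
                                                    Sequence[SimulationResult]]
                     ) -> pd.DataFrame:
    """One row per (multiplier, crop), averaged over iterations.

    Columns: multiplier, crop, entered_kg, retail_fulfillment, total_loss,
    expiration_loss, breakage_loss, storage_loss, transport_loss (fractions
    of entered mass).
    """
    rows = []
    for mult in sorted(results_by_multiplier):
        results = results_by_multiplier[mult]
        crops = sorted({c for r in results for c in r.entered})
        for crop in crops:
            ffs, tots, exps, brks, stos, tras, ents = [], [], [], [], [], [], []
            for r in results:
                lb = loss_breakdown(r, crop)
                tots.append(lb.total)
                exps.append(lb.by_mechanism[MECHANISM_EXPIRED])
                brks.append(lb.by_mechanism[MECHANISM_BROKEN])
                stos.append(lb.storage)
                tras.append(lb.transport)
                ents.append(r.entered.get(crop, 0.0))
                try:
                    ffs.append(retail_fulfillment(r, crop))
                except NoArrivalsError:
                    pass
            rows.append({
                "multiplier": mult,
                "crop": crop,
                "entered_kg": float(np.mean(ents)),
                "retail_fulfillment": float(np.mean(ffs)) if ffs else np.nan,
                "total_loss": float(np.mean(tots)),
                "expiration_loss": float(np.mean(exps)),
                "breakage_loss": float(np.mean(brks)),
                "storage_loss": float(np.mean(stos)),
                "transport_loss": float(np.mean(tras)),
            })
    return pd.DataFrame(rows)
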