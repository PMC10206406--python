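"""Entry of vegetables into the chain.

Village-market production follows a per-crop annual rate distributed across
villages by catchment population and across the year by normalised monthly
season weights, scaled by the scenario's production multiplier with
lognormal day-to-day noise. State-level imports and exports keep the chain
in approximate equilibrium with consumer demand month by month: monthly
deficits are imported at Tier-1 wholesale markets, monthly surpluses are
exported from Tier-1/2 markets to an external sink.

The simulated calendar uses twelve 30-day months; day ``d`` (0-based) falls
in month ``(d // 30) % 12 + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (VILLAGE, WHOLESALE, SELLING_LEVELS, Crop, NetworkSpec,
                   ScenarioConfig)

DAYS_PER_MONTH = 30


def month_of_day(day: int) -> int:
    """Calendar month (1..12) of a 0-based simulation day; 30-day months."""
    return (int(day) // DAYS_PER_MONTH) % 12 + 1


def seasonal_weight(crop: Crop, month: int) -> float:
    """Monthly production weight normalised so the 12-month mean is 1."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    w = np.asarray(crop.season_weights, dtype=float)
    mean = w.mean()
    if mean == 0:
        raise ValueError(f"{crop.name}: all season weights are zero")
    return float(w[month - 1] / mean)


def statewide_daily_demand(network: NetworkSpec,
                           crops: List[Crop]) -> Dict[str, float]:
    """Expected kg/day of consumer demand per crop across all selling nodes."""
    visits = sum(loc.expected_daily_visits for loc in network.locations
                 if loc.level in SELLING_LEVELS)
    return {c.name: visits * c.per_capita_demand / 1000.0 for c in crops}


@dataclass
class SupplyPlan:
    """Expected daily production, import and export rates.

    ``production`` maps crop -> village id -> annual-mean kg/day (the
    seasonal weight is applied at draw time). ``imports`` and ``exports``
    map crop -> month -> statewide kg/day.
    """

    production: Dict[str, Dict[str, float]]
    imports: Dict[str, Dict[int, float]]
    exports: Dict[str, Dict[int, float]]
    statewide_demand: Dict[str, float]

    def monthly_production(self, crop: Crop, month: int) -> float:
        """Statewide expected production kg/day of ``crop`` in ``month``."""
        base = sum(self.production.get(crop.name, {}).values())
        return base * seasonal_weight(crop, month)


def build_supply_plan(network: NetworkSpec, crops: List[Crop],
                      statewide_demand: Dict[str, float],
                      production_ratio: Optional[Dict[str, float]] = None
                      ) -> SupplyPlan:
    """Construct the equilibrium supply plan.

    Annual-mean statewide production of each crop is
    ``production_ratio[crop] * statewide_demand[crop]`` (ratio defaults
    to 1), split across village markets proportionally to catchment
    population. For each month, any gap between seasonal production and the
    (constant) demand is closed by imports at Tier-1 markets; any surplus is
    exported from Tier-1/2 markets, so that supply equals demand every month.
    """
    production_ratio = production_ratio or {}
    villages = [loc for loc in network.locations if loc.level == VILLAGE]
    if not villages:
        raise ValueError("network has no village markets")
    tier1 = [loc for loc in network.locations
             if loc.level == WHOLESALE and loc.tier == 1]

    pop = np.array([v.catchment_population for v in villages], dtype=float)
    if pop.sum() <= 0:
        pop = np.ones(len(villages))
    shares = pop / pop.sum()

    production: Dict[str, Dict[str, float]] = {}
    imports: Dict[str, Dict[int, float]] = {}
    exports: Dict[str, Dict[int, float]] = {}

    for crop in crops:
        demand = statewide_demand[crop.name]
        if demand <= 0:
            raise ValueError(f"{crop.name}: statewide demand must be > 0")
        ratio = production_ratio.get(crop.name, 1.0)
        base = ratio * demand  # annual-mean kg/day
        production[crop.name] = {
            v.id: base * s for v, s in zip(villages, shares)}
        imports[crop.name] = {}
        exports[crop.name] = {}
        for month in range(1, 13):
            prod_m = base * seasonal_weight(crop, month)
            gap = demand - prod_m
            if gap > 0:
                if not tier1:
                    raise ValueError(
                        f"{crop.name}: imports needed in month {month} but "
                        "network has no Tier-1 wholesale market")
                imports[crop.name][month] = gap
                exports[crop.name][month] = 0.0
            else:
                imports[crop.name][month] = 0.0
                exports[crop.name][month] = -gap

    return SupplyPlan(production=production, imports=imports, exports=exports,
                      statewide_demand=dict(statewide_demand))


def daily_entries(plan: SupplyPlan, network: NetworkSpec, crop: Crop,
                  day: int, multiplier: float, rng: np.random.Generator,
                  sigma: float = 0.1) -> List[Tuple[str, float]]:
    """Masses entering at each village market on one day.

    Each village receives ``multiplier * rate * seasonal_weight * noise``
    where the noise is lognormal with unit mean (``exp(N(-sigma^2/2,
    sigma))``); ``sigma=0`` disables it.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    month = month_of_day(day)
    w = seasonal_weight(crop, month)
    rates = plan.production.get(crop.name, {})
    out: List[Tuple[str, float]] = []
    for vid in sorted(rates):
        base = rates[vid]
        if sigma > 0:
            noise = float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
        else:
            noise = 1.0
        out.append((vid, multiplier * base * w * noise))
    return out
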