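"""Result container for one simulation iteration."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .core import ScenarioConfig
from .demand import ArrivalTally


@dataclass
class SimulationResult:
    """Event tallies from one iteration, accumulated after burn-in.

    All masses are kg. ``losses`` is keyed (crop, stage, mechanism) with
    stages from :mod:`vegchain.core` and mechanisms ``"expired"`` /
    ``"broken"``. ``chain_time`` holds (days-in-chain, kg) samples for every
    unit of mass exiting the chain (consumption, export or loss).
    ``carried_in`` is the stock on hand and in transit at the burn-in
    boundary, needed to close the mass balance over the measured window.
    """

    tally: ArrivalTally = field(default_factory=ArrivalTally)
    losses: Dict[Tuple[str, str, str], float] = field(default_factory=dict)
    entered: Dict[str, float] = field(default_factory=dict)
    carried_in: Dict[str, float] = field(default_factory=dict)
    exported: Dict[str, float] = field(default_factory=dict)
    ending_stock: Dict[str, float] = field(default_factory=dict)
    ending_transit: Dict[str, float] = field(default_factory=dict)
    chain_time: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)
    loc_levels: Dict[str, str] = field(default_factory=dict)
    config: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0

    def add_loss(self, crop: str, stage: str, mechanism: str, kg: float) -> None:
        if kg < 0:
            raise ValueError("loss mass must be >= 0")
        if kg == 0:
            return
        key = (crop, stage, mechanism)
        self.losses[key] = self.losses.get(key, 0.0) + kg

    def add_exit_sample(self, crop: str, days: float, kg: float) -> None:
        if kg <= 0:
            return
        self.chain_time.setdefault(crop, []).append((days, kg))

    def total_loss_kg(self, crop: str) -> float:
        return sum(v for (c, _s, _m), v in self.losses.items() if c == crop)

    def purchased_kg(self, crop: str) -> float:
        return sum(row[2] for (c, _l, _d), row in self.tally.data.items()
                   if c == crop)
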