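"""File formats: network / crop tables, scenario config, result tables.

All tables are plain comma-separated UTF-8 text with a header row, so they
are human-diffable and language-neutral:

* ``locations.csv`` — id, level, tier, lat, lon, population,
  direct_sale_fraction, storage_volume_m3, arrival_hour
* ``routes.csv`` — origin, destination, vehicle_m3, travel_h, depart_hour,
  quantity_mode, frequency_mode, initiator, persistence, review_period_d,
  safety_stock_d, fixed_quantity_kg, leg_breakage_mean
* ``partners.csv`` — a, b (undirected wholesale trading edges)
* ``crops.csv`` — name, lifespan_d, density_kg_m3, demand_g_capita_d,
  cold_factor, m1..m12
* results — ``tallies.csv`` (per crop/location/day arrivals, fulfilled,
  purchased_kg), ``losses.csv`` (per crop/stage/mechanism kg),
  ``summary.csv`` (scenario summary), ``manifest.json``

Unknown columns are ignored with a logged warning.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import (Crop, Location, NetworkSpec, OrderingPolicy, Route,
                   ScenarioConfig, validate_network)
from .results import SimulationResult

log = logging.getLogger(__name__)

_LOC_COLS = ["id", "level", "tier", "lat", "lon", "population",
             "direct_sale_fraction", "storage_volume_m3", "arrival_hour"]
_ROUTE_COLS = ["origin", "destination", "vehicle_m3", "travel_h",
               "depart_hour", "quantity_mode", "frequency_mode", "initiator",
               "persistence", "review_period_d", "safety_stock_d",
               "fixed_quantity_kg", "leg_breakage_mean"]


class TableFormatError(ValueError):
    """A table is missing required columns or contains malformed values."""


def _require(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{name}: missing required column(s) "
                               f"{', '.join(missing)}")


def _warn_unknown(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    unknown = [c for c in df.columns if c not in cols]
    if unknown:
        log.warning("%s: ignoring unknown column(s) %s", name,
                    ", ".join(unknown))


def write_network_tables(spec: NetworkSpec, directory) -> Dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    loc_rows = []
    for loc in spec.locations:
        loc_rows.append({
            "id": loc.id, "level": loc.level,
            "tier": "" if loc.tier is None else loc.tier,
            "lat": loc.lat, "lon": loc.lon,
            "population": loc.catchment_population,
            "direct_sale_fraction": loc.direct_sale_fraction,
            "storage_volume_m3": ("" if math.isinf(loc.storage_volume)
                                  else loc.storage_volume),
            "arrival_hour": loc.mean_consumer_arrival_time})
    route_rows = []
    for r in spec.routes:
        route_rows.append({
            "origin": r.origin, "destination": r.destination,
            "vehicle_m3": r.vehicle_volume, "travel_h": r.travel_time,
            "depart_hour": r.mean_departure_time,
            "quantity_mode": r.policy.quantity_mode,
            "frequency_mode": r.policy.frequency_mode,
            "initiator": r.policy.initiator,
            "persistence": r.policy.persistence,
            "review_period_d": r.policy.review_period,
            "safety_stock_d": r.policy.safety_stock,
            "fixed_quantity_kg": r.policy.fixed_quantity_kg,
            "leg_breakage_mean": r.leg_breakage_mean})
    paths = {
        "locations": directory / "locations.csv",
        "routes": directory / "routes.csv",
        "partners": directory / "partners.csv",
    }
    # %.17g preserves float64 exactly across the text round-trip
    pd.DataFrame(loc_rows, columns=_LOC_COLS).to_csv(
        paths["locations"], index=False, float_format="%.17g")
    pd.DataFrame(route_rows, columns=_ROUTE_COLS).to_csv(
        paths["routes"], index=False, float_format="%.17g")
    pd.DataFrame(spec.wholesale_partner_graph, columns=["a", "b"]).to_csv(
        paths["partners"], index=False)
    return paths


def read_network_tables(directory) -> NetworkSpec:
    """Read a network from ``locations.csv``/``routes.csv``/``partners.csv``.

    Raises :class:`TableFormatError` on missing columns or malformed values;
    structural problems (dangling references etc.) are reported through
    :func:`vegchain.core.validate_network` by the caller.
    """
    directory = Path(directory)
    loc_path = directory / "locations.csv"
    route_path = directory / "routes.csv"
    if not loc_path.exists() or not route_path.exists():
        raise TableFormatError(
            f"{directory}: need locations.csv and routes.csv")
    locs_df = pd.read_csv(loc_path, dtype={"id": str},
                          float_precision="round_trip")
    _require(locs_df, ["id", "level", "lat", "lon"], "locations.csv")
    _warn_unknown(locs_df, _LOC_COLS, "locations.csv")
    routes_df = pd.read_csv(route_path, dtype={"origin": str,
                                               "destination": str},
                            float_precision="round_trip")
    _require(routes_df, ["origin", "destination", "vehicle_m3", "travel_h"],
             "routes.csv")
    _warn_unknown(routes_df, _ROUTE_COLS, "routes.csv")

    locations: List[Location] = []
    for _, row in locs_df.iterrows():
        tier = row.get("tier")
        tier = None if tier is None or pd.isna(tier) or tier == "" else int(tier)
        storage = row.get("storage_volume_m3")
        storage = (math.inf if storage is None or pd.isna(storage)
                   or storage == "" else float(storage))
        lat, lon = float(row["lat"]), float(row["lon"])
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise TableFormatError(
                f"locations.csv: malformed coordinate for {row['id']}")
        locations.append(Location(
            id=str(row["id"]), level=str(row["level"]), tier=tier,
            lat=lat, lon=lon,
            catchment_population=float(row.get("population", 0.0) or 0.0),
            direct_sale_fraction=float(row.get("direct_sale_fraction", 0.0)
                                       or 0.0),
            storage_volume=storage,
            mean_consumer_arrival_time=float(row.get("arrival_hour", 12.0)
                                             or 12.0)))

    def _get(row, col, default):
        v = row.get(col)
        return default if v is None or (isinstance(v, float) and pd.isna(v)) \
            else v

    routes: List[Route] = []
    for _, row in routes_df.iterrows():
        policy = OrderingPolicy(
            quantity_mode=str(_get(row, "quantity_mode", "variable")),
            frequency_mode=str(_get(row, "frequency_mode", "fixed")),
            initiator=str(_get(row, "initiator", "supplier_delivers")),
            persistence=str(_get(row, "persistence", "persistent")),
            review_period=float(_get(row, "review_period_d", 1.0)),
            safety_stock=float(_get(row, "safety_stock_d", 2.0)),
            fixed_quantity_kg=float(_get(row, "fixed_quantity_kg", 0.0)))
        routes.append(Route(
            origin=str(row["origin"]), destination=str(row["destination"]),
            vehicle_volume=float(row["vehicle_m3"]),
            travel_time=float(row["travel_h"]),
            mean_departure_time=float(_get(row, "depart_hour", 6.0)),
            policy=policy,
            leg_breakage_mean=float(_get(row, "leg_breakage_mean", 0.02))))

    partners = []
    partners_path = directory / "partners.csv"
    if partners_path.exists():
        pdf = pd.read_csv(partners_path, dtype=str)
        _require(pdf, ["a", "b"], "partners.csv")
        partners = [(str(a), str(b)) for a, b in zip(pdf["a"], pdf["b"])]

    return NetworkSpec(locations=locations, routes=routes,
                       wholesale_partner_graph=partners)


def write_crops(crops: Sequence[Crop], path) -> Path:
    path = Path(path)
    rows = []
    for c in crops:
        row = {"name": c.name, "lifespan_d": c.ambient_lifespan,
               "density_kg_m3": c.bulk_density,
               "demand_g_capita_d": c.per_capita_demand,
               "cold_factor": c.cold_aging_factor}
        row.update({f"m{i+1}": w for i, w in enumerate(c.season_weights)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_crops(path) -> List[Crop]:
    df = pd.read_csv(path)
    _require(df, ["name", "lifespan_d", "density_kg_m3",
                  "demand_g_capita_d"], "crops.csv")
    crops = []
    for _, row in df.iterrows():
        weights = tuple(float(row.get(f"m{i}", 1.0)) for i in range(1, 13))
        crops.append(Crop(
            name=str(row["name"]),
            ambient_lifespan=float(row["lifespan_d"]),
            bulk_density=float(row["density_kg_m3"]),
            per_capita_demand=float(row["demand_g_capita_d"]),
            season_weights=weights,
            cold_aging_factor=float(row.get("cold_factor", 1.0))))
    return crops


def read_scenario_config(path) -> ScenarioConfig:
    """Read a scenario config from a YAML mapping of ScenarioConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TableFormatError(f"{path}: config must be a mapping")
    valid = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise TableFormatError(
            f"{path}: unknown config key(s) {', '.join(sorted(unknown))}")
    return ScenarioConfig(**raw)


def tallies_frame(result: SimulationResult) -> pd.DataFrame:
    rows = [{"crop": c, "location": loc, "day": day, "arrivals": int(a),
             "fulfilled": int(f), "purchased_kg": m}
            for (c, loc, day), (a, f, m) in sorted(result.tally.data.items())]
    return pd.DataFrame(rows, columns=["crop", "location", "day", "arrivals",
                                       "fulfilled", "purchased_kg"])


def losses_frame(result: SimulationResult) -> pd.DataFrame:
    rows = [{"crop": c, "stage": s, "mechanism": m, "kg": kg}
            for (c, s, m), kg in sorted(result.losses.items())]
    return pd.DataFrame(rows, columns=["crop", "stage", "mechanism", "kg"])


def write_results(results: Sequence[SimulationResult],
                  summary: Optional[pd.DataFrame], directory,
                  config: Optional[ScenarioConfig] = None,
                  wall_time_s: Optional[float] = None) -> Dict[str, List[str]]:
    """Write per-iteration tallies and losses, the summary, and a manifest.

    Returns the manifest mapping of file kinds to paths; every referenced
    file exists on return.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "software": f"vegchain {__version__}",
        "seeds": [r.seed for r in results],
        "wall_time_s": wall_time_s,
    }
    if config is not None:
        manifest["config"] = {k: getattr(config, k)
                              for k in ScenarioConfig.__dataclass_fields__}
    tally_files, loss_files = [], []
    for r in results:
        tpath = directory / f"tallies_seed{r.seed}.csv"
        lpath = directory / f"losses_seed{r.seed}.csv"
        tallies_frame(r).to_csv(tpath, index=False)
        losses_frame(r).to_csv(lpath, index=False)
        tally_files.append(str(tpath))
        loss_files.append(str(lpath))
    manifest["tally_files"] = tally_files
    manifest["loss_files"] = loss_files
    if summary is not None:
        spath = directory / "summary.csv"
        summary.to_csv(spath, index=False)
        manifest["summary_file"] = str(spath)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def export_geojson(spec: NetworkSpec, path) -> Path:
    """Optional GeoJSON export of locations for mapping."""
    features = []
    for loc in spec.locations:
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [loc.lon, loc.lat]},
            "properties": {"id": loc.id, "level": loc.level,
                           "tier": loc.tier,
                           "population": loc.catchment_population}})
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
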