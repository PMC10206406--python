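import numpy as np
import pytest

import vegchain as vc
from vegchain.core import (Crop, Location, Lot, OrderingPolicy, Route,
                           RETAILER, VILLAGE, WHOLESALE, validate_network,
                           NetworkSpec)
from vegchain.trade import (DemandEstimate, assign_nearest_partners,
                            compute_order, haversine_km, lateral_transfers,
                            load_vehicle, transit)


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((20.0, 85.0), (20.0, 85.0)) == 0.0

    def test_one_degree_of_longitude_at_equator(self):
        # 2 * pi * 6371 / 360
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
            111.19, abs=0.01)

    def test_symmetry(self):
        a, b = (19.3, 84.9), (21.7, 86.2)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))


def _loc(id, level, lat, lon, tier=None):
    return Location(id=id, level=level, lat=lat, lon=lon, tier=tier,
                    catchment_population=1000, direct_sale_fraction=0.05)


class TestNearestPartners:
    def test_village_routes_to_closest_wholesale(self):
        locs = [_loc("v0", VILLAGE, 20.0, 85.0),
                _loc("wA", WHOLESALE, 20.0, 85.05, tier=1),   # ~5 km
                _loc("wB", WHOLESALE, 20.0, 85.10, tier=2)]   # ~10 km
        routes, _ = assign_nearest_partners(locs)
        village_routes = [r for r in routes if r.origin == "v0"]
        assert len(village_routes) == 1
        assert village_routes[0].destination == "wA"

    def test_equidistant_tie_broken_by_lower_id(self):
        locs = [_loc("v0", VILLAGE, 20.0, 85.0),
                _loc("wA", WHOLESALE, 20.0, 85.05, tier=1),
                _loc("wB", WHOLESALE, 20.0, 84.95, tier=1)]
        routes, _ = assign_nearest_partners(locs)
        assert [r for r in routes if r.origin == "v0"][0].destination == "wA"

    def test_generated_network_satisfies_structural_invariants(self):
        net = vc.generate_network(vc.GeneratorParams(
            n_village=20, n_tier1=1, n_tier2=2, n_tier3=5,
            retailers_per_wholesale=3, seed=9))
        assert validate_network(net) == []

    def test_no_wholesale_markets_is_an_error(self):
        with pytest.raises(ValueError):
            assign_nearest_partners([_loc("v0", VILLAGE, 20.0, 85.0)])


class TestComputeOrder:
    def test_covered_position_orders_nothing(self):
        policy = OrderingPolicy(review_period=1.0, safety_stock=1.0)
        est = DemandEstimate(daily_demand=100.0, on_hand=250.0, in_transit=0.0)
        assert compute_order(policy, est) == 0.0

    def test_order_up_to_arithmetic(self):
        policy = OrderingPolicy(review_period=1.0, safety_stock=1.0)
        est = DemandEstimate(daily_demand=100.0, on_hand=50.0, in_transit=0.0)
        assert compute_order(policy, est) == 150.0

    def test_in_transit_counts_toward_position(self):
        policy = OrderingPolicy(review_period=1.0, safety_stock=1.0)
        est = DemandEstimate(daily_demand=100.0, on_hand=50.0,
                             in_transit=100.0)
        assert compute_order(policy, est) == 50.0

    def test_fixed_mode_ships_constant_when_triggered(self):
        policy = OrderingPolicy(quantity_mode="fixed", safety_stock=1.0,
                                fixed_quantity_kg=500.0)
        low = DemandEstimate(daily_demand=100.0, on_hand=50.0, in_transit=0.0)
        high = DemandEstimate(daily_demand=100.0, on_hand=200.0,
                              in_transit=0.0)
        assert compute_order(policy, low) == 500.0
        assert compute_order(policy, high) == 0.0


class TestLateralTransfers:
    def test_balanced_markets_trade_nothing(self):
        est = {m: {"c": DemandEstimate(daily_demand=100.0, on_hand=300.0,
                                       in_transit=0.0,
                                       local_daily_demand=10.0)}
               for m in ("A", "B")}
        assert lateral_transfers([("A", "B")], est) == []

    def test_deficit_pulls_from_partner_surplus(self):
        est = {
            "A": {"c": DemandEstimate(daily_demand=100.0, on_hand=600.0,
                                      in_transit=0.0,
                                      local_daily_demand=100.0)},
            "B": {"c": DemandEstimate(daily_demand=100.0, on_hand=50.0,
                                      in_transit=0.0,
                                      local_daily_demand=10.0)},
        }
        # B's position (50) is under one day of demand; it asks its partner
        # to top it up to three days (300 - 50 = 250)
        transfers = lateral_transfers([("A", "B")], est, target_days=3.0)
        assert transfers == [("A", "B", "c", 250.0)]

    def test_no_transfer_from_non_partner(self):
        # B is short but only non-partner C has surplus
        est = {
            "B": {"c": DemandEstimate(daily_demand=100.0, on_hand=0.0,
                                      in_transit=0.0)},
            "C": {"c": DemandEstimate(daily_demand=100.0, on_hand=900.0,
                                      in_transit=0.0)},
            "D": {"c": DemandEstimate(daily_demand=100.0, on_hand=100.0,
                                      in_transit=0.0)},
        }
        assert lateral_transfers([("B", "D")], est) == []

    def test_sender_keeps_one_day_of_local_demand(self):
        est = {
            "A": {"c": DemandEstimate(daily_demand=120.0, on_hand=200.0,
                                      in_transit=0.0,
                                      local_daily_demand=150.0)},
            "B": {"c": DemandEstimate(daily_demand=100.0, on_hand=0.0,
                                      in_transit=0.0)},
        }
        transfers = lateral_transfers([("A", "B")], est)
        assert sum(kg for *_x, kg in transfers) <= 200.0 - 150.0

    def test_information_locality(self):
        # perturbing a non-partner's inventory leaves orders unchanged
        base = {
            "A": {"c": DemandEstimate(daily_demand=100.0, on_hand=900.0,
                                      in_transit=0.0)},
            "B": {"c": DemandEstimate(daily_demand=100.0, on_hand=10.0,
                                      in_transit=0.0)},
            "Z": {"c": DemandEstimate(daily_demand=100.0, on_hand=10.0,
                                      in_transit=0.0)},
        }
        perturbed = {k: dict(v) for k, v in base.items()}
        perturbed["Z"] = {"c": DemandEstimate(daily_demand=100.0,
                                              on_hand=5000.0, in_transit=0.0)}
        edges = [("A", "B")]
        assert (lateral_transfers(edges, base)
                == lateral_transfers(edges, perturbed))


class TestLoadVehicle:
    CROPS = {
        "brinjal": Crop(name="brinjal", ambient_lifespan=4, bulk_density=400,
                        per_capita_demand=50),
        "potato": Crop(name="potato", ambient_lifespan=21, bulk_density=650,
                       per_capita_demand=90),
    }

    def test_everything_fits(self):
        lots = [Lot(crop="potato", mass=65.0)]
        loaded, left = load_vehicle(lots, 1.0, self.CROPS)
        assert len(loaded) == 1 and left == []

    def test_most_perishable_loaded_first(self):
        lots = [Lot(crop="potato", mass=650.0),
                Lot(crop="brinjal", mass=400.0)]
        loaded, left = load_vehicle(lots, 1.0, self.CROPS)
        assert [l.crop for l in loaded] == ["brinjal"]
        assert [l.crop for l in left] == ["potato"]

    def test_density_converts_mass_to_volume(self):
        # 650 kg of potato at 650 kg/m3 fills exactly 1 m3
        lots = [Lot(crop="potato", mass=650.0),
                Lot(crop="potato", mass=10.0)]
        loaded, left = load_vehicle(lots, 1.0, self.CROPS)
        assert sum(l.mass for l in loaded) == pytest.approx(650.0)

    def test_boundary_lot_split_conserves_mass(self):
        lots = [Lot(crop="brinjal", mass=500.0, effective_age=2.0),
                Lot(crop="brinjal", mass=500.0, effective_age=1.0)]
        loaded, left = load_vehicle(lots, 1.5, self.CROPS)
        assert sum(l.mass for l in loaded) == pytest.approx(600.0)
        assert (sum(l.mass for l in loaded) + sum(l.mass for l in left)
                == pytest.approx(1000.0))
        # within a crop, older stock ships first
        assert loaded[0].effective_age == 2.0


class TestTransit:
    CROPS = {"c": Crop(name="c", ambient_lifespan=4.0, bulk_density=500,
                       per_capita_demand=50)}

    def _route(self, breakage=0.0, hours=5.0):
        return Route(origin="a", destination="b", vehicle_volume=10.0,
                     travel_time=hours, leg_breakage_mean=breakage)

    def test_lots_age_by_travel_time(self):
        lots = [Lot(crop="c", mass=10.0, effective_age=1.0)]
        arrived, expired, broken = transit(lots, self._route(hours=5.0),
                                           self.CROPS,
                                           np.random.default_rng(0))
        assert arrived[0].effective_age == pytest.approx(1.0 + 5.0 / 24.0)
        assert expired == {} and broken == {}

    def test_midtransit_expiration_tallied(self):
        lots = [Lot(crop="c", mass=10.0, effective_age=3.9),
                Lot(crop="c", mass=5.0, effective_age=0.5)]
        arrived, expired, _b = transit(lots, self._route(hours=12.0),
                                       self.CROPS, np.random.default_rng(0))
        assert expired["c"] == 10.0
        assert [l.mass for l in arrived] == [5.0]

    def test_leg_breakage_recovers_configured_mean(self):
        rng = np.random.default_rng(8)
        route = self._route(breakage=0.02)
        total_in, total_broken = 0.0, 0.0
        for _ in range(10_000):
            lots = [Lot(crop="c", mass=100.0)]
            _a, _e, broken = transit(lots, route, self.CROPS, rng)
            total_in += 100.0
            total_broken += broken.get("c", 0.0)
        se = np.sqrt(0.02 / total_in)
        assert abs(total_broken / total_in - 0.02) < 3 * se

    def test_mass_conserved_across_outcomes(self):
        rng = np.random.default_rng(3)
        lots = [Lot(crop="c", mass=50.0, effective_age=3.9),
                Lot(crop="c", mass=50.0, effective_age=1.0)]
        arrived, expired, broken = transit(lots, self._route(breakage=0.3),
                                           self.CROPS, rng)
        total = (sum(l.mass for l in arrived) + sum(expired.values())
                 + sum(broken.values()))
        assert total == pytest.approx(100.0)
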