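import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vegchain.core import Crop, Lot
from vegchain.perish import (age_lots, draw_breakage, effective_aging_rate,
                             remove_expired)


def _crop(lifespan=4.0, cold=1.0, name="brinjal"):
    return Crop(name=name, ambient_lifespan=lifespan, bulk_density=400.0,
                per_capita_demand=50.0, cold_aging_factor=cold)


class TestAging:
    def test_ambient_and_transit_rate_is_one(self):
        c = _crop(cold=0.25)
        assert effective_aging_rate("ambient", c) == 1.0
        assert effective_aging_rate("transit", c) == 1.0

    def test_cold_rate_is_crop_factor(self):
        assert effective_aging_rate("cold", _crop(cold=0.25)) == 0.25

    def test_unknown_storage_kind_rejected(self):
        with pytest.raises(ValueError):
            effective_aging_rate("freezer", _crop())

    def test_zero_elapsed_leaves_lots_unchanged(self):
        c = _crop()
        lots = [Lot(crop=c.name, mass=10.0, effective_age=1.0)]
        age_lots(lots, 0.0, "ambient", {c.name: c})
        assert lots[0].effective_age == 1.0

    def test_negative_elapsed_rejected(self):
        c = _crop()
        with pytest.raises(ValueError):
            age_lots([], -1.0, "ambient", {c.name: c})

    def test_brinjal_expires_after_96h_ambient(self):
        # shortest-lived crop: 4-day ambient lifespan
        c = _crop(lifespan=4.0)
        lot = Lot(crop=c.name, mass=5.0)
        age_lots([lot], 96.0, "ambient", {c.name: c})
        assert lot.is_expired(c)

    def test_mixed_cold_then_ambient_schedule(self):
        # 48 h cold at factor 0.5 contributes 1 day, 72 h ambient 3 days
        c = _crop(lifespan=10.0, cold=0.5)
        lot = Lot(crop=c.name, mass=1.0)
        age_lots([lot], 48.0, "cold", {c.name: c})
        age_lots([lot], 72.0, "ambient", {c.name: c})
        assert lot.effective_age == pytest.approx(4.0)

    def test_cold_factor_one_matches_ambient(self):
        c1, c2 = _crop(cold=1.0, name="a"), _crop(cold=1.0, name="b")
        l1, l2 = Lot(crop="a", mass=1.0), Lot(crop="b", mass=1.0)
        for hours in (12.0, 30.0, 6.0):
            age_lots([l1], hours, "cold", {"a": c1})
            age_lots([l2], hours, "ambient", {"b": c2})
        assert l1.effective_age == l2.effective_age


class TestExpiration:
    def test_empty_inventory(self):
        survivors, expired = remove_expired([], {})
        assert survivors == [] and expired == {}

    def test_boundary_is_closed(self):
        c = _crop(lifespan=4.0)
        crops = {c.name: c}
        at_boundary = Lot(crop=c.name, mass=2.0, effective_age=4.0)
        survivors, expired = remove_expired([at_boundary], crops)
        assert survivors == [] and expired[c.name] == 2.0

    def test_splits_by_age_and_conserves_mass(self):
        c = _crop(lifespan=4.0)
        crops = {c.name: c}
        lots = [Lot(crop=c.name, mass=3.0, effective_age=3.9),
                Lot(crop=c.name, mass=5.0, effective_age=4.1)]
        survivors, expired = remove_expired(lots, crops)
        assert [l.mass for l in survivors] == [3.0]
        assert expired[c.name] == 5.0
        assert sum(l.mass for l in survivors) + expired[c.name] == 8.0

    def test_shorter_lifespan_never_reduces_expired_mass(self):
        # monotonicity on a fixed aging trace
        ages = [1.0, 3.5, 4.0, 6.2, 8.0]
        masses = [1.0, 2.0, 3.0, 4.0, 5.0]
        expired_by_lifespan = []
        for lifespan in (9.0, 6.0, 4.0, 2.0):
            c = _crop(lifespan=lifespan)
            lots = [Lot(crop=c.name, mass=m, effective_age=a)
                    for a, m in zip(ages, masses)]
            _s, expired = remove_expired(lots, {c.name: c})
            expired_by_lifespan.append(expired.get(c.name, 0.0))
        assert expired_by_lifespan == sorted(expired_by_lifespan)


class TestBreakage:
    def test_zero_rate_breaks_nothing(self):
        rng = np.random.default_rng(0)
        assert draw_breakage(100.0, 0.0, 1.0, rng) == 0.0

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            draw_breakage(-1.0, 0.02, 1.0, rng)
        with pytest.raises(ValueError):
            draw_breakage(1.0, 1.0, 1.0, rng)
        with pytest.raises(ValueError):
            draw_breakage(1.0, 0.02, 0.0, rng)

    def test_monte_carlo_mean_recovers_configured_rate(self):
        # 1e4 draws on 100 kg lots at 2%: Poisson mean 2 units per lot
        rng = np.random.default_rng(42)
        draws = np.array([draw_breakage(100.0, 0.02, 1.0, rng)
                          for _ in range(10_000)])
        frac = draws.mean() / 100.0
        se = np.sqrt(0.02 / 100.0 / 10_000)  # Var(P(2))/100^2 per draw
        assert abs(frac - 0.02) < 3 * se

    def test_cap_restricts_support_to_available_mass(self):
        rng = np.random.default_rng(1)
        vals = {draw_breakage(1.0, 0.5, 1.0, rng) for _ in range(500)}
        assert vals <= {0.0, 1.0}
        assert vals == {0.0, 1.0}  # both outcomes occur at rate 0.5

    @given(st.integers(1, 6))
    @settings(max_examples=6, deadline=None, derandomize=True)
    def test_multi_stage_survival_matches_closed_form(self, k):
        # surviving fraction after k independent 2% stages ~ (1-r)^k
        rng = np.random.default_rng(1000 + k)
        r, n, m0 = 0.02, 3000, 50.0
        surviving = np.empty(n)
        for i in range(n):
            m = m0
            for _ in range(k):
                m -= draw_breakage(m, r, 1.0, rng)
            surviving[i] = m / m0
        expected = (1 - r) ** k
        se = surviving.std(ddof=1) / np.sqrt(n)
        assert abs(surviving.mean() - expected) < 3 * se + 1e-4

    def test_breakage_never_exceeds_mass(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = float(rng.uniform(0, 5))
            assert draw_breakage(m, 0.4, 1.0, rng) <= m
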