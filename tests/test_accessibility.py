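"""E2SFCA: decay kernel, the two steps, conservation and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smallarea import (
    ConfigError,
    DecaySpec,
    decay_weight,
    step1_supply_ratio,
    step2_accessibility,
    stratified_accessibility,
    travel_time_matrix,
)

from conftest import P1, make_grid_city, make_hospitals

GAUSS = DecaySpec(d0=60.0)
BINARY = DecaySpec(d0=60.0, form="binary")


class TestTravelTime:
    def test_coincident_points_zero_minutes(self):
        city = make_grid_city(1, [1000])
        hosp = make_hospitals([(city.townships.cx.iloc[0], city.townships.cy.iloc[0])], [10])
        t = travel_time_matrix(city, hosp, speed_kmh=40)
        assert t[0, 0] == 0.0

    def test_forty_km_at_forty_kmh_is_sixty_minutes(self):
        city = make_grid_city(1, [1000])
        cx, cy = city.townships.cx.iloc[0], city.townships.cy.iloc[0]
        hosp = make_hospitals([(cx + 40_000.0, cy)], [10])
        t = travel_time_matrix(city, hosp, speed_kmh=40)
        assert t[0, 0] == pytest.approx(60.0)

    def test_values_move_with_labels_under_reordering(self):
        city = make_grid_city(2, [1, 1, 1, 1])
        hosp = make_hospitals([(0.0, 0.0), (15_000.0, 5_000.0)], [10, 20])
        t = travel_time_matrix(city, hosp, 40)
        t_swapped = travel_time_matrix(city, hosp.iloc[::-1].reset_index(drop=True), 40)
        assert np.allclose(t[:, ::-1], t_swapped)

    def test_zero_speed_rejected(self):
        city = make_grid_city(1, [1])
        hosp = make_hospitals([(0.0, 0.0)], [1])
        with pytest.raises(ConfigError, match="speed"):
            travel_time_matrix(city, hosp, speed_kmh=0)


class TestDecayWeight:
    def test_zero_time_gives_unit_weight(self):
        assert decay_weight(0.0, GAUSS) == pytest.approx(1.0)

    def test_boundary_and_beyond_are_zero(self):
        assert decay_weight(60.0, GAUSS) == pytest.approx(0.0, abs=1e-12)
        assert decay_weight(61.0, GAUSS) == 0.0
        assert decay_weight(1e6, GAUSS) == 0.0

    def test_half_catchment_weight(self):
        # [exp(-1/8) - exp(-1/2)] / [1 - exp(-1/2)] = 0.7014 to 3 s.f.
        assert decay_weight(30.0, GAUSS) == pytest.approx(0.7014, abs=5e-4)

    def test_binary_is_indicator(self):
        assert decay_weight(59.9, BINARY) == 1.0
        assert decay_weight(60.0, BINARY) == 1.0
        assert decay_weight(60.1, BINARY) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0, max_value=200), st.floats(min_value=0, max_value=200))
    def test_monotone_non_increasing_and_bounded(self, t1, t2):
        lo, hi = sorted((t1, t2))
        w_lo, w_hi = decay_weight(lo, GAUSS), decay_weight(hi, GAUSS)
        assert 0.0 <= w_hi <= w_lo <= 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ConfigError, match="non-negative"):
            decay_weight(-1.0, GAUSS)

    def test_invalid_d0_rejected(self):
        with pytest.raises(ConfigError, match="d0"):
            DecaySpec(d0=0.0)


class TestTwoSteps:
    def test_single_pair_ratio_at_zero_time(self):
        w = np.array([[1.0]])
        r = step1_supply_ratio(np.array([100.0]), np.array([1000.0]), w)
        assert r[0] == pytest.approx(0.1)

    def test_single_pair_ratio_at_half_catchment(self):
        w = np.array([[decay_weight(30.0, GAUSS)]])
        r = step1_supply_ratio(np.array([100.0]), np.array([1000.0]), w)
        assert r[0] == pytest.approx(0.1426, abs=2e-4)

    def test_zero_supply_gives_zero_ratio(self):
        w = np.array([[1.0]])
        r = step1_supply_ratio(np.array([0.0]), np.array([1000.0]), w)
        assert r[0] == 0.0

    def test_supply_with_no_reachable_demand_zeroed(self, caplog):
        w = np.array([[0.0]])
        with caplog.at_level("WARNING"):
            r = step1_supply_ratio(np.array([50.0]), np.array([1000.0]), w)
        assert r[0] == 0.0
        assert "zero weighted demand" in caplog.text

    def test_single_pair_accessibility_weights_cancel(self):
        # A = 1000*W*R with R = S/(W*P) -> 1000*S/P for any W > 0
        for t in (0.0, 10.0, 45.0):
            w = np.array([[decay_weight(t, GAUSS)]])
            r = step1_supply_ratio(np.array([100.0]), np.array([1000.0]), w)
            a = step2_accessibility(r, w)
            assert a[0] == pytest.approx(100.0)

    def test_two_by_two_all_coincident(self):
        # P = (1000, 3000), S = (100, 300), all travel times 0:
        # every township gets 1000 * 400/4000 = 100 supply per 1000
        w = np.ones((2, 2))
        r = step1_supply_ratio(np.array([100.0, 300.0]), np.array([1000.0, 3000.0]), w)
        a = step2_accessibility(r, w)
        assert np.allclose(a, 100.0)


def random_toy(rng, n_side=3, n_hosp=4, spread=60_000.0):
    n = n_side * n_side
    city = make_grid_city(n_side, rng.integers(100, 5000, n), cell_m=spread / n_side)
    coords = rng.uniform(0, spread, size=(n_hosp, 2))
    hosp = make_hospitals(
        coords, rng.integers(0, 500, n_hosp), is_pci=rng.uniform(size=n_hosp) < 0.5
    )
    return city, hosp


class TestConservationAndStratification:
    def test_conservation_on_random_toys(self, rng):
        """Sum_i P_i A_i / 1000 equals the total supply of reachable hospitals."""
        for _ in range(25):
            city, hosp = random_toy(rng)
            tt = travel_time_matrix(city, hosp, 40)
            surface = stratified_accessibility(city, hosp, GAUSS, strata=("total",))
            a = surface.set_index("township_id")["value"].reindex(city.townships.index)
            pop = city.demand_population(P1.label)
            w = decay_weight(tt, GAUSS)
            reachable = (w.sum(axis=0) > 0) | (hosp["beds"].to_numpy() == 0)
            expected = hosp.loc[np.asarray(reachable), "beds"].sum()
            assert (a * pop / 1000).sum() == pytest.approx(expected, abs=1e-6)

    def test_binary_global_catchment_closed_form(self, rng):
        city, hosp = random_toy(rng, spread=10_000.0)
        spec = DecaySpec(d0=1e6, form="binary")
        surface = stratified_accessibility(city, hosp, spec, strata=("total",))
        expected = 1000.0 * hosp["beds"].sum() / city.demand_population(P1.label).sum()
        assert np.allclose(surface["value"], expected)

    def test_pci_plus_non_pci_equals_total(self, rng):
        for _ in range(5):
            city, hosp = random_toy(rng)
            s = stratified_accessibility(city, hosp, GAUSS)
            wide = s.pivot_table(
                index=["township_id", "period"], columns="stratum", values="value"
            )
            assert np.allclose(wide["pci"] + wide["non_pci"], wide["total"], atol=1e-9)

    def test_all_pci_makes_non_pci_zero(self, rng):
        city, hosp = random_toy(rng)
        hosp["is_pci"] = True
        s = stratified_accessibility(city, hosp, GAUSS)
        wide = s.pivot_table(index=["township_id", "period"], columns="stratum", values="value")
        assert np.allclose(wide["non_pci"], 0.0)
        assert np.allclose(wide["pci"], wide["total"])

    def test_personnel_identical_to_beds_when_equal(self, rng):
        city, hosp = random_toy(rng)
        hosp["personnel"] = hosp["beds"]
        s_beds = stratified_accessibility(city, hosp, GAUSS, supply_kind="beds")
        s_pers = stratified_accessibility(city, hosp, GAUSS, supply_kind="personnel")
        assert np.allclose(s_beds["value"], s_pers["value"])

    def test_adding_a_hospital_never_decreases_accessibility(self, rng):
        city, hosp = random_toy(rng)
        before = stratified_accessibility(city, hosp, GAUSS, strata=("total",))["value"]
        extra = make_hospitals([(30_000.0, 30_000.0)], [200])
        extra["hospital_id"] = "Hnew"
        more = pd.concat([hosp, extra], ignore_index=True)
        after = stratified_accessibility(city, more, GAUSS, strata=("total",))["value"]
        assert (after.to_numpy() >= before.to_numpy() - 1e-12).all()

    def test_increasing_supply_never_decreases_accessibility(self, rng):
        city, hosp = random_toy(rng)
        before = stratified_accessibility(city, hosp, GAUSS, strata=("total",))["value"]
        richer = hosp.assign(beds=hosp["beds"] + 100)
        after = stratified_accessibility(city, richer, GAUSS, strata=("total",))["value"]
        assert (after.to_numpy() >= before.to_numpy() - 1e-12).all()

    def test_unreachable_townships_get_zero(self):
        city = make_grid_city(2, [100, 100, 100, 100], cell_m=5_000.0)
        hosp = make_hospitals([(1e7, 1e7)], [500])  # far outside every catchment
        s = stratified_accessibility(city, hosp, GAUSS, strata=("total",))
        assert np.allclose(s["value"], 0.0)

    def test_hospitals_inactive_before_first_period(self, small_synthetic):
        city, hosp = small_synthetic.city, small_synthetic.hospitals.copy()
        late = [p.label for p in city.periods][-1]
        hosp["first_period"] = late
        s = stratified_accessibility(city, hosp, GAUSS, strata=("total",))
        early = s[s["period"] != late]["value"]
        assert np.allclose(early, 0.0)
        assert s[s["period"] == late]["value"].sum() > 0
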