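"""Aggregation, direct standardization, percent change, inequality metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smallarea import (
    AGE_SEX_STANDARD_WEIGHTS,
    AGE_STANDARD_WEIGHTS,
    ConfigError,
    SchemaError,
    StandardWeights,
    aggregate_periods,
    classify_changes,
    coefficient_of_variation,
    decile_ratio,
    percent_change,
    standardize,
    standardize_draws,
)
from smallarea.schema import DEFAULT_PERIODS


def annual_table(value_name, values_by_year, townships=("T0",)):
    rows = []
    for t in townships:
        for year, v in values_by_year.items():
            rows.append((t, year, "male", "35-64", v))
    return pd.DataFrame(rows, columns=["township_id", "year", "sex", "age_group", value_name])


class TestAggregatePeriods:
    def test_deaths_sum_population_mean(self):
        years = {y: d for y, d in zip(range(2007, 2019), [1, 2, 3] * 4)}
        deaths = annual_table("deaths", years)
        pop = annual_table("population", {y: 600 for y in range(2007, 2019)})
        d, p = aggregate_periods(deaths, pop, DEFAULT_PERIODS)
        assert (d["deaths"] == 6).all()
        assert (p["population"] == 600).all()

    def test_matches_brute_force_sums(self, rng):
        townships = [f"T{k}" for k in range(5)]
        rows_d, rows_p = [], []
        for t in townships:
            for y in range(2007, 2019):
                rows_d.append((t, y, "male", "35-64", int(rng.integers(0, 50))))
                rows_p.append((t, y, "male", "35-64", int(rng.integers(1000, 9999))))
        deaths = pd.DataFrame(rows_d, columns=["township_id", "year", "sex", "age_group", "deaths"])
        pop = pd.DataFrame(rows_p, columns=["township_id", "year", "sex", "age_group", "population"])
        d, p = aggregate_periods(deaths, pop, DEFAULT_PERIODS)
        for t in townships:
            for per in DEFAULT_PERIODS:
                yrs = range(per.years[0], per.years[1] + 1)
                want_d = deaths[(deaths.township_id == t) & deaths.year.isin(yrs)]["deaths"].sum()
                want_p = pop[(pop.township_id == t) & pop.year.isin(yrs)]["population"].mean()
                got_d = d[(d.township_id == t) & (d.period == per.label)]["deaths"].iloc[0]
                got_p = p[(p.township_id == t) & (p.period == per.label)]["population"].iloc[0]
                assert got_d == want_d
                assert got_p == pytest.approx(want_p)

    def test_missing_year_named_in_error(self):
        deaths = annual_table("deaths", {y: 1 for y in range(2007, 2019) if y != 2011})
        pop = annual_table("population", {y: 100 for y in range(2007, 2019)})
        with pytest.raises(SchemaError, match="2011"):
            aggregate_periods(deaths, pop, DEFAULT_PERIODS)


class TestStandardize:
    def test_printed_weights_hand_example(self):
        rates = {"35-64": 10.0, "65-79": 100.0, "80+": 1000.0}
        assert standardize(rates, AGE_STANDARD_WEIGHTS) == pytest.approx(53.29)

    def test_equal_rates_are_fixed_point_age_weights(self):
        rates = {a: 73.2 for a in ("35-64", "65-79", "80+")}
        assert standardize(rates, AGE_STANDARD_WEIGHTS) == pytest.approx(73.2)

    def test_equal_rates_are_fixed_point_age_sex_weights(self):
        rates = {cell: 42.0 for cell in AGE_SEX_STANDARD_WEIGHTS.cells()}
        assert standardize(rates, AGE_SEX_STANDARD_WEIGHTS) == pytest.approx(42.0)

    def test_bounded_by_min_and_max_cell_rate(self, rng):
        for _ in range(20):
            rates = {a: rng.uniform(1, 500) for a in ("35-64", "65-79", "80+")}
            s = standardize(rates, AGE_STANDARD_WEIGHTS)
            assert min(rates.values()) <= s <= max(rates.values())

    def test_missing_cell_is_hard_error(self):
        with pytest.raises(SchemaError, match="80"):
            standardize({"35-64": 1.0, "65-79": 2.0}, AGE_STANDARD_WEIGHTS)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum"):
            StandardWeights({"a": 0.5, "b": 0.4})

    def test_draw_wise_standardization_is_linear(self, rng):
        draws = {a: rng.lognormal(3, 0.5, size=(200, 7)) for a in ("35-64", "65-79", "80+")}
        out = standardize_draws(draws, AGE_STANDARD_WEIGHTS)
        k = 3
        per_draw = [
            standardize({a: draws[a][s, k] for a in draws}, AGE_STANDARD_WEIGHTS)
            for s in range(200)
        ]
        assert np.allclose(out[:, k], per_draw)


class TestPercentChange:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(86.3, 49.4, -42.8), (98.9, 60.5, -38.8), (70.6, 37.2, -47.3)],
    )
    def test_study_period_declines(self, start, end, expected):
        assert percent_change(start, end) == pytest.approx(expected, abs=0.05)

    def test_no_change_is_zero(self):
        assert percent_change(55.5, 55.5) == 0.0

    def test_zero_start_is_missing(self):
        assert np.isnan(percent_change(0.0, 10.0))


class TestDecileRatio:
    def test_constant_vector_is_one(self):
        assert decile_ratio(np.full(50, 3.3)) == pytest.approx(1.0)

    def test_linear_sequence_quantile_rule(self):
        # values 1..101: P10 = 11, P90 = 91 under linear interpolation
        assert decile_ratio(np.arange(1, 102)) == pytest.approx(91 / 11)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, c):
        vals = np.arange(1, 40, dtype=float)
        assert decile_ratio(vals * c) == pytest.approx(decile_ratio(vals), rel=1e-9)

    def test_zero_p10_flagged_infinite(self):
        vals = np.concatenate([np.zeros(20), np.ones(10)])
        with pytest.warns(UserWarning, match="P10"):
            assert decile_ratio(vals) == np.inf

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            decile_ratio(np.arange(1, 6))


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation(np.full(20, 5.0)) == 0.0

    def test_hand_example(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        vals = np.array([2.0, 9.0, 4.0, 7.0])
        assert coefficient_of_variation(vals * 17) == pytest.approx(coefficient_of_variation(vals))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ConfigError, match="mean"):
            coefficient_of_variation([-1.0, 1.0])


class TestClassifyChanges:
    def test_study_share_declining(self):
        changes = np.concatenate([-np.ones(279), np.ones(307 - 279)])
        out = classify_changes(changes)
        assert out["pct_declining"] == pytest.approx(90.9, abs=0.05)

    def test_study_share_steep_decline(self):
        changes = np.concatenate([np.full(79, -60.0), np.full(307 - 79, -10.0)])
        out = classify_changes(changes)
        assert out["pct_declining_50"] == pytest.approx(25.7, abs=0.05)

    def test_all_positive_none_declining(self):
        out = classify_changes(np.ones(10))
        assert out["pct_declining"] == 0.0
        assert out["pct_increasing"] == 100.0

    def test_boundary_of_steep_decline_is_closed(self):
        out = classify_changes(np.array([-50.0, -49.999]))
        assert out["n_declining_50"] == 1

    def test_missing_excluded_and_counted(self):
        out = classify_changes(np.array([np.nan, -1.0, 1.0]))
        assert out["n_missing"] == 1
        assert out["n"] == 2

    def test_fractions_partition_non_missing(self, rng):
        changes = rng.normal(0, 30, 100)
        out = classify_changes(changes)
        total = out["pct_declining"] + out["pct_increasing"] + out["pct_zero"]
        assert total == pytest.approx(100.0)
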