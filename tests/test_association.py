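"""Level (mixed) and change (OLS) association models, and the model suite."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from smallarea import (
    ChangeModel,
    ConfigError,
    LevelModel,
    SchemaError,
    compute_accessibility,
    run_model_suite,
    stratified_accessibility,
)

PERIODS = ["2007-2009", "2010-2012", "2013-2015", "2016-2018"]


def mixed_data(rng, n_town=80, slope=-2.0, sd_town=8.0, sd_noise=4.0):
    """Township-period panel with a known slope and random intercepts."""
    rows = []
    intercepts = rng.normal(0, sd_town, n_town)
    for i in range(n_town):
        base_a = rng.uniform(0, 20)
        for t, per in enumerate(PERIODS):
            a = base_a + 1.5 * t + rng.normal(0, 1)
            y = 100 + slope * a + intercepts[i] + rng.normal(0, sd_noise)
            rows.append((f"T{i}", per, y, a))
    return pd.DataFrame(rows, columns=["township_id", "period", "mortality", "accessibility"])


class TestLevelModel:
    def test_recovers_known_slope_within_three_ses(self, rng):
        data = mixed_data(rng, slope=-2.0)
        res = LevelModel(data, model_id=1).fit()
        se = (res.ci_high - res.ci_low) / (2 * 1.96)
        assert abs(res.beta - (-2.0)) < 3 * se
        assert res.n_groups == 80
        assert res.ci_low <= res.beta <= res.ci_high

    def test_zero_group_variance_falls_back_to_pooled_ols(self):
        # seed chosen so the REML estimate sits exactly on the zero boundary,
        # which is the degenerate case the fallback exists for
        data = mixed_data(np.random.default_rng(3), sd_town=0.0, sd_noise=3.0)
        res = LevelModel(data, model_id=1).fit()
        x = sm.add_constant(data[["accessibility"]].astype(float))
        ols = sm.OLS(data["mortality"].astype(float), x).fit()
        assert res.ols_fallback
        assert res.beta == pytest.approx(ols.params["accessibility"], abs=1e-6)

    def test_constant_exposure_not_identifiable(self):
        data = pd.DataFrame(
            {
                "township_id": ["T0", "T1"] * 2,
                "period": ["2007-2009"] * 2 + ["2010-2012"] * 2,
                "mortality": [50.0, 60.0, 55.0, 65.0],
                "accessibility": 5.0,
            }
        )
        with pytest.raises(ConfigError, match="constant"):
            LevelModel(data, model_id=1)

    def test_missing_covariate_named(self, rng):
        data = mixed_data(rng)
        with pytest.raises(SchemaError, match="hypertension"):
            LevelModel(data, model_id=2)


class TestChangeModel:
    def test_exact_line_gives_per_ten_beta(self):
        n = 60
        x = np.linspace(-30, 80, n)
        data = pd.DataFrame(
            {
                "township_id": [f"T{i}" for i in range(n)],
                "mortality_pct_change": -0.071 * x,
                "accessibility_pct_change": x,
            }
        )
        res = ChangeModel(data, model_id=1).fit()
        assert res.beta == pytest.approx(-0.71, abs=1e-9)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_per_ten_effect(self, rng):
        n = 307
        x = rng.uniform(-20, 120, n)
        y = 5 - 0.09 * x + rng.normal(0, 10, n)  # per-10 effect -0.9
        data = pd.DataFrame(
            {
                "township_id": [f"T{i}" for i in range(n)],
                "mortality_pct_change": y,
                "accessibility_pct_change": x,
            }
        )
        res = ChangeModel(data, model_id=1).fit()
        se = (res.ci_high - res.ci_low) / (2 * 1.96)
        assert abs(res.beta - (-0.9)) < 3 * se

    def test_intercept_shift_leaves_slope_unchanged(self, rng):
        n = 100
        x = rng.uniform(0, 50, n)
        y = -0.05 * x + rng.normal(0, 2, n)
        make = lambda yy: pd.DataFrame(
            {
                "township_id": [f"T{i}" for i in range(n)],
                "mortality_pct_change": yy,
                "accessibility_pct_change": x,
            }
        )
        r1 = ChangeModel(make(y), model_id=1).fit()
        r2 = ChangeModel(make(y + 25.0), model_id=1).fit()
        assert r1.beta == pytest.approx(r2.beta, abs=1e-9)

    def test_undefined_changes_excluded_and_counted(self, rng):
        n = 30
        data = pd.DataFrame(
            {
                "township_id": [f"T{i}" for i in range(n)],
                "mortality_pct_change": rng.normal(size=n),
                "accessibility_pct_change": rng.normal(size=n),
            }
        )
        data.loc[:4, "accessibility_pct_change"] = np.nan
        res = ChangeModel(data, model_id=1).fit()
        assert res.n_excluded == 5
        assert res.n_obs == 25

    def test_orthogonal_covariates_leave_beta_unchanged(self, rng):
        """Partitioned regression: regressors orthogonal to [1, x] cannot move the slope."""
        n = 64
        x = rng.normal(0, 1, n)
        design = np.column_stack([np.ones(n), x])
        proj = design @ np.linalg.pinv(design)
        covs = {}
        for name in ("hypertension", "diabetes", "hypercholesterolemia", "smoking"):
            z = rng.normal(0, 1, n)
            covs[f"{name}_pct_change"] = z - proj @ z
        y = 3 - 0.4 * x + rng.normal(0, 1, n)
        data = pd.DataFrame(
            {
                "township_id": [f"T{i}" for i in range(n)],
                "mortality_pct_change": y,
                "accessibility_pct_change": x,
                **covs,
            }
        )
        r1 = ChangeModel(data, model_id=1).fit()
        r2 = ChangeModel(data, model_id=2).fit()
        assert r2.beta == pytest.approx(r1.beta, abs=1e-6)


class TestSignRecovery:
    def test_injected_negative_effect_detected(self):
        """gamma < 0 in the generator yields a negative, significant level beta."""
        from smallarea import SimulationConfig, generate_city
        from smallarea.pipeline import _crude_standardized  # helper used below

        hits = 0
        reps = 10
        for k in range(reps):
            syn = generate_city(
                SimulationConfig(n_townships=40, seed=500 + k, n_hospitals=20, gamma=-0.05,
                                 period_trend=0.0)
            )
            access = compute_accessibility(syn.city, syn.hospitals)
            mortality = _crude_standardized(syn.city, syn.deaths)
            res = LevelModel(
                mortality.merge(
                    access[access.stratum == "total"][["township_id", "period", "value"]],
                    on=["township_id", "period"],
                ).rename(columns={"rate": "mortality", "value": "accessibility"}),
                model_id=1,
            ).fit()
            if res.beta < 0 and res.p_value < 0.05:
                hits += 1
        assert hits >= 9


class TestModelSuite:
    def test_full_suite_shape_and_finiteness(self, small_synthetic):
        from smallarea.pipeline import _crude_standardized

        syn = small_synthetic
        access = stratified_accessibility(syn.city, syn.hospitals)
        mortality = _crude_standardized(syn.city, syn.deaths)
        out = run_model_suite(mortality, access, syn.covariates, supply_kinds=("beds",))
        assert len(out) == 18
        assert out["beta"].notna().all()
        assert (out["ci_low"] <= out["beta"]).all()
        assert (out["beta"] <= out["ci_high"]).all()

    def test_personnel_equal_beds_gives_equal_betas(self, small_synthetic):
        from smallarea.pipeline import _crude_standardized

        syn = small_synthetic
        hosp = syn.hospitals.copy()
        hosp["personnel"] = hosp["beds"]
        access = pd.concat(
            [
                stratified_accessibility(syn.city, hosp, supply_kind=k)
                for k in ("beds", "personnel")
            ],
            ignore_index=True,
        )
        mortality = _crude_standardized(syn.city, syn.deaths)
        out = run_model_suite(mortality, access, syn.covariates, supply_kinds=("beds", "personnel"))
        beds = out[out.supply_kind == "beds"].reset_index(drop=True)
        pers = out[out.supply_kind == "personnel"].reset_index(drop=True)
        assert np.allclose(beds["beta"], pers["beta"], atol=1e-8)

    def test_missing_surface_named(self, small_synthetic):
        with pytest.raises(SchemaError, match="mortality"):
            run_model_suite(pd.DataFrame(), pd.DataFrame({"a": [1]}), pd.DataFrame({"a": [1]}))
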