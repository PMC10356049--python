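"""Period aggregation, direct standardization, and geographic inequality.

Direct standardization replaces each township's own population composition
with a fixed standard population: the standardized rate is the weighted
average sum_cell w_cell * rate_cell, with the weights the standard
population's cell proportions.  The study's standard is the 2010 census 35+
population; the printed age weights are 82.9%, 14.0% and 3.1% for 35-64,
65-79 and >=80 years, and the age-sex weights are 43.1/6.6/1.4 (men) and
39.8/7.4/1.7 (women), each set summing to 1.

Geographic inequality across townships is summarised two ways: the ratio of
the 90th to the 10th percentile of township mortality (a tail measure) and
the coefficient of variation (a whole-distribution sensitivity measure).
Quantiles use linear interpolation between order statistics throughout —
the P90/P10 ratio is sensitive to the rule at ~300 areas, so it is fixed
and documented rather than configurable.

Percent change from the first to the last period is 100*(end-start)/start;
townships with a zero start value have no defined relative change and are
reported as missing, mirroring the handling of townships with no baseline
accessibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .schema import AGE_GROUPS, SEXES, Period

__all__ = [
    "StandardWeights",
    "AGE_STANDARD_WEIGHTS",
    "AGE_SEX_STANDARD_WEIGHTS",
    "aggregate_periods",
    "standardize",
    "standardize_draws",
    "percent_change",
    "decile_ratio",
    "coefficient_of_variation",
    "classify_changes",
]


@dataclass(frozen=True)
class StandardWeights:
    """Standard-population cell weights; keys are age bands or (sex, age)."""

    weights: Mapping

    def __post_init__(self):
        w = dict(self.weights)
        total = float(sum(w.values()))
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"standard weights sum to {total}, not 1")
        for cell, x in w.items():
            if not (0 < x < 1):
                raise ConfigError(f"weight for {cell} must be in (0,1), got {x}")
        object.__setattr__(self, "weights", w)

    def cells(self):
        return list(self.weights)


#: 2010-census age weights for the 35+ population (both sexes combined)
AGE_STANDARD_WEIGHTS = StandardWeights({"35-64": 0.829, "65-79": 0.140, "80+": 0.031})

#: 2010-census age-sex weights (six cells, summing to 1 across both sexes)
AGE_SEX_STANDARD_WEIGHTS = StandardWeights(
    {
        ("male", "35-64"): 0.431,
        ("male", "65-79"): 0.066,
        ("male", "80+"): 0.014,
        ("female", "35-64"): 0.398,
        ("female", "65-79"): 0.074,
        ("female", "80+"): 0.017,
    }
)


def aggregate_periods(
    annual_deaths: pd.DataFrame,
    annual_population: pd.DataFrame,
    periods: Sequence[Period],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate annual tables into 3-year periods.

    Deaths are summed over the period's years; population is the 3-year mean
    (the exposure basis — multiply by the period length for person-years).
    Inputs are long tables with a ``year`` column; every year of every period
    must be present, otherwise the missing year is named in the error.

    Returns (period deaths, period populations) keyed by period label.
    """
    for name, df, value in (
        ("deaths", annual_deaths, "deaths"),
        ("population", annual_population, "population"),
    ):
        missing = {"township_id", "year", "sex", "age_group", value} - set(df.columns)
        if missing:
            raise SchemaError(f"annual {name} table missing column(s): {sorted(missing)}")
        years = set(df["year"].unique())
        for p in periods:
            for y in range(p.years[0], p.years[1] + 1):
                if y not in years:
                    raise SchemaError(f"annual {name} table is missing year {y} of period {p.label}")

    def label_of(year: int) -> str | None:
        for p in periods:
            if p.years[0] <= year <= p.years[1]:
                return p.label
        return None

    key = ["township_id", "period", "sex", "age_group"]
    d = annual_deaths.copy()
    d["period"] = d["year"].map(label_of)
    d = d.dropna(subset=["period"])
    deaths = d.groupby(key, as_index=False)["deaths"].sum()

    q = annual_population.copy()
    q["period"] = q["year"].map(label_of)
    q = q.dropna(subset=["period"])
    pop = q.groupby(key, as_index=False)["population"].mean()
    return deaths, pop


def standardize(stratum_rates: Mapping, weights: StandardWeights) -> float:
    """Directly standardized rate: sum_cell weight * rate.

    Every weight cell must be present in ``stratum_rates``; a missing cell is
    a hard error — silently renormalizing the remaining weights would change
    the estimand.
    """
    missing = [c for c in weights.cells() if c not in stratum_rates]
    if missing:
        raise SchemaError(f"stratum rate(s) missing for standardization cell(s): {missing}")
    return float(sum(w * stratum_rates[c] for c, w in weights.weights.items()))


def standardize_draws(rate_draws: Mapping, weights: StandardWeights) -> np.ndarray:
    """Draw-wise standardization: each cell maps to an (S, n) draw array.

    Returns the (S, n) array of standardized-rate draws, so downstream
    summaries yield CIs for the standardized rates themselves.
    """
    missing = [c for c in weights.cells() if c not in rate_draws]
    if missing:
        raise SchemaError(f"rate draws missing for standardization cell(s): {missing}")
    out = None
    for c, w in weights.weights.items():
        arr = np.asarray(rate_draws[c], dtype=float) * w
        out = arr if out is None else out + arr
    return out


def percent_change(rate_start: float, rate_end: float) -> float:
    """Relative change in percent from start to end; NaN when start is 0."""
    if rate_start < 0 or rate_end < 0:
        raise ConfigError("rates must be non-negative")
    if rate_start == 0:
        return float("nan")
    return 100.0 * (rate_end - rate_start) / rate_start


def decile_ratio(values) -> float:
    """P90/P10 ratio under linear-interpolation quantiles.

    Returns inf when P10 is 0 (flagged via warning); warns below 10 values,
    where the tails are not meaningfully estimated.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        warnings.warn(f"decile ratio on only {len(x)} values; tails are unstable", stacklevel=2)
    if len(x) == 0:
        return float("nan")
    p10, p90 = np.quantile(x, [0.10, 0.90])
    if p10 == 0:
        warnings.warn("P10 is zero; decile ratio is infinite", stacklevel=2)
        return float("inf")
    return float(p90 / p10)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) over the mean; requires a positive mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    m = x.mean()
    if m <= 0:
        raise ConfigError(f"coefficient of variation needs a positive mean, got {m}")
    return float(x.std(ddof=1) / m)


def classify_changes(changes) -> dict:
    """Summarise township percent changes: declining, declining >=50%, increasing.

    Missing (NaN) values are excluded and counted.  The >=50%-decline
    boundary is closed (change <= -50).  Fractions are reported with their
    numerators and denominators.
    """
    x = np.asarray(changes, dtype=float)
    missing = int(np.sum(~np.isfinite(x)))
    x = x[np.isfinite(x)]
    n = len(x)
    n_decline = int(np.sum(x < 0))
    n_decline50 = int(np.sum(x <= -50))
    n_increase = int(np.sum(x > 0))
    n_zero = n - n_decline - n_increase
    frac = lambda k: 100.0 * k / n if n else float("nan")
    return {
        "n": n,
        "n_missing": missing,
        "n_declining": n_decline,
        "pct_declining": frac(n_decline),
        "n_declining_50": n_decline50,
        "pct_declining_50": frac(n_decline50),
        "n_increasing": n_increase,
        "pct_increasing": frac(n_increase),
        "n_zero": n_zero,
        "pct_zero": frac(n_zero),
    }
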