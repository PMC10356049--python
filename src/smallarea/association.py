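"""Ecological association between health-care accessibility and mortality.

Two designs, mirroring the study's Tables of level and change associations:

* **Level model** — township-period observations; a linear mixed model with a
  random intercept per township accounts for the longitudinal repeats:

      mortality_it = b0 + b1 * accessibility_it + covariates + a_i + e_it

  with mortality the standardized rate per 100 000 and accessibility in
  natural units (supply per 1000 population), so b1 reads "per one bed per
  1000".  Estimated by REML with large-sample Wald intervals.

* **Change model** — one observation per township; OLS of the 2007->2018
  percent change in mortality on the percent change in accessibility, with
  the coefficient rescaled to a per-10-percentage-point increase.  Townships
  whose baseline accessibility is zero have no defined relative change and
  are excluded (and counted).

Covariate sets follow the study's model ladder:
  Model 1: accessibility only;
  Model 2: + cardiovascular risk-factor prevalences (hypertension, diabetes,
           hypercholesterolemia, smoking) — levels for the level model,
           percent changes for the change model;
  Model 3: + socioeconomic factors (proportion married, high-school-or-above,
           per-capita disposable income, proportion unemployed), entered as
           baseline levels in both designs.

Covariates observed at district level are assigned to member townships as-is;
no correction is made for that induced clustering beyond the township random
intercept (a documented limitation of the design).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ConfigError, SchemaError

__all__ = [
    "AssociationResult",
    "LevelModel",
    "ChangeModel",
    "fit_level_model",
    "fit_change_model",
    "run_model_suite",
    "RISK_FACTORS",
    "SOCIOECONOMIC",
]

log = logging.getLogger(__name__)

RISK_FACTORS = ["hypertension", "diabetes", "hypercholesterolemia", "smoking"]
SOCIOECONOMIC = ["married", "high_school", "income", "unemployed"]


def covariate_set(model_id: int, form: str) -> list[str]:
    """Covariate names for Models 1-3 (form: 'level' or 'change')."""
    if model_id not in (1, 2, 3):
        raise ConfigError(f"model_id must be 1, 2 or 3, got {model_id}")
    cols: list[str] = []
    if model_id >= 2:
        suffix = "_pct_change" if form == "change" else ""
        cols += [f"{c}{suffix}" for c in RISK_FACTORS]
    if model_id >= 3:
        cols += SOCIOECONOMIC
    return cols


@dataclass
class AssociationResult:
    """One fitted association: the accessibility coefficient and its inference."""

    model_id: int
    form: str  # "level" | "change"
    stratum: str  # "total" | "pci" | "non_pci"
    supply_kind: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_groups: int | None = None
    n_excluded: int = 0
    var_township: float | None = None
    var_residual: float | None = None
    ols_fallback: bool = False

    def summary(self) -> str:
        unit = "per 10% increase" if self.form == "change" else "per unit (supply/1000)"
        extra = " [OLS fallback]" if self.ols_fallback else ""
        return (
            f"Model {self.model_id} ({self.form}, {self.stratum}, {self.supply_kind}): "
            f"beta {unit} = {self.beta:.3f} "
            f"(95% CI {self.ci_low:.3f} to {self.ci_high:.3f}), "
            f"p = {self.p_value:.3g}, n = {self.n_obs}{extra}"
        )

    def to_row(self) -> dict:
        return {
            "model_id": self.model_id,
            "form": self.form,
            "stratum": self.stratum,
            "supply_kind": self.supply_kind,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "n_excluded": self.n_excluded,
            "ols_fallback": self.ols_fallback,
        }


class LevelModel:
    """Random-intercept mixed model of mortality levels on accessibility.

    ``data`` must contain columns ``township_id``, ``mortality``,
    ``accessibility`` and every covariate of the requested model; one row per
    township-period.
    """

    def __init__(self, data: pd.DataFrame, model_id: int = 1, period_effects: bool = False):
        required = {"township_id", "mortality", "accessibility"}
        missing = required - set(data.columns)
        if missing:
            raise SchemaError(f"level-model data missing column(s): {sorted(missing)}")
        self.covariates = covariate_set(model_id, "level")
        missing = set(self.covariates) - set(data.columns)
        if missing:
            raise SchemaError(f"Model {model_id} covariate(s) missing: {sorted(missing)}")
        self.data = data.dropna(subset=["mortality", "accessibility", *self.covariates]).copy()
        self.n_excluded = len(data) - len(self.data)
        self.model_id = model_id
        self.period_effects = period_effects
        if self.data["accessibility"].nunique() <= 1:
            raise ConfigError("accessibility is constant; the slope is not identifiable")

    def _design(self) -> pd.DataFrame:
        x = self.data[["accessibility", *self.covariates]].astype(float)
        if self.period_effects:
            dummies = pd.get_dummies(self.data["period"], prefix="period", drop_first=True)
            x = pd.concat([x, dummies.astype(float)], axis=1)
        return sm.add_constant(x)

    def fit(self, stratum: str = "total", supply_kind: str = "beds") -> AssociationResult:
        y = self.data["mortality"].astype(float)
        x = self._design()
        groups = self.data["township_id"]
        ols_fallback = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = MixedLM(y, x, groups=groups).fit(reml=True)
                var_re = float(np.asarray(res.cov_re)[0, 0])
                singular = not np.isfinite(var_re) or var_re <= 1e-8 * res.scale
            except (np.linalg.LinAlgError, ValueError):
                res, singular = None, True
        if res is None or singular:
            ols_fallback = True
            log.warning(
                "between-township variance is (near) zero or the mixed fit failed; "
                "falling back to pooled OLS"
            )
            res = sm.OLS(y, x).fit()
            var_re = 0.0
        ci = res.conf_int().loc["accessibility"]
        return AssociationResult(
            model_id=self.model_id,
            form="level",
            stratum=stratum,
            supply_kind=supply_kind,
            beta=float(res.params["accessibility"]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            p_value=float(res.pvalues["accessibility"]),
            n_obs=len(y),
            n_groups=int(groups.nunique()),
            n_excluded=self.n_excluded,
            var_township=var_re,
            var_residual=float(res.scale) if hasattr(res, "scale") else None,
            ols_fallback=ols_fallback,
        )


class ChangeModel:
    """OLS of mortality percent change on accessibility percent change.

    ``data`` has one row per township with columns ``mortality_pct_change``
    and ``accessibility_pct_change`` (NaN = undefined relative change,
    excluded and counted) plus the requested covariates.  The reported beta
    is per 10-percentage-point increase in accessibility.
    """

    def __init__(self, data: pd.DataFrame, model_id: int = 1):
        required = {"township_id", "mortality_pct_change", "accessibility_pct_change"}
        missing = required - set(data.columns)
        if missing:
            raise SchemaError(f"change-model data missing column(s): {sorted(missing)}")
        self.covariates = covariate_set(model_id, "change")
        missing = set(self.covariates) - set(data.columns)
        if missing:
            raise SchemaError(f"Model {model_id} covariate(s) missing: {sorted(missing)}")
        keep = ["mortality_pct_change", "accessibility_pct_change", *self.covariates]
        self.data = data.dropna(subset=keep).copy()
        self.n_excluded = len(data) - len(self.data)
        if self.n_excluded:
            log.warning(
                "%d township(s) excluded from the change model (undefined percent change)",
                self.n_excluded,
            )
        self.model_id = model_id
        if self.data["accessibility_pct_change"].nunique() <= 1:
            raise ConfigError("accessibility change is constant; the slope is not identifiable")

    def fit(self, stratum: str = "total", supply_kind: str = "beds") -> AssociationResult:
        y = self.data["mortality_pct_change"].astype(float)
        x = sm.add_constant(
            self.data[["accessibility_pct_change", *self.covariates]].astype(float)
        )
        res = sm.OLS(y, x).fit()
        ci = res.conf_int().loc["accessibility_pct_change"]
        # rescale: per 10-percentage-point increase in accessibility
        return AssociationResult(
            model_id=self.model_id,
            form="change",
            stratum=stratum,
            supply_kind=supply_kind,
            beta=float(res.params["accessibility_pct_change"]) * 10.0,
            ci_low=float(ci[0]) * 10.0,
            ci_high=float(ci[1]) * 10.0,
            p_value=float(res.pvalues["accessibility_pct_change"]),
            n_obs=int(res.nobs),
            n_groups=int(res.nobs),
            n_excluded=self.n_excluded,
        )


# ---------------------------------------------------------------------------
# convenience wrappers over the Model classes
# ---------------------------------------------------------------------------

def fit_level_model(
    mortality: pd.DataFrame,
    accessibility: pd.DataFrame,
    covariates: pd.DataFrame | None,
    model_id: int = 1,
    stratum: str = "total",
    supply_kind: str = "beds",
    period_effects: bool = False,
) -> AssociationResult:
    """Assemble township-period rows from the two surfaces and fit the level model.

    ``mortality``: long surface with columns township_id, period, group, rate
    (the ``total`` group is used).  ``accessibility``: long surface with
    columns township_id, period, supply_kind, stratum, value.
    """
    data = _merge_levels(mortality, accessibility, covariates, stratum, supply_kind)
    return LevelModel(data, model_id, period_effects).fit(stratum, supply_kind)


def fit_change_model(
    mortality: pd.DataFrame,
    accessibility: pd.DataFrame,
    covariates: pd.DataFrame | None,
    model_id: int = 1,
    stratum: str = "total",
    supply_kind: str = "beds",
) -> AssociationResult:
    """Compute first->last-period percent changes per township and fit OLS."""
    data = _merge_changes(mortality, accessibility, covariates, stratum, supply_kind)
    return ChangeModel(data, model_id).fit(stratum, supply_kind)


def _mortality_total(mortality: pd.DataFrame) -> pd.DataFrame:
    m = mortality
    if "group" in m.columns:
        m = m[m["group"] == "total"]
    col = "rate" if "rate" in m.columns else "value"
    return m[["township_id", "period", col]].rename(columns={col: "mortality"})


def _access_slice(accessibility: pd.DataFrame, stratum: str, supply_kind: str) -> pd.DataFrame:
    a = accessibility
    if "supply_kind" in a.columns:
        a = a[a["supply_kind"] == supply_kind]
    a = a[a["stratum"] == stratum]
    if a.empty:
        raise SchemaError(
            f"accessibility surface has no rows for stratum={stratum!r}, "
            f"supply_kind={supply_kind!r}"
        )
    return a[["township_id", "period", "value"]].rename(columns={"value": "accessibility"})


def _merge_levels(mortality, accessibility, covariates, stratum, supply_kind) -> pd.DataFrame:
    m = _mortality_total(mortality)
    a = _access_slice(accessibility, stratum, supply_kind)
    data = m.merge(a, on=["township_id", "period"], how="inner")
    if data.empty:
        raise SchemaError("mortality and accessibility surfaces share no township-periods")
    if covariates is not None:
        time_varying = ["township_id", "period", *[c for c in RISK_FACTORS if c in covariates]]
        data = data.merge(covariates[time_varying], on=["township_id", "period"], how="left")
        static = [c for c in SOCIOECONOMIC if c in covariates]
        if static:
            first = covariates.sort_values("period").groupby("township_id")[static].first()
            data = data.merge(first, on="township_id", how="left")
    return data


def _first_last(periods: pd.Series) -> tuple[str, str]:
    labels = sorted(periods.unique())
    if len(labels) < 2:
        raise SchemaError("need at least two periods to compute changes")
    return labels[0], labels[-1]


def _pct_change_wide(df: pd.DataFrame, value: str, out: str) -> pd.DataFrame:
    from .rates import percent_change

    first, last = _first_last(df["period"])
    wide = df.pivot_table(index="township_id", columns="period", values=value, aggfunc="first")
    change = [
        percent_change(s, e) if pd.notna(s) and pd.notna(e) else float("nan")
        for s, e in zip(wide[first], wide[last])
    ]
    return pd.DataFrame({"township_id": wide.index, out: change})


def _merge_changes(mortality, accessibility, covariates, stratum, supply_kind) -> pd.DataFrame:
    m = _pct_change_wide(_mortality_total(mortality), "mortality", "mortality_pct_change")
    a = _pct_change_wide(
        _access_slice(accessibility, stratum, supply_kind), "accessibility", "accessibility_pct_change"
    )
    data = m.merge(a, on="township_id", how="inner")
    if covariates is not None:
        for c in RISK_FACTORS:
            if c in covariates:
                ch = _pct_change_wide(
                    covariates[["township_id", "period", c]].rename(columns={c: "v"}),
                    "v",
                    f"{c}_pct_change",
                )
                data = data.merge(ch, on="township_id", how="left")
        static = [c for c in SOCIOECONOMIC if c in covariates]
        if static:
            first = covariates.sort_values("period").groupby("township_id")[static].first()
            data = data.merge(first, on="township_id", how="left")
    return data


def run_model_suite(
    mortality: pd.DataFrame,
    accessibility: pd.DataFrame,
    covariates: pd.DataFrame,
    supply_kinds: tuple[str, ...] = ("beds",),
    period_effects: bool = False,
) -> pd.DataFrame:
    """Fit Models 1-3 x {total, pci, non_pci} x {level, change} per supply kind.

    Returns a long DataFrame (18 rows per supply kind) mirroring the layout
    of the level- and change-association tables; any missing component
    surface raises a SchemaError naming it.
    """
    if mortality is None or mortality.empty:
        raise SchemaError("mortality surface is missing or empty")
    if accessibility is None or accessibility.empty:
        raise SchemaError("accessibility surface is missing or empty")
    if covariates is None or covariates.empty:
        raise SchemaError("covariate table is missing or empty")
    rows = []
    for supply_kind in supply_kinds:
        for stratum in ("total", "pci", "non_pci"):
            for model_id in (1, 2, 3):
                res = fit_level_model(
                    mortality, accessibility, covariates, model_id, stratum, supply_kind,
                    period_effects=period_effects,
                )
                rows.append(res.to_row())
                res = fit_change_model(
                    mortality, accessibility, covariates, model_id, stratum, supply_kind
                )
                rows.append(res.to_row())
    return pd.DataFrame(rows)
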