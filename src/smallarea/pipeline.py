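"""End-to-end orchestration: data -> accessibility -> smoothing -> rates ->
inequality -> association, with deterministic seeding and a run manifest.

The pipeline consumes either input files (GeoJSON + CSV tables) or a
synthetic-city configuration, and emits five long-format CSVs plus a
manifest:

* ``access.csv``      accessibility per township x period x stratum
* ``mortality.csv``   standardized mortality with 95% CIs per township x period
* ``inequality.csv``  P90/P10 and CV per period and group
* ``changes.csv``     township percent changes (first -> last period)
* ``assoc.csv``       the association model suite (levels and changes)
* ``manifest.json``   config hash, seeds, and package version

Standardization is draw-wise: stratum-level posterior rate draws from the
per-(sex, age, period) BYM fits are combined with the standard weights draw
by draw, so the reported CIs are CIs of the standardized rates.  Stage seeds
fan out deterministically from the global seed; two runs with the same
config and seed produce byte-identical outputs (the manifest carries no
timestamps for exactly this reason).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import DecaySpec, stratified_accessibility
from .association import run_model_suite
from .bym import BYMConfig, BYMModel, posterior_summary
from .errors import ConfigError, SmallAreaError
from .rates import (
    AGE_SEX_STANDARD_WEIGHTS,
    AGE_STANDARD_WEIGHTS,
    classify_changes,
    coefficient_of_variation,
    decile_ratio,
    percent_change,
    standardize_draws,
)
from .schema import (
    AGE_GROUPS,
    SEXES,
    CityFrame,
    load_city,
    load_deaths,
    load_hospitals,
    write_surface,
)
from .synthetic import SimulationConfig, generate_city

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "standardized_mortality"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of (paths | synthetic) is set."""

    out_dir: str | Path = "smallarea_out"
    seed: int = 0
    # input files (real-data route)
    geo_path: str | None = None
    pop_path: str | None = None
    hospitals_path: str | None = None
    deaths_path: str | None = None
    covariates_path: str | None = None
    # synthetic route
    synthetic: SimulationConfig | None = None
    # stage settings
    decay: DecaySpec = field(default_factory=DecaySpec)
    speed_kmh: float = 40.0
    bym: BYMConfig = field(default_factory=BYMConfig)
    supply_kinds: tuple[str, ...] = ("beds",)
    period_effects: bool = False

    def validate(self) -> None:
        has_paths = any([self.geo_path, self.pop_path, self.hospitals_path, self.deaths_path])
        if has_paths and self.synthetic is not None:
            raise ConfigError("give either input paths or a synthetic config, not both")
        if not has_paths and self.synthetic is None:
            raise ConfigError("one of input paths or a synthetic config is required")
        if has_paths and not all(
            [self.geo_path, self.pop_path, self.hospitals_path, self.deaths_path]
        ):
            raise ConfigError("all of geo/pop/hospitals/deaths paths are required together")


def _config_hash(config: PipelineConfig) -> str:
    def sanitize(o):
        if isinstance(o, dict):
            return {str(k): sanitize(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [sanitize(x) for x in o]
        if isinstance(o, (str, int, float, bool)) or o is None:
            return o
        if hasattr(o, "__dict__"):
            return sanitize({k: v for k, v in vars(o).items() if not k.startswith("_")})
        return str(o)

    fields = asdict(config)
    fields.pop("out_dir", None)  # where outputs land is not a scientific input
    payload = json.dumps(sanitize(fields), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(global_seed: int, stage: str, k: int = 0) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}:{k}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def standardized_mortality(
    city: CityFrame, deaths: pd.DataFrame, bym_config: BYMConfig, global_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BYM-smooth every stratum slice and standardize draw-wise.

    Returns (mortality surface, convergence table).  The surface has one row
    per township x period x group (total / male / female) with the
    standardized posterior mean rate and its 95% CI per 100 000 per year.
    """
    rows, conv = [], []
    draws_by_cell: dict = {}
    for p_idx, period in enumerate(city.periods):
        for s_idx, sex in enumerate(SEXES):
            for a_idx, age in enumerate(AGE_GROUPS):
                seed = _stage_seed(global_seed, "bym", p_idx * 100 + s_idx * 10 + a_idx)
                model = BYMModel.from_tables(deaths, city, sex, age, period.label)
                fit = model.fit(replace(bym_config, seed=seed))
                draws_by_cell[(period.label, sex, age)] = fit.rate_draws()
                conv.append(
                    {
                        "period": period.label,
                        "sex": sex,
                        "age_group": age,
                        "converged": fit.converged,
                        **{f"rhat_{k}": v for k, v in fit.rhat.items()},
                    }
                )
    for period in city.periods:
        cell = lambda s, a: draws_by_cell[(period.label, s, a)]
        group_draws = {
            "total": standardize_draws(
                {(s, a): cell(s, a) for s in SEXES for a in AGE_GROUPS},
                AGE_SEX_STANDARD_WEIGHTS,
            ),
            "male": standardize_draws(
                {a: cell("male", a) for a in AGE_GROUPS}, AGE_STANDARD_WEIGHTS
            ),
            "female": standardize_draws(
                {a: cell("female", a) for a in AGE_GROUPS}, AGE_STANDARD_WEIGHTS
            ),
        }
        for group, draws in group_draws.items():
            mean, lo, hi = posterior_summary(draws)
            rows.append(
                pd.DataFrame(
                    {
                        "township_id": city.township_ids,
                        "period": period.label,
                        "group": group,
                        "rate": mean,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True), pd.DataFrame(conv)


def _crude_standardized(city: CityFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """Directly standardized *crude* rates (no spatial smoothing), per period.

    Used for quick looks and for calibration experiments where the smoothing
    stage would only add computation: stratum rate = deaths / person-years
    per 100 000, standardized with the fixed weights.  Returns the same
    layout as the smoothed mortality surface but without CIs.
    """
    rows = []
    for period in city.periods:
        cell_rates = {}
        for sex in SEXES:
            for age in AGE_GROUPS:
                m = (
                    (deaths["period"] == period.label)
                    & (deaths["sex"] == sex)
                    & (deaths["age_group"] == age)
                )
                y = (
                    deaths.loc[m]
                    .set_index("township_id")["deaths"]
                    .reindex(city.townships.index, fill_value=0)
                    .to_numpy(dtype=float)
                )
                pop = city.stratum_population(period.label, sex, age).to_numpy(dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    cell_rates[(sex, age)] = np.where(
                        pop > 0, y / (pop * period.n_years) * 1e5, 0.0
                    )
        groups = {
            "total": standardize_draws(cell_rates, AGE_SEX_STANDARD_WEIGHTS),
            "male": standardize_draws(
                {a: cell_rates[("male", a)] for a in AGE_GROUPS}, AGE_STANDARD_WEIGHTS
            ),
            "female": standardize_draws(
                {a: cell_rates[("female", a)] for a in AGE_GROUPS}, AGE_STANDARD_WEIGHTS
            ),
        }
        for group, rate in groups.items():
            rows.append(
                pd.DataFrame(
                    {
                        "township_id": city.township_ids,
                        "period": period.label,
                        "group": group,
                        "rate": rate,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _inequality_table(mortality: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (period, group), sub in mortality.groupby(["period", "group"]):
        vals = sub["rate"].to_numpy()
        rows.append(
            {
                "period": period,
                "group": group,
                "p90_p10_ratio": decile_ratio(vals),
                "cv": coefficient_of_variation(vals),
            }
        )
    return pd.DataFrame(rows).sort_values(["group", "period"]).reset_index(drop=True)


def _changes_table(mortality: pd.DataFrame, accessibility: pd.DataFrame) -> pd.DataFrame:
    periods = sorted(mortality["period"].unique())
    first, last = periods[0], periods[-1]
    rows = []
    m_tot = mortality[mortality["group"] == "total"]
    wide_m = m_tot.pivot_table(index="township_id", columns="period", values="rate")
    a_tot = accessibility[
        (accessibility["stratum"] == "total")
        & (accessibility["supply_kind"] == accessibility["supply_kind"].iloc[0])
    ]
    wide_a = a_tot.pivot_table(index="township_id", columns="period", values="value")
    for tid in wide_m.index:
        rows.append(
            {
                "township_id": tid,
                "mortality_pct_change": percent_change(wide_m.loc[tid, first], wide_m.loc[tid, last]),
                "accessibility_pct_change": percent_change(
                    wide_a.loc[tid, first], wide_a.loc[tid, last]
                )
                if tid in wide_a.index
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write the output bundle; return the tables in memory.

    Any stage failure aborts with the stage name; partial outputs written so
    far are preserved in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if config.synthetic is not None:
            syn = generate_city(replace(config.synthetic, seed=_stage_seed(config.seed, "synth")))
            city, hospitals, deaths = syn.city, syn.hospitals, syn.deaths
            covariates = syn.covariates
        else:
            city = load_city(config.geo_path, config.pop_path)
            hospitals = load_hospitals(config.hospitals_path, city.periods)
            deaths = load_deaths(config.deaths_path, city)
            covariates = (
                pd.read_csv(config.covariates_path, dtype={"township_id": str, "period": str})
                if config.covariates_path
                else None
            )

        stage = "accessibility"
        access = pd.concat(
            [
                stratified_accessibility(
                    city, hospitals, config.decay, kind, config.speed_kmh
                )
                for kind in config.supply_kinds
            ],
            ignore_index=True,
        )
        write_surface(access, out / "access.csv")

        stage = "bym_smoothing"
        mortality, convergence = standardized_mortality(city, deaths, config.bym, config.seed)
        mortality.to_csv(out / "mortality.csv", index=False)
        convergence.to_csv(out / "convergence.csv", index=False)

        stage = "inequality"
        inequality = _inequality_table(mortality)
        inequality.to_csv(out / "inequality.csv", index=False)

        stage = "changes"
        changes = _changes_table(mortality, access)
        changes.to_csv(out / "changes.csv", index=False)

        stage = "association"
        assoc = None
        if covariates is not None:
            assoc = run_model_suite(
                mortality, access, covariates, config.supply_kinds, config.period_effects
            )
            assoc.to_csv(out / "assoc.csv", index=False)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_townships": city.n_townships,
            "periods": [p.label for p in city.periods],
            "supply_kinds": list(config.supply_kinds),
            "stage_seeds": {
                "synth": _stage_seed(config.seed, "synth"),
                "bym_first": _stage_seed(config.seed, "bym", 0),
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except SmallAreaError as err:
        raise SmallAreaError(f"pipeline stage {stage!r} failed: {err}") from err
    return {
        "city": city,
        "access": access,
        "mortality": mortality,
        "convergence": convergence,
        "inequality": inequality,
        "changes": changes,
        "assoc": assoc,
        "manifest": manifest,
    }


def make_report(outputs: dict | str | Path) -> str:
    """Human-readable markdown summary of a pipeline run.

    Tabulates period medians and IQRs of standardized mortality, inequality
    metrics per period, the township change classification, and the
    association suite.  Idempotent: regenerating from the same outputs gives
    the same text.
    """
    if not isinstance(outputs, dict):
        root = Path(outputs)
        read = lambda name: pd.read_csv(root / name, dtype={"township_id": str, "period": str})
        outputs = {"mortality": read("mortality.csv"), "inequality": read("inequality.csv"),
                   "changes": read("changes.csv")}
        assoc_path = root / "assoc.csv"
        outputs["assoc"] = pd.read_csv(assoc_path) if assoc_path.exists() else None
    mortality = outputs.get("mortality")
    if mortality is None or len(mortality) == 0:
        raise SmallAreaError("mortality surface is missing or empty; cannot build the report")
    lines = ["# Small-area mortality and accessibility report", ""]
    lines += ["## Standardized mortality by period (per 100 000/year)", ""]
    lines += ["| group | period | median | IQR |", "|---|---|---|---|"]
    for (group, period), sub in mortality.groupby(["group", "period"]):
        q1, med, q3 = np.quantile(sub["rate"], [0.25, 0.5, 0.75])
        lines.append(f"| {group} | {period} | {med:.1f} | ({q1:.1f}-{q3:.1f}) |")
    ineq = outputs.get("inequality")
    if ineq is not None and len(ineq):
        lines += ["", "## Geographic inequality", ""]
        lines += ["| group | period | P90/P10 | CV |", "|---|---|---|---|"]
        for _, r in ineq.iterrows():
            lines.append(
                f"| {r['group']} | {r['period']} | {r['p90_p10_ratio']:.2f} | {r['cv']:.3f} |"
            )
    changes = outputs.get("changes")
    if changes is not None and len(changes):
        summary = classify_changes(changes["mortality_pct_change"])
        lines += [
            "",
            "## Township mortality changes (first to last period)",
            "",
            f"- declining: {summary['n_declining']}/{summary['n']} "
            f"({summary['pct_declining']:.1f}%)",
            f"- declining >=50%: {summary['n_declining_50']}/{summary['n']} "
            f"({summary['pct_declining_50']:.1f}%)",
            f"- increasing: {summary['n_increasing']}/{summary['n']} "
            f"({summary['pct_increasing']:.1f}%)",
        ]
        acc = classify_changes(changes["accessibility_pct_change"])
        lines.append(
            f"- accessibility increasing: {acc['n_increasing']}/{acc['n']} "
            f"({acc['pct_increasing']:.1f}%)"
        )
    assoc = outputs.get("assoc")
    if assoc is not None and len(assoc):
        lines += ["", "## Association models", ""]
        lines += [
            "| form | stratum | model | beta | 95% CI | p |",
            "|---|---|---|---|---|---|",
        ]
        for _, r in assoc.iterrows():
            lines.append(
                f"| {r['form']} | {r['stratum']} | {int(r['model_id'])} | {r['beta']:.3f} "
                f"| ({r['ci_low']:.3f}, {r['ci_high']:.3f}) | {r['p_value']:.3g} |"
            )
    return "\n".join(lines) + "\n"
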