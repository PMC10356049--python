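"""Synthetic cities with the statistical structure the analysis assumes.

The registry data behind the original study design are access-restricted, so
every downstream stage is exercised on generated cities that emulate the
study setting: ~300 contiguous townships tiling a ~120 km square (Voronoi
cells of uniform points, or a regular grid for closed-form checks),
log-normal township populations calibrated to a median of ~34 000 with a
P90/P10 spread of ~8, hospitals clustered toward the urban core with
log-normal bed counts, and Poisson death counts driven by a spatially
correlated log-relative-risk surface:

    deaths[i, s] ~ Poisson( pop[i, s] * years * rate_s *
                            exp(alpha + u_i + v_i + gamma * A_i + trend_t) )

with u an intrinsic CAR (ICAR) field on the contiguity graph, v i.i.d.
Gaussian noise, and an optional injected accessibility effect gamma used to
test the association stage (the original analysis estimates such an
association; the injection here is a testing device, not an empirical claim).

Population strata use the 2010-census standard-population composition
(sex x three age bands of the 35+ population), so direct standardization is
exercised non-trivially; baseline stratum rates increase with age and are
higher in men, with magnitudes giving period-by-sex death totals of order
8000 at 307 townships.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .errors import ConfigError
from .schema import (
    AGE_GROUPS,
    DEFAULT_PERIODS,
    CityFrame,
    Period,
    SEXES,
    build_adjacency,
)

__all__ = ["SimulationConfig", "SyntheticCity", "generate_city", "sample_icar", "simulate_deaths"]

#: 2010-census composition of the 35+ population, sex x age band (fractions of total)
POPULATION_COMPOSITION = {
    ("male", "35-64"): 0.431,
    ("male", "65-79"): 0.066,
    ("male", "80+"): 0.014,
    ("female", "35-64"): 0.398,
    ("female", "65-79"): 0.074,
    ("female", "80+"): 0.017,
}

#: baseline mortality per 100 000 per year by (sex, age band)
DEFAULT_BASELINE_RATES = {
    ("male", "35-64"): 10.0,
    ("male", "65-79"): 120.0,
    ("male", "80+"): 500.0,
    ("female", "35-64"): 5.0,
    ("female", "65-79"): 80.0,
    ("female", "80+"): 450.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults are the study conditions.

    Populations are log-normal with median exp(population_log_mean); the
    default log-mean 10.43 and log-sd 0.82 put the median at ~33 900 and the
    P90/P10 ratio at ~8.2.  ``urban_concentration`` >= 0 controls how tightly
    hospitals cluster at the city center (0 = uniform).  ``period_trend`` is
    an additive log-risk step per period, capturing the secular mortality
    decline.  ``gamma`` is the per-unit (supply per 1000) effect of
    accessibility on log risk; 0 by default (null city).
    """

    n_townships: int = 307
    seed: int = 0
    city_width_m: float = 120_000.0
    layout: str = "voronoi"  # or "grid"
    population_log_mean: float = 10.43
    population_log_sd: float = 0.82
    population_growth: float = 0.03  # per period, multiplicative
    n_hospitals: int = 150
    urban_concentration: float = 2.0
    beds_log_mean: float = 6.0
    beds_log_sd: float = 0.8
    personnel_per_bed: float = 1.4
    pci_fraction: float = 0.3
    hospital_open_fraction: float = 0.6  # fraction active from the first period
    alpha: float = 0.0
    tau_u: float = 10.0
    tau_v: float = 25.0
    gamma: float = 0.0
    period_trend: float = -0.15
    baseline_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    periods: tuple[Period, ...] = DEFAULT_PERIODS
    contiguity: str = "rook"

    def validate(self) -> None:
        if self.n_townships < 4:
            raise ConfigError(f"n_townships must be >= 4, got {self.n_townships}")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ConfigError("precisions tau_u, tau_v must be > 0")
        if self.urban_concentration < 0:
            raise ConfigError("urban_concentration must be >= 0")
        if not (0 < self.pci_fraction <= 1):
            raise ConfigError("pci_fraction must be in (0, 1]")
        for key, r in self.baseline_rates.items():
            if r <= 0:
                raise ConfigError(f"baseline rate for {key} must be > 0")
            # expected deaths must not exceed population: rate * years * e^headroom < 1
            n_years = self.periods[0].n_years
            if r / 1e5 * n_years * np.exp(abs(self.alpha) + 3.0) > 1.0:
                raise ConfigError(
                    f"baseline rate {r}/100k for {key} implies expected deaths "
                    "exceeding population under plausible risk surfaces"
                )
        if self.layout not in ("voronoi", "grid"):
            raise ConfigError(f"unknown layout {self.layout!r}")


@dataclass
class SyntheticCity:
    """A generated city plus the ground truth used to generate it."""

    city: CityFrame
    hospitals: pd.DataFrame
    deaths: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame  # township_id, u, v, log_rr (alpha + u + v)
    config: SimulationConfig


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _voronoi_polygons(points: np.ndarray, width: float) -> list[Polygon]:
    """Finite Voronoi cells clipped to [0, width]^2 via point mirroring."""
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, width), (1, 0.0), (1, width)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    square = box(0.0, 0.0, width, width)
    polys = []
    for k in range(len(points)):
        region = vor.regions[vor.point_region[k]]
        poly = Polygon(vor.vertices[region]).intersection(square)
        polys.append(poly)
    return polys


def _grid_polygons(n: int, width: float) -> list[Polygon]:
    side = int(np.ceil(np.sqrt(n)))
    cell = width / side
    polys = []
    for k in range(n):
        r, c = divmod(k, side)
        polys.append(box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell))
    return polys


# ---------------------------------------------------------------------------
# ICAR field
# ---------------------------------------------------------------------------

def sample_icar(adjacency: nx.Graph, tau_u: float, seed: int | np.random.Generator) -> np.ndarray:
    """Draw a zero-sum intrinsic CAR field on a connected graph.

    The ICAR precision Q = tau_u (D - W) is rank n-1; the draw is taken in
    the non-null eigenspace (covariance = pseudo-inverse of Q) and therefore
    sums to zero by construction.
    """
    if tau_u <= 0:
        raise ConfigError("tau_u must be > 0")
    nodes = list(adjacency.nodes)
    n = len(nodes)
    if n > 1 and not nx.is_connected(adjacency):
        from .errors import ConnectivityError

        raise ConnectivityError(nx.connected_components(adjacency))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lap = nx.laplacian_matrix(adjacency, nodelist=nodes).toarray().astype(float)
    eigval, eigvec = np.linalg.eigh(tau_u * lap)
    # first eigenvalue ~0 corresponds to the constant (null) direction
    z = rng.standard_normal(n - 1)
    u = eigvec[:, 1:] @ (z / np.sqrt(eigval[1:]))
    return u - u.mean()


# ---------------------------------------------------------------------------
# deaths
# ---------------------------------------------------------------------------

def simulate_deaths(
    city: CityFrame,
    log_rr: np.ndarray,
    accessibility: pd.DataFrame | None,
    gamma: float,
    baseline_rates: dict,
    seed: int | np.random.Generator,
    period_trend: float = 0.0,
) -> pd.DataFrame:
    """Poisson death counts per township x period x sex x age band.

    deaths ~ Poisson(pop * years * rate_s/1e5 * exp(log_rr + gamma*A + trend)).
    ``accessibility`` is a long surface with stratum 'total' (may be None when
    gamma is 0).  Expected counts exceeding the stratum population raise a
    config error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_rr = np.asarray(log_rr, dtype=float)
    rows = []
    for t_idx, period in enumerate(city.periods):
        if accessibility is not None and gamma != 0.0:
            acc = accessibility[
                (accessibility["period"] == period.label)
                & (accessibility["stratum"] == "total")
            ].set_index("township_id")["value"]
            a = acc.reindex(city.townships.index).to_numpy(dtype=float)
        else:
            a = np.zeros(city.n_townships)
        rr = np.exp(log_rr + gamma * a + period_trend * t_idx)
        for (sex, age), rate in baseline_rates.items():
            pop = city.stratum_population(period.label, sex, age).to_numpy(dtype=float)
            mu = pop * period.n_years * rate / 1e5 * rr
            if np.any(mu > pop * period.n_years):
                raise ConfigError(
                    f"expected deaths exceed person-years in stratum "
                    f"({sex}, {age}, {period.label}); lower the baseline rate"
                )
            y = rng.poisson(mu)
            rows.append(
                pd.DataFrame(
                    {
                        "township_id": city.township_ids,
                        "period": period.label,
                        "sex": sex,
                        "age_group": age,
                        "deaths": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# the full generator
# ---------------------------------------------------------------------------

def _make_covariates(
    city: CityFrame, centers: np.ndarray, width: float, rng: np.random.Generator
) -> pd.DataFrame:
    """District-blocked covariates: risk factors per period + socioeconomics.

    Townships are grouped into a 4x4 grid of districts; each district gets a
    base prevalence for hypertension/diabetes/hypercholesterolemia/smoking
    (higher away from the urban core), a mild upward trend over periods, and
    socioeconomic levels (income and education higher near the core).
    """
    n = city.n_townships
    width_d = width / 4
    dist_r = np.floor(centers[:, 0] / width_d).clip(0, 3).astype(int)
    dist_c = np.floor(centers[:, 1] / width_d).clip(0, 3).astype(int)
    district = dist_r * 4 + dist_c
    center = np.array([width / 2, width / 2])
    periurban = np.hypot(*(centers - center).T) / (width / 2)  # 0 core .. ~1.4 corner

    base = {}
    for d in np.unique(district):
        mask = district == d
        peri = periurban[mask].mean()
        base[d] = {
            "hypertension": 0.25 + 0.08 * peri + rng.normal(0, 0.02),
            "diabetes": 0.08 + 0.03 * peri + rng.normal(0, 0.01),
            "hypercholesterolemia": 0.10 + 0.02 * peri + rng.normal(0, 0.01),
            "smoking": 0.20 + 0.05 * peri + rng.normal(0, 0.02),
            "income": 40_000 * np.exp(-0.5 * peri + rng.normal(0, 0.1)),
            "married": float(np.clip(0.75 + rng.normal(0, 0.03), 0, 1)),
            "unemployed": float(np.clip(0.04 + 0.02 * peri + rng.normal(0, 0.01), 0, 1)),
        }
    high_school = np.clip(0.6 - 0.25 * periurban + rng.normal(0, 0.05, n), 0.05, 0.95)
    rows = []
    for t_idx, period in enumerate(city.periods):
        trend = 0.01 * t_idx  # risk factors creep upward over the study
        for k, tid in enumerate(city.township_ids):
            b = base[district[k]]
            rows.append(
                {
                    "township_id": tid,
                    "period": period.label,
                    "district": int(district[k]),
                    "hypertension": float(np.clip(b["hypertension"] + trend, 0, 1)),
                    "diabetes": float(np.clip(b["diabetes"] + trend / 2, 0, 1)),
                    "hypercholesterolemia": float(np.clip(b["hypercholesterolemia"] + trend / 2, 0, 1)),
                    "smoking": float(np.clip(b["smoking"] - trend, 0, 1)),
                    "income": b["income"],
                    "married": b["married"],
                    "high_school": float(high_school[k]),
                    "unemployed": b["unemployed"],
                }
            )
    return pd.DataFrame(rows)


def generate_city(config: SimulationConfig) -> SyntheticCity:
    """Generate a full synthetic city; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, width = config.n_townships, config.city_width_m

    # --- townships -------------------------------------------------------
    if config.layout == "grid":
        polys = _grid_polygons(n, width)
    else:
        pts = rng.uniform(0, width, size=(n, 2))
        polys = _voronoi_polygons(pts, width)
    ids = [f"T{k:04d}" for k in range(n)]
    townships = pd.DataFrame(
        {
            "geometry": polys,
            "cx": [p.centroid.x for p in polys],
            "cy": [p.centroid.y for p in polys],
        },
        index=pd.Index(ids, name="township_id"),
    )
    adjacency = build_adjacency(dict(zip(ids, polys)), rule=config.contiguity)

    # --- populations -----------------------------------------------------
    base_pop = rng.lognormal(config.population_log_mean, config.population_log_sd, n)
    pop_rows = []
    for t_idx, period in enumerate(config.periods):
        total = base_pop * (1 + config.population_growth) ** t_idx
        for (sex, age), frac in POPULATION_COMPOSITION.items():
            pop_rows.append(
                pd.DataFrame(
                    {
                        "township_id": ids,
                        "period": period.label,
                        "sex": sex,
                        "age_group": age,
                        "population": np.round(total * frac).astype(int),
                    }
                )
            )
    population = pd.concat(pop_rows, ignore_index=True)
    city = CityFrame(townships, population, adjacency, config.periods)

    # --- hospitals -------------------------------------------------------
    m = config.n_hospitals
    sd = width / (2.0 * (1.0 + config.urban_concentration))
    hxy = np.clip(rng.normal(width / 2, sd, size=(m, 2)), 0, width)
    beds = np.maximum(20, np.round(rng.lognormal(config.beds_log_mean, config.beds_log_sd, m))).astype(int)
    personnel = np.round(beds * config.personnel_per_bed * rng.uniform(0.8, 1.2, m)).astype(int)
    n_pci = max(1, int(round(config.pci_fraction * m)))
    is_pci = np.zeros(m, dtype=bool)
    is_pci[np.argsort(beds)[::-1][:n_pci]] = True  # largest hospitals do PCI
    labels = [p.label for p in config.periods]
    first = np.where(
        rng.uniform(size=m) < config.hospital_open_fraction,
        0,
        rng.integers(1, len(labels), size=m),
    )
    hospitals = pd.DataFrame(
        {
            "hospital_id": [f"H{k:03d}" for k in range(m)],
            "x": hxy[:, 0],
            "y": hxy[:, 1],
            "beds": beds,
            "personnel": personnel,
            "is_pci": is_pci,
            "first_period": [labels[f] for f in first],
        }
    )

    # --- risk surface and deaths ----------------------------------------
    u = sample_icar(adjacency, config.tau_u, rng)
    v = rng.normal(0, 1 / np.sqrt(config.tau_v), n)
    log_rr = config.alpha + u + v
    accessibility = None
    if config.gamma != 0.0:
        from .accessibility import compute_accessibility

        accessibility = compute_accessibility(city, hospitals)
    deaths = simulate_deaths(
        city,
        log_rr,
        accessibility,
        config.gamma,
        config.baseline_rates,
        rng,
        period_trend=config.period_trend,
    )
    covariates = _make_covariates(city, city.centroids(), width, rng)
    truth = pd.DataFrame(
        {"township_id": ids, "u": u, "v": v, "log_rr": log_rr, "gamma": config.gamma}
    )
    return SyntheticCity(city, hospitals, deaths, covariates, truth, config)
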