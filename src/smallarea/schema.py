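"""Shared data model and file I/O for the small-area mortality analysis.

The spatial backbone is a :class:`CityFrame`: township polygons in a projected
planar CRS (meters), their centroids, stratified populations per 3-year
period, and a symmetric contiguity (adjacency) relation.  Supply units live in
a hospital table; observed outcomes in a death table stratified by township,
period, sex and age group.

File formats are deliberately plain: GeoJSON FeatureCollections for geometry
(the ``township_id`` property is the key) and UTF-8 comma-separated CSV with a
header row for every table.  Geometry must already be in a projected CRS in
meters — geographic (lon/lat) coordinates are rejected, never silently
reprojected, because every distance computation downstream is planar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import ConnectivityError, SchemaError

__all__ = [
    "Period",
    "CityFrame",
    "SEXES",
    "AGE_GROUPS",
    "DEFAULT_PERIODS",
    "build_adjacency",
    "load_city",
    "write_city",
    "load_hospitals",
    "write_hospitals",
    "validate_hospitals",
    "load_deaths",
    "write_deaths",
    "validate_deaths",
    "write_surface",
    "read_surface",
]

SEXES = ("male", "female")
AGE_GROUPS = ("35-64", "65-79", "80+")

HOSPITAL_COLUMNS = ["hospital_id", "x", "y", "beds", "personnel", "is_pci", "first_period"]
DEATH_COLUMNS = ["township_id", "period", "sex", "age_group", "deaths"]
POPULATION_COLUMNS = ["township_id", "period", "sex", "age_group", "population"]


@dataclass(frozen=True)
class Period:
    """A 3-year aggregation window, e.g. ``Period("2007-2009", (2007, 2009))``."""

    label: str
    years: tuple[int, int]

    def __post_init__(self):
        lo, hi = self.years
        if hi - lo != 2:
            raise SchemaError(f"period {self.label!r}: years {self.years} do not span 3 years")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @classmethod
    def from_label(cls, label: str) -> "Period":
        lo, hi = label.split("-")
        return cls(label, (int(lo), int(hi)))


#: The default study design: four contiguous 3-year periods, 2007-2018.
DEFAULT_PERIODS = (
    Period("2007-2009", (2007, 2009)),
    Period("2010-2012", (2010, 2012)),
    Period("2013-2015", (2013, 2015)),
    Period("2016-2018", (2016, 2018)),
)


def validate_periods(periods: Sequence[Period]) -> None:
    """Periods must be consecutive, non-overlapping 3-year windows."""
    if not periods:
        raise SchemaError("at least one period is required")
    for a, b in zip(periods, periods[1:]):
        if b.years[0] != a.years[1] + 1:
            raise SchemaError(
                f"periods {a.label!r} and {b.label!r} leave a gap or overlap"
            )


@dataclass
class CityFrame:
    """Townships: geometry, centroids, stratified populations, adjacency.

    Parameters
    ----------
    townships : DataFrame indexed by township_id with columns
        ``geometry`` (shapely polygon, projected meters), ``cx``, ``cy``
        (centroid coordinates, meters).
    population : long DataFrame with columns township_id, period, sex,
        age_group, population (non-negative, per-period counts).
    adjacency : networkx.Graph over township_ids (symmetric, irreflexive).
    periods : the study periods, in chronological order.
    """

    townships: pd.DataFrame
    population: pd.DataFrame
    adjacency: nx.Graph
    periods: tuple[Period, ...] = DEFAULT_PERIODS

    def __post_init__(self):
        self.periods = tuple(self.periods)
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        idx = self.townships.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate township_id(s): {dupes}")
        missing_cols = {"geometry", "cx", "cy"} - set(self.townships.columns)
        if missing_cols:
            raise SchemaError(f"townships table missing column(s): {sorted(missing_cols)}")
        missing = set(POPULATION_COLUMNS) - set(self.population.columns)
        if missing:
            raise SchemaError(f"population table missing column(s): {sorted(missing)}")
        unknown = set(self.population["township_id"]) - set(idx)
        if unknown:
            raise SchemaError(
                f"population rows reference unknown township_id(s): {sorted(unknown)[:5]}"
            )
        if (self.population["population"] < 0).any():
            bad = self.population.loc[self.population["population"] < 0].iloc[0]
            raise SchemaError(
                f"negative population for township {bad['township_id']!r}, "
                f"period {bad['period']!r}, {bad['sex']}/{bad['age_group']}"
            )
        labels = {p.label for p in self.periods}
        bad_periods = set(self.population["period"]) - labels
        if bad_periods:
            raise SchemaError(f"population rows with unknown period(s): {sorted(bad_periods)}")
        validate_periods(self.periods)
        # adjacency: symmetric by construction in nx.Graph; check irreflexive + closed
        if any(u == v for u, v in self.adjacency.edges):
            raise SchemaError("adjacency contains self-loops")
        extra = set(self.adjacency.nodes) - set(idx)
        if extra:
            raise SchemaError(f"adjacency references unknown township_id(s): {sorted(extra)[:5]}")
        if len(idx) > 1 and not nx.is_connected(self.adjacency):
            raise ConnectivityError(nx.connected_components(self.adjacency))

    # -- convenience --------------------------------------------------------
    @property
    def township_ids(self) -> list[str]:
        return list(self.townships.index)

    @property
    def n_townships(self) -> int:
        return len(self.townships)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of centroid coordinates in meters."""
        return self.townships[["cx", "cy"]].to_numpy(dtype=float)

    def demand_population(self, period: str) -> pd.Series:
        """Total population (all sexes and ages) per township for a period.

        This is the demand side of the accessibility computation; the analysis
        does not stratify demand.
        """
        sub = self.population[self.population["period"] == period]
        out = sub.groupby("township_id")["population"].sum()
        return out.reindex(self.townships.index, fill_value=0.0)

    def stratum_population(self, period: str, sex: str, age_group: str) -> pd.Series:
        m = (
            (self.population["period"] == period)
            & (self.population["sex"] == sex)
            & (self.population["age_group"] == age_group)
        )
        out = self.population.loc[m].set_index("township_id")["population"]
        return out.reindex(self.townships.index, fill_value=0.0)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def build_adjacency(
    geometries: Mapping[str, BaseGeometry], rule: str = "rook"
) -> nx.Graph:
    """Polygon-contiguity graph over the mapping's keys.

    rook: neighbors share a boundary of positive length.
    queen: neighbors share a boundary or a single point.

    A single polygon yields an empty relation (with a warning, since the ICAR
    prior is undefined without neighbors).
    """
    if rule not in ("rook", "queen"):
        raise SchemaError(f"unknown contiguity rule {rule!r} (expected 'rook' or 'queen')")
    ids = list(geometries)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if len(ids) == 1:
        warnings.warn(
            "single polygon: adjacency is empty and the ICAR prior is undefined",
            stacklevel=2,
        )
        return graph
    geoms = [geometries[i] for i in ids]
    tree = STRtree(geoms)
    for a, i in enumerate(ids):
        for b in tree.query(geoms[a]):
            b = int(b)
            if b <= a:
                continue
            g1, g2 = geoms[a], geoms[b]
            if not g1.touches(g2) and not g1.intersects(g2):
                continue
            inter = g1.intersection(g2)
            if rule == "queen":
                if not inter.is_empty:
                    graph.add_edge(i, ids[b])
            else:
                if inter.length > 0:
                    graph.add_edge(i, ids[b])
    return graph


def _check_projected(geoms: Iterable[BaseGeometry]) -> None:
    """Reject coordinates that look geographic (degrees) rather than meters."""
    xs, ys = [], []
    for g in geoms:
        minx, miny, maxx, maxy = g.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    if xs and max(map(abs, xs)) <= 180.0 and max(map(abs, ys)) <= 90.0:
        raise SchemaError(
            "geometry coordinates fall inside lon/lat ranges; a projected CRS in "
            "meters is required (reproject upstream, e.g. to a local UTM zone)"
        )


# ---------------------------------------------------------------------------
# city I/O
# ---------------------------------------------------------------------------

def load_city(
    geo_path: str | Path,
    pop_path: str | Path,
    rule: str = "rook",
    periods: Sequence[Period] | None = None,
) -> CityFrame:
    """Read the township layer (GeoJSON) and population table (CSV).

    Builds adjacency with the given contiguity rule and returns a validated
    CityFrame; any invariant violation raises with a located message.
    """
    geo_path, pop_path = Path(geo_path), Path(pop_path)
    with open(geo_path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{geo_path}: expected a GeoJSON FeatureCollection")
    rows = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        tid = props.get("township_id")
        if tid is None:
            raise SchemaError(f"{geo_path}: feature {k} lacks a 'township_id' property")
        geom = shape(feat["geometry"])
        rows.append((str(tid), geom))
    if not rows:
        raise SchemaError(f"{geo_path}: no features")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{geo_path}: duplicate township_id(s): {dupes}")
    geoms = dict(rows)
    _check_projected(geoms.values())
    townships = pd.DataFrame(
        {
            "geometry": [geoms[i] for i in ids],
            "cx": [geoms[i].centroid.x for i in ids],
            "cy": [geoms[i].centroid.y for i in ids],
        },
        index=pd.Index(ids, name="township_id"),
    )
    population = pd.read_csv(pop_path, dtype={"township_id": str, "period": str})
    missing = set(POPULATION_COLUMNS) - set(population.columns)
    if missing:
        raise SchemaError(f"{pop_path}: missing column(s): {sorted(missing)}")
    if periods is None:
        periods = tuple(
            sorted(
                (Period.from_label(p) for p in population["period"].unique()),
                key=lambda p: p.years,
            )
        )
    adjacency = build_adjacency(geoms, rule=rule)
    return CityFrame(townships, population, adjacency, tuple(periods))


def write_city(city: CityFrame, geo_path: str | Path, pop_path: str | Path) -> None:
    """Write a CityFrame back to GeoJSON + CSV (inverse of :func:`load_city`)."""
    features = [
        {
            "type": "Feature",
            "properties": {"township_id": tid},
            "geometry": mapping(row["geometry"]),
        }
        for tid, row in city.townships.iterrows()
    ]
    with open(geo_path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    city.population.to_csv(pop_path, index=False)


# ---------------------------------------------------------------------------
# hospitals & deaths
# ---------------------------------------------------------------------------

def validate_hospitals(hospitals: pd.DataFrame, periods: Sequence[Period] = DEFAULT_PERIODS) -> pd.DataFrame:
    missing = set(HOSPITAL_COLUMNS) - set(hospitals.columns)
    if missing:
        raise SchemaError(f"hospital table missing column(s): {sorted(missing)}")
    if hospitals["hospital_id"].duplicated().any():
        dupes = hospitals.loc[hospitals["hospital_id"].duplicated(), "hospital_id"].tolist()
        raise SchemaError(f"duplicate hospital_id(s): {dupes}")
    for col in ("beds", "personnel"):
        if (hospitals[col] < 0).any():
            bad = hospitals.loc[hospitals[col] < 0, "hospital_id"].iloc[0]
            raise SchemaError(f"hospital {bad!r}: negative {col}")
    labels = [p.label for p in periods]
    bad = set(hospitals["first_period"]) - set(labels)
    if bad:
        raise SchemaError(f"hospital first_period value(s) not a study period: {sorted(bad)}")
    return hospitals


def active_mask(hospitals: pd.DataFrame, period: str, periods: Sequence[Period] = DEFAULT_PERIODS) -> np.ndarray:
    """Hospitals contribute supply only from their first active period onward."""
    order = {p.label: k for k, p in enumerate(periods)}
    if period not in order:
        raise SchemaError(f"unknown period {period!r}")
    firsts = hospitals["first_period"].map(order)
    return (firsts <= order[period]).to_numpy()


def load_hospitals(path: str | Path, periods: Sequence[Period] = DEFAULT_PERIODS) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"hospital_id": str, "first_period": str})
    if "is_pci" in df.columns:
        df["is_pci"] = df["is_pci"].astype(bool)
    return validate_hospitals(df, periods)


def write_hospitals(hospitals: pd.DataFrame, path: str | Path) -> None:
    hospitals.to_csv(path, index=False)


def validate_deaths(deaths: pd.DataFrame, city: CityFrame | None = None) -> pd.DataFrame:
    missing = set(DEATH_COLUMNS) - set(deaths.columns)
    if missing:
        raise SchemaError(f"death table missing column(s): {sorted(missing)}")
    key = ["township_id", "period", "sex", "age_group"]
    if deaths.duplicated(subset=key).any():
        bad = deaths.loc[deaths.duplicated(subset=key), key].iloc[0].tolist()
        raise SchemaError(f"duplicate death-table key: {bad}")
    if (deaths["deaths"] < 0).any():
        raise SchemaError("negative death counts present")
    bad_age = set(deaths["age_group"]) - set(AGE_GROUPS)
    if bad_age:
        raise SchemaError(f"unknown age group(s) {sorted(bad_age)}; expected {AGE_GROUPS}")
    bad_sex = set(deaths["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"unknown sex value(s) {sorted(bad_sex)}; expected {SEXES}")
    if city is not None:
        unknown = set(deaths["township_id"]) - set(city.townships.index)
        if unknown:
            raise SchemaError(f"death rows reference unknown township_id(s): {sorted(unknown)[:5]}")
    return deaths


def load_deaths(path: str | Path, city: CityFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"township_id": str, "period": str})
    return validate_deaths(df, city)


def write_deaths(deaths: pd.DataFrame, path: str | Path) -> None:
    deaths.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

SURFACE_KEY = ["township_id", "period", "stratum"]


def write_surface(surface: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format surface CSV (township_id, period, stratum, value[, ci]).

    Read-back with :func:`read_surface` reproduces the values to full float
    precision (pandas writes shortest round-tripping decimal representations).
    """
    missing = {"township_id", "period", "value"} - set(surface.columns)
    if missing:
        raise SchemaError(f"surface missing column(s): {sorted(missing)}")
    surface.to_csv(path, index=False)


def read_surface(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"township_id": str, "period": str})
    missing = {"township_id", "period", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: surface missing column(s): {sorted(missing)}")
    return df
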