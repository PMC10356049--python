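"""Enhanced two-step floating catchment area (E2SFCA) accessibility.

Accessibility of township *i* to hospital care is measured in supply units
(beds, or personnel in the sensitivity variant) per 1000 population:

    step 1:  R_j = S_j / sum_i W(t_ij) P_i        (supply-to-demand ratio)
    step 2:  A_i = 1000 * sum_j W(t_ij) R_j

where t_ij is the travel time from township centroid i to hospital j and W is
a distance-decay weight that vanishes beyond the catchment threshold d0.  The
default kernel is the normalized Gaussian with a hard cutoff,

    W(t) = [exp(-(1/2)(t/d0)^2) - exp(-1/2)] / [1 - exp(-1/2)]   for t <= d0,
    W(t) = 0                                                      for t  > d0,

which is 1 at t=0, falls continuously to 0 at t=d0, and encodes that closer
facilities are preferred even within a shared catchment.  A binary kernel
(1 inside the catchment) is available for closed-form checks.

The method conserves supply: summed over townships, P_i A_i / 1000 equals the
total supply of all hospitals that reach at least one person.  Stratifying
hospitals (PCI vs non-PCI) against the full population demand keeps the
stratified surfaces additive: pci + non_pci = total, exactly.

Travel times default to straight-line distance over a constant driving speed;
a user-supplied townships x hospitals matrix of minutes (e.g. from a road
network router) bypasses this and is the recommended path for real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .schema import CityFrame, DEFAULT_PERIODS, active_mask

__all__ = [
    "DecaySpec",
    "travel_time_matrix",
    "decay_weight",
    "step1_supply_ratio",
    "step2_accessibility",
    "compute_accessibility",
    "stratified_accessibility",
]

log = logging.getLogger(__name__)

#: default catchment: 60 minutes of driving at 40 km/h
DEFAULT_D0_MINUTES = 60.0
DEFAULT_SPEED_KMH = 40.0


@dataclass(frozen=True)
class DecaySpec:
    """Distance-decay kernel: catchment threshold ``d0`` (minutes) and form."""

    d0: float = DEFAULT_D0_MINUTES
    form: str = "gaussian_normalized"

    def __post_init__(self):
        if self.d0 <= 0:
            raise ConfigError(f"catchment threshold d0 must be > 0, got {self.d0}")
        if self.form not in ("gaussian_normalized", "binary"):
            raise ConfigError(f"unknown decay form {self.form!r}")


def travel_time_matrix(
    city: CityFrame, hospitals: pd.DataFrame, speed_kmh: float = DEFAULT_SPEED_KMH
) -> np.ndarray:
    """Euclidean travel times in minutes, townships x hospitals.

    Coordinates are planar meters; ``speed_kmh`` converts distance to driving
    time.  Zero iff the two points coincide.
    """
    if speed_kmh <= 0:
        raise ConfigError(f"speed must be > 0 km/h, got {speed_kmh}")
    cent = city.centroids()  # (n, 2) meters
    hxy = hospitals[["x", "y"]].to_numpy(dtype=float)  # (m, 2)
    d = np.hypot(cent[:, None, 0] - hxy[None, :, 0], cent[:, None, 1] - hxy[None, :, 1])
    meters_per_minute = speed_kmh * 1000.0 / 60.0
    return d / meters_per_minute


def decay_weight(t: np.ndarray | float, spec: DecaySpec) -> np.ndarray | float:
    """Distance-decay weight in [0, 1]; monotone non-increasing on [0, d0]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("travel times must be non-negative")
    if spec.form == "binary":
        w = (t <= spec.d0).astype(float)
    else:
        half = np.exp(-0.5)
        w = np.where(
            t <= spec.d0,
            (np.exp(-0.5 * (t / spec.d0) ** 2) - half) / (1.0 - half),
            0.0,
        )
    return w if w.ndim else float(w)


def step1_supply_ratio(
    supply: np.ndarray, demand_pop: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Per-hospital supply-to-demand ratio R_j = S_j / sum_i W_ij P_i.

    A hospital with positive supply whose catchment covers zero weighted
    population gets R_j = 0 (no demand, no allocation) with a logged warning.
    """
    supply = np.asarray(supply, dtype=float)
    weighted_demand = weights.T @ np.asarray(demand_pop, dtype=float)  # per hospital
    ratio = np.zeros_like(supply)
    ok = weighted_demand > 0
    ratio[ok] = supply[ok] / weighted_demand[ok]
    orphan = (~ok) & (supply > 0)
    if orphan.any():
        log.warning(
            "%d hospital(s) with supply but zero weighted demand in catchment; "
            "their supply ratio is set to 0 (indices %s)",
            int(orphan.sum()),
            np.flatnonzero(orphan).tolist(),
        )
    return ratio


def step2_accessibility(ratio: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-township accessibility A_i = 1000 * sum_j W_ij R_j (per 1000 pop)."""
    return 1000.0 * (weights @ np.asarray(ratio, dtype=float))


def _one_period(
    city: CityFrame,
    hospitals: pd.DataFrame,
    period: str,
    spec: DecaySpec,
    supply_kind: str,
    speed_kmh: float,
    tt: np.ndarray,
    hospital_subset: np.ndarray | None = None,
) -> np.ndarray:
    act = active_mask(hospitals, period, city.periods)
    if hospital_subset is not None:
        act = act & hospital_subset
    pop = city.demand_population(period).to_numpy(dtype=float)
    if not act.any():
        return np.zeros(city.n_townships)
    w = decay_weight(tt[:, act], spec)
    supply = hospitals.loc[act, supply_kind].to_numpy(dtype=float)
    ratio = step1_supply_ratio(supply, pop, w)
    return step2_accessibility(ratio, w)


def compute_accessibility(
    city: CityFrame,
    hospitals: pd.DataFrame,
    spec: DecaySpec = DecaySpec(),
    supply_kind: str = "beds",
    speed_kmh: float = DEFAULT_SPEED_KMH,
    travel_times: np.ndarray | None = None,
    periods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Total accessibility surface: township x period, supply per 1000 pop.

    ``travel_times`` (townships x hospitals, minutes) overrides the Euclidean
    default.  Hospitals contribute only in periods at or after their
    ``first_period``; demand is the period's total population.
    """
    return stratified_accessibility(
        city, hospitals, spec, supply_kind, speed_kmh, travel_times, periods,
        strata=("total",),
    )


def stratified_accessibility(
    city: CityFrame,
    hospitals: pd.DataFrame,
    spec: DecaySpec = DecaySpec(),
    supply_kind: str = "beds",
    speed_kmh: float = DEFAULT_SPEED_KMH,
    travel_times: np.ndarray | None = None,
    periods: Sequence[str] | None = None,
    strata: Sequence[str] = ("total", "pci", "non_pci"),
) -> pd.DataFrame:
    """Accessibility per hospital stratum (total / pci / non_pci).

    Step-1 ratios are computed within each hospital subset against the *full*
    population demand, so pci + non_pci = total holds exactly per
    township-period.  An empty subset yields an all-zero surface with a
    warning.
    """
    if supply_kind not in ("beds", "personnel"):
        raise ConfigError(f"supply_kind must be 'beds' or 'personnel', got {supply_kind!r}")
    if travel_times is None:
        tt = travel_time_matrix(city, hospitals, speed_kmh)
    else:
        tt = np.asarray(travel_times, dtype=float)
        if tt.shape != (city.n_townships, len(hospitals)):
            raise ContractError(
                f"travel-time matrix shape {tt.shape} does not match "
                f"(townships={city.n_townships}, hospitals={len(hospitals)})"
            )
    if periods is None:
        periods = [p.label for p in city.periods]
    is_pci = hospitals["is_pci"].to_numpy(dtype=bool)
    subsets = {"total": None, "pci": is_pci, "non_pci": ~is_pci}
    for name in strata:
        sub = subsets.get(name)
        if sub is not None and not sub.any():
            log.warning("hospital stratum %r is empty; its surface is all zero", name)
    rows = []
    for period in periods:
        for name in strata:
            a = _one_period(
                city, hospitals, period, spec, supply_kind, speed_kmh, tt,
                hospital_subset=subsets[name],
            )
            rows.append(
                pd.DataFrame(
                    {
                        "township_id": city.township_ids,
                        "period": period,
                        "supply_kind": supply_kind,
                        "stratum": name,
                        "value": a,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
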