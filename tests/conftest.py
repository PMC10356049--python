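import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from smallarea import CityFrame, Period, SimulationConfig, build_adjacency, generate_city

# a single valid 3-year study period for toy fixtures
P1 = Period("2007-2009", (2007, 2009))


def make_grid_city(n_side: int, populations, cell_m: float = 10_000.0,
                   periods=(P1,)) -> CityFrame:
    """Regular n_side x n_side grid of square townships with given total pops.

    ``populations`` is a flat sequence (len n_side**2); the whole population
    is placed in a single stratum (male, 35-64) so that demand totals equal
    the given numbers.
    """
    n = n_side * n_side
    polys = {}
    for k in range(n):
        r, c = divmod(k, n_side)
        polys[f"T{k}"] = box(c * cell_m, r * cell_m, (c + 1) * cell_m, (r + 1) * cell_m)
    ids = list(polys)
    townships = pd.DataFrame(
        {
            "geometry": [polys[i] for i in ids],
            "cx": [polys[i].centroid.x for i in ids],
            "cy": [polys[i].centroid.y for i in ids],
        },
        index=pd.Index(ids, name="township_id"),
    )
    rows = []
    for p in periods:
        for i, pop in zip(ids, populations):
            rows.append((i, p.label, "male", "35-64", pop))
    population = pd.DataFrame(rows, columns=["township_id", "period", "sex", "age_group", "population"])
    with warnings.catch_warnings():
        if n == 1:  # the single-polygon ICAR warning is expected for 1-cell toys
            warnings.simplefilter("ignore", UserWarning)
        adjacency = build_adjacency(polys)
    return CityFrame(townships, population, adjacency, tuple(periods))


def make_hospitals(coords, beds, is_pci=None, personnel=None, first_period=P1.label):
    m = len(coords)
    return pd.DataFrame(
        {
            "hospital_id": [f"H{k}" for k in range(m)],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "beds": list(beds),
            "personnel": list(personnel) if personnel is not None else list(beds),
            "is_pci": list(is_pci) if is_pci is not None else [False] * m,
            "first_period": first_period,
        }
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A 40-township synthetic city shared by read-only tests."""
    return generate_city(SimulationConfig(n_townships=40, seed=1, n_hospitals=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
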