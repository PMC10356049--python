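"""Plain choropleth export for township surfaces.

Deliberately minimal: fill polygons by value with a colorbar, nothing more.
Styled map products belong in a GIS, not here.
"""

from __future__ import annotations

import numpy as np
from matplotlib import pyplot as plt
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon

from .errors import SchemaError
from .schema import CityFrame

__all__ = ["plot_choropleth"]


def plot_choropleth(city: CityFrame, values, ax=None, cmap: str = "viridis",
                    title: str | None = None, label: str | None = None):
    """Fill township polygons by value; returns the matplotlib Axes.

    ``values`` is a mapping or Series keyed by township_id, or an array in
    the CityFrame's township order.
    """
    ids = city.township_ids
    if hasattr(values, "get") or hasattr(values, "reindex"):
        vals = np.array([values[t] for t in ids], dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
    if vals.shape != (len(ids),):
        raise SchemaError(f"expected one value per township ({len(ids)}), got {vals.shape}")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    patches = []
    for geom in city.townships["geometry"]:
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for poly in polys:
            patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
    # MultiPolygon parts share their township's value
    repeat = [
        len(g.geoms) if g.geom_type == "MultiPolygon" else 1
        for g in city.townships["geometry"]
    ]
    coll = PatchCollection(patches, cmap=cmap, edgecolor="white", linewidth=0.3)
    coll.set_array(np.repeat(vals, repeat))
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    plt.colorbar(coll, ax=ax, shrink=0.7, label=label)
    return ax
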