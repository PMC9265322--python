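"""Locate ecological nodes from hydrological analysis of the resistance surface.

Derives ridge and valley lines by D8 flow accumulation (on the surface and
its negation), then types nodes: strategic (ridge x maximum-cost corridor),
natural (crossings of corridors persistent across the land-cover dates) and
artificial (valley x paddy/water cells).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import numpy as np
import pandas as pd

from econetkit import hydronodes as hydro
from econetkit.grid import read_raster
from econetkit.pipeline import _corridor_mask, _nodes_geojson

from common import RESULTS, demo_config


def main():
    cfg = demo_config()
    surface = read_raster(RESULTS / "resistance.tif")
    landcover = read_raster(RESULTS / "landcover_t2.tif", "categorical")
    dates = [read_raster(RESULTS / f"landcover_t{k}.tif", "categorical")
             for k in range(3)]
    corridors = pd.read_csv(RESULTS / "corridors.csv")
    geo = json.loads((RESULTS / "corridors.geojson").read_text())

    valley, ridge = hydro.valleys_and_ridges(surface, cfg.hydrology_quantile)
    print(f"valley cells: {valley.sum()}, ridge cells: {ridge.sum()} "
          f"(accumulation quantile {cfg.hydrology_quantile})")

    # corridor cell masks from the exported geometry
    def cells_of(feature):
        x0, ytop = surface.origin
        cs = surface.cell_size
        return [(int((ytop - y) / cs), int((x - x0) / cs))
                for x, y in feature["geometry"]["coordinates"]]

    masks = [_corridor_mask(surface.shape, cells_of(f))
             for f in geo["features"]]
    costs = corridors["cum_cost"].tolist()
    max_mask = masks[int(np.argmax(costs))] if masks else None

    fg = np.isin(landcover.values, sorted(cfg.foreground_classes))
    persistent = []
    for mask, feat in zip(masks, geo["features"]):
        cells = np.argwhere(mask)
        frac = min(
            np.isin(d.values[cells[:, 0], cells[:, 1]],
                    sorted(cfg.foreground_classes)).mean()
            for d in dates)
        if frac >= 0.6:
            persistent.append(mask)
    print(f"{len(persistent)} of {len(masks)} corridors persistent across dates")

    artificial = (landcover.values == 1) | (landcover.values == 5)
    nodes = hydro.classify_nodes(ridge, valley, max_mask, persistent,
                                 artificial, cfg.node_merge_radius_cells)
    with open(RESULTS / "nodes.geojson", "w") as fh:
        json.dump(_nodes_geojson(nodes, surface), fh, indent=1)

    counts = {t: sum(1 for n in nodes if n.node_type == t)
              for t in ("strategic", "natural", "artificial")}
    pd.Series(counts, name="count").to_csv(RESULTS / "node_counts.csv")
    print(f"{len(nodes)} nodes:", counts)


if __name__ == "__main__":
    main()
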