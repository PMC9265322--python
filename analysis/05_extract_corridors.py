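"""Extract and rank ecological corridors.

Traces the least-cost path between every source pair over the resistance
surface, filters short and duplicate paths, ranks the survivors with the
gravity model and assigns the three tiers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import pandas as pd

from econetkit import corridors as corr
from econetkit import mspa as mspa_mod
from econetkit.grid import read_raster
from econetkit.pipeline import _corridors_geojson

from common import RESULTS, demo_config


def main():
    cfg = demo_config()
    surface = read_raster(RESULTS / "resistance.tif")
    mspa_grid = read_raster(RESULTS / "mspa.tif", "categorical")
    sources_table = pd.read_csv(RESULTS / "sources.csv")
    source_ids = set(sources_table[sources_table["is_source"]]["patch_id"])

    patches = mspa_mod.extract_cores(mspa_grid, cfg.min_core_area_cells)
    sources = [p for p in patches if p.id in source_ids]
    print(f"{len(sources)} sources -> {len(sources) * (len(sources) - 1) // 2} "
          f"candidate pairs")

    paths = corr.least_cost_paths(surface, sources,
                                  cfg.corridor_min_length_km,
                                  cfg.corridor_dedup_overlap)
    print(f"{len(paths)} paths survive the >= {cfg.corridor_min_length_km} km "
          f"length filter and deduplication")

    areas = {p.id: p.area_km2 for p in sources}
    grav = corr.gravity(paths, areas, cfg.gravity_area_unit)
    corridor_set = corr.classify_corridors(paths, grav, cfg.gravity_tier_bounds)
    frame = corridor_set.to_frame()
    frame.to_csv(RESULTS / "corridors.csv", index=False)
    with open(RESULTS / "corridors.geojson", "w") as fh:
        json.dump(_corridors_geojson(corridor_set, surface), fh, indent=1)

    tiers = frame["level"].value_counts().sort_index()
    print(f"tiers (bounds {cfg.gravity_tier_bounds}): "
          + ", ".join(f"level {k}: {v}" for k, v in tiers.items())
          + f"; excluded: {len(corridor_set.excluded)}")
    print(frame.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
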