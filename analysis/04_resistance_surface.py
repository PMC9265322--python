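"""Build the comprehensive resistance surface.

Grades the four layers (MSPA class, land cover, elevation, slope) with the
published coefficient tables and overlays them with the AHP weights
0.5638 / 0.2634 / 0.1178 / 0.055.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import numpy as np

from econetkit.grid import read_raster, write_raster
from econetkit.resistance import build_resistance_surface, config_hash

from common import RESULTS, demo_config


def main():
    cfg = demo_config()
    mspa_grid = read_raster(RESULTS / "mspa.tif", "categorical")
    landcover = read_raster(RESULTS / "landcover_t2.tif", "categorical")
    dem = read_raster(RESULTS / "dem.tif")
    slope = read_raster(RESULTS / "slope.tif")

    surface = build_resistance_surface(mspa_grid, landcover, dem, slope,
                                       cfg.resistance, seed=cfg.seed)
    write_raster(surface, RESULTS / "resistance.tif")
    with open(RESULTS / "resistance_provenance.json", "w") as fh:
        json.dump({"config_hash": config_hash(cfg.resistance),
                   "mode": cfg.resistance.classing_mode,
                   "weights": list(cfg.resistance.weights)}, fh, indent=1)

    v = surface.values
    print(f"resistance surface: min {v.min():.2f}, mean {v.mean():.2f}, "
          f"max {v.max():.2f} (config {config_hash(cfg.resistance)})")
    q = np.quantile(v, [0.1, 0.5, 0.9])
    print(f"deciles 10/50/90: {q[0]:.1f} / {q[1]:.1f} / {q[2]:.1f}")


if __name__ == "__main__":
    main()
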