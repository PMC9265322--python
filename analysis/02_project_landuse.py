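"""Project future land cover with the Markov-CA model.

Estimates the class-transition matrix from the first two demo dates,
projects per-class demand one step ahead, allocates it spatially with the
cellular automaton (suitability from a multinomial-logistic fit on DEM and
slope), and scores the allocation against the held-out third date.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np

from econetkit.grid import read_raster, write_raster
from econetkit.markov_ca import (CAState, agreement, ca_allocate,
                                 default_suitability, estimate_transitions,
                                 project_demand)

from common import RESULTS, SEED


def main():
    dates = [read_raster(RESULTS / f"landcover_t{k}.tif", "categorical")
             for k in range(3)]
    dem = read_raster(RESULTS / "dem.tif")
    slope = read_raster(RESULTS / "slope.tif")

    tm = estimate_transitions(dates[0], dates[1])
    tm.to_frame().round(3).to_csv(RESULTS / "transfer_matrix_km2.csv")
    changed = tm.counts.sum() - np.trace(tm.counts)
    print(f"transition matrix from t0 -> t1: {changed} of {tm.counts.sum()} "
          f"cells changed class")

    current = {c: int((dates[1].values == c).sum()) for c in tm.classes}
    demand = project_demand(tm, current, steps=1)
    print("projected demand (cells):",
          {c: demand[c] for c in sorted(demand)})

    suit = default_suitability([dem, slope], dates[0], dates[1], seed=SEED)
    restricted = dates[1].values == 5  # water is frozen
    state = CAState(current=dates[1], suitability=suit, demand=demand,
                    restricted=restricted, classes=tm.classes, seed=SEED)
    projected = ca_allocate(state)
    write_raster(projected, RESULTS / "landcover_projected.tif")

    kappa, oa = agreement(dates[2], projected)
    print(f"agreement with held-out t2: kappa = {kappa:.4f}, OA = {oa:.4f}")
    resid = {c: int((projected.values == c).sum()) - demand[c]
             for c in tm.classes}
    print("demand residuals (cells):", resid)


if __name__ == "__main__":
    main()
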