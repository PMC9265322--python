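"""End-to-end ecological-network construction.

``run_pipeline`` chains the stages over a stack of aligned rasters —
land-cover date(s), DEM, slope — and writes a run directory with seven
artifacts: the MSPA raster, the source table, the resistance raster, corridor
GeoJSON + CSV, node GeoJSON, the network-metrics CSV and a parameter log.
A run is a pure function of (inputs, config): the same seed yields
byte-identical tabular outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import corridors as corr
from . import hydronodes as hydro
from . import mspa as mspa_mod
from . import network_eval as neteval
from .config import PipelineConfig, save_config
from .grid import Grid, align_stack, write_raster
from .resistance import build_resistance_surface, config_hash

__all__ = ["PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    mspa_grid: Grid
    patches: list
    importances: pd.DataFrame
    source_ids: list[int]
    resistance: Grid
    corridor_set: corr.CorridorSet
    nodes: list
    metrics: pd.DataFrame
    run_dir: Path | None = None


def _corridor_mask(shape: tuple[int, int], cells) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rows = [c[0] for c in cells]
    cols = [c[1] for c in cells]
    mask[rows, cols] = True
    return mask


def _corridors_geojson(corridor_set: corr.CorridorSet, grid: Grid) -> dict:
    feats = []
    for k, (path, g, lvl) in enumerate(corridor_set.corridors, start=1):
        coords = [list(grid.cell_center_xy(r, c)) for r, c in path.cells]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": {"id": k, "src": path.src_id, "dst": path.dst_id,
                           "length_km": round(path.length_km, 4),
                           "gravity": round(g, 4), "level": lvl},
        })
    return {"type": "FeatureCollection", "features": feats}


def _nodes_geojson(nodes, grid: Grid) -> dict:
    feats = []
    for k, node in enumerate(nodes, start=1):
        x, y = grid.cell_center_xy(node.cell[0], node.cell[1])
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {"id": k, "node_type": node.node_type,
                           "provenance": node.provenance},
        })
    return {"type": "FeatureCollection", "features": feats}


def _persistence_fraction(path_cells, landcover: Grid, foreground: frozenset[int]) -> float:
    vals = landcover.values
    fg = 0
    for r, c in path_cells:
        if int(vals[r, c]) in foreground:
            fg += 1
    return fg / max(len(path_cells), 1)


def run_pipeline(config: PipelineConfig,
                 landcover_dates: list[Grid],
                 dem: Grid,
                 slope: Grid,
                 roads_rivers_mask: np.ndarray | None = None,
                 run_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on the final land-cover date and write artifacts.

    ``landcover_dates`` is ordered oldest to newest; the newest date is the
    analysis substrate, the older ones inform corridor persistence (a corridor
    is persistent when at least 60 % of its cells are foreground in every
    date).  ``roads_rivers_mask`` supplements paddy and water cells in the
    artificial-node rule.
    """
    config.validate()
    stage = "alignment"
    try:
        layers = align_stack([*landcover_dates, dem, slope])
        dates, dem, slope = layers[:-2], layers[-2], layers[-1]
        landcover = dates[-1]

        stage = "mspa"
        binary = mspa_mod.binary_landscape(landcover, config.foreground_classes)
        mspa_grid = mspa_mod.classify(binary, config.mspa_edge_width_cells,
                                      config.mspa_connectivity)
        patches = mspa_mod.extract_cores(mspa_grid, config.min_core_area_cells)
        if len(patches) < 2:
            raise PipelineError("fewer than 2 core patches; landscape too sparse")

        stage = "connectivity"
        graph = conn.build_patch_graph(
            patches, landcover.cell_size, config.optimal_threshold_m,
            config.connectivity_probability)
        importances = conn.importance(graph, "PC")
        source_ids = conn.select_sources(importances, config.min_dpc)
        if len(source_ids) < 2:  # keep the pipeline connected on sparse demos
            ranked = importances.sort_values("dPC", ascending=False)
            source_ids = ranked["patch_id"].astype(int).head(2).tolist()
        sources = [p for p in patches if p.id in set(source_ids)]

        stage = "resistance"
        surface = build_resistance_surface(mspa_grid, landcover, dem, slope,
                                           config.resistance, seed=config.seed)

        stage = "corridors"
        paths = corr.least_cost_paths(surface, sources,
                                      config.corridor_min_length_km,
                                      config.corridor_dedup_overlap)
        if not paths:
            raise PipelineError("no corridor passed the length filter")
        areas = {p.id: p.area_km2 for p in sources}
        grav = corr.gravity(paths, areas, config.gravity_area_unit)
        corridor_set = corr.classify_corridors(paths, grav,
                                               config.gravity_tier_bounds)

        stage = "nodes"
        valley, ridge = hydro.valleys_and_ridges(surface, config.hydrology_quantile)
        retained = corridor_set.corridors
        if retained:
            max_cost = max(retained, key=lambda c: c[0].cum_cost)
            max_mask = _corridor_mask(surface.shape, max_cost[0].cells)
        else:
            max_mask = None
        persistent_masks = [
            _corridor_mask(surface.shape, c[0].cells) for c in retained
            if all(_persistence_fraction(c[0].cells, d, config.foreground_classes) >= 0.6
                   for d in dates)
        ]
        artificial = (landcover.values == 1) | (landcover.values == 5)
        if roads_rivers_mask is not None:
            artificial |= roads_rivers_mask
        nodes = hydro.classify_nodes(ridge, valley, max_mask, persistent_masks,
                                     artificial, config.node_merge_radius_cells)

        stage = "evaluation"
        metrics = neteval.evaluate_network(corridor_set, nodes)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(mspa_grid, patches, importances, source_ids, surface,
                            corridor_set, nodes, metrics)
    if run_dir is not None:
        result.run_dir = _write_artifacts(result, config, Path(run_dir), landcover)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig,
                     run_dir: Path, landcover: Grid) -> Path:
    run_dir.mkdir(parents=True, exist_ok=True)
    write_raster(result.mspa_grid, run_dir / "mspa.tif")
    write_raster(result.resistance, run_dir / "resistance.tif")

    src_rows = []
    sel = set(result.source_ids)
    for rec in result.importances.sort_values("patch_id").itertuples():
        src_rows.append({"patch_id": int(rec.patch_id),
                         "area_km2": round(float(rec.area_km2), 6),
                         "dPC": round(float(rec.dPC), 6),
                         "is_source": int(rec.patch_id) in sel})
    pd.DataFrame(src_rows).to_csv(run_dir / "sources.csv", index=False)

    result.corridor_set.to_frame().to_csv(run_dir / "corridors.csv", index=False)
    with open(run_dir / "corridors.geojson", "w") as fh:
        json.dump(_corridors_geojson(result.corridor_set, landcover), fh, indent=1)
    with open(run_dir / "nodes.geojson", "w") as fh:
        json.dump(_nodes_geojson(result.nodes, landcover), fh, indent=1)
    result.metrics.to_csv(run_dir / "network_metrics.csv", index=False)
    save_config(config, run_dir / "params.yaml")
    with open(run_dir / "provenance.json", "w") as fh:
        json.dump({"resistance_config_hash": config_hash(config.resistance),
                   "seed": config.seed,
                   "n_sources": len(result.source_ids),
                   "n_corridors": len(result.corridor_set.corridors),
                   "n_nodes": len(result.nodes)}, fh, indent=1, sort_keys=True)
    return run_dir
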