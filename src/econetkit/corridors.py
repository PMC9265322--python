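"""Least-cost ecological corridors and gravity-model ranking.

Movement cost between 8-adjacent cells is the mean of the two endpoint
resistances times the step length (1 for rook moves, sqrt(2) for diagonal,
in cell units), so a path's cumulative cost is resistance x distance.
Cost distance is solved exactly with Dijkstra on the sparse cell graph;
least-cost paths are backtraced from the cheapest cell of the destination
patch.  Paths shorter than a minimum geometric length are dropped and
near-duplicate paths (cell overlap above a threshold) are deduplicated.

Surviving pairs are ranked with the interaction-force (gravity) model

    G_ij = L_max^2 * ln(a_i) * ln(a_j) / L_ij^2

where ``L_ij`` is the path's cumulative resistance, ``L_max`` the largest
cumulative resistance among candidate corridors and ``a`` patch areas (in a
unit, hectares by default, that keeps ln(a) positive).  Corridors are tiered:
gravity > 100 level 1, (10, 100] level 2, (1, 10] level 3, <= 1 excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import Grid
from .mspa import CorePatch

__all__ = [
    "CostField", "CostPath", "cost_distance", "least_cost_paths",
    "gravity", "classify_corridors", "CorridorSet",
]

_SQRT2 = np.sqrt(2.0)
# neighbour offsets and step lengths; order fixes the backlink codes 1..8
_NEIGHBORS = [(-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2),
              (0, -1, 1.0), (0, 1, 1.0),
              (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2)]


def _cell_graph(theta: np.ndarray):
    """Sparse 8-connected cost graph; edge weight = mean resistance x step."""
    rows, cols = theta.shape
    n = rows * cols
    idx = np.arange(n).reshape(rows, cols)
    data, ii, jj = [], [], []
    for dr, dc, step in _NEIGHBORS[:4]:  # upper half; graph is symmetric
        src = idx[max(0, -dr):rows - max(0, dr), max(0, -dc):cols - max(0, dc)]
        dst = idx[max(0, dr):rows + min(0, dr), max(0, dc):cols + min(0, dc)]
        w = 0.5 * (theta.ravel()[src.ravel()] + theta.ravel()[dst.ravel()]) * step
        ii.append(src.ravel())
        jj.append(dst.ravel())
        data.append(w)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    data = np.concatenate(data)
    return coo_matrix((np.concatenate([data, data]),
                       (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
                      shape=(n, n)).tocsr()


@dataclass
class CostField:
    """Cumulative cost from a source cell set, plus backtracking predecessors."""

    cumulative_cost: Grid
    predecessors: np.ndarray  # flat predecessor index per cell, -9999 at sources


def cost_distance(surface: Grid, source_cells: list[tuple[int, int]]) -> CostField:
    """Exact multi-source Dijkstra cost distance over the resistance surface."""
    theta = np.asarray(surface.values, dtype=float)
    if not source_cells:
        raise ValueError("at least one source cell required")
    if np.any(~np.isnan(theta) & (theta <= 0)):
        raise ValueError("all resistances must be > 0")
    work = np.where(np.isnan(theta), np.inf, theta)
    graph = _cell_graph(work)
    rows, cols = theta.shape
    src_idx = [r * cols + c for r, c in source_cells]
    dist, pred, _ = dijkstra(graph, directed=False, indices=src_idx,
                             return_predecessors=True, min_only=True)
    return CostField(
        cumulative_cost=surface.copy_with(dist.reshape(rows, cols)),
        predecessors=pred,
    )


@dataclass
class CostPath:
    """A least-cost path between two source patches."""

    src_id: int
    dst_id: int
    cells: list[tuple[int, int]]
    length_km: float
    cum_cost: float

    @property
    def cell_set(self) -> frozenset:
        return frozenset(self.cells)


def _backtrace(pred: np.ndarray, end_flat: int, cols: int) -> list[tuple[int, int]]:
    path = []
    cur = end_flat
    while cur >= 0:
        path.append((cur // cols, cur % cols))
        cur = pred[cur]
    return path[::-1]


def _path_length_km(cells: list[tuple[int, int]], cell_size: float) -> float:
    steps = np.diff(np.asarray(cells, dtype=float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum()) * cell_size / 1000.0


def least_cost_paths(surface: Grid, patches: list[CorePatch],
                     min_length_km: float = 10.0,
                     dedup_overlap: float = 0.9) -> list[CostPath]:
    """Backtraced least-cost path for every unordered patch pair, filtered.

    Filters: geometric length below ``min_length_km`` dropped; paths whose
    cell sets overlap at least ``dedup_overlap`` (Jaccard on the smaller set)
    deduplicated, keeping the lower-cost one.  Unreachable pairs are skipped.
    """
    if len(patches) < 2:
        raise ValueError("need at least 2 patches")
    rows, cols = surface.shape
    paths: list[CostPath] = []
    for i, pi in enumerate(patches):
        cf = cost_distance(surface, list(pi.cells))
        cost = cf.cumulative_cost.values.ravel()
        for pj in patches[i + 1:]:
            flat_j = [r * cols + c for r, c in pj.cells]
            costs_j = cost[flat_j]
            if not np.isfinite(costs_j).any():
                continue  # unreachable pair
            end = flat_j[int(np.argmin(costs_j))]
            cells = _backtrace(cf.predecessors, end, cols)
            paths.append(CostPath(
                src_id=pi.id, dst_id=pj.id, cells=cells,
                length_km=_path_length_km(cells, surface.cell_size),
                cum_cost=float(cost[end]),
            ))
    paths = [p for p in paths if p.length_km >= min_length_km]
    # dedup: order by cost so the cheaper of an overlapping pair survives
    paths.sort(key=lambda p: p.cum_cost)
    kept: list[CostPath] = []
    for p in paths:
        dup = False
        pset = p.cell_set
        for q in kept:
            inter = len(pset & q.cell_set)
            if inter / max(1, min(len(pset), len(q.cell_set))) >= dedup_overlap:
                dup = True
                break
        if not dup:
            kept.append(p)
    kept.sort(key=lambda p: (p.src_id, p.dst_id))
    return kept


def gravity(paths: list[CostPath], areas_km2: dict[int, float],
            area_unit: str = "ha") -> pd.DataFrame:
    """Interaction force G_ij = L_max^2 ln(a_i) ln(a_j) / L_ij^2 per path.

    Areas are converted from km^2 to ``area_unit`` ('ha' or 'km2') before the
    log; every patch must exceed one area unit so ln stays positive.
    """
    if not paths:
        return pd.DataFrame(columns=["src", "dst", "length_km", "cum_cost", "gravity"])
    factor = {"ha": 100.0, "km2": 1.0}.get(area_unit)
    if factor is None:
        raise ValueError(f"unknown area unit {area_unit!r}")
    scaled = {pid: a * factor for pid, a in areas_km2.items()}
    bad = [pid for pid in {p.src_id for p in paths} | {p.dst_id for p in paths}
           if scaled[pid] <= 1.0]
    if bad:
        raise ValueError(
            f"patch areas {bad} are <= 1 {area_unit}; ln(area) would be "
            f"non-positive - choose a smaller area unit")
    l_max = max(p.cum_cost for p in paths)
    rows = []
    for p in paths:
        g = (l_max ** 2 * np.log(scaled[p.src_id]) * np.log(scaled[p.dst_id])
             / p.cum_cost ** 2)
        rows.append({"src": p.src_id, "dst": p.dst_id, "length_km": p.length_km,
                     "cum_cost": p.cum_cost, "gravity": float(g)})
    return pd.DataFrame(rows)


@dataclass
class CorridorSet:
    """Tiered corridors: (path, gravity, level); level None means excluded."""

    corridors: list[tuple[CostPath, float, int]] = field(default_factory=list)
    excluded: list[tuple[CostPath, float]] = field(default_factory=list)

    def by_level(self, *levels: int) -> list[tuple[CostPath, float, int]]:
        return [c for c in self.corridors if c[2] in levels]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": k + 1, "src": p.src_id, "dst": p.dst_id,
                 "length_km": round(p.length_km, 4), "cum_cost": round(p.cum_cost, 6),
                 "gravity": round(g, 4), "level": lvl}
                for k, (p, g, lvl) in enumerate(self.corridors)]
        return pd.DataFrame(rows, columns=["id", "src", "dst", "length_km",
                                           "cum_cost", "gravity", "level"])


def assign_level(g: float, bounds: tuple[float, float, float] = (1.0, 10.0, 100.0)
                 ) -> int | None:
    """Tier for one gravity value; None when excluded (g <= lowest bound)."""
    lo, mid, hi = bounds
    if g > hi:
        return 1
    if g > mid:
        return 2
    if g > lo:
        return 3
    return None


def classify_corridors(paths: list[CostPath], grav: pd.DataFrame,
                       bounds: tuple[float, float, float] = (1.0, 10.0, 100.0)
                       ) -> CorridorSet:
    """Assign gravity tiers; corridors at or below the lowest bound are excluded."""
    key = {(int(r.src), int(r.dst)): float(r.gravity) for r in grav.itertuples()}
    out = CorridorSet()
    ordered = sorted(paths, key=lambda p: -key.get((p.src_id, p.dst_id), 0.0))
    for p in ordered:
        g = key.get((p.src_id, p.dst_id))
        if g is None:
            continue
        lvl = assign_level(g, bounds)
        if lvl is None:
            out.excluded.append((p, g))
        else:
            out.corridors.append((p, g, lvl))
    return out
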