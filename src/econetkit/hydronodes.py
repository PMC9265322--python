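"""Ecological nodes from hydrological analysis of the resistance surface.

The resistance surface is treated as terrain: after priority-flood sink
filling, D8 flow directions (steepest descent, diagonal drops divided by
sqrt(2), ties broken in the fixed order E, SE, S, SW, W, NW, N, NE) and flow
accumulation are computed.  Valley lines are cells whose accumulation reaches
a high quantile; ridge lines are the same rule applied to the negated
surface.  Nodes are typed by intersection:

* **strategic** — ridge lines crossing the maximum-cost corridor cells,
* **natural**   — crossings among corridors persistent across dates,
* **artificial** — valley lines crossing roads / rivers / paddy masks.

Intersections are tested after 1-cell dilation (raster lines are thin) and
merged within a radius into single points at the cluster centroid.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Grid

__all__ = ["fill_sinks", "d8", "FlowField", "valleys_and_ridges",
           "EcoNode", "classify_nodes", "merge_points"]

# D8 tie-break priority: E, SE, S, SW, W, NW, N, NE  (codes 1..8)
_D8_ORDER = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_D8_STEP = [1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)]


def fill_sinks(surface: Grid) -> Grid:
    """Priority-flood depression filling.

    Every interior cell is raised minimally so a non-ascending 8-path to the
    grid boundary exists; idempotent; monotone ramps pass through unchanged.
    """
    z = np.asarray(surface.values, dtype=float)
    rows, cols = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(rows):
        for c in (0, cols - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    for c in range(1, cols - 1):
        for r in (0, rows - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    while heap:
        h, r, c = heapq.heappop(heap)
        filled[r, c] = h
        for dr, dc in _D8_ORDER:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not visited[rr, cc]:
                visited[rr, cc] = True
                heapq.heappush(heap, (max(z[rr, cc], h), rr, cc))
    return surface.copy_with(filled)


@dataclass
class FlowField:
    """D8 directions (codes 1..8, 0 = outlet), accumulation and filled surface."""

    flow_direction: Grid
    flow_accumulation: Grid
    filled_surface: Grid


def d8(surface: Grid, prefilled: bool = False) -> FlowField:
    """D8 flow direction and accumulation on a (filled) surface.

    Direction = steepest drop/step-length among the 8 neighbours, ties broken
    by the fixed priority order; flat cells drain toward the nearest
    already-draining neighbour (breadth-first over flats), so every non-outlet
    cell has exactly one direction.  Accumulation counts strictly upstream
    cells (a cell's own area excluded).
    """
    filled = surface if prefilled else fill_sinks(surface)
    z = np.asarray(filled.values, dtype=float)
    rows, cols = z.shape
    direction = np.zeros(z.shape, dtype=np.int8)
    for r in range(rows):
        for c in range(cols):
            best_slope, best_code = 0.0, 0
            for code, ((dr, dc), step) in enumerate(zip(_D8_ORDER, _D8_STEP), start=1):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                s = (z[r, c] - z[rr, cc]) / step
                if s > best_slope:
                    best_slope, best_code = s, code
            direction[r, c] = best_code
    # resolve flats: BFS from flat cells adjacent to a draining (or boundary
    # outlet) cell of equal height, in priority order for determinism
    from collections import deque

    on_border = np.zeros(z.shape, dtype=bool)
    on_border[0, :] = on_border[-1, :] = True
    on_border[:, 0] = on_border[:, -1] = True
    undrained = (direction == 0) & ~on_border  # border flats are outlets
    queue: deque[tuple[int, int]] = deque()
    resolved = ~undrained
    order = np.argsort(z, axis=None, kind="stable")  # low cells first, deterministic
    for flat_idx in order:
        r, c = divmod(int(flat_idx), cols)
        if not undrained[r, c]:
            continue
        for code, (dr, dc) in enumerate(_D8_ORDER, start=1):
            rr, cc = r + dr, c + dc
            if (0 <= rr < rows and 0 <= cc < cols and resolved[rr, cc]
                    and z[rr, cc] <= z[r, c]):
                direction[r, c] = code
                resolved[r, c] = True
                queue.append((r, c))
                break
    while queue:
        r, c = queue.popleft()
        for code, (dr, dc) in enumerate(_D8_ORDER, start=1):
            rr, cc = r + dr, c + dc
            if (0 <= rr < rows and 0 <= cc < cols and not resolved[rr, cc]
                    and z[rr, cc] == z[r, c]):
                # neighbour drains into this resolved cell: opposite code
                direction[rr, cc] = ((code + 3) % 8) + 1
                resolved[rr, cc] = True
                queue.append((rr, cc))

    # accumulation by Kahn topological order over the flow DAG
    acc = np.zeros(z.shape, dtype=np.int64)
    indeg = np.zeros(z.shape, dtype=np.int32)
    for r in range(rows):
        for c in range(cols):
            code = direction[r, c]
            if code:
                dr, dc = _D8_ORDER[code - 1]
                indeg[r + dr, c + dc] += 1
    stack = [(r, c) for r in range(rows) for c in range(cols) if indeg[r, c] == 0]
    while stack:
        r, c = stack.pop()
        code = direction[r, c]
        if not code:
            continue
        dr, dc = _D8_ORDER[code - 1]
        rr, cc = r + dr, c + dc
        acc[rr, cc] += acc[r, c] + 1
        indeg[rr, cc] -= 1
        if indeg[rr, cc] == 0:
            stack.append((rr, cc))
    return FlowField(
        flow_direction=surface.copy_with(direction),
        flow_accumulation=surface.copy_with(acc),
        filled_surface=filled,
    )


def valleys_and_ridges(surface: Grid, quantile: float = 0.95
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(valley cells, ridge cells) as boolean masks.

    Valleys: flow accumulation on the filled surface at or above its
    ``quantile``; ridges: the same rule on the negated surface.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    acc_v = d8(surface).flow_accumulation.values
    acc_r = d8(surface.copy_with(-np.asarray(surface.values, float))).flow_accumulation.values
    valley = acc_v >= np.quantile(acc_v, quantile)
    ridge = acc_r >= np.quantile(acc_r, quantile)
    return valley, ridge


@dataclass(frozen=True)
class EcoNode:
    """One ecological node: grid cell, type, and the rule that produced it."""

    cell: tuple[float, float]   # (row, col), cluster centroid
    node_type: str              # strategic | natural | artificial
    provenance: str


def merge_points(cells: list[tuple[int, int]], merge_radius: float
                 ) -> list[tuple[float, float]]:
    """Union-find clustering of cells within ``merge_radius`` (chebyshev);
    each cluster collapses to its centroid.  Order-independent."""
    if not cells:
        return []
    pts = sorted(set(cells))
    parent = list(range(len(pts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if (abs(pts[i][0] - pts[j][0]) <= merge_radius
                    and abs(pts[i][1] - pts[j][1]) <= merge_radius):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[tuple[int, int]]] = {}
    for i, p in enumerate(pts):
        clusters.setdefault(find(i), []).append(p)
    out = [(float(np.mean([p[0] for p in grp])), float(np.mean([p[1] for p in grp])))
           for grp in clusters.values()]
    return sorted(out)


def _dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    if iterations <= 0:
        return mask
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool),
                                   iterations=iterations)


def classify_nodes(ridge: np.ndarray, valley: np.ndarray,
                   max_cost_corridor_cells: np.ndarray | None,
                   persistent_corridor_masks: list[np.ndarray] | None,
                   artificial_mask: np.ndarray | None,
                   merge_radius: float = 3.0) -> list[EcoNode]:
    """Type and merge ecological nodes.

    ``max_cost_corridor_cells``: raster mask of the maximum-cost corridor(s)
    (strategic rule); ``persistent_corridor_masks``: one mask per persistent
    corridor, crossings among distinct corridors become natural nodes;
    ``artificial_mask``: union of roads, rivers and paddy cells (artificial
    rule).  Every mask is dilated one cell before intersection; missing masks
    skip their node type.
    """
    nodes: list[EcoNode] = []
    if max_cost_corridor_cells is not None:
        hits = _dilate(ridge) & _dilate(max_cost_corridor_cells)
        for cell in merge_points([tuple(c) for c in np.argwhere(hits)], merge_radius):
            nodes.append(EcoNode(cell, "strategic", "ridge x max-cost corridor"))
    if persistent_corridor_masks is not None and len(persistent_corridor_masks) >= 2:
        cross = np.zeros_like(ridge, dtype=bool)
        dilated = [_dilate(m) for m in persistent_corridor_masks]
        for i in range(len(dilated)):
            for j in range(i + 1, len(dilated)):
                cross |= dilated[i] & dilated[j]
        for cell in merge_points([tuple(c) for c in np.argwhere(cross)], merge_radius):
            nodes.append(EcoNode(cell, "natural", "persistent corridor crossing"))
    if artificial_mask is not None:
        hits = _dilate(valley) & _dilate(artificial_mask)
        for cell in merge_points([tuple(c) for c in np.argwhere(hits)], merge_radius):
            nodes.append(EcoNode(cell, "artificial", "valley x roads/rivers/paddy"))
    return nodes
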