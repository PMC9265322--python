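"""Graph-theoretic habitat connectivity indices and patch importance.

Given core patches (areas ``a_i`` and pairwise edge-to-edge distances
``d_ij``), an unweighted graph links patch pairs with ``d_ij <= threshold``.
Three landscape indices are computed, each normalized by ``SL``, the total
area of the analysed patch set (optionally the full study area):

* ``LCP  = sum_components (component_area / SL)^2``
* ``IIC  = [sum_ij a_i a_j / (1 + nl_ij)] / SL^2`` with ``nl_ij`` the number
  of links on the topological shortest path (pairs in different components
  contribute 0),
* ``PC   = [sum_ij a_i a_j mu*_ij] / SL^2`` with ``mu*_ij`` the maximum
  product of direct dispersal probabilities over paths; the direct kernel is
  a negative exponential ``p(d) = exp(k d)`` calibrated so ``p = p0`` exactly
  at the threshold distance (``k = ln(p0)/threshold``).

Per-patch importance ``dPhi_x = 100 (Phi - Phi_without_x) / Phi`` (percent;
``SL`` held fixed during removal) ranks patches; ecological sources are those
with ``dPC`` strictly above a cutoff (default 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mspa import CorePatch

__all__ = [
    "PatchGraph", "patch_distances", "build_patch_graph",
    "compute_lcp", "compute_iic", "compute_pc", "n_components",
    "importance", "threshold_sweep", "select_sources",
]


def patch_distances(patches: list[CorePatch], cell_size: float) -> np.ndarray:
    """Pairwise edge-to-edge distances in metres.

    Approximated as the minimum cell-centre distance between patches minus
    one cell size, floored at 0, so edge-adjacent patches are 0 m apart.
    """
    n = len(patches)
    if n == 0:
        raise ValueError("need at least one patch")
    d = np.zeros((n, n))
    pts = [np.asarray(p.cells, dtype=float) for p in patches]
    trees = [cKDTree(p) for p in pts]
    for i in range(n):
        for j in range(i + 1, n):
            dmin, _ = trees[i].query(pts[j], k=1)
            d_cells = float(dmin.min())
            d[i, j] = d[j, i] = max(d_cells - 1.0, 0.0) * cell_size
    return d


@dataclass
class PatchGraph:
    """Patch set + threshold graph carrying all connectivity indices."""

    areas: np.ndarray                      # km^2, shape (n,)
    distances: np.ndarray                  # metres, shape (n, n)
    threshold: float                       # metres
    probability_at_threshold: float = 0.5
    ids: list[int] = field(default_factory=list)
    total_area: float | None = None        # SL; defaults to sum of areas

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        n = self.areas.size
        if self.distances.shape != (n, n):
            raise ValueError("distance matrix shape does not match patch count")
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")
        if not self.ids:
            self.ids = list(range(1, n + 1))
        if not 0 < self.probability_at_threshold < 1:
            raise ValueError("probability_at_threshold must lie in (0, 1)")

    @property
    def n(self) -> int:
        return self.areas.size

    @property
    def sl(self) -> float:
        sl = self.total_area if self.total_area is not None else float(self.areas.sum())
        if sl <= 0:
            raise ValueError("SL (total area) must be > 0")
        return sl

    def adjacency(self) -> np.ndarray:
        adj = self.distances <= self.threshold
        np.fill_diagonal(adj, False)
        return adj

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        rows, cols = np.nonzero(np.triu(self.adjacency(), 1))
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
        return g

    def subgraph_without(self, x: int) -> "PatchGraph":
        keep = [i for i in range(self.n) if i != x]
        return PatchGraph(
            areas=self.areas[keep],
            distances=self.distances[np.ix_(keep, keep)],
            threshold=self.threshold,
            probability_at_threshold=self.probability_at_threshold,
            ids=[self.ids[i] for i in keep],
            total_area=self.sl,  # SL held fixed on removal
        )


def build_patch_graph(patches: list[CorePatch], cell_size: float, threshold: float,
                      probability: float = 0.5, total_area: float | None = None
                      ) -> PatchGraph:
    d = patch_distances(patches, cell_size)
    return PatchGraph(
        areas=np.array([p.area_km2 for p in patches]),
        distances=d,
        threshold=threshold,
        probability_at_threshold=probability,
        ids=[p.id for p in patches],
        total_area=total_area,
    )


def n_components(graph: PatchGraph) -> int:
    return nx.number_connected_components(graph.graph())


def compute_lcp(graph: PatchGraph) -> float:
    """Landscape coincidence probability: sum over components of (area/SL)^2."""
    sl = graph.sl
    total = 0.0
    for comp in nx.connected_components(graph.graph()):
        delta = graph.areas[list(comp)].sum()
        total += (delta / sl) ** 2
    return total


def _nl_matrix(graph: PatchGraph) -> np.ndarray:
    """Topological shortest-path link counts; inf between components."""
    g = graph.graph()
    nl = np.full((graph.n, graph.n), np.inf)
    np.fill_diagonal(nl, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, steps in lengths.items():
            nl[src, dst] = steps
    return nl


def compute_iic(graph: PatchGraph) -> float:
    """Integral index of connectivity."""
    nl = _nl_matrix(graph)
    a = graph.areas
    with np.errstate(divide="ignore"):
        contrib = np.outer(a, a) / (1.0 + nl)
    contrib[np.isinf(nl)] = 0.0
    return float(contrib.sum()) / graph.sl ** 2


def max_product_probability(graph: PatchGraph) -> np.ndarray:
    """mu*_ij: best path product of direct probabilities on the threshold graph."""
    k = math.log(graph.probability_at_threshold) / graph.threshold
    adj = graph.adjacency()
    g = nx.Graph()
    g.add_nodes_from(range(graph.n))
    rows, cols = np.nonzero(np.triu(adj, 1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        # -log p >= 0, so Dijkstra maximizes the product
        g.add_edge(i, j, weight=-k * graph.distances[i, j])
    mu = np.zeros((graph.n, graph.n))
    np.fill_diagonal(mu, 1.0)
    for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        for dst, w in dists.items():
            mu[src, dst] = math.exp(-w)
    return mu


def compute_pc(graph: PatchGraph) -> float:
    """Probability of connectivity."""
    mu = max_product_probability(graph)
    a = graph.areas
    return float((np.outer(a, a) * mu).sum()) / graph.sl ** 2


_INDEX_FN = {"LCP": compute_lcp, "IIC": compute_iic, "PC": compute_pc}


def importance(graph: PatchGraph, index: str = "PC") -> pd.DataFrame:
    """Per-patch importance dPhi = 100 (Phi - Phi_remove_x) / Phi, in percent.

    SL is held fixed during removals, so dPhi is a pure connectivity-loss
    measure.  Returns a DataFrame with columns ``patch_id``, ``area_km2``,
    ``phi_removed`` and ``d<index>``; NaN when the full index is zero.
    """
    if graph.n < 2:
        raise ValueError("importance needs at least 2 patches")
    fn = _INDEX_FN[index.upper()]
    phi = fn(graph)
    rows = []
    for x in range(graph.n):
        phi_rm = fn(graph.subgraph_without(x))
        d = 100.0 * (phi - phi_rm) / phi if phi > 0 else float("nan")
        rows.append({
            "patch_id": graph.ids[x],
            "area_km2": graph.areas[x],
            "phi_removed": phi_rm,
            f"d{index.upper()}": d,
        })
    return pd.DataFrame(rows)


def threshold_sweep(patches: list[CorePatch], cell_size: float,
                    thresholds: list[float], probability: float = 0.5,
                    total_area: float | None = None) -> pd.DataFrame:
    """Indices and mean/max per-patch importances at each distance threshold."""
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds to sweep")
    d = patch_distances(patches, cell_size)
    areas = np.array([p.area_km2 for p in patches])
    ids = [p.id for p in patches]
    rows = []
    for thr in thresholds:
        g = PatchGraph(areas=areas, distances=d, threshold=thr,
                       probability_at_threshold=probability,
                       ids=ids, total_area=total_area)
        row = {"threshold_m": thr, "NC": n_components(g),
               "LCP": compute_lcp(g), "IIC": compute_iic(g), "PC": compute_pc(g)}
        for index in ("LCP", "IIC", "PC"):
            imp = importance(g, index)[f"d{index}"]
            row[f"d{index}_mean"] = float(imp.mean())
            row[f"d{index}_max"] = float(imp.max())
        rows.append(row)
    return pd.DataFrame(rows)


def stable_threshold(patches: list[CorePatch], cell_size: float,
                     thresholds: list[float], probability: float = 0.5,
                     top_k: int = 5) -> float:
    """Heuristic optimal threshold: smallest at which the top-k dPC ranking
    matches the next threshold's ranking; falls back to the last threshold."""
    d = patch_distances(patches, cell_size)
    areas = np.array([p.area_km2 for p in patches])
    ids = [p.id for p in patches]
    rankings = []
    for thr in sorted(thresholds):
        g = PatchGraph(areas=areas, distances=d, threshold=thr,
                       probability_at_threshold=probability, ids=ids)
        imp = importance(g, "PC").sort_values("dPC", ascending=False)
        rankings.append(tuple(imp["patch_id"].head(top_k)))
    for thr, r1, r2 in zip(sorted(thresholds), rankings, rankings[1:]):
        if r1 == r2:
            return thr
    return sorted(thresholds)[-1]


def select_sources(importances: pd.DataFrame, min_dpc: float = 1.0) -> list[int]:
    """Patch ids with dPC strictly greater than ``min_dpc``, descending by dPC."""
    if "dPC" not in importances.columns:
        raise ValueError("importances must carry a dPC column")
    sel = importances[importances["dPC"] > min_dpc].sort_values("dPC", ascending=False)
    return sel["patch_id"].astype(int).tolist()
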