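"""Independent brute-force oracles.

Deliberately written in plain Python with per-cell/per-path exhaustive
queries, sharing no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


# ---------------------------------------------------------------------------
# Morphological classification oracle
# ---------------------------------------------------------------------------

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_N4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _cheb_dist_map(shape, targets):
    """Chebyshev distance from every cell to the nearest target cell (BFS)."""
    rows, cols = shape
    INF = 10 ** 9
    dist = [[INF] * cols for _ in range(rows)]
    q = deque()
    for r, c in targets:
        dist[r][c] = 0
        q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in _N8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and dist[rr][cc] > dist[r][c] + 1:
                dist[rr][cc] = dist[r][c] + 1
                q.append((rr, cc))
    return dist


def _components(shape, cells, neighbours):
    rows, cols = shape
    cells = set(cells)
    seen = set()
    comps = []
    for start in sorted(cells):
        if start in seen:
            continue
        comp = {start}
        seen.add(start)
        q = deque([start])
        while q:
            r, c = q.popleft()
            for dr, dc in neighbours:
                nxt = (r + dr, c + dc)
                if nxt in cells and nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    q.append(nxt)
        comps.append(comp)
    return comps


def mspa_oracle(fg_grid, edge_width, fg_connectivity=8):
    """Classify every cell of a 0/1 grid into the seven morphological codes.

    Codes match the package convention: 0 background, 1 core, 2 islet,
    3 edge, 4 bridge, 5 branch, 6 loop, 7 perforation.
    """
    w = edge_width
    # the map edge behaves as background: surround the grid with bg cells
    pad = w + 1
    inner_cols = len(fg_grid[0])
    padded = ([[0] * (inner_cols + 2 * pad)] * pad
              + [[0] * pad + list(row) + [0] * pad for row in fg_grid]
              + [[0] * (inner_cols + 2 * pad)] * pad)
    fg_grid = padded
    rows = len(fg_grid)
    cols = len(fg_grid[0])
    shape = (rows, cols)
    fg = {(r, c) for r in range(rows) for c in range(cols) if fg_grid[r][c] == 1}
    bg = {(r, c) for r in range(rows) for c in range(cols) if (r, c) not in fg}
    nb_fg = _N8 if fg_connectivity == 8 else _N4
    nb_bg = _N4 if fg_connectivity == 8 else _N8

    out = [[0] * cols for _ in range(rows)]
    if not fg:
        return out
    d_bg = _cheb_dist_map(shape, bg) if bg else None
    core = {p for p in fg if d_bg is None or d_bg[p[0]][p[1]] > w}
    for r, c in core:
        out[r][c] = 1

    bg_comps = _components(shape, bg, nb_bg)
    outside = set()
    holes = set()
    for comp in bg_comps:
        on_border = any(r in (0, rows - 1) or c in (0, cols - 1) for r, c in comp)
        (outside if on_border else holes).update(comp)

    d_core = _cheb_dist_map(shape, core) if core else None
    d_out = _cheb_dist_map(shape, outside) if outside else None
    d_hole = _cheb_dist_map(shape, holes) if holes else None
    INF = 10 ** 9

    def dc(p):
        return d_core[p[0]][p[1]] if d_core else INF

    def do(p):
        return d_out[p[0]][p[1]] if d_out else INF

    def dh(p):
        return d_hole[p[0]][p[1]] if d_hole else INF

    residual = fg - core
    near = {p for p in residual if dc(p) <= w}
    for p in near:
        out[p[0]][p[1]] = 3 if do(p) <= dh(p) else 7

    far = residual - near
    core_comps = _components(shape, core, _N8)
    for comp in _components(shape, far, nb_fg):
        d_comp = _cheb_dist_map(shape, comp)
        contact = {p for p in core if d_comp[p[0]][p[1]] <= w + 1}
        touched = [k for k, cc in enumerate(core_comps) if cc & contact]
        if not touched:
            code = 2
        elif len(touched) >= 2:
            code = 4
        else:
            zones = _components(shape, contact & core_comps[touched[0]], _N8)
            code = 6 if len(zones) >= 2 else 5
        for r, c in comp:
            out[r][c] = code
    return [row[pad:-pad] for row in out[pad:-pad]]


# ---------------------------------------------------------------------------
# Exhaustive path oracles for the connectivity indices
# ---------------------------------------------------------------------------


def enumerate_nl(adj, i, j):
    """Fewest links between i and j by exhaustive simple-path enumeration."""
    n = len(adj)
    if i == j:
        return 0
    best = math.inf
    others = [k for k in range(n) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (i, *mid, j)
            if all(adj[a][b] for a, b in zip(path, path[1:])):
                best = min(best, len(path) - 1)
    return best


def enumerate_max_product(prob, adj, i, j):
    """Maximum product of direct probabilities over all simple paths i->j."""
    n = len(prob)
    if i == j:
        return 1.0
    best = 0.0
    others = [k for k in range(n) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (i, *mid, j)
            if all(adj[a][b] for a, b in zip(path, path[1:])):
                p = 1.0
                for a, b in zip(path, path[1:]):
                    p *= prob[a][b]
                best = max(best, p)
    return best


# ---------------------------------------------------------------------------
# Grid shortest-path oracle (iterative relaxation, no priority queue)
# ---------------------------------------------------------------------------


def relaxation_cost_distance(theta, sources):
    """Exact minimum cumulative cost by Bellman-Ford-style relaxation.

    Move cost between 8-adjacent cells = mean endpoint resistance x step
    length (1 rook, sqrt(2) diagonal).  Converges because costs are positive.
    """
    rows = len(theta)
    cols = len(theta[0])
    cost = [[math.inf] * cols for _ in range(rows)]
    for r, c in sources:
        cost[r][c] = 0.0
    changed = True
    while changed:
        changed = False
        for r in range(rows):
            for c in range(cols):
                for dr, dc in _N8:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols):
                        continue
                    step = math.sqrt(2.0) if dr and dc else 1.0
                    cand = cost[rr][cc] + 0.5 * (theta[r][c] + theta[rr][cc]) * step
                    if cand < cost[r][c] - 1e-15:
                        cost[r][c] = cand
                        changed = True
    return cost
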