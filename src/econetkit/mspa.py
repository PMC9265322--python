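"""Morphological spatial pattern analysis (MSPA).

Segments a binary foreground/background landscape into the seven classical
morphological classes — core, islet, edge, perforation, bridge, loop, branch —
using chamfer (8-neighbourhood / chessboard) distances:

* **core**: foreground farther than ``edge_width`` (chessboard) from any
  background cell — i.e. survives erosion by a square structuring element.
* **edge / perforation**: non-core foreground within ``edge_width`` of core;
  edge faces background connected to the grid border, perforation faces an
  enclosed background hole (ties go to edge).
* **connectors**: the remaining non-core foreground, taken as connected
  components: *bridge* contacts ≥2 distinct core components, *loop* contacts
  one core component at ≥2 disjoint contact zones, *branch* contacts one core
  at one zone, *islet* contacts no core.  A contact zone is a connected
  component of the core cells within chessboard distance ``edge_width + 1``
  of the connector.

The seven classes partition the foreground exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import MSPA_CODES
from .grid import Grid

__all__ = ["MSPA_CODES", "classify", "extract_cores", "CorePatch", "binary_landscape"]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return _STRUCT8
    if connectivity == 4:
        return _STRUCT4
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def binary_landscape(landcover: Grid, foreground_classes: set[int] | frozenset[int]) -> Grid:
    """Reduce a categorical land-cover grid to 0/1 background/foreground."""
    if not foreground_classes:
        raise ValueError("foreground_classes must be non-empty")
    fg = np.isin(landcover.values, sorted(foreground_classes)).astype(np.int8)
    if landcover.nodata is not None:
        fg[landcover.values == landcover.nodata] = 0
    out = landcover.copy_with(fg)
    out.nodata = None
    return out


def _chessboard_distance_to(mask: np.ndarray) -> np.ndarray:
    """Chessboard distance from every cell to the nearest True cell of ``mask``."""
    if not mask.any():
        return np.full(mask.shape, np.iinfo(np.int32).max, dtype=np.int32)
    return ndimage.distance_transform_cdt(~mask, metric="chessboard").astype(np.int32)


def classify(landscape: Grid, edge_width_cells: int = 1,
             foreground_connectivity: int = 8) -> Grid:
    """Assign each foreground cell one of the seven MSPA classes.

    ``landscape`` holds {0, 1}; nodata (if any) is treated as background.
    Background connectivity is taken complementary to the foreground
    (8-connected foreground implies 4-connected background and vice versa),
    the standard convention that keeps foreground and background topology
    consistent.
    """
    if edge_width_cells < 1:
        raise ValueError("edge_width_cells must be >= 1")
    w = int(edge_width_cells)
    # the map edge behaves as background: work on a bg-padded copy
    pad = w + 1
    fg = np.pad(landscape.values == 1, pad, constant_values=False)
    fg_struct = _structure(foreground_connectivity)
    bg_struct = _structure(4 if foreground_connectivity == 8 else 8)

    out = np.zeros(fg.shape, dtype=np.int8)
    if not fg.any():
        return landscape.copy_with(out[pad:-pad, pad:-pad])

    bg = ~fg
    d_bg = _chessboard_distance_to(bg)
    core = fg & (d_bg > w)
    out[core] = MSPA_CODES["core"]

    # split background into border-connected "outside" and enclosed holes
    bg_labels, n_bg = ndimage.label(bg, structure=bg_struct)
    border_labels = np.unique(np.concatenate([
        bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    outside = np.isin(bg_labels, border_labels)
    holes = bg & ~outside

    d_core = _chessboard_distance_to(core)
    d_out = _chessboard_distance_to(outside)
    d_hole = _chessboard_distance_to(holes)

    residual = fg & ~core
    near = residual & (d_core <= w)
    out[near & (d_out <= d_hole)] = MSPA_CODES["edge"]
    out[near & (d_hole < d_out)] = MSPA_CODES["perforation"]

    far = residual & ~near
    if far.any():
        core_labels, _ = ndimage.label(core, structure=_STRUCT8)
        far_labels, n_far = ndimage.label(far, structure=fg_struct)
        for lab in range(1, n_far + 1):
            comp = far_labels == lab
            d_comp = _chessboard_distance_to(comp)
            contact_core = core & (d_comp <= w + 1)
            touched = np.unique(core_labels[contact_core])
            touched = touched[touched > 0]
            if touched.size == 0:
                code = MSPA_CODES["islet"]
            elif touched.size >= 2:
                code = MSPA_CODES["bridge"]
            else:
                zone_mask = contact_core & (core_labels == touched[0])
                _, n_zones = ndimage.label(zone_mask, structure=_STRUCT8)
                code = MSPA_CODES["loop"] if n_zones >= 2 else MSPA_CODES["branch"]
            out[comp] = code

    result = landscape.copy_with(out[pad:-pad, pad:-pad])
    result.nodata = None
    return result


@dataclass(frozen=True)
class CorePatch:
    """A labelled core component: candidate ecological source."""

    id: int
    cells: tuple[tuple[int, int], ...]
    area_cells: int
    area_km2: float
    centroid: tuple[float, float]  # (row, col)


def extract_cores(mspa: Grid, min_area_cells: int = 1, cell_size: float | None = None
                  ) -> list[CorePatch]:
    """Label 8-connected core components and drop those below ``min_area_cells``."""
    cs = cell_size if cell_size is not None else mspa.cell_size
    core = mspa.values == MSPA_CODES["core"]
    labels, n = ndimage.label(core, structure=_STRUCT8)
    patches: list[CorePatch] = []
    pid = 0
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_area_cells:
            continue
        pid += 1
        patches.append(CorePatch(
            id=pid,
            cells=tuple(zip(rows.tolist(), cols.tolist())),
            area_cells=int(rows.size),
            area_km2=float(rows.size) * cs * cs / 1e6,
            centroid=(float(rows.mean()), float(cols.mean())),
        ))
    return patches
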