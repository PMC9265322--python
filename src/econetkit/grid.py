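"""Raster grid container and I/O.

A :class:`Grid` is the common currency of the pipeline: a 2-D array with a
cell size in metres, the (x, y) map coordinate of the outer corner of the
top-left cell (row 0 is northmost), a nodata sentinel, and a free-text CRS
label.  Two on-disk dialects are supported: single-band GeoTIFF (georeferencing
carried in the ModelPixelScale / ModelTiepoint tags, nodata in the GDAL_NODATA
tag) and Esri ASCII grid.

All layers entering a pipeline run must share shape, cell size and origin;
:func:`align_stack` enforces this rather than silently resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "GridFormatError",
    "GridAlignmentError",
    "read_raster",
    "write_raster",
    "align_stack",
]

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_IMAGE_DESCRIPTION = 270


class GridFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


class GridAlignmentError(ValueError):
    """Raised when layers disagree in shape, cell size or origin."""


@dataclass
class Grid:
    """A georeferenced 2-D raster.

    Parameters
    ----------
    values
        2-D array.  Integer arrays are treated as categorical.
    cell_size
        Metres per cell side (square cells only).
    origin
        (x, y) of the outer corner of the top-left cell.
    nodata
        Sentinel value; never participates in arithmetic.
    crs_tag
        Free-text coordinate-system label (metadata only).
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask().sum())

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata (NaN counts as nodata)."""
        mask = np.ones(self.values.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= ~np.isnan(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask

    def cell_center_xy(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a cell center (row 0 north, x east, y north)."""
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 - (row + 0.5) * self.cell_size
        return x, y

    def copy_with(self, values: np.ndarray) -> "Grid":
        """New grid sharing this grid's geometry."""
        return replace(self, values=np.asarray(values))

    def same_geometry(self, other: "Grid", tol_frac: float = 0.5) -> bool:
        """True when shape, cell size and origin agree within tol_frac cells."""
        if self.shape != other.shape:
            return False
        if not math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9):
            return False
        tol = tol_frac * self.cell_size
        return (
            abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


# ---------------------------------------------------------------------------
# Esri ASCII grid
# ---------------------------------------------------------------------------

_ASC_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing ASCII grid header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    try:
        body = np.loadtxt(lines[data_start:], dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: unparseable ASCII grid body: {exc}") from None
    body = np.atleast_2d(body)
    if body.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows}x{ncols} values, got {body.size}"
        )
    values = body.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    cell = header["cellsize"]
    # xllcorner/yllcorner locate the lower-left corner; convert to top-left.
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0) + nrows * cell
    return Grid(values, cell_size=cell, origin=(x0, y0), nodata=nodata)


def _write_ascii(grid: Grid, path: Path) -> None:
    nrows, ncols = grid.shape
    x0, ytop = grid.origin
    yll = ytop - nrows * grid.cell_size
    nodata = grid.nodata if grid.nodata is not None else -9999
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        vals = np.where(np.isnan(vals), nodata, vals)
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    fmt = "%d" if is_int else "%.17g"
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, vals, fmt=fmt)


# ---------------------------------------------------------------------------
# GeoTIFF (via tifffile, georeferencing in standard GeoTIFF tags)
# ---------------------------------------------------------------------------


def _read_geotiff(path: Path) -> Grid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = {tag.code: tag.value for tag in page.tags.values()}
    except (tifffile.TiffFileError, OSError) as exc:
        raise GridFormatError(f"{path}: unreadable TIFF: {exc}") from None
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster")
    cell = 1.0
    origin = (0.0, 0.0)
    if _TAG_MODEL_PIXEL_SCALE in tags:
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise GridFormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        cell = float(sx)
    if _TAG_MODEL_TIEPOINT in tags:
        tp = tags[_TAG_MODEL_TIEPOINT]
        # raster point (i, j) maps to model point (x, y); tie to raster origin
        i, j = tp[0], tp[1]
        x, y = tp[3], tp[4]
        origin = (float(x - i * cell), float(y + j * cell))
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA])
        if np.issubdtype(values.dtype, np.integer):
            nodata = int(nodata)
    crs_tag = str(tags.get(_TAG_IMAGE_DESCRIPTION, "") or "")
    return Grid(values, cell_size=cell, origin=origin, nodata=nodata, crs_tag=crs_tag)


def _write_geotiff(grid: Grid, path: Path) -> None:
    x0, y0 = grid.origin
    cs = float(grid.cell_size)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if grid.nodata is not None:
        nd = grid.nodata
        nd_str = str(int(nd)) if float(nd) == int(nd) else repr(float(nd))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd_str) + 1, nd_str))
    tifffile.imwrite(
        path,
        grid.values,
        extratags=extratags,
        description=grid.crs_tag or None,
    )


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------


def read_raster(path: str | Path, expected_kind: str = "continuous") -> Grid:
    """Read a GeoTIFF or Esri ASCII grid.

    ``expected_kind`` is ``"categorical"`` or ``"continuous"``; categorical
    reads reject fractional cell values and return an integer array.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"raster not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        grid = _read_geotiff(path)
    else:
        grid = _read_ascii(path)
    if expected_kind == "categorical":
        vals = grid.values
        valid = grid.valid_mask()
        frac = vals[valid] % 1 if np.issubdtype(vals.dtype, np.floating) else None
        if frac is not None and np.any(frac != 0):
            raise GridFormatError(
                f"{path}: categorical raster contains fractional values"
            )
        ivals = vals.astype(np.int64)
        if grid.nodata is not None:
            ivals[~valid] = int(grid.nodata)
            grid = replace(grid, values=ivals, nodata=int(grid.nodata))
        else:
            grid = replace(grid, values=ivals)
    elif expected_kind != "continuous":
        raise ValueError(f"expected_kind must be categorical|continuous, got {expected_kind!r}")
    return grid


def write_raster(grid: Grid, path: str | Path) -> None:
    """Write a grid as GeoTIFF (``.tif``/``.tiff``) or Esri ASCII (anything else)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(grid, path)
    else:
        _write_ascii(grid, path)


def align_stack(layers: list[Grid]) -> list[Grid]:
    """Verify that all layers share one geometry; snap sub-half-cell origin offsets.

    Raises :class:`GridAlignmentError` naming the first offending layer when
    shapes or cell sizes differ, or origins disagree by more than half a cell.
    """
    if not layers:
        raise ValueError("align_stack needs at least one layer")
    ref = layers[0]
    out = [ref]
    for k, layer in enumerate(layers[1:], start=1):
        if layer.shape != ref.shape:
            raise GridAlignmentError(
                f"layer {k}: shape {layer.shape} != reference {ref.shape}"
            )
        if not math.isclose(layer.cell_size, ref.cell_size, rel_tol=1e-9):
            raise GridAlignmentError(
                f"layer {k}: cell_size {layer.cell_size} != reference {ref.cell_size}"
            )
        dx = abs(layer.origin[0] - ref.origin[0])
        dy = abs(layer.origin[1] - ref.origin[1])
        if dx > 0.5 * ref.cell_size or dy > 0.5 * ref.cell_size:
            raise GridAlignmentError(
                f"layer {k}: origin {layer.origin} offset from reference "
                f"{ref.origin} by more than half a cell"
            )
        out.append(replace(layer, origin=ref.origin))
    return out
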