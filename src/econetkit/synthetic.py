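"""Seeded synthetic landscapes for exercising the network pipeline.

The generator emulates the broad structure the analysis assumes: terrain that
is high and rough in the west and low in the east, autocorrelated multi-class
land cover with woodland/grassland on high or steep ground and paddy on low
flat ground, a long narrow west-east river corridor flanked by bottomland, a
central block of construction land, and multi-date land-cover sequences whose
class transitions follow a known row-stochastic matrix.

Everything is deterministic given ``SynthSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import LAND_CLASSES
from .grid import Grid

__all__ = ["SynthSpec", "make_dem", "slope_from_dem", "make_landcover", "make_series",
           "default_demo_spec"]

# Order in which classes are stacked along the low->high terrain/field composite.
# Water and paddy claim the lowest cells, woodland the highest.
_ELEVATION_ORDER = [5, 1, 6, 2, 7, 8, 4, 3]


@dataclass
class SynthSpec:
    """Specification of a synthetic landscape.

    ``class_proportions`` must sum to 1; ``transition_matrix`` (class codes in
    sorted order of the proportion keys) must be row-stochastic.
    """

    shape: tuple[int, int] = (220, 300)
    cell_size: float = 90.0
    class_proportions: dict[int, float] = field(default_factory=lambda: {
        1: 0.14, 2: 0.30, 3: 0.16, 4: 0.12, 5: 0.05, 6: 0.04, 7: 0.16, 8: 0.03,
    })
    autocorrelation_range: float = 6.0
    dem_roughness: float = 0.6
    river_row_frac: float = 0.35      # vertical placement of the west-east river
    river_amplitude_frac: float = 0.08
    river_width_cells: int = 2
    river_flank_cells: int = 1
    urban_center_frac: tuple[float, float] = (0.55, 0.55)
    urban_radius_cells: int = 18
    n_dates: int = 2
    transition_matrix: np.ndarray | None = None
    contiguity_lambda: float = 0.5
    seed: int = 0

    def classes(self) -> list[int]:
        return sorted(self.class_proportions)

    def validate(self) -> None:
        if self.shape[0] < 8 or self.shape[1] < 8:
            raise ValueError("shape must be at least 8x8")
        if not 0 < self.dem_roughness < 1:
            raise ValueError("dem_roughness must lie in (0, 1)")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, dtype=float)
            k = len(self.class_proportions)
            if tm.shape != (k, k):
                raise ValueError(f"transition matrix must be {k}x{k}")
            if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("transition matrix must be row-stochastic")


def default_demo_spec(seed: int = 42) -> SynthSpec:
    """The demo landscape used by the analysis scripts: ~20 x 27 km at 90 m cells."""
    k = 8
    tm = np.eye(k) * 0.97 + np.full((k, k), 0.03 / (k - 1))
    np.fill_diagonal(tm, 0.97)
    # urban growth: dry land converts to construction at an elevated rate
    tm[1, 6] += 0.03
    tm[1] /= tm[1].sum()
    return SynthSpec(n_dates=3, transition_matrix=tm, seed=seed)


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------


def _diamond_square(n: int, roughness: float, rng: np.random.Generator) -> np.ndarray:
    """Midpoint-displacement fractal surface on a (n x n) grid, n = 2**k + 1."""
    surf = np.zeros((n, n))
    surf[0, 0], surf[0, -1], surf[-1, 0], surf[-1, -1] = roughness * rng.normal(size=4)
    step = n - 1
    # initial amplitude scales with roughness so the r->0 limit is flat
    amp = roughness
    decay = 2.0 ** (-roughness)
    while step > 1:
        half = step // 2
        # diamond step
        for r in range(half, n, step):
            for c in range(half, n, step):
                corners = (surf[r - half, c - half] + surf[r - half, c + half]
                           + surf[r + half, c - half] + surf[r + half, c + half])
                surf[r, c] = corners / 4.0 + rng.normal() * amp
        # square step
        for r in range(0, n, half):
            start = half if (r // half) % 2 == 0 else 0
            for c in range(start, n, step):
                total, cnt = 0.0, 0
                for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n and 0 <= cc < n:
                        total += surf[rr, cc]
                        cnt += 1
                surf[r, c] = total / cnt + rng.normal() * amp
        amp *= decay
        step = half
    return surf


def make_dem(spec: SynthSpec) -> Grid:
    """Fractal elevation surface with a deterministic west-high/east-low trend.

    The fractal part is midpoint displacement with amplitude proportional to
    ``dem_roughness``; as roughness approaches 0 the surface collapses onto
    the pure linear trend.
    """
    spec.validate()
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)
    n = 2 ** int(np.ceil(np.log2(max(rows, cols) - 1))) + 1
    frac = _diamond_square(n, spec.dem_roughness, rng)[:rows, :cols]
    frac *= 120.0  # metres of fractal relief at roughness 1
    trend = np.linspace(400.0, 80.0, cols)[None, :] * np.ones((rows, 1))
    return Grid(trend + frac, cell_size=spec.cell_size, origin=(0.0, rows * spec.cell_size))


def slope_from_dem(dem: Grid) -> Grid:
    """Slope in degrees from central differences (Horn-style 2-cell span)."""
    z = dem.values.astype(float)
    gy, gx = np.gradient(z, dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return dem.copy_with(slope)


# ---------------------------------------------------------------------------
# Land cover
# ---------------------------------------------------------------------------


def _river_mask(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """(water cells, flanking bottomland cells) of the sinuous west-east river."""
    rows, cols = spec.shape
    water = np.zeros((rows, cols), dtype=bool)
    if spec.river_width_cells <= 0:
        return water, np.zeros_like(water)
    c = np.arange(cols)
    center = (spec.river_row_frac * rows
              + spec.river_amplitude_frac * rows * np.sin(2 * np.pi * c / cols * 1.5))
    half = spec.river_width_cells / 2.0
    r = np.arange(rows)[:, None]
    water = np.abs(r - center[None, :]) <= half
    flank = ndimage.binary_dilation(
        water, structure=np.ones((3, 3), bool), iterations=max(spec.river_flank_cells, 0)
    ) & ~water
    return water, flank


def _urban_mask(spec: SynthSpec) -> np.ndarray:
    rows, cols = spec.shape
    if spec.urban_radius_cells <= 0:
        return np.zeros((rows, cols), dtype=bool)
    cr = spec.urban_center_frac[0] * rows
    cc = spec.urban_center_frac[1] * cols
    r, c = np.ogrid[:rows, :cols]
    return (r - cr) ** 2 + (c - cc) ** 2 <= spec.urban_radius_cells ** 2


def make_landcover(spec: SynthSpec, dem: Grid) -> Grid:
    """Autocorrelated categorical land cover co-varying with terrain.

    A Gaussian random field (white noise smoothed with sigma =
    ``autocorrelation_range`` cells) is blended with standardized elevation;
    classes are assigned by quantile slicing of the composite in a fixed
    low-to-high affinity order (water/paddy lowest ... grassland/woodland
    highest), which realizes ``class_proportions`` exactly before the river
    and urban overlays are stamped on.
    """
    spec.validate()
    if dem.shape != spec.shape:
        raise ValueError("dem shape does not match spec shape")
    missing = [c for c in spec.class_proportions if c not in LAND_CLASSES]
    if missing:
        raise ValueError(f"proportions reference unknown classes: {missing}")
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed + 1)
    noise = rng.normal(size=(rows, cols))
    fieldv = ndimage.gaussian_filter(noise, sigma=spec.autocorrelation_range)
    fieldv = (fieldv - fieldv.mean()) / (fieldv.std() or 1.0)
    z = dem.values.astype(float)
    zstd = (z - z.mean()) / (z.std() or 1.0)
    composite = 0.55 * fieldv + 0.45 * zstd
    # tiny jitter breaks ties so quantile slicing is exact
    composite += rng.normal(scale=1e-9, size=composite.shape)

    order = [c for c in _ELEVATION_ORDER if c in spec.class_proportions]
    order += [c for c in spec.classes() if c not in order]
    fractions = np.array([spec.class_proportions[c] for c in order])
    ranks = composite.ravel().argsort().argsort()  # 0 .. N-1
    cuts = np.floor(np.cumsum(fractions) * ranks.size + 0.5).astype(int)
    codes = np.empty(ranks.size, dtype=np.int64)
    lo = 0
    for cls, hi in zip(order, cuts):
        codes[(ranks >= lo) & (ranks < hi)] = cls
        lo = hi
    codes[ranks >= lo] = order[-1]
    lc = codes.reshape(rows, cols)

    water, flank = _river_mask(spec)
    if spec.class_proportions.get(5, 0) > 0 or spec.river_width_cells > 0:
        lc[water] = 5
        lc[flank] = 6
    urban = _urban_mask(spec)
    lc[urban] = 7
    return Grid(lc, cell_size=spec.cell_size, origin=dem.origin)


# ---------------------------------------------------------------------------
# Multi-date series
# ---------------------------------------------------------------------------


def _neighbor_counts(lc: np.ndarray, cls: int) -> np.ndarray:
    """Number of 8-neighbours of each cell already in class ``cls``."""
    mask = (lc == cls).astype(np.int32)
    kernel = np.ones((3, 3), dtype=np.int32)
    kernel[1, 1] = 0
    return ndimage.convolve(mask, kernel, mode="constant", cval=0)


def make_series(spec: SynthSpec) -> list[Grid]:
    """Land-cover sequence driven by the spec's transition matrix.

    Per-cell targets are drawn independently from the matrix row of the cell's
    current class, so empirical transition frequencies converge exactly to the
    matrix.  Spatial contiguity is then imposed without touching those
    frequencies: within each source class, a fraction ``contiguity_lambda`` of
    the drawn off-diagonal targets is reassigned to the cells of that class
    with the most 8-neighbours already in the target class.  Permuting targets
    within a source class leaves per-class transition counts unchanged.
    """
    spec.validate()
    if spec.n_dates < 2:
        raise ValueError("n_dates must be >= 2 for a series")
    if spec.transition_matrix is None:
        raise ValueError("a transition matrix is required for make_series")
    tm = np.asarray(spec.transition_matrix, dtype=float)
    classes = spec.classes()
    idx_of = {c: k for k, c in enumerate(classes)}

    dem = make_dem(spec)
    first = make_landcover(spec, dem)
    series = [first]
    rng = np.random.default_rng(spec.seed + 1000)
    lc = first.values.copy()
    for _ in range(spec.n_dates - 1):
        nxt = lc.copy()
        for cls in classes:
            cells = np.flatnonzero(lc.ravel() == cls)
            if cells.size == 0:
                continue
            row = tm[idx_of[cls]]
            draws = rng.choice(len(classes), size=cells.size, p=row)
            targets = np.array(classes)[draws]
            changing = targets != cls
            n_change = int(changing.sum())
            if n_change == 0:
                continue
            # contiguity: route a lambda-share of the changes to the cells of
            # this class most surrounded by the target class
            change_targets = np.sort(targets[changing])  # deterministic grouping
            rng.shuffle(change_targets)
            assigned = np.full(cells.size, -1, dtype=np.int64)
            available = np.ones(cells.size, dtype=bool)
            for tgt in np.unique(change_targets):
                n_t = int((change_targets == tgt).sum())
                nb = _neighbor_counts(lc, int(tgt)).ravel()[cells].astype(float)
                score = spec.contiguity_lambda * nb + rng.random(cells.size)
                score[~available] = -np.inf
                pick = np.argpartition(-score, n_t - 1)[:n_t]
                assigned[pick] = tgt
                available[pick] = False
            changed = assigned >= 0
            nxt.ravel()[cells[changed]] = assigned[changed]
        series.append(first.copy_with(nxt))
        lc = nxt
    return series
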