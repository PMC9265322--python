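"""Comprehensive ecological-resistance surface.

Four graded layers — MSPA class, land-cover class, elevation and slope —
are mapped to resistance coefficients on a 1-100 ladder and combined as a
weighted arithmetic sum with AHP-derived layer weights.  Elevation and slope
can be classed either by the fixed published breaks or by 5-class
Fisher-Jenks natural breaks computed from the data.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np

from .config import MSPA_CODES, ResistanceConfig
from .grid import Grid, align_stack

__all__ = [
    "ahp_weights", "grade_categorical", "grade_continuous", "jenks_breaks",
    "grade_layer", "compose", "build_resistance_surface",
]

# Saaty random-consistency indices for n = 1..10
_SAATY_RI = [0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49]


def ahp_weights(pairwise: np.ndarray, tol: float = 1e-10,
                max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """AHP priority weights and consistency ratio from a reciprocal matrix.

    Weights are the normalized principal eigenvector (power iteration to
    ``tol``); CR = ((lambda_max - n)/(n - 1)) / RI with Saaty's RI table.
    A warning is raised when CR > 0.1 (judgements inconsistent).
    """
    m = np.asarray(pairwise, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if np.any(m <= 0):
        raise ValueError("pairwise matrix must be positive")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("pairwise matrix diagonal must be 1")
    if not np.allclose(m * m.T, 1.0, atol=1e-8):
        raise ValueError("pairwise matrix must be reciprocal (m_ji = 1/m_ij)")

    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = m @ w
        nxt /= nxt.sum()
        if np.abs(nxt - w).max() < tol:
            w = nxt
            break
        w = nxt
    lam = float((m @ w / w).mean())
    if n <= 2:
        cr = 0.0
    else:
        ri = _SAATY_RI[n - 1] if n <= 10 else _SAATY_RI[-1]
        cr = ((lam - n) / (n - 1)) / ri
    if cr > 0.1:
        warnings.warn(f"AHP consistency ratio {cr:.3f} exceeds 0.1", stacklevel=2)
    return w, cr


def grade_categorical(grid: Grid, table: dict[int, float] | dict[str, float],
                      code_names: dict[int, str] | None = None) -> Grid:
    """Map categorical codes to coefficients by exact lookup.

    ``table`` keys are either integer codes or class names resolved through
    ``code_names``.  Unknown codes raise, listing the offenders.
    """
    if code_names is not None:
        lut = {code: table[name] for code, name in code_names.items() if name in table}
    else:
        lut = {int(k): v for k, v in table.items()}
    vals = grid.values
    valid = grid.valid_mask()
    out = np.zeros(grid.shape, dtype=float)
    present = np.unique(vals[valid])
    unknown = [int(c) for c in present if int(c) not in lut]
    if unknown:
        raise ValueError(f"no resistance coefficient for category code(s) {unknown}")
    for code, coeff in lut.items():
        out[vals == code] = coeff
    out[~valid] = np.nan
    return grid.copy_with(out)


def grade_continuous(grid: Grid, breaks: tuple[float, ...],
                     coefficients: tuple[float, ...]) -> Grid:
    """Map a continuous layer to coefficients by fixed class breaks.

    ``breaks`` are the upper bounds of the first k-1 classes (value < b0 ->
    coefficients[0], b0 <= value < b1 -> coefficients[1], ...).
    """
    if len(coefficients) != len(breaks) + 1:
        raise ValueError("need one more coefficient than breaks")
    idx = np.digitize(grid.values.astype(float), breaks, right=False)
    out = np.asarray(coefficients, dtype=float)[idx]
    out[~grid.valid_mask()] = np.nan
    return grid.copy_with(out)


def jenks_breaks(values: np.ndarray, n_classes: int = 5,
                 max_samples: int = 2000, seed: int = 0) -> list[float]:
    """Fisher-Jenks natural breaks (exact dynamic program on sorted values).

    Returns the k-1 interior break values (upper bounds of the first k-1
    classes).  Large inputs are subsampled deterministically.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no data for natural breaks")
    if v.size > max_samples:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=max_samples, replace=False)
    v = np.sort(v)
    uniq = np.unique(v)
    k = min(n_classes, uniq.size)
    if k <= 1:
        return []
    n = v.size
    # prefix sums for O(1) within-class sum of squared deviations
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: int, j: int) -> float:  # cells v[i:j]
        cnt = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / cnt

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                cand = cost[c - 1, i] + ssd(i, j)
                if cand < best:
                    best, arg = cand, i
            cost[c, j] = best
            split[c, j] = arg
    # backtrack class boundaries; breaks placed between adjacent class extremes
    bounds = []
    j = n
    for c in range(k, 1, -1):
        i = split[c, j]
        bounds.append((v[i - 1] + v[i]) / 2.0 if 0 < i < n else v[0])
        j = i
    return sorted(bounds)


def grade_layer(grid: Grid, table, mode: str = "fixed_breaks",
                breaks: tuple[float, ...] | None = None,
                code_names: dict[int, str] | None = None, seed: int = 0) -> Grid:
    """Grade one layer to resistance coefficients.

    Categorical layers (``table`` a mapping) use exact code lookup; continuous
    layers (``table`` a coefficient ladder) use ``breaks`` in ``fixed_breaks``
    mode or data-driven Fisher-Jenks breaks in ``natural_breaks`` mode, the
    coefficient ladder applying low class -> low coefficient either way.
    """
    if isinstance(table, dict):
        return grade_categorical(grid, table, code_names)
    coefficients = tuple(table)
    if mode == "fixed_breaks":
        if breaks is None:
            raise ValueError("fixed_breaks mode needs explicit breaks")
        return grade_continuous(grid, breaks, coefficients)
    if mode == "natural_breaks":
        jb = jenks_breaks(grid.values[grid.valid_mask()], len(coefficients), seed=seed)
        coeffs = coefficients[: len(jb) + 1]
        return grade_continuous(grid, tuple(jb), coeffs)
    raise ValueError(f"unknown grading mode {mode!r}")


def compose(layers: list[Grid], weights) -> Grid:
    """Weighted-sum overlay of graded layers, clamped to [1, 100]."""
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(layers):
        raise ValueError("one weight per layer required")
    if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be positive and sum to 1")
    layers = align_stack(list(layers))
    stack = np.stack([lay.values.astype(float) for lay in layers])
    combo = np.tensordot(weights, stack, axes=1)
    combo = np.clip(combo, 1.0, 100.0)
    combo[np.isnan(stack).any(axis=0)] = np.nan
    return layers[0].copy_with(combo)


def config_hash(cfg: ResistanceConfig) -> str:
    """Stable hash of the grading configuration, for provenance logging."""
    payload = json.dumps({
        "mspa": cfg.mspa_coefficients,
        "landcover": {str(k): v for k, v in cfg.landcover_coefficients.items()},
        "elev": [list(cfg.elevation_breaks), list(cfg.elevation_coefficients)],
        "slope": [list(cfg.slope_breaks), list(cfg.slope_coefficients)],
        "weights": list(cfg.weights),
        "mode": cfg.classing_mode,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_resistance_surface(mspa_grid: Grid, landcover: Grid, dem: Grid, slope: Grid,
                             cfg: ResistanceConfig | None = None, seed: int = 0) -> Grid:
    """Grade the four layers with the configured tables and overlay them."""
    cfg = cfg or ResistanceConfig()
    cfg.validate()
    code_of = {v: k for k, v in MSPA_CODES.items()}
    g_mspa = grade_categorical(mspa_grid, cfg.mspa_coefficients, code_names=code_of)
    g_lc = grade_categorical(landcover, cfg.landcover_coefficients)
    g_dem = grade_layer(dem, cfg.elevation_coefficients, cfg.classing_mode,
                        breaks=cfg.elevation_breaks, seed=seed)
    g_slope = grade_layer(slope, cfg.slope_coefficients, cfg.classing_mode,
                          breaks=cfg.slope_breaks, seed=seed + 1)
    return compose([g_mspa, g_lc, g_dem, g_slope], cfg.weights)
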