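"""Markov-chain demand projection and cellular-automaton allocation.

The land-use change model has three parts: (1) a class-transition matrix
cross-tabulated from two observed rasters, (2) a Markov projection of future
per-class cell demand (counts x P^steps, integer-rounded with exact
conservation), and (3) a cellular automaton that reallocates cells toward
the projected demand.  Each CA iteration converts a batch of cells from
surplus classes to deficit classes, choosing cells by seeded roulette over
``suitability x neighbourhood density x class inertia``; restricted cells
never change and a class-pair convertibility matrix can forbid transitions.
Suitability defaults to a multinomial-logistic model fitted on a small
subsample of an observed raster pair; any per-class probability surface can
be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .grid import Grid

__all__ = [
    "TransitionMatrix", "estimate_transitions", "project_demand",
    "CAState", "ca_allocate", "default_suitability", "agreement",
]


@dataclass
class TransitionMatrix:
    """Class-to-class cell counts between two dates, with row probabilities."""

    classes: list[int]
    counts: np.ndarray          # (k, k) cell counts
    cell_size: float            # metres, for the area table

    @property
    def probabilities(self) -> np.ndarray:
        c = self.counts.astype(float)
        totals = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, c / totals, 0.0)
        # empty classes stay where they are
        for i in np.flatnonzero(totals.ravel() == 0):
            p[i, i] = 1.0
        return p

    @property
    def areas_km2(self) -> np.ndarray:
        return self.counts * (self.cell_size ** 2) / 1e6

    def to_frame(self) -> pd.DataFrame:
        """Transfer-area table (km^2), classes x classes, diagonal included."""
        return pd.DataFrame(self.areas_km2, index=self.classes, columns=self.classes)


def estimate_transitions(a: Grid, b: Grid, classes: list[int] | None = None
                         ) -> TransitionMatrix:
    """Cross-tabulate per-cell class pairs between two aligned rasters."""
    if a.shape != b.shape:
        raise ValueError("rasters must share shape")
    va, vb = a.values.ravel(), b.values.ravel()
    valid = np.ones(va.size, dtype=bool)
    if a.nodata is not None:
        valid &= va != a.nodata
    if b.nodata is not None:
        valid &= vb != b.nodata
    va, vb = va[valid], vb[valid]
    if classes is None:
        classes = sorted(set(np.unique(va)) | set(np.unique(vb)))
    classes = [int(c) for c in classes]
    if not set(np.unique(va)).issubset(classes) or not set(np.unique(vb)).issubset(classes):
        raise ValueError("rasters contain classes outside the stated legend")
    k = len(classes)
    ia = np.searchsorted(classes, va)
    ib = np.searchsorted(classes, vb)
    counts = np.bincount(ia * k + ib, minlength=k * k).reshape(k, k)
    return TransitionMatrix(classes=classes, counts=counts, cell_size=a.cell_size)


def _largest_remainder(real: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative reals to integers summing exactly to ``total``."""
    floor = np.floor(real).astype(np.int64)
    short = total - int(floor.sum())
    if short > 0:
        order = np.argsort(-(real - floor), kind="stable")
        floor[order[:short]] += 1
    elif short < 0:  # numerical overshoot
        order = np.argsort(real - floor, kind="stable")
        for i in order:
            if floor[i] > 0 and short < 0:
                floor[i] -= 1
                short += 1
    return floor


def project_demand(tm: TransitionMatrix, current: dict[int, int] | np.ndarray,
                   steps: int = 1) -> dict[int, int]:
    """Per-class cell demand after ``steps`` applications of the Markov matrix.

    Rounded with largest-remainder correction so the total is conserved
    exactly.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if isinstance(current, dict):
        vec = np.array([current.get(c, 0) for c in tm.classes], dtype=float)
    else:
        vec = np.asarray(current, dtype=float)
    total = int(round(vec.sum()))
    p = np.linalg.matrix_power(tm.probabilities, steps)
    demand = vec @ p
    rounded = _largest_remainder(demand, total)
    return {c: int(n) for c, n in zip(tm.classes, rounded)}


@dataclass
class CAState:
    """Inputs of one cellular-automaton allocation run."""

    current: Grid
    suitability: dict[int, np.ndarray]     # class -> per-cell probability
    demand: dict[int, int]
    restricted: np.ndarray | None = None   # True = frozen
    convertibility: np.ndarray | None = None  # (k, k) bool, rows=from
    classes: list[int] = field(default_factory=list)
    neighborhood: int = 3
    max_iterations: int = 300
    tolerance: float = 0.005
    batch_fraction: float = 0.25           # share of remaining deficit converted per iter
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted(self.demand)
        if self.neighborhood % 2 == 0 or self.neighborhood < 1:
            raise ValueError("neighborhood must be odd and >= 1")


def _neighbour_density(lc: np.ndarray, cls: int, size: int) -> np.ndarray:
    mask = (lc == cls).astype(float)
    kernel = np.ones((size, size))
    kernel[size // 2, size // 2] = 0.0
    dens = ndimage.convolve(mask, kernel, mode="constant", cval=0.0)
    return dens / (kernel.sum() or 1.0)


def ca_allocate(state: CAState) -> Grid:
    """Iterate conversions until class counts meet demand within tolerance.

    Per iteration, for every deficit class a batch of candidate cells
    (currently in surplus classes, convertible, unrestricted) is drawn by
    seeded roulette with weights ``suitability x (neighbourhood density +
    0.01) x inertia``, where the class inertia multiplier grows with the
    remaining relative deficit.  Only surplus-to-deficit conversions happen,
    so the total absolute deficit never increases.
    """
    lc = state.current.values.copy()
    classes = state.classes
    idx = {c: i for i, c in enumerate(classes)}
    demand_total = sum(state.demand.values())
    if demand_total != lc.size:
        raise ValueError(
            f"demand ({demand_total} cells) infeasible for raster of {lc.size} cells")
    rng = np.random.default_rng(state.seed)
    restricted = (state.restricted if state.restricted is not None
                  else np.zeros(lc.shape, dtype=bool))
    conv = state.convertibility
    inertia = {c: 1.0 for c in classes}
    tol_cells = max(1.0, state.tolerance * demand_total / max(len(classes), 1))

    def counts() -> dict[int, int]:
        return {c: int((lc == c).sum()) for c in classes}

    for _ in range(state.max_iterations):
        cnt = counts()
        deficit = {c: state.demand.get(c, 0) - cnt[c] for c in classes}
        if all(abs(d) <= tol_cells for d in deficit.values()):
            break
        # inertia: push classes still short of demand, damp overshooting ones
        for c in classes:
            rel = deficit[c] / max(state.demand.get(c, 1), 1)
            inertia[c] = float(np.clip(inertia[c] * (1.0 + 0.5 * rel), 0.1, 10.0))
        surplus_classes = [c for c in classes if deficit[c] < -tol_cells]
        deficit_classes = [c for c in classes if deficit[c] > tol_cells]
        if not surplus_classes or not deficit_classes:
            break
        surplus_budget = {c: -deficit[c] for c in surplus_classes}
        for tgt in sorted(deficit_classes, key=lambda c: -deficit[c]):
            need = int(np.ceil(deficit[tgt] * state.batch_fraction))
            need = max(need, 1)
            donors = [c for c in surplus_classes if surplus_budget.get(c, 0) >= 1
                      and (conv is None or conv[idx[c], idx[tgt]])]
            if not donors:
                continue
            cand_mask = np.isin(lc, donors) & ~restricted
            cand = np.flatnonzero(cand_mask.ravel())
            if cand.size == 0:
                continue
            dens = _neighbour_density(lc, tgt, state.neighborhood).ravel()[cand]
            suit = state.suitability[tgt].ravel()[cand]
            score = suit * (dens + 0.01) * inertia[tgt]
            if score.sum() <= 0:
                score = np.ones_like(score)
            take = min(need, cand.size, int(sum(surplus_budget[c] for c in donors)))
            if take <= 0:
                continue
            pick = rng.choice(cand, size=take, replace=False, p=score / score.sum())
            # respect per-donor budgets
            flat = lc.ravel()
            converted = 0
            for cell in pick:
                src = int(flat[cell])
                if surplus_budget.get(src, 0) >= 1:
                    flat[cell] = tgt
                    surplus_budget[src] -= 1
                    converted += 1
            if converted == 0:
                continue
    return state.current.copy_with(lc)


def default_suitability(predictors: list[Grid], train_from: Grid, train_to: Grid,
                        classes: list[int] | None = None,
                        sample_fraction: float = 0.01, seed: int = 0
                        ) -> dict[int, np.ndarray]:
    """Multinomial-logistic per-class suitability surfaces.

    Fitted on a seeded subsample (default 1 % of cells) of the *end* raster of
    an observed pair, with the predictor grids as features; probabilities are
    normalized per cell.  Degenerate single-class training yields the class
    prior everywhere (uniform over the one class) with a warning.
    """
    if not predictors:
        raise ValueError("at least one predictor grid required")
    if classes is None:
        classes = sorted(int(c) for c in np.unique(train_to.values))
    x = np.stack([np.asarray(p.values, float).ravel() for p in predictors], axis=1)
    y = train_to.values.ravel()
    rng = np.random.default_rng(seed)
    n = y.size
    take = max(int(n * sample_fraction), 10 * len(classes))
    sample = rng.choice(n, size=min(take, n), replace=False)
    xs, ys = x[sample], y[sample]
    present = np.unique(ys)
    if present.size < 2:
        import warnings

        warnings.warn("single-class training sample; returning uniform suitability",
                      stacklevel=2)
        flat = np.full(n, 1.0 / len(classes))
        return {c: flat.reshape(train_to.shape).copy() for c in classes}
    mu, sd = xs.mean(axis=0), xs.std(axis=0)
    sd[sd == 0] = 1.0
    model = LogisticRegression(max_iter=1000)
    model.fit((xs - mu) / sd, ys)
    proba = model.predict_proba((x - mu) / sd)
    out: dict[int, np.ndarray] = {}
    fitted = {int(c): k for k, c in enumerate(model.classes_)}
    for c in classes:
        if c in fitted:
            out[c] = proba[:, fitted[c]].reshape(train_to.shape)
        else:
            out[c] = np.zeros(train_to.shape)
    # renormalize per cell over the requested class set
    total = np.sum([out[c] for c in classes], axis=0)
    total[total == 0] = 1.0
    for c in classes:
        out[c] = out[c] / total
    return out


def agreement(reference: Grid, simulated: Grid) -> tuple[float, float]:
    """(kappa, overall accuracy) between two categorical rasters."""
    if reference.shape != simulated.shape:
        raise ValueError("rasters must share shape")
    a = reference.values.ravel()
    b = simulated.values.ravel()
    classes = np.unique(np.concatenate([a, b]))
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    conf = np.zeros((k, k), dtype=np.int64)
    ai = np.searchsorted(classes, a)
    bi = np.searchsorted(classes, b)
    np.add.at(conf, (ai, bi), 1)
    n = conf.sum()
    oa = np.trace(conf) / n
    pe = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / n ** 2
    kappa = (oa - pe) / (1 - pe) if pe < 1 else 1.0
    return float(kappa), float(oa)
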