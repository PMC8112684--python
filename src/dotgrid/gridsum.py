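"""Rectangle-lattice summarization of a dot field.

The identified dots are far too numerous to test individually, so the card
is tiled into rectangles (default 20x20 = 400) and each rectangle is
featurized by its 3-vector of (small, medium, large) dot counts.  A
rule-based ladder then assigns each rectangle a density category:

R1  Highly-dense:     >= 1 large dot, or >= 2 medium dots
R2  Dense:            exactly 1 medium dot (no large)
R3  Sparse:           >= 2 small dots (no medium/large)
R4  Extremely-sparse: at most 1 small dot

The categories nest into cumulative scales [R1] <= [R1-R2] <= [R1-R3] for
multiscale uniformness testing.  A hierarchical-clustering tree over the
weighted count vectors (weights = class mean radii) is available as the
diagnostic that guided the categorization rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .dots import DotCollection, SIZE_CLASSES

__all__ = [
    "RectGrid",
    "partition_grid",
    "featurize",
    "weighted_distance",
    "categorize_rectangles",
    "cumulative_scale",
    "LEVELS",
]

LEVELS = {"R1": 1, "R1R2": 2, "R1R3": 3}


@dataclass
class RectGrid:
    """Rectangle tiling of a paper region with per-cell features/categories.

    ``row_edges``/``col_edges`` are pixel boundaries (half-open cells);
    ``counts`` is (rows, cols, 3) in (small, medium, large) order;
    ``categories`` is (rows, cols) with values 1..4 for R1..R4.
    """

    rows: int
    cols: int
    row_edges: np.ndarray
    col_edges: np.ndarray
    counts: np.ndarray | None = None
    categories: np.ndarray | None = None
    linkage_tree: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def to_frame(self) -> pd.DataFrame:
        if self.counts is None:
            raise ValueError("grid is not featurized")
        recs = []
        for r in range(self.rows):
            for c in range(self.cols):
                rec = dict(row=r, col=c,
                           n_small=int(self.counts[r, c, 0]),
                           n_medium=int(self.counts[r, c, 1]),
                           n_large=int(self.counts[r, c, 2]))
                if self.categories is not None:
                    rec["category"] = f"R{int(self.categories[r, c])}"
                recs.append(rec)
        return pd.DataFrame(recs)


def partition_grid(bounds: tuple[int, int, int, int], rows: int, cols: int) -> RectGrid:
    """Tile a half-open pixel rectangle into ``rows`` x ``cols`` cells.

    Near-equal integer tiling: every cell gets the floor share and the
    trailing row/column absorbs the remainder.
    """
    if rows * cols < 4:
        raise ValueError("need at least 4 rectangles")
    x0, y0, x1, y1 = bounds
    w, h = x1 - x0, y1 - y0
    if w < cols or h < rows:
        raise ValueError(f"grid {rows}x{cols} larger than pixel dimensions {w}x{h}")
    col_edges = np.concatenate([x0 + np.arange(cols) * (w // cols), [x1]])
    row_edges = np.concatenate([y0 + np.arange(rows) * (h // rows), [y1]])
    return RectGrid(rows=rows, cols=cols, row_edges=row_edges, col_edges=col_edges)


def featurize(grid: RectGrid, dots: DotCollection) -> RectGrid:
    """Count small/medium/large dots per rectangle by centroid membership.

    A centroid outside the grid bounds is assigned to the nearest rectangle
    with a warning.  Counts are conserved: they sum to the number of dots.
    """
    counts = np.zeros((grid.rows, grid.cols, 3), dtype=int)
    class_index = {cls: i for i, cls in enumerate(SIZE_CLASSES)}
    n_outside = 0
    for dot in dots:
        if dot.size_class is None:
            raise ValueError("dots must be size-classified before featurization")
        x, y = dot.centroid
        c = int(np.searchsorted(grid.col_edges, x, side="right")) - 1
        r = int(np.searchsorted(grid.row_edges, y, side="right")) - 1
        if not (0 <= r < grid.rows and 0 <= c < grid.cols):
            n_outside += 1
            r = min(max(r, 0), grid.rows - 1)
            c = min(max(c, 0), grid.cols - 1)
        counts[r, c, class_index[dot.size_class]] += 1
    if n_outside:
        warnings.warn(f"{n_outside} dot centroid(s) outside grid; assigned to nearest rectangle",
                      stacklevel=2)
    grid.counts = counts
    return grid


def weighted_distance(u, v, w) -> float:
    """Weighted Euclidean distance sqrt(sum_i (w_i (u_i - v_i))^2).

    The weights are the class mean radii, so differences in large-dot
    counts dominate differences in small-dot counts.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sqrt(np.sum((w * (u - v)) ** 2)))


def categorize_rectangles(
    grid: RectGrid,
    *,
    weights=None,
    linkage: str = "ward",
    compute_tree: bool = False,
) -> RectGrid:
    """Apply the R1-R4 density rules; optionally build the diagnostic HC tree.

    The rules are exhaustive and mutually exclusive on any count vector.
    When ``compute_tree`` is set, an agglomerative tree over the
    weight-scaled feature vectors is stored on ``grid.linkage_tree``
    (``weights`` defaults to (1, 2, 3) if no class mean radii are given).
    """
    if grid.counts is None:
        raise ValueError("grid is not featurized")
    small = grid.counts[:, :, 0]
    medium = grid.counts[:, :, 1]
    large = grid.counts[:, :, 2]
    cat = np.full((grid.rows, grid.cols), 4, dtype=int)
    cat[small >= 2] = 3
    cat[medium == 1] = 2
    cat[(large >= 1) | (medium >= 2)] = 1
    grid.categories = cat
    if compute_tree:
        w = np.asarray(weights if weights is not None else (1.0, 2.0, 3.0), dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        feats = grid.counts.reshape(-1, 3) * w
        grid.linkage_tree = sch.linkage(feats, method=linkage)
    return grid


def cumulative_scale(grid_or_categories, level: str) -> np.ndarray:
    """Cells (row, col) whose category falls inside a cumulative scale.

    ``level`` is one of 'R1', 'R1R2', 'R1R3'; the returned sets are nested.
    Cells labelled 0 (unassigned background in synthetic fields) never
    qualify.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {sorted(LEVELS)}, got {level!r}")
    cats = getattr(grid_or_categories, "categories", grid_or_categories)
    if cats is None:
        raise ValueError("grid is not categorized")
    cats = np.asarray(cats)
    sel = (cats >= 1) & (cats <= LEVELS[level])
    return np.argwhere(sel)
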