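"""Multiscale 2D spatial-uniformness test via MSTs and an HC-tree p-value.

Observed dense rectangles are connected by a minimum spanning tree (MST)
whose edge-length distribution summarizes their spatial concentration.
Under complete spatial randomness, the same number of cells is resampled
uniformly from the grid B times, giving a null ensemble of MSTs.  All B+1
edge-length distributions are binned on a common 10-bin histogram, a
hierarchical-clustering tree is grown over the B+1 count rows, and the
observed row's isolation in that tree is scored by the *product of odds*
(PO): descending from the root to the observed leaf, each bifurcation
contributes (size of the branch containing the leaf) / (size of the other
branch).  A leaf split off early against many alternatives accumulates a
tiny PO.  The p-value is the fraction of null leaves with a strictly
smaller PO — a quantity that is exchangeable, hence approximately uniform,
under the null.

A conventional ROC/AUC comparison of the observed edge-length distribution
against each null one is computed alongside; AUC below 0.5 means the
observed distances are stochastically smaller (tighter clustering) than
expected under uniformness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .gridsum import LEVELS, cumulative_scale

__all__ = [
    "MSTResult",
    "HistogramMatrix",
    "PathCode",
    "TestReport",
    "UniformnessTest",
    "build_mst",
    "null_mst_ensemble",
    "histogram_matrix",
    "hc_tree_rows",
    "leaf_path_odds",
    "all_leaf_odds",
    "tree_p_value",
    "roc_auc_ensemble",
    "run_uniformness_test",
]


@dataclass(frozen=True)
class MSTResult:
    """Minimum spanning tree over 2D points: edges and their lengths."""

    points: np.ndarray
    edges: np.ndarray
    weights: np.ndarray

    @property
    def k(self) -> int:
        return len(self.points)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def build_mst(points) -> MSTResult:
    """Euclidean MST via Prim's algorithm with deterministic tie-breaking.

    Ties are broken by lowest node index; the edge list is reported in
    lexicographic (i, j) order with i < j.  Requires k >= 2 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (k, 2) points, got shape {pts.shape}")
    k = len(pts)
    if k < 2:
        raise ValueError("need at least 2 points for a spanning tree")
    dist = cdist(pts, pts)
    in_tree = np.zeros(k, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    best_from = np.zeros(k, dtype=int)
    edges = np.empty((k - 1, 2), dtype=int)
    weights = np.empty(k - 1, dtype=float)
    for t in range(k - 1):
        cand = np.where(in_tree, np.inf, best)
        j = int(np.argmin(cand))
        u, v = best_from[j], j
        edges[t] = (min(u, v), max(u, v))
        weights[t] = best[j]
        in_tree[j] = True
        closer = ~in_tree & (dist[j] < best)
        best[closer] = dist[j][closer]
        best_from[closer] = j
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return MSTResult(points=pts, edges=edges[order], weights=weights[order])


def null_mst_ensemble(grid_shape: tuple[int, int], k: int, B: int, seed=None) -> list[MSTResult]:
    """B MSTs over k cells drawn uniformly without replacement from the grid.

    Cells are the rectangles of a ``rows x cols`` lattice; coordinates are
    (row, col) in grid units, matching the observed-cell coordinates.
    """
    rows, cols = grid_shape
    n_cells = rows * cols
    if k > n_cells:
        raise ValueError(f"cannot draw {k} distinct cells from {n_cells}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(B):
        idx = rng.choice(n_cells, size=k, replace=False)
        pts = np.column_stack([idx // cols, idx % cols]).astype(float)
        out.append(build_mst(pts))
    return out


@dataclass(frozen=True)
class HistogramMatrix:
    """(B+1) x n_bins count matrix over shared bin edges; row 0 = observed."""

    bin_edges: np.ndarray
    counts: np.ndarray


def histogram_matrix(obs: MSTResult, nulls: list[MSTResult], n_bins: int = 10) -> HistogramMatrix:
    """Bin all B+1 edge-length multisets on pooled equal-width bins.

    The rightmost bin is closed, so every row sums to k-1.  A pooled
    distance multiset with zero range collapses to a single degenerate bin
    with a warning.
    """
    all_w = [obs.weights] + [m.weights for m in nulls]
    if any(len(w) != len(obs.weights) for w in all_w):
        raise ValueError("all MSTs must have the same number of edges")
    pooled = np.concatenate(all_w)
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi - lo < 1e-12:
        warnings.warn("zero-variance pooled distances; using a single degenerate bin",
                      stacklevel=2)
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.vstack([np.histogram(w, bins=edges)[0] for w in all_w])
    return HistogramMatrix(bin_edges=edges, counts=counts)


def hc_tree_rows(matrix, method: str = "ward") -> np.ndarray:
    """Agglomerative binary tree (scipy linkage) over histogram rows."""
    counts = getattr(matrix, "counts", matrix)
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 rows to build a tree")
    return sch.linkage(counts, method=method)


def _tree_arrays(Z: np.ndarray):
    n = len(Z) + 1
    size = np.concatenate([np.ones(n), Z[:, 3]]).astype(int)
    parent = np.full(2 * n - 1, -1, dtype=int)
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)
    for m in range(n - 1):
        parent[left[m]] = parent[right[m]] = n + m
    return n, size, parent, left, right


@dataclass(frozen=True)
class PathCode:
    """Root-to-leaf descent record: branch codes, sizes and the odds product.

    ``codes[k]`` is 0 if the leaf lies in the left child at the k-th
    bifurcation and 1 otherwise; ``branch_sizes[k]`` is (|L|, |R|).  The
    product of odds multiplies, per step,
    |L|^(1-d) |R|^d / (|L|^d |R|^(1-d)) — i.e. containing over other
    branch size — and the descent stops at the singleton observed leaf.
    """

    codes: tuple[int, ...]
    branch_sizes: tuple[tuple[int, int], ...]
    po: float

    @property
    def depth(self) -> int:
        return len(self.codes)


def leaf_path_odds(Z: np.ndarray, leaf: int) -> PathCode:
    """Descend the linkage tree to ``leaf``, recording codes, sizes and PO."""
    n, size, parent, left, right = _tree_arrays(Z)
    if not 0 <= leaf < n:
        raise ValueError(f"leaf {leaf} not in tree with {n} leaves")
    steps = []
    node = leaf
    while parent[node] != -1:
        par = parent[node]
        m = par - n
        l, r = left[m], right[m]
        d = 0 if node == l else 1
        steps.append((d, int(size[l]), int(size[r]), int(size[node]),
                      int(size[r if node == l else l])))
        node = par
    steps.reverse()
    po = 1.0
    for _, _, _, containing, other in steps:
        po *= containing / other
    return PathCode(
        codes=tuple(s[0] for s in steps),
        branch_sizes=tuple((s[1], s[2]) for s in steps),
        po=po,
    )


def all_leaf_odds(Z: np.ndarray) -> np.ndarray:
    """Product of odds for every leaf of a linkage tree."""
    n, size, parent, left, right = _tree_arrays(Z)
    po = np.ones(n)
    for leaf in range(n):
        node = leaf
        acc = 1.0
        while parent[node] != -1:
            par = parent[node]
            m = par - n
            sib = right[m] if node == left[m] else left[m]
            acc *= size[node] / size[sib]
            node = par
        po[leaf] = acc
    return po


def tree_p_value(po_obs: float, po_ensemble) -> float:
    """Fraction of null odds strictly below the observed one.

    Ties count as not-less, so equal odds never contribute evidence.
    """
    po_ensemble = np.asarray(po_ensemble, dtype=float)
    if len(po_ensemble) == 0:
        raise ValueError("empty ensemble")
    return float(np.count_nonzero(po_ensemble < po_obs) / len(po_ensemble))


def _rank_auc(obs: np.ndarray, null: np.ndarray) -> float:
    n_o, n_n = len(obs), len(null)
    ranks = rankdata(np.concatenate([obs, null]))
    u = ranks[:n_o].sum() - n_o * (n_o + 1) / 2.0
    return float(u / (n_o * n_n))


def roc_auc_ensemble(obs_distances, null_distances: list) -> np.ndarray:
    """Mann-Whitney AUC of the observed distances against each null multiset.

    Orientation: AUC = P(observed > null) with ties counted by halves, so
    AUC < 0.5 means the observed distances are stochastically smaller.
    Identical multisets give exactly 0.5.
    """
    obs = np.asarray(obs_distances, dtype=float)
    if len(obs) == 0:
        raise ValueError("empty observed distance multiset")
    out = np.empty(len(null_distances))
    for i, nd in enumerate(null_distances):
        nd = np.asarray(nd, dtype=float)
        if len(nd) == 0:
            raise ValueError("empty null distance multiset")
        out[i] = _rank_auc(obs, nd)
    return out


@dataclass
class TestReport:
    """Full record of one uniformness test at one cumulative scale."""

    level: str
    k: int
    B: int
    seed: object
    linkage: str
    bin_edges: np.ndarray
    po_obs: float
    po_null: np.ndarray
    p_value: float
    auc: np.ndarray
    mst_obs: MSTResult
    mst_null: list[MSTResult] = field(repr=False, default_factory=list)
    histogram: HistogramMatrix | None = field(repr=False, default=None)
    tree: np.ndarray | None = field(repr=False, default=None)

    def auc_summary(self) -> dict[str, float]:
        return {
            "min": float(self.auc.min()),
            "median": float(np.median(self.auc)),
            "max": float(self.auc.max()),
        }

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "k": self.k,
            "B": self.B,
            "seed": int(self.seed) if isinstance(self.seed, (int, np.integer)) else None,
            "linkage": self.linkage,
            "PO_obs": float(self.po_obs),
            "p_value": float(self.p_value),
            "auc_summary": self.auc_summary(),
            "bin_edges": [float(e) for e in self.bin_edges],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


class UniformnessTest(BaseEstimator):
    """MST + HC-tree product-of-odds test of 2D spatial uniformness.

    Parameters
    ----------
    level : cumulative density scale, 'R1', 'R1R2' or 'R1R3'.
    B : size of the null MST ensemble.
    linkage : linkage for the histogram-row tree (the p-value can depend on
        it; ward is the default and is recorded in the report).
    n_bins : histogram bins over the pooled distances.
    random_state : seed for the null ensemble.

    Fitted attributes (after ``fit(categories)`` on a (rows, cols) integer
    category field): ``report_``, ``p_value_``, ``po_obs_``, ``auc_``.
    """

    def __init__(self, level: str = "R1", B: int = 500, linkage: str = "ward",
                 n_bins: int = 10, random_state=None):
        self.level = level
        self.B = B
        self.linkage = linkage
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y=None):
        cats = np.asarray(getattr(X, "categories", X))
        if cats.ndim != 2:
            raise ValueError(f"expected a (rows, cols) category field, got shape {cats.shape}")
        cells = cumulative_scale(cats, self.level)
        k = len(cells)
        if k < 3:
            raise ValueError(
                f"too few dense rectangles to test at scale {self.level} (k={k} < 3)"
            )
        rng = np.random.default_rng(self.random_state)
        obs = build_mst(cells.astype(float))
        nulls = null_mst_ensemble(cats.shape, k, self.B, rng)
        hm = histogram_matrix(obs, nulls, n_bins=self.n_bins)
        Z = hc_tree_rows(hm, method=self.linkage)
        po = all_leaf_odds(Z)
        po_obs = float(po[0])
        p = tree_p_value(po_obs, po[1:])
        auc = roc_auc_ensemble(obs.weights, [m.weights for m in nulls])
        self.report_ = TestReport(
            level=self.level, k=k, B=self.B, seed=self.random_state,
            linkage=self.linkage, bin_edges=hm.bin_edges, po_obs=po_obs,
            po_null=po[1:], p_value=p, auc=auc, mst_obs=obs,
            mst_null=nulls, histogram=hm, tree=Z,
        )
        self.p_value_ = p
        self.po_obs_ = po_obs
        self.auc_ = auc
        return self


def run_uniformness_test(categories, level: str = "R1", B: int = 500,
                         seed=None, linkage: str = "ward", n_bins: int = 10) -> TestReport:
    """Run the full uniformness test on a category field at one scale."""
    test = UniformnessTest(level=level, B=B, linkage=linkage,
                           n_bins=n_bins, random_state=seed)
    return test.fit(categories).report_
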