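"""MST construction, histogram matrix, HC-tree odds and the test harness."""

import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist

from dotgrid.uniformtest import (
    UniformnessTest,
    all_leaf_odds,
    build_mst,
    hc_tree_rows,
    histogram_matrix,
    leaf_path_odds,
    null_mst_ensemble,
    roc_auc_ensemble,
    run_uniformness_test,
    tree_p_value,
)


# ---------------------------------------------------------------- oracles
def _prufer_to_edges(seq, k):
    degree = [1] * k
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = sorted(i for i in range(k) if degree[i] == 1)
    seq = list(seq)
    for v in seq:
        u = leaves.pop(0)
        edges.append((u, v))
        degree[v] -= 1
        if degree[v] == 1:
            import bisect
            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    return edges


def mst_weight_exhaustive(points):
    """Minimum over all k^(k-2) labelled spanning trees (Cayley)."""
    pts = np.asarray(points, float)
    k = len(pts)
    dist = cdist(pts, pts)
    if k == 2:
        return dist[0, 1]
    best = np.inf
    for seq in itertools.product(range(k), repeat=k - 2):
        w = sum(dist[u, v] for u, v in _prufer_to_edges(seq, k))
        best = min(best, w)
    return best


def literal_odds_product(path):
    """Evaluate the per-step odds from the binary codes and branch sizes:
    |L|^(1-d) |R|^d / (|L|^d |R|^(1-d)), multiplied along the path."""
    po = 1.0
    for d, (l, r) in zip(path.codes, path.branch_sizes):
        po *= (l ** (1 - d) * r**d) / (l**d * r ** (1 - d))
    return po


def _naive_average_linkage(X):
    """O(n^3) agglomeration with average linkage (Lance-Williams)."""
    X = np.asarray(X, float)
    n = len(X)
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    active = {i: ([i], i) for i in range(n)}  # cluster -> (members, node id)
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        keys = sorted(active)
        best = (np.inf, None)
        for a, b in itertools.combinations(keys, 2):
            if D[a, b] < best[0]:
                best = (D[a, b], (a, b))
        d, (a, b) = best
        merges.append((active[a][1], active[b][1], d, sizes[a] + sizes[b]))
        for c in keys:
            if c in (a, b):
                continue
            D[a, c] = D[c, a] = (sizes[a] * D[a, c] + sizes[b] * D[b, c]) / (sizes[a] + sizes[b])
        active[a] = (active[a][0] + active[b][0], next_id)
        sizes[a] += sizes.pop(b)
        del active[b]
        D[b, :] = D[:, b] = np.inf
        next_id += 1
    return merges


# ------------------------------------------------------------------- MST
def test_mst_collinear_points():
    mst = build_mst([(0, 0), (1, 0), (3, 0)])
    assert mst.total_weight == pytest.approx(3.0)
    assert {tuple(e) for e in mst.edges} == {(0, 1), (1, 2)}


def test_mst_two_points():
    mst = build_mst([(0, 0), (3, 4)])
    assert len(mst.edges) == 1 and mst.total_weight == pytest.approx(5.0)


def test_mst_matches_exhaustive_minimum(rng):
    for k in (3, 4, 5, 6):
        for _ in range(5):
            pts = rng.uniform(0, 10, size=(k, 2))
            mst = build_mst(pts)
            assert len(mst.edges) == k - 1
            assert mst.total_weight == pytest.approx(mst_weight_exhaustive(pts))


def test_mst_requires_two_points():
    with pytest.raises(ValueError):
        build_mst([(0, 0)])


def test_null_ensemble_reproducible_and_shaped():
    e1 = null_mst_ensemble((20, 20), 25, 10, seed=5)
    e2 = null_mst_ensemble((20, 20), 25, 10, seed=5)
    assert all(len(m.edges) == 24 for m in e1)
    assert all(np.array_equal(a.points, b.points) for a, b in zip(e1, e2))
    with pytest.raises(ValueError):
        null_mst_ensemble((2, 2), 5, 1, seed=0)


def test_null_ensemble_cell_inclusion_uniform():
    """Per-cell inclusion frequency over many draws matches k/N."""
    rows = cols = 10
    k, B = 10, 2000
    ensemble = null_mst_ensemble((rows, cols), k, B, seed=99)
    freq = np.zeros((rows, cols))
    for m in ensemble:
        for r, c in m.points.astype(int):
            freq[r, c] += 1
    freq /= B
    p = k / (rows * cols)
    sigma = np.sqrt(p * (1 - p) / B)
    assert np.all(np.abs(freq - p) < 4.5 * sigma)
    assert abs(freq.mean() - p) < 3 * sigma / np.sqrt(rows * cols)


# ------------------------------------------------------------- histograms
def test_histogram_rows_sum_to_edge_count():
    obs = build_mst([(0, 0), (1, 0), (3, 0), (3, 2)])
    nulls = null_mst_ensemble((5, 5), 4, 7, seed=3)
    hm = histogram_matrix(obs, nulls)
    assert hm.counts.shape == (8, 10)
    assert np.all(hm.counts.sum(axis=1) == 3)


def test_histogram_hand_computed_toy():
    class Fake:
        def __init__(self, w):
            self.weights = np.asarray(w, float)

    hm = histogram_matrix(Fake([1, 1, 2]), [Fake([2, 2, 3])], n_bins=10)
    # pooled range [1, 3], width 0.2: 1->bin0, 2->bin5, 3->bin9 (closed)
    assert np.array_equal(hm.counts[0], [2, 0, 0, 0, 0, 1, 0, 0, 0, 0])
    assert np.array_equal(hm.counts[1], [0, 0, 0, 0, 0, 2, 0, 0, 0, 1])


def test_histogram_identical_rows_and_degenerate_bins():
    class Fake:
        def __init__(self, w):
            self.weights = np.asarray(w, float)

    hm = histogram_matrix(Fake([1, 2]), [Fake([1, 2])])
    assert np.array_equal(hm.counts[0], hm.counts[1])
    with pytest.warns(UserWarning, match="degenerate"):
        hm = histogram_matrix(Fake([1, 1]), [Fake([1, 1])])
    assert hm.counts.shape == (2, 1)


# ---------------------------------------------------------------- HC tree
def test_hc_tree_shape_and_outlier_isolation():
    rows = np.array([[5, 0, 0]] * 3 + [[0, 0, 9]], dtype=float)
    Z = hc_tree_rows(rows)
    assert Z.shape == (3, 4)
    path = leaf_path_odds(Z, 3)
    assert path.branch_sizes[0] in ((1, 3), (3, 1))
    assert path.po == pytest.approx(1 / 3)


def test_hc_tree_merge_order_matches_naive_agglomeration(rng):
    for _ in range(10):
        X = rng.normal(size=(6, 4))
        Z = hc_tree_rows(X, method="average")
        naive = _naive_average_linkage(X)
        assert np.allclose(Z[:, 2], [m[2] for m in naive])
        assert np.array_equal(Z[:, 3].astype(int), [m[3] for m in naive])


def test_leaf_path_odds_examples():
    # 4 leaves, perfectly balanced: (2|2) then (1|1) -> PO = 1
    Z = np.array([[0, 1, 1.0, 2], [2, 3, 1.0, 2], [4, 5, 5.0, 4]], dtype=float)
    for leaf in range(4):
        assert leaf_path_odds(Z, leaf).po == pytest.approx(1.0)
    # 3 leaves, observed in the 2-branch: (2|1) then (1|1) -> PO = 2
    Z3 = np.array([[0, 1, 1.0, 2], [2, 3, 4.0, 3]], dtype=float)
    assert leaf_path_odds(Z3, 0).po == pytest.approx(2.0)
    # ... and the singleton leaf: PO = 1/2
    assert leaf_path_odds(Z3, 2).po == pytest.approx(0.5)
    with pytest.raises(ValueError):
        leaf_path_odds(Z3, 7)


def test_literal_odds_equal_telescoped_on_random_trees(rng):
    """The coded per-step odds product telescopes to the product of
    containing/other branch sizes, on arbitrary linkage trees."""
    for _ in range(50):
        n = int(rng.integers(3, 40))
        Z = sch.linkage(rng.normal(size=(n, 3)), method="ward")
        po = all_leaf_odds(Z)
        for leaf in range(0, n, max(1, n // 5)):
            path = leaf_path_odds(Z, leaf)
            assert path.po == pytest.approx(po[leaf], rel=1e-12)
            assert literal_odds_product(path) == pytest.approx(path.po, rel=1e-12)
            # descent ends at the singleton observed leaf
            assert path.branch_sizes[-1][path.codes[-1]] == 1


def test_tree_p_value_arithmetic():
    assert tree_p_value(0.5, [1, 2, 3]) == 0.0
    assert tree_p_value(10, [1, 2, 3]) == 1.0
    ensemble = np.ones(500); ensemble[0] = 1e-6
    assert tree_p_value(0.5, ensemble) == pytest.approx(0.002)
    # ties count as not-less
    assert tree_p_value(1.0, np.ones(10)) == 0.0


# --------------------------------------------------------------- ROC/AUC
def test_auc_identical_distributions_is_half(rng):
    w = rng.exponential(1.0, 37)
    assert roc_auc_ensemble(w, [w.copy()])[0] == 0.5


def test_auc_orientation_extremes():
    assert roc_auc_ensemble([1, 2], [[5, 6]])[0] == 0.0  # observed smaller
    assert roc_auc_ensemble([5, 6], [[1, 2]])[0] == 1.0


def test_auc_matches_trapezoidal_roc(rng):
    obs = rng.normal(0, 1, 200)
    null = rng.normal(0.3, 1.2, 150)
    auc = roc_auc_ensemble(obs, [null])[0]
    # empirical ROC sweep: P(obs > t) vs P(null > t)
    ts = np.unique(np.concatenate([obs, null]))
    tpr = [(obs > t).mean() for t in ts] + [0.0]
    fpr = [(null > t).mean() for t in ts] + [0.0]
    trap = -np.trapezoid(np.array([1.0] + tpr), np.array([1.0] + fpr))
    assert auc == pytest.approx(trap, abs=1e-9)


# ---------------------------------------------------------------- harness
def test_run_test_reproducible(clustered_field):
    r1 = run_uniformness_test(clustered_field.categories, "R1", B=50, seed=8)
    r2 = run_uniformness_test(clustered_field.categories, "R1", B=50, seed=8)
    assert r1.p_value == r2.p_value and r1.po_obs == r2.po_obs
    assert np.array_equal(r1.po_null, r2.po_null)
    assert r1.to_json() == r2.to_json()


def test_run_test_requires_enough_cells():
    cats = np.full((5, 5), 4); cats[0, 0] = 1
    with pytest.raises(ValueError, match="too few dense rectangles"):
        run_uniformness_test(cats, "R1", B=10, seed=0)


def test_estimator_api(clustered_field):
    est = UniformnessTest(level="R1", B=50, random_state=8)
    est.fit(clustered_field.categories)
    assert 0 <= est.p_value_ <= 1
    assert est.get_params()["B"] == 50
    report = est.report_
    assert report.k == (clustered_field.categories == 1).sum()
    assert len(report.auc) == 50
    summary = report.auc_summary()
    assert summary["min"] <= summary["median"] <= summary["max"]
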