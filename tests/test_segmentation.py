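"""Focal-area training, square validation, recovery and mask fusion."""

import numpy as np
import pytest

from dotgrid.segmentation import (
    BACKGROUND,
    PURPLE,
    YELLOW,
    ColorCardSegmenter,
    FocalAreaSpec,
    ReferenceCubeSet,
    build_reference_cubes,
    classify_by_nearest_cube,
    classify_row,
    fuse_labels,
    validate_squares,
)

YELLOW_RGB = np.array([225, 215, 70], dtype=float)
PURPLE_RGB = np.array([110, 60, 150], dtype=float)


def _two_cluster_row(rng, n_purple=60, n_yellow=240, sigma=4.0):
    purple = np.clip(rng.normal(PURPLE_RGB, sigma, (n_purple, 3)), 0, 255)
    yellow = np.clip(rng.normal(YELLOW_RGB, sigma, (n_yellow, 3)), 0, 255)
    pixels = np.vstack([purple, yellow]).round()
    truth = np.zeros(len(pixels), dtype=bool)
    truth[:n_purple] = True
    return pixels, truth


def test_classify_row_recovers_planted_clusters(rng):
    """Two well-separated planted color clusters: the smaller branch is
    labelled purple and recovers >= 99% of the planted labels."""
    pixels, truth = _two_cluster_row(rng)
    labels = classify_row(pixels, 10)
    assert (labels == truth).mean() >= 0.99


def test_classify_row_uniform_row_is_purple_free(rng):
    pixels = np.clip(rng.normal(YELLOW_RGB, 3.0, (300, 3)), 0, 255).round()
    assert not classify_row(pixels, 10).any()


def test_classify_row_single_cube_all_yellow():
    pixels = np.tile([100, 100, 100], (50, 1))
    assert not classify_row(pixels, 10).any()


def test_classify_row_symmetric_tie_rule():
    """With equal branch sizes, the branch farther from the modal cube is
    purple — here the modal cube sits with the yellow-like cluster."""
    near = [(40 + 10 * i, 40, 40) for i in range(5)]  # 5 cubes near the modal mass
    far = [(200 + 10 * i, 200, 200) for i in range(5)]  # 5 cubes far away
    pixels = np.array(near * 3 + far)  # modal cube lies in the near group
    labels = classify_row(pixels, 10)
    assert not labels[: 3 * len(near)].any()
    assert labels[3 * len(near):].all()


def test_classify_row_min_pixels():
    with pytest.raises(ValueError):
        classify_row(np.array([[1, 2, 3]]), 10)


def test_validate_squares_cleans_confusable_square(rng):
    """A square whose 'purple' pixels are colorimetrically yellow is flagged
    and cleaned; a clean square is untouched."""
    good, truth_good = _two_cluster_row(rng)
    bad = np.clip(rng.normal(YELLOW_RGB, 4.0, (300, 3)), 0, 255).round()
    bad_purple = np.zeros(300, dtype=bool)
    bad_purple[:60] = True  # mislabeled noise: identical color distribution
    pixels = np.vstack([good, bad])
    purple = np.concatenate([truth_good, bad_purple])
    squares = np.concatenate([np.zeros(len(good), int), np.ones(300, int)])
    cleaned, flagged = validate_squares(pixels, purple, squares)
    assert flagged == [1]
    assert not cleaned[squares == 1].any()
    assert np.array_equal(cleaned[squares == 0], truth_good)


def test_validate_squares_flags_implausibly_purple_square(rng):
    pixels, truth = _two_cluster_row(rng)
    all_purple = np.clip(rng.normal(YELLOW_RGB, 4.0, (100, 3)), 0, 255).round()
    pixels = np.vstack([pixels, all_purple])
    purple = np.concatenate([truth, np.ones(100, bool)])
    squares = np.concatenate([np.zeros(len(truth), int), np.full(100, 7)])
    cleaned, flagged = validate_squares(pixels, purple, squares)
    assert flagged == [7]
    assert not cleaned[squares == 7].any()


def test_validate_squares_identity_when_clean(rng):
    pixels, truth = _two_cluster_row(rng)
    squares = np.arange(len(pixels)) % 5
    cleaned, flagged = validate_squares(pixels, truth, squares)
    assert flagged == []
    assert np.array_equal(cleaned, truth)
    assert cleaned.sum() <= truth.sum()  # never increases purple


def test_build_reference_cubes_majority_and_disjoint():
    pixels = np.array([[5, 5, 5]] * 8 + [[250, 250, 250]] * 5)
    purple = np.array([True] * 3 + [False] * 5 + [True] * 5)
    refs = build_reference_cubes(pixels, purple, 10)
    # cube (0,0,0): 3 purple vs 5 yellow -> yellow wins; cube (25,..): all purple
    assert len(refs.yellow_centers) == 1 and len(refs.purple_centers) == 1
    assert np.allclose(refs.yellow_centers[0], [5, 5, 5])
    assert np.allclose(refs.purple_centers[0], [255, 255, 255])


def test_build_reference_cubes_requires_purple():
    pixels = np.tile([10, 10, 10], (20, 1))
    with pytest.raises(ValueError, match="focal area"):
        build_reference_cubes(pixels, np.zeros(20, bool), 10)


def test_nearest_cube_classification_and_tie(rng):
    refs = ReferenceCubeSet(
        n=1,
        purple_centers=np.array([[100.0, 50.0, 140.0]]),
        yellow_centers=np.array([[220.0, 210.0, 60.0]]),
    )
    assert classify_by_nearest_cube([[100, 50, 140]], refs)[0]
    midpoint = (refs.purple_centers[0] + refs.yellow_centers[0]) / 2
    assert not classify_by_nearest_cube([midpoint], refs)[0]  # tie -> yellow
    # held-out purple pixels with channel noise sigma=3 stay purple >= 95%
    noisy = np.clip(rng.normal(refs.purple_centers[0], 3.0, (2000, 3)), 0, 255)
    assert classify_by_nearest_cube(noisy, refs).mean() >= 0.95
    # idempotent / deterministic
    assert np.array_equal(classify_by_nearest_cube(noisy, refs),
                          classify_by_nearest_cube(noisy, refs))


def test_fuse_labels_union_and_errors():
    a = np.full((4, 4), YELLOW); a[0, 0] = PURPLE; a[3, 3] = BACKGROUND
    b = np.full((4, 4), YELLOW); b[1, 1] = PURPLE; b[3, 3] = BACKGROUND
    fused = fuse_labels(a, b)
    assert fused[0, 0] == PURPLE and fused[1, 1] == PURPLE
    assert fused[3, 3] == BACKGROUND
    # superset of each input's purple set
    for m in (a, b):
        assert np.all(fused[m == PURPLE] == PURPLE)
    assert np.array_equal(fuse_labels(a, a), a)
    with pytest.raises(ValueError):
        fuse_labels(a, np.full((3, 3), YELLOW))


def test_focal_area_spec_validation():
    with pytest.raises(ValueError):
        FocalAreaSpec((10, 10, 10, 20))
    spec = FocalAreaSpec((0, 0, 100, 39), n_rows=39)
    edges = spec.row_edges()
    assert len(edges) == 40 and edges[0] == 0 and edges[-1] == 39


def test_segmenter_end_to_end_determinism(small_card):
    img, truth, _ = small_card
    m1 = ColorCardSegmenter().fit_predict(img)
    m2 = ColorCardSegmenter().fit_predict(img)
    assert np.array_equal(m1, m2)
    assert (m1 == truth).mean() >= 0.99


def test_segmenter_background_outside_paper_region(small_card):
    img, _, _ = small_card
    seg = ColorCardSegmenter(paper_region=(20, 20, 380, 240))
    mask = seg.fit_predict(img)
    assert np.all(mask[:20, :] == BACKGROUND)
    assert np.all(mask[20:240, 20:380] != BACKGROUND)


def test_segmenter_sklearn_params_roundtrip():
    seg = ColorCardSegmenter(rgb_scale=2)
    params = seg.get_params()
    assert params["rgb_scale"] == 2
    seg.set_params(hsv_scale=5)
    assert seg.hsv_scale == 5
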