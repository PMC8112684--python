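"""Exhaustive target-color pixel identification on spray test cards.

The card carries two color families — purple droplet stains on a yellow
background — but heterogeneous shading makes any fixed color threshold
fail.  The approach here is data driven:

1.  A low-shade *focal area* inside the card is split into horizontal rows;
    each row's occupied color cubes are bipartitioned by agglomerative
    clustering, the smaller branch being declared purple.
2.  Each row is further split into squares and validated: squares whose
    purple/yellow populations are not separable (low AUC on the global
    discriminant axis) or that are implausibly purple are cleaned back to
    yellow.
3.  The whole card is then recovered by nearest-reference-cube
    classification: every cube ever occupied by an identified purple
    (yellow) focal pixel contributes its center, and outside pixels take
    the class of the Euclidean-nearest center.

The procedure runs twice — on RGB at a fine cube scale and on HSV at a
coarse one — and the two masks are fused by taking the union of their
purple sets, since the two color models fail under shading in different
places.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .colorspace import axis_cubes, build_cube_grid, cube_centers, quantize, rgb_to_hsv_255

__all__ = [
    "BACKGROUND",
    "YELLOW",
    "PURPLE",
    "FocalAreaSpec",
    "ReferenceCubeSet",
    "ColorCardSegmenter",
    "classify_row",
    "validate_squares",
    "build_reference_cubes",
    "classify_by_nearest_cube",
    "fuse_labels",
    "segment_paper",
]

# Label values used throughout; masks are (H, W) integer arrays.
BACKGROUND = 0
YELLOW = 1
PURPLE = 2


@dataclass(frozen=True)
class FocalAreaSpec:
    """Low-shade training rectangle, split into rows of squares.

    ``rect`` is a half-open pixel rectangle (x0, y0, x1, y1), 0-based,
    x rightward, y downward.
    """

    rect: tuple[int, int, int, int]
    n_rows: int = 39
    squares_per_row: int = 10

    def __post_init__(self):
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate focal rectangle {self.rect}")
        if self.n_rows < 1 or self.squares_per_row < 1:
            raise ValueError("n_rows and squares_per_row must be >= 1")

    def row_edges(self) -> np.ndarray:
        _, y0, _, y1 = self.rect
        return np.linspace(y0, y1, self.n_rows + 1).round().astype(int)

    def square_edges(self) -> np.ndarray:
        x0, _, x1, _ = self.rect
        return np.linspace(x0, x1, self.squares_per_row + 1).round().astype(int)


@dataclass(frozen=True)
class ReferenceCubeSet:
    """Cube centers learned from the focal area, per class."""

    n: int
    purple_centers: np.ndarray
    yellow_centers: np.ndarray

    def __post_init__(self):
        if len(self.purple_centers) == 0 or len(self.yellow_centers) == 0:
            raise ValueError("reference cube sets must both be non-empty")


def classify_row(
    row_pixels,
    n: int,
    *,
    linkage: str = "ward",
    sep_threshold: float = 30.0,
    min_pixels: int = 2,
) -> np.ndarray:
    """Label one focal-area row's pixels purple/yellow by HC bipartition.

    Builds the row's occupied color cubes at scale ``n``, clusters their
    representatives agglomeratively, cuts at the root bifurcation and labels
    the pixels of the smaller branch purple.  Returns a boolean array
    (True = purple).

    Fallbacks: a single occupied cube, or a root split whose branch mean
    representatives are closer than ``sep_threshold`` channel units, declare
    the row purple-free.  An exact branch-size tie is resolved by labelling
    purple the branch whose mean representative lies farther from the row's
    modal (most occupied) cube.
    """
    arr = np.asarray(row_pixels)
    if len(arr) < min_pixels:
        raise ValueError(f"row has {len(arr)} pixels, need at least {min_pixels}")
    grid = build_cube_grid(arr, n)
    if grid.n_occupied < 2:
        return np.zeros(len(arr), dtype=bool)
    Z = sch.linkage(grid.representatives, method=linkage)
    branch = sch.fcluster(Z, 2, criterion="maxclust")  # values in {1, 2}
    if len(np.unique(branch)) < 2:  # degenerate (all-identical representatives)
        return np.zeros(len(arr), dtype=bool)
    mean1 = grid.representatives[branch == 1].mean(axis=0)
    mean2 = grid.representatives[branch == 2].mean(axis=0)
    if np.linalg.norm(mean1 - mean2) < sep_threshold:
        return np.zeros(len(arr), dtype=bool)
    size1 = int((branch == 1).sum())
    size2 = int((branch == 2).sum())
    if size1 != size2:
        purple_branch = 1 if size1 < size2 else 2
    else:
        modal = grid.representatives[int(np.argmax(grid.counts))]
        d1 = np.linalg.norm(mean1 - modal)
        d2 = np.linalg.norm(mean2 - modal)
        purple_branch = 1 if d1 > d2 else 2
    return branch[grid.inverse] == purple_branch


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC = P(pos > neg) with ties counted by halves."""
    n_pos, n_neg = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def validate_squares(
    pixels,
    purple: np.ndarray,
    square_ids: np.ndarray,
    *,
    auc_threshold: float = 0.95,
    max_purple_fraction: float = 0.8,
) -> tuple[np.ndarray, list[int]]:
    """Square-level separability check; cleans confusable squares to yellow.

    For each square, the purple and yellow pixel populations are projected
    on the focal area's global purple-vs-yellow discriminant axis and their
    separability scored as a rank AUC.  Squares with AUC below
    ``auc_threshold``, or with a purple fraction above
    ``max_purple_fraction``, are flagged and reassigned wholly yellow.
    Squares with only one class present pass the AUC check (nothing to
    confuse) but remain subject to the purple-fraction rule.

    Returns the cleaned boolean purple array and the sorted flagged square
    ids.  Never increases the purple-pixel count.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    purple = np.asarray(purple, dtype=bool).copy()
    square_ids = np.asarray(square_ids)
    if not purple.any():
        return purple, []
    axis = arr[purple].mean(axis=0) - arr[~purple].mean(axis=0)
    proj = arr @ axis
    flagged: list[int] = []
    for sq in np.unique(square_ids):
        in_sq = square_ids == sq
        n_total = int(in_sq.sum())
        if n_total == 0:
            continue
        p_mask = purple & in_sq
        n_purple = int(p_mask.sum())
        if n_purple == 0:
            continue
        if n_purple / n_total > max_purple_fraction:
            flagged.append(int(sq))
            continue
        auc = _rank_auc(proj[p_mask], proj[in_sq & ~purple])
        if auc < auc_threshold:
            flagged.append(int(sq))
    for sq in flagged:
        purple[square_ids == sq] = False
    return purple, sorted(flagged)


def build_reference_cubes(pixels, purple: np.ndarray, n: int) -> ReferenceCubeSet:
    """Collect per-class cube centers from labelled focal pixels.

    Every scale-``n`` cube occupied by at least one purple pixel contributes
    its geometric center to the purple list, likewise for yellow; a cube
    occupied by both classes goes to the class with more pixels in it (an
    exact tie counts as yellow).  Raises if no purple cube survives,
    advising focal-area relocation.
    """
    arr = np.asarray(pixels)
    purple = np.asarray(purple, dtype=bool)
    grid = build_cube_grid(arr, n)
    purple_counts = np.bincount(grid.inverse, weights=purple.astype(float), minlength=grid.n_occupied)
    is_purple_cube = purple_counts > grid.counts / 2.0
    centers = grid.centers()
    if not is_purple_cube.any():
        raise ValueError(
            "no purple pixels identified in the focal area; relocate the focal area"
        )
    if is_purple_cube.all():
        raise ValueError(
            "no yellow pixels identified in the focal area; relocate the focal area"
        )
    return ReferenceCubeSet(
        n=int(n),
        purple_centers=centers[is_purple_cube],
        yellow_centers=centers[~is_purple_cube],
    )


def classify_by_nearest_cube(pixels, refs: ReferenceCubeSet) -> np.ndarray:
    """Label pixels by the class of their Euclidean-nearest reference center.

    An exact distance tie goes to yellow (the conservative choice: cleaning
    errs toward the background class).  Returns a boolean purple array.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if len(arr) == 0:
        return np.zeros(0, dtype=bool)
    d_purple, _ = cKDTree(refs.purple_centers).query(arr, workers=-1)
    d_yellow, _ = cKDTree(refs.yellow_centers).query(arr, workers=-1)
    return d_purple < d_yellow


def fuse_labels(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Fuse two label masks: purple wherever either is purple.

    The two masks must share geometry and background support.
    """
    mask_a = np.asarray(mask_a)
    mask_b = np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask geometry mismatch: {mask_a.shape} vs {mask_b.shape}")
    if not np.array_equal(mask_a == BACKGROUND, mask_b == BACKGROUND):
        raise ValueError("masks disagree on the background region")
    fused = mask_a.copy()
    fused[(mask_a == PURPLE) | (mask_b == PURPLE)] = PURPLE
    return fused


def _default_focal(paper: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    # Centered rectangle covering ~60% of the paper area (each dimension
    # scaled by sqrt(0.6)).
    x0, y0, x1, y1 = paper
    w, h = x1 - x0, y1 - y0
    f = math.sqrt(0.6)
    fw, fh = max(1, round(w * f)), max(1, round(h * f))
    fx0 = x0 + (w - fw) // 2
    fy0 = y0 + (h - fh) // 2
    return (fx0, fy0, fx0 + fw, fy0 + fh)


class ColorCardSegmenter(BaseEstimator):
    """Two-branch (RGB + HSV) color-dot segmenter for spray test cards.

    Parameters
    ----------
    rgb_scale, hsv_scale : cube scales used for reference-cube recovery in
        each branch.  The RGB branch uses unit cubes to sharpen within-cube
        color uniformness; the HSV branch keeps the coarse scale.
    train_scale : cube scale for the focal-area row-wise HC bipartition.
    n_rows, squares_per_row : focal-area layout.
    linkage : agglomerative linkage for the row trees.
    sep_threshold : root-split separation (channel units) below which a row
        is declared purple-free.
    auc_threshold, max_purple_fraction : square-validation parameters.
    paper_region, focal_area : half-open pixel rectangles (x0, y0, x1, y1);
        ``None`` auto-defaults to the whole image resp. a centered
        rectangle covering 60% of the paper area.

    Fitted attributes
    -----------------
    refs_ : dict branch -> ReferenceCubeSet (or None for a purple-free branch)
    focal_purple_ : dict branch -> boolean purple labels over focal pixels
    flagged_squares_ : dict branch -> cleaned square ids
    paper_region_, focal_area_ : resolved rectangles
    image_ : the fitted image (predict() with no argument segments it)
    """

    _BRANCHES = ("rgb", "hsv")

    def __init__(
        self,
        rgb_scale: int = 1,
        hsv_scale: int = 10,
        train_scale: int = 10,
        n_rows: int = 39,
        squares_per_row: int = 10,
        linkage: str = "ward",
        sep_threshold: float = 30.0,
        auc_threshold: float = 0.95,
        max_purple_fraction: float = 0.8,
        paper_region: tuple[int, int, int, int] | None = None,
        focal_area: tuple[int, int, int, int] | None = None,
    ):
        self.rgb_scale = rgb_scale
        self.hsv_scale = hsv_scale
        self.train_scale = train_scale
        self.n_rows = n_rows
        self.squares_per_row = squares_per_row
        self.linkage = linkage
        self.sep_threshold = sep_threshold
        self.auc_threshold = auc_threshold
        self.max_purple_fraction = max_purple_fraction
        self.paper_region = paper_region
        self.focal_area = focal_area

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _check_image(X) -> np.ndarray:
        img = np.asarray(X)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("image channels must lie in [0, 255]")
        return img.astype(np.int64)

    def _branch_values(self, img: np.ndarray, branch: str) -> np.ndarray:
        flat = img.reshape(-1, 3)
        if branch == "rgb":
            return flat
        return rgb_to_hsv_255(flat)

    def _branch_scale(self, branch: str) -> int:
        return self.rgb_scale if branch == "rgb" else self.hsv_scale

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        """Train focal-area labels and per-branch reference cube sets."""
        img = self._check_image(X)
        h, w = img.shape[:2]
        paper = tuple(self.paper_region) if self.paper_region is not None else (0, 0, w, h)
        px0, py0, px1, py1 = paper
        if not (0 <= px0 < px1 <= w and 0 <= py0 < py1 <= h):
            raise ValueError(f"paper region {paper} outside image {w}x{h}")
        focal_rect = tuple(self.focal_area) if self.focal_area is not None else _default_focal(paper)
        focal = FocalAreaSpec(focal_rect, self.n_rows, self.squares_per_row)
        fx0, fy0, fx1, fy1 = focal.rect
        if not (px0 <= fx0 < fx1 <= px1 and py0 <= fy0 < fy1 <= py1):
            raise ValueError(f"focal area {focal.rect} outside paper region {paper}")

        yy, xx = np.mgrid[0:h, 0:w]
        in_focal = (xx >= fx0) & (xx < fx1) & (yy >= fy0) & (yy < fy1)
        focal_flat = in_focal.ravel()
        fxx, fyy = xx.ravel()[focal_flat], yy.ravel()[focal_flat]

        row_edges = focal.row_edges()
        sq_edges = focal.square_edges()
        row_of = np.clip(np.searchsorted(row_edges, fyy, side="right") - 1, 0, focal.n_rows - 1)
        sq_of = np.clip(np.searchsorted(sq_edges, fxx, side="right") - 1, 0, focal.squares_per_row - 1)
        square_ids = row_of * focal.squares_per_row + sq_of

        self.refs_ = {}
        self.focal_purple_ = {}
        self.flagged_squares_ = {}
        for branch in self._BRANCHES:
            vals = self._branch_values(img, branch)[focal_flat]
            purple = np.zeros(len(vals), dtype=bool)
            for r in range(focal.n_rows):
                sel = row_of == r
                if sel.sum() < 2:
                    continue
                purple[sel] = classify_row(
                    vals[sel],
                    self.train_scale,
                    linkage=self.linkage,
                    sep_threshold=self.sep_threshold,
                )
            purple, flagged = validate_squares(
                vals,
                purple,
                square_ids,
                auc_threshold=self.auc_threshold,
                max_purple_fraction=self.max_purple_fraction,
            )
            self.focal_purple_[branch] = purple
            self.flagged_squares_[branch] = flagged
            try:
                self.refs_[branch] = build_reference_cubes(vals, purple, self._branch_scale(branch))
            except ValueError:
                warnings.warn(
                    f"{branch} branch found no purple in the focal area; "
                    "branch contributes an all-yellow mask",
                    stacklevel=2,
                )
                self.refs_[branch] = None

        self.paper_region_ = paper
        self.focal_area_ = focal
        self.image_ = img
        self._in_focal = in_focal
        return self

    def _branch_mask(self, img: np.ndarray, branch: str, same_image: bool) -> np.ndarray:
        h, w = img.shape[:2]
        px0, py0, px1, py1 = self.paper_region_
        mask = np.full((h, w), BACKGROUND, dtype=np.uint8)
        yy, xx = np.mgrid[0:h, 0:w]
        in_paper = (xx >= px0) & (xx < px1) & (yy >= py0) & (yy < py1)
        mask[in_paper] = YELLOW
        refs = self.refs_[branch]
        if refs is None:
            return mask
        vals = self._branch_values(img, branch)
        if same_image:
            outside = in_paper & ~self._in_focal
            purple_out = classify_by_nearest_cube(vals[outside.ravel()], refs)
            plane = np.zeros((h, w), dtype=bool)
            plane[outside] = purple_out
            plane[self._in_focal] = self.focal_purple_[branch]
        else:
            purple = classify_by_nearest_cube(vals[in_paper.ravel()], refs)
            plane = np.zeros((h, w), dtype=bool)
            plane[in_paper] = purple
        mask[plane & in_paper] = PURPLE
        return mask

    def predict(self, X=None) -> np.ndarray:
        """Segment an image into BACKGROUND / YELLOW / PURPLE labels.

        With no argument, segments the fitted image (trained focal labels
        are used inside the focal area, nearest-cube recovery outside).
        With a new image of the same geometry, all paper pixels are
        classified by the learned reference cubes.
        """
        if not hasattr(self, "refs_"):
            raise ValueError("segmenter is not fitted")
        if X is None:
            img, same = self.image_, True
        else:
            img = self._check_image(X)
            same = img.shape == self.image_.shape and np.array_equal(img, self.image_)
        masks = [self._branch_mask(img, b, same) for b in self._BRANCHES]
        return fuse_labels(masks[0], masks[1])

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict()


def segment_paper(image, **params) -> np.ndarray:
    """One-shot pipeline: fit a :class:`ColorCardSegmenter` and segment."""
    return ColorCardSegmenter(**params).fit_predict(image)
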