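"""Connected color-dots: extraction, size measures, classes and size laws.

A color-dot is a maximal connected set of purple pixels on the 2D lattice.
Each dot is sized two ways: a counting measure (number of pixels) and a
continuous measure (radius of the smallest circle enclosing the pixel
centers).  A well-tuned sprayer should ideally yield a Poisson law for the
counts and an Exponential law for the radii; the MLEs and a one-sample
Kolmogorov-Smirnov test quantify the departure.

Pixels are modeled as lattice-center points, so a singleton dot has radius
0 and two edge-adjacent pixels have radius 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kstest
from skimage.measure import label as _cc_label

from .segmentation import PURPLE

__all__ = [
    "Dot",
    "DotCollection",
    "SizeFit",
    "extract_dots",
    "minimum_enclosing_circle",
    "smallest_enclosing_radius",
    "classify_dot_sizes",
    "fit_count_poisson",
    "fit_size_exponential",
    "ks_exponential_test",
]

SIZE_CLASSES = ("small", "medium", "large")

_EPS = 1e-9


@dataclass
class Dot:
    """One connected purple component.

    ``coords`` holds (row, col) pixel coordinates; centroid is (x, y) with
    x rightward and y downward.
    """

    coords: np.ndarray
    radius: float
    size_class: str | None = None

    @property
    def pixel_count(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.coords.mean(axis=0)
        return (float(c), float(r))


@dataclass
class DotCollection:
    dots: list[Dot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.dots)

    def __iter__(self):
        return iter(self.dots)

    def __getitem__(self, i) -> Dot:
        return self.dots[i]

    @property
    def pixel_counts(self) -> np.ndarray:
        return np.array([d.pixel_count for d in self.dots], dtype=int)

    @property
    def radii(self) -> np.ndarray:
        return np.array([d.radius for d in self.dots], dtype=float)

    @property
    def size_classes(self) -> list[str | None]:
        return [d.size_class for d in self.dots]

    def class_mean_radii(self) -> dict[str, float]:
        """Mean radius per size class (the weights used downstream)."""
        out = {}
        radii, classes = self.radii, self.size_classes
        for cls in SIZE_CLASSES:
            sel = [r for r, c in zip(radii, classes) if c == cls]
            if sel:
                out[cls] = float(np.mean(sel))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.dots):
            x, y = d.centroid
            rows.append(
                dict(dot_id=i, centroid_x=x, centroid_y=y,
                     pixel_count=d.pixel_count, radius=d.radius,
                     size_class=d.size_class)
            )
        return pd.DataFrame(
            rows,
            columns=["dot_id", "centroid_x", "centroid_y", "pixel_count", "radius", "size_class"],
        )


def extract_dots(mask: np.ndarray, connectivity: int = 8) -> DotCollection:
    """Extract maximal connected purple components from a label mask.

    ``connectivity`` is 4 (edge neighbors) or 8 (edge + diagonal, default).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask)
    binary = mask == PURPLE
    lab = _cc_label(binary, connectivity=2 if connectivity == 8 else 1)
    dots = []
    n = lab.max()
    if n:
        order = np.argsort(lab.ravel(), kind="stable")
        flat = lab.ravel()[order]
        coords_all = np.column_stack(np.unravel_index(order, lab.shape))
        starts = np.searchsorted(flat, np.arange(1, n + 2))
        for i in range(n):
            coords = coords_all[starts[i]:starts[i + 1]]
            pts = np.column_stack([coords[:, 1], coords[:, 0]]).astype(float)  # (x, y)
            _, radius = minimum_enclosing_circle(pts)
            dots.append(Dot(coords=coords, radius=radius))
    return DotCollection(dots)


def _circumcircle(a, b, c):
    """Center/radius of the circle through three points, or None if collinear."""
    ax, ay = a; bx, by = b; cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - np.asarray(a)))


def minimum_enclosing_circle(points) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing circle of a 2D point set.

    Convex-hull reduction followed by the deterministic incremental
    (Welzl-style) construction on a fixed shuffle of the hull vertices.
    """
    pts = np.unique(np.asarray(points, dtype=np.float64).reshape(-1, 2), axis=0)
    if len(pts) == 0:
        raise ValueError("cannot enclose an empty point set")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) == 2:
        return (pts[0] + pts[1]) / 2.0, float(np.linalg.norm(pts[0] - pts[1]) / 2.0)
    if len(pts) > 8:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            # collinear: diameter endpoints suffice
            t = pts @ (pts.max(axis=0) - pts.min(axis=0))
            pts = pts[[int(np.argmin(t)), int(np.argmax(t))]]
            return (pts[0] + pts[1]) / 2.0, float(np.linalg.norm(pts[0] - pts[1]) / 2.0)
    # fixed shuffle for expected-linear behavior, deterministic output
    pts = pts[np.random.default_rng(0).permutation(len(pts))]

    def two(a, b):
        return (a + b) / 2.0, float(np.linalg.norm(a - b) / 2.0)

    c, r = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - c) <= r + _EPS:
            continue
        c, r = pts[i].copy(), 0.0
        for j in range(i):
            if np.linalg.norm(pts[j] - c) <= r + _EPS:
                continue
            c, r = two(pts[i], pts[j])
            for k in range(j):
                if np.linalg.norm(pts[k] - c) <= r + _EPS:
                    continue
                cc = _circumcircle(pts[i], pts[j], pts[k])
                if cc is None:
                    # collinear triple: smallest circle is on the farthest pair
                    pairs = [two(pts[i], pts[j]), two(pts[i], pts[k]), two(pts[j], pts[k])]
                    c, r = max(pairs, key=lambda p: p[1])
                else:
                    c, r = cc
    return c, r


def smallest_enclosing_radius(dot_or_points) -> float:
    """Radius of the smallest circle containing a dot's pixel centers."""
    if isinstance(dot_or_points, Dot):
        coords = dot_or_points.coords
        pts = np.column_stack([coords[:, 1], coords[:, 0]])
    else:
        pts = np.asarray(dot_or_points, dtype=float)
    return minimum_enclosing_circle(pts)[1]


def classify_dot_sizes(
    dots: DotCollection,
    method: str = "hc",
    *,
    thresholds: tuple[float, float] | None = None,
    linkage: str = "ward",
) -> DotCollection:
    """Assign each dot a small/medium/large size class (in place).

    ``method='hc'`` (default): 1-D agglomerative 3-cut on the radii, the
    classes ordered by mean radius.  Fewer than 3 distinct radii fall back
    to all-small with a warning.  ``method='thresholds'``: fixed radius
    cut points (t1, t2) — small if r <= t1, large if r > t2, else medium.
    """
    if len(dots) == 0:
        raise ValueError("cannot classify an empty dot collection")
    radii = dots.radii
    if method == "thresholds":
        if thresholds is None:
            raise ValueError("method='thresholds' requires thresholds=(t1, t2)")
        t1, t2 = thresholds
        if not t1 < t2:
            raise ValueError("thresholds must satisfy t1 < t2")
        classes = np.where(radii <= t1, 0, np.where(radii <= t2, 1, 2))
    elif method == "hc":
        if len(np.unique(radii)) < 3:
            warnings.warn("fewer than 3 distinct radii; all dots classed small", stacklevel=2)
            classes = np.zeros(len(radii), dtype=int)
        else:
            Z = sch.linkage(radii[:, None], method=linkage)
            grp = sch.fcluster(Z, 3, criterion="maxclust")
            means = {g: radii[grp == g].mean() for g in np.unique(grp)}
            order = {g: rank for rank, g in enumerate(sorted(means, key=means.get))}
            classes = np.array([order[g] for g in grp])
    else:
        raise ValueError(f"unknown method {method!r}")
    for d, c in zip(dots.dots, classes):
        d.size_class = SIZE_CLASSES[int(c)]
    return dots


@dataclass(frozen=True)
class SizeFit:
    lambda_p: float
    lambda_e: float
    ks_statistic: float
    ks_p: float


def fit_count_poisson(counts) -> float:
    """Poisson intensity MLE for per-dot pixel counts: the sample mean."""
    counts = np.asarray(getattr(counts, "pixel_counts", counts), dtype=float)
    if len(counts) == 0:
        raise ValueError("no dots to fit")
    return float(counts.mean())


def fit_size_exponential(radii) -> float:
    """Exponential rate MLE for dot radii: 1 / mean of the positive radii."""
    radii = np.asarray(getattr(radii, "radii", radii), dtype=float)
    radii = radii[radii > 0]
    if len(radii) == 0:
        raise ValueError("no dots with positive radius")
    return float(1.0 / radii.mean())


def ks_exponential_test(radii, rate: float) -> tuple[float, float]:
    """One-sample KS test of the radii against Exponential(``rate``).

    Uses the plug-in rate directly (no Lilliefors correction), which is
    anti-conservative when the rate was itself estimated from the data.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    radii = np.asarray(radii, dtype=float)
    radii = radii[radii > 0]
    if len(radii) == 0:
        raise ValueError("no positive radii to test")
    res = kstest(radii, "expon", args=(0, 1.0 / rate))
    return float(res.statistic), float(res.pvalue)


def fit_size_laws(dots: DotCollection) -> SizeFit:
    """Convenience: both MLEs plus the KS test at the fitted rate."""
    lam_p = fit_count_poisson(dots)
    lam_e = fit_size_exponential(dots)
    stat, p = ks_exponential_test(dots.radii, lam_e)
    return SizeFit(lambda_p=lam_p, lambda_e=lam_e, ks_statistic=stat, ks_p=p)
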