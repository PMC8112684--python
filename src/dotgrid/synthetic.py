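"""Synthetic fixtures: spray-card images and rectangle-category fields.

The generators make every pipeline stage testable without real imagery.

``generate_card`` emulates a water-sensitive test card: a yellow base with
Gaussian channel noise, purple disks stamped at uniform-random centers
with heterogeneous radii, and optional multiplicative shading fields over
declared regions (emulating local shadows from paper unevenness or
occluding objects).  Ground truth — the label mask and the per-dot table —
is returned alongside the image.

``generate_uniform_field`` and ``generate_clustered_field`` reproduce the
two simulation designs for the spatial test: i.i.d. categories per cell,
versus R1 seed blocks (center + bottom) whose unlabelled neighbors become
R2/R3/R4 with propagation probabilities 0.4 / 0.5 / 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .segmentation import PURPLE, YELLOW

__all__ = [
    "CardParams",
    "CategoryField",
    "generate_card",
    "generate_uniform_field",
    "generate_clustered_field",
    "DEFAULT_R1_BLOCKS",
]

# Default category proportions for the uniform field: R1 expectation of
# 25 cells on a 400-cell grid mirrors the sparsity of a well-behaved card.
DEFAULT_UNIFORM_PROBS = (0.0625, 0.0625, 0.125, 0.75)

# R1 seed blocks (r0, c0, r1, c1), half-open, on the default 20x20 grid:
# one block around the center, one near the bottom.
DEFAULT_R1_BLOCKS = ((8, 8, 11, 11), (16, 5, 19, 10))


@dataclass
class CardParams:
    """Generation parameters for a synthetic spray card.

    ``shading`` is a list of ((x0, y0, x1, y1), multiplier) pairs with
    multipliers in (0, 1]; regions are half-open pixel rectangles.  Either
    ``dots`` fixes the disks explicitly as (x, y, radius) triples or
    ``n_dots`` sets the Poisson intensity of the dot count, with radii
    drawn from a clipped Exponential.
    """

    width: int = 1000
    height: int = 600
    background: tuple[int, int, int] = (225, 215, 70)
    background_sigma: float = 4.0
    dot_color: tuple[int, int, int] = (110, 60, 150)
    dot_sigma: float = 4.0
    n_dots: float = 200.0
    radius_scale: float = 3.0
    radius_min: float = 1.0
    radius_max: float = 15.0
    dots: list[tuple[float, float, float]] | None = None
    shading: list[tuple[tuple[int, int, int, int], float]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        for _, m in self.shading:
            if not 0 < m <= 1:
                raise ValueError(f"shading multiplier {m} outside (0, 1]")
        if self.radius_min <= 0 or self.radius_max < self.radius_min:
            raise ValueError("need 0 < radius_min <= radius_max")


def generate_card(params: CardParams) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a synthetic card; return (image, truth mask, dot table).

    The truth mask labels every pixel YELLOW or PURPLE (the card fills the
    image, so there is no background).  The dot table records each stamped
    disk's center, radius and whether it was clipped at the image border.
    Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    truth = np.full((h, w), YELLOW, dtype=np.uint8)

    if params.dots is not None:
        disks = [(float(x), float(y), float(r)) for x, y, r in params.dots]
    else:
        n = int(rng.poisson(params.n_dots))
        centers = rng.uniform([0, 0], [w, h], size=(n, 2))
        radii = np.clip(rng.exponential(params.radius_scale, size=n),
                        params.radius_min, params.radius_max)
        disks = [(float(x), float(y), float(r)) for (x, y), r in zip(centers, radii)]

    records = []
    for x, y, r in disks:
        if r <= 0:
            raise ValueError("dot radii must be positive")
        x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
        y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
        clipped = x0 < 0 or y0 < 0 or x1 > w or y1 > h
        cx0, cx1 = max(x0, 0), min(x1, w)
        cy0, cy1 = max(y0, 0), min(y1, h)
        if cx1 > cx0 and cy1 > cy0:
            yy, xx = np.mgrid[cy0:cy1, cx0:cx1]
            inside = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
            truth[cy0:cy1, cx0:cx1][inside] = PURPLE
        records.append(dict(x=x, y=y, radius=r, clipped=clipped))
    table = pd.DataFrame(records, columns=["x", "y", "radius", "clipped"])

    img = np.where((truth == PURPLE)[:, :, None],
                   np.array(params.dot_color, dtype=float),
                   np.array(params.background, dtype=float))
    for (sx0, sy0, sx1, sy1), m in params.shading:
        img[max(sy0, 0):min(sy1, h), max(sx0, 0):min(sx1, w)] *= m
    sigma = np.where(truth == PURPLE, params.dot_sigma, params.background_sigma)
    img += rng.normal(0.0, 1.0, size=img.shape) * sigma[:, :, None]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth, table


@dataclass
class CategoryField:
    """Per-cell R1..R4 categories (0 = unlabelled) plus generation metadata."""

    categories: np.ndarray
    mode: str
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.categories.shape

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.shape
        recs = [dict(row=r, col=c, category=f"R{self.categories[r, c]}"
                     if self.categories[r, c] else "unlabelled")
                for r in range(rows) for c in range(cols)]
        return pd.DataFrame(recs)


def generate_uniform_field(rows: int, cols: int,
                           probs=DEFAULT_UNIFORM_PROBS, seed=None) -> CategoryField:
    """I.i.d. categorical assignment of R1..R4 to every cell."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (4,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("probs must be 4 non-negative values summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cats = rng.choice(np.arange(1, 5), size=(rows, cols), p=probs)
    return CategoryField(categories=cats.astype(int), mode="uniform",
                         seed=seed if isinstance(seed, int) else None,
                         metadata={"probs": tuple(probs)})


_NBHD = np.ones((3, 3), dtype=bool)  # 8-adjacency


def generate_clustered_field(rows: int = 20, cols: int = 20,
                             r1_blocks=DEFAULT_R1_BLOCKS,
                             p2: float = 0.4, p3: float = 0.5, p4: float = 0.6,
                             seed=None) -> CategoryField:
    """Clustered field: R1 seed blocks with stochastic neighbor propagation.

    Cells in ``r1_blocks`` are R1.  Unlabelled 8-neighbors of R1 become R2
    with probability ``p2``; unlabelled neighbors of R2 become R3 with
    probability ``p3``; unlabelled neighbors of R3 become R4 with
    probability ``p4``.  Remaining cells stay unlabelled (category 0) and
    never enter a cumulative testing scale.
    """
    cats = np.zeros((rows, cols), dtype=int)
    n_seed = 0
    for r0, c0, r1, c1 in r1_blocks:
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError(f"R1 block {(r0, c0, r1, c1)} outside {rows}x{cols} grid")
        cats[r0:r1, c0:c1] = 1
        n_seed += (r1 - r0) * (c1 - c0)
    if n_seed == 0:
        raise ValueError("empty R1 seed region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for level, p in ((2, p2), (3, p3), (4, p4)):
        candidates = binary_dilation(cats == level - 1, structure=_NBHD) & (cats == 0)
        chosen = candidates & (rng.random((rows, cols)) < p)
        cats[chosen] = level
    return CategoryField(categories=cats, mode="clustered",
                         seed=seed if isinstance(seed, int) else None,
                         metadata={"r1_blocks": tuple(map(tuple, r1_blocks)),
                                   "p2": p2, "p3": p3, "p4": p4})
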