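"""Color-cube quantization and the color-complexity measure.

A natural color image occupies only a tiny fraction of the 256^3 discrete
color space: strong associations among the three channels confine the pixel
cloud to a few thousand distinct colors.  Partitioning the space into
axis-aligned cubes of side ``n`` and asking which cubes are occupied gives a
cheap, data-driven summary of that color variety.  The *color-complexity* of
a pixel set is the fraction of cubes occupied, and each occupied cube is
represented by the center of mass of the pixels it contains — the working
unit for all downstream clustering.

Both RGB and HSV coordinates are handled on the integer ``[0, 255]`` scale;
hue is binned linearly (its circular topology is deliberately ignored, see
the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv

__all__ = [
    "CubeGrid",
    "axis_cubes",
    "build_cube_grid",
    "cube_centers",
    "quantize",
    "rgb_to_hsv_255",
]


def _as_pixels(pixels) -> np.ndarray:
    """Validate and return an (m, 3) integer-valued channel array."""
    arr = np.asarray(pixels)
    if arr.ndim == 1 and arr.shape == (3,):
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (m, 3) channel triples, got shape {arr.shape}")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("channel values must lie in [0, 255]")
    return arr


def rgb_to_hsv_255(pixels) -> np.ndarray:
    """Convert RGB triples in [0, 255] to HSV triples rescaled to [0, 255].

    Standard RGB->HSV conversion with each HSV channel mapped linearly onto
    [0, 255] and rounded to the nearest integer, so both color models live
    on the same integer lattice and share the cube machinery.
    """
    arr = _as_pixels(pixels)
    hsv = _mpl_rgb_to_hsv(arr.astype(np.float64) / 255.0)
    return np.clip(np.rint(hsv * 255.0), 0, 255).astype(np.int64)


def quantize(pixels, n: int) -> np.ndarray:
    """Map channel triples to cube indices via component-wise ``floor(c / n)``."""
    if int(n) != n or n < 1:
        raise ValueError(f"cube scale n must be a positive integer, got {n!r}")
    arr = _as_pixels(pixels)
    return arr.astype(np.int64) // int(n)


def axis_cubes(n: int) -> int:
    """Number of cubes per axis at scale ``n``: ceil(256 / n).

    The last cube on each axis may be smaller than ``n`` (e.g. n=10 gives
    26 cubes per axis, the last covering only [250, 255]).
    """
    if int(n) != n or n < 1:
        raise ValueError(f"cube scale n must be a positive integer, got {n!r}")
    return -(-256 // int(n))


def cube_centers(indices: np.ndarray, n: int) -> np.ndarray:
    """Geometric centers of cubes given their (k, 3) integer indices."""
    return np.asarray(indices, dtype=np.float64) * n + n / 2.0


@dataclass(frozen=True)
class CubeGrid:
    """Occupancy summary of a pixel multiset at cube scale ``n``.

    Attributes
    ----------
    n : cube side length.
    indices : (k, 3) integer cube coordinates of the occupied cubes.
    counts : (k,) pixel count per occupied cube.
    representatives : (k, 3) center of mass of the pixels in each cube.
    inverse : (m,) index into ``indices`` for each input pixel.
    """

    n: int
    indices: np.ndarray
    counts: np.ndarray
    representatives: np.ndarray
    inverse: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return len(self.counts)

    @property
    def axis_cubes(self) -> int:
        return axis_cubes(self.n)

    @property
    def complexity(self) -> float:
        """Fraction of the ceil(256/n)^3 cubes that are occupied."""
        return self.n_occupied / self.axis_cubes**3

    def centers(self) -> np.ndarray:
        return cube_centers(self.indices, self.n)


def build_cube_grid(pixels, n: int) -> CubeGrid:
    """Quantize a pixel multiset and summarize per-cube occupancy.

    Raises ``ValueError`` on an empty pixel list.
    """
    arr = _as_pixels(pixels)
    if len(arr) == 0:
        raise ValueError("cannot build a cube grid from an empty pixel set")
    q = quantize(arr, n)
    a = axis_cubes(n)
    code = (q[:, 0] * a + q[:, 1]) * a + q[:, 2]
    uniq, inverse, counts = np.unique(code, return_inverse=True, return_counts=True)
    k = len(uniq)
    sums = np.zeros((k, 3), dtype=np.float64)
    np.add.at(sums, inverse, arr.astype(np.float64))
    reps = sums / counts[:, None]
    idx = np.empty((k, 3), dtype=np.int64)
    idx[:, 2] = uniq % a
    rest = uniq // a
    idx[:, 1] = rest % a
    idx[:, 0] = rest // a
    return CubeGrid(n=int(n), indices=idx, counts=counts, representatives=reps, inverse=inverse)
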