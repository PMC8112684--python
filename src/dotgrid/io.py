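"""Image and artifact input/output plus the run configuration.

Coordinates in every CSV are 0-based, x rightward, y downward, with
half-open pixel rectangles.  Masks are stored as single-channel PNGs with
0 = background, 128 = yellow, 255 = purple.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .segmentation import BACKGROUND, PURPLE, YELLOW

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "write_dots_csv",
    "write_grid_csv",
    "RunConfig",
    "run_pipeline",
]

_CSV_HEADER = "# coordinates: 0-based, x rightward, y downward; rectangles half-open\n"

_MASK_CODES = np.array([0, 128, 255], dtype=np.uint8)  # BACKGROUND, YELLOW, PURPLE


def read_image(path) -> np.ndarray:
    """Read a raster image as an (H, W, 3) uint8 RGB array.

    Alpha is dropped, grayscale is promoted to 3 identical channels and
    16-bit data is rescaled to 8-bit with a warning.
    """
    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit input rescaled to 8-bit", stacklevel=2)
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a label mask as a single-channel PNG (0/128/255)."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 2:
        raise ValueError("mask labels must be in {0, 1, 2}")
    iio.imwrite(path, _MASK_CODES[mask])


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back into {BACKGROUND, YELLOW, PURPLE} labels."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    mask = np.full(arr.shape, BACKGROUND, dtype=np.uint8)
    mask[arr == 128] = YELLOW
    mask[arr == 255] = PURPLE
    return mask


def _write_csv(path, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        frame.to_csv(fh, index=False)


def write_dots_csv(path, dots) -> None:
    _write_csv(path, dots.to_frame())


def write_grid_csv(path, grid) -> None:
    _write_csv(path, grid.to_frame())


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Rectangles are (x0, y0, x1, y1) half-open pixel coordinates; ``None``
    means auto-default (whole image / centered focal area).
    """

    image: str = ""
    outdir: str = "out"
    paper_region: tuple[int, int, int, int] | None = None
    focal_area: tuple[int, int, int, int] | None = None
    rgb_scale: int = 1
    hsv_scale: int = 10
    train_scale: int = 10
    n_rows: int = 39
    squares_per_row: int = 10
    connectivity: int = 8
    grid_rows: int = 20
    grid_cols: int = 20
    size_method: str = "hc"
    size_thresholds: tuple[float, float] | None = None
    B: int = 500
    seed: int = 0
    linkage: str = "ward"

    _RECT_FIELDS = ("paper_region", "focal_area")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` text config; unknown keys are rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = cls._coerce(key, val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    @classmethod
    def _coerce(cls, key: str, val: str):
        if val.lower() in ("none", ""):
            return None
        if key in cls._RECT_FIELDS or key == "size_thresholds":
            parts = tuple(float(p) if "." in p else int(p) for p in val.replace(",", " ").split())
            return parts
        if key in ("image", "outdir", "size_method", "linkage"):
            return val
        return int(val)

    def validate(self) -> "RunConfig":
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for name in (
            "rgb_scale", "hsv_scale", "train_scale", "n_rows",
            "squares_per_row", "grid_rows", "grid_cols", "B",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, image: np.ndarray | None = None) -> dict[str, str]:
    """Run segment -> dots -> grid -> uniformness tests; write all artifacts.

    Returns a mapping of artifact names to paths.  Artifacts: mask PNG,
    dot table CSV, grid summary CSV, one TestReport JSON per cumulative
    scale, and a log recording every resolved default.
    """
    from .dots import classify_dot_sizes, extract_dots
    from .gridsum import categorize_rectangles, featurize, partition_grid
    from .segmentation import ColorCardSegmenter
    from .uniformtest import run_uniformness_test

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    logger = logging.getLogger(f"dotgrid.run.{id(config)}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    artifacts = {"log": str(log_path)}
    try:
        if image is None:
            image = read_image(config.image)
            logger.info("stage=read image=%s shape=%s", config.image, image.shape)

        seg = ColorCardSegmenter(
            rgb_scale=config.rgb_scale, hsv_scale=config.hsv_scale,
            train_scale=config.train_scale, n_rows=config.n_rows,
            squares_per_row=config.squares_per_row, linkage=config.linkage,
            paper_region=config.paper_region, focal_area=config.focal_area,
        )
        mask = seg.fit_predict(image)
        logger.info("stage=segment paper_region=%s focal_area=%s (auto-default where config gave none)",
                    seg.paper_region_, seg.focal_area_.rect)
        logger.info("stage=segment flagged_squares=%s", seg.flagged_squares_)
        mask_path = outdir / "mask.png"
        write_mask(mask_path, mask)
        artifacts["mask"] = str(mask_path)

        dots = extract_dots(mask, connectivity=config.connectivity)
        logger.info("stage=dots connectivity=%d n_dots=%d", config.connectivity, len(dots))
        if len(dots):
            classify_dot_sizes(dots, method=config.size_method,
                               thresholds=config.size_thresholds)
        dots_path = outdir / "dots.csv"
        write_dots_csv(dots_path, dots)
        artifacts["dots"] = str(dots_path)

        grid = partition_grid(seg.paper_region_, config.grid_rows, config.grid_cols)
        featurize(grid, dots)
        mean_radii = dots.class_mean_radii()
        weights = [mean_radii.get(c) for c in ("small", "medium", "large")]
        weights = None if any(w is None for w in weights) else tuple(weights)
        categorize_rectangles(grid, weights=weights, linkage=config.linkage)
        logger.info("stage=grid rows=%d cols=%d weights=%s",
                    config.grid_rows, config.grid_cols, weights)
        grid_path = outdir / "grid.csv"
        write_grid_csv(grid_path, grid)
        artifacts["grid"] = str(grid_path)

        for level in ("R1", "R1R2", "R1R3"):
            report_path = outdir / f"report_{level}.json"
            try:
                report = run_uniformness_test(
                    grid.categories, level=level, B=config.B,
                    seed=config.seed, linkage=config.linkage,
                )
                report_path.write_text(report.to_json() + "\n")
                logger.info("stage=test level=%s k=%d p=%.4f PO=%.6g",
                            level, report.k, report.p_value, report.po_obs)
            except ValueError as exc:
                report_path.write_text(json.dumps(
                    {"level": level, "error": str(exc)}, indent=2) + "\n")
                logger.info("stage=test level=%s skipped: %s", level, exc)
            artifacts[f"report_{level}"] = str(report_path)

        logger.info("stage=done resolved_config=%s", config.to_dict())
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)
    return artifacts
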