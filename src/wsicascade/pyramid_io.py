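"""Data model and I/O for pyramidal slides, masks and probability heatmaps.

All coordinate conventions live here: coordinates are 0-based with
``(x, y) = (column, row)``, windows are half-open squares in level-0
pixels, and pyramid level *k* is exactly ``2**k``-fold downsampled from
level 0 (so level 0 is the full-resolution 40x scan, level 3 is 5x, and
level 5 is 1.25x).

Slides are stored as multipage TIFFs whose page *k* is level *k*; masks
are single-channel 8-bit PNGs; heatmaps are single-channel float32
TIFFs. Real-scanner formats are out of scope.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "SlidePyramid",
    "MaskRaster",
    "Heatmap",
    "Window",
    "read_pyramid",
    "write_pyramid",
    "map_coords",
    "read_window",
    "write_heatmap",
    "read_heatmap",
    "write_mask",
    "read_mask",
    "downsample2x",
]

#: Fill value for regions of a window that fall outside the slide.
#: Slide background is white glass, so border patches stay well defined.
WHITE = 255

#: Mask scales supported by the pipeline: level 0, dense heatmap (1/8),
#: tissue mask (1/32, i.e. 1.25x), rough heatmap (1/128).
VALID_MASK_SCALES = (1, 8, 32, 128)

#: Dimensions may deviate from exact ceil-division by this many pixels
#: (scanner rounding); anything larger is a malformed pyramid.
DIM_TOLERANCE = 1


@dataclass
class Window:
    """Half-open square window ``[x, x+size) x [y, y+size)`` in level-0 px."""

    x: int
    y: int
    size: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("window origin must be non-negative")
        if self.size <= 0:
            raise ValueError("window size must be positive")


@dataclass
class SlidePyramid:
    """Multi-level RGB image with level-0 coordinate authority.

    ``levels[k]`` is an ``(h, w, 3)`` uint8 array with side lengths
    ``ceil(side0 / 2**k)`` (within scanner-rounding tolerance). Level 0
    is 40x magnification; level *k* is ``40 / 2**k`` x.
    """

    levels: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("pyramid needs at least one level")
        h0, w0 = self.levels[0].shape[:2]
        for k, lvl in enumerate(self.levels):
            if lvl.ndim != 3 or lvl.shape[2] != 3 or lvl.dtype != np.uint8:
                raise ValueError(f"level {k} is not an 8-bit RGB raster")
            eh = math.ceil(h0 / 2**k)
            ew = math.ceil(w0 / 2**k)
            if abs(lvl.shape[0] - eh) > DIM_TOLERANCE or abs(lvl.shape[1] - ew) > DIM_TOLERANCE:
                raise ValueError(
                    f"malformed pyramid: level {k} has shape {lvl.shape[:2]}, "
                    f"expected about ({eh}, {ew})"
                )

    @property
    def width0(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height0(self) -> int:
        return self.levels[0].shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def downsample(self, k: int) -> int:
        """Downsample factor of level ``k`` relative to level 0."""
        return 2**k

    def magnification(self, k: int) -> float:
        """Objective magnification of level ``k`` (level 0 is 40x)."""
        return 40.0 / 2**k


@dataclass
class MaskRaster:
    """Binary raster at ``1/level_scale`` of the level-0 side.

    Semantics: 1 = tumor (or tissue foreground), 0 = normal (or
    background).
    """

    data: np.ndarray
    level_scale: int

    def __post_init__(self) -> None:
        if self.level_scale not in VALID_MASK_SCALES:
            raise ValueError(f"level_scale must be one of {VALID_MASK_SCALES}")
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("mask must be a non-empty 2-D raster")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)

    @property
    def foreground_fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class Heatmap:
    """Tumor-probability raster at 1/8 (dense) or 1/128 (rough) scale.

    ``provenance`` counts how many patch predictions contributed to each
    cell; cells with no contribution carry the fill value 0.0.
    """

    data: np.ndarray
    level_scale: int
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("heatmap must be a non-empty 2-D raster")
        if self.level_scale not in (8, 128):
            raise ValueError("heatmap level_scale must be 8 or 128")
        self.data = np.asarray(self.data, dtype=np.float32)
        if np.nanmin(self.data) < 0.0 or np.nanmax(self.data) > 1.0:
            raise ValueError("heatmap values must lie in [0, 1]")
        if self.provenance is None:
            self.provenance = np.ones_like(self.data, dtype=np.int32)


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def _check_scale(s: int) -> None:
    if s < 1 or (s & (s - 1)) != 0:
        raise ValueError(f"scale must be a positive power of two, got {s}")


def map_coords(p: tuple[int, int], from_scale: int, to_scale: int) -> tuple[int, int]:
    """Map a 0-based point between raster scales: ``floor(p*from/to)``.

    Exact (invertible) when ``to_scale`` divides ``from_scale * p``;
    otherwise quantized toward the origin by less than one target pixel.
    """
    _check_scale(from_scale)
    _check_scale(to_scale)
    return (p[0] * from_scale // to_scale, p[1] * from_scale // to_scale)


# ---------------------------------------------------------------------------
# Window reads
# ---------------------------------------------------------------------------

def read_window(slide: SlidePyramid, w: Window, level: int = 0) -> np.ndarray:
    """Read a square window, given in level-0 coordinates, at ``level``.

    Returns a ``(size/2**level)``-sided RGB raster. Area outside the
    slide is filled with white. Raises if the window misses the slide
    entirely.
    """
    if level < 0 or level >= slide.n_levels:
        raise ValueError(f"level {level} not present in pyramid")
    if w.x >= slide.width0 or w.y >= slide.height0:
        raise ValueError("window entirely outside slide")
    ds = 2**level
    if w.size % ds != 0:
        raise ValueError(f"window size {w.size} not divisible by 2**{level}")
    out_side = w.size // ds
    lvl = slide.levels[level]
    x0, y0 = w.x // ds, w.y // ds
    out = np.full((out_side, out_side, 3), WHITE, dtype=np.uint8)
    x1 = min(x0 + out_side, lvl.shape[1])
    y1 = min(y0 + out_side, lvl.shape[0])
    if x1 > x0 and y1 > y0:
        out[: y1 - y0, : x1 - x0] = lvl[y0:y1, x0:x1]
    return out


# ---------------------------------------------------------------------------
# Pyramid construction / file I/O
# ---------------------------------------------------------------------------

def downsample2x(img: np.ndarray) -> np.ndarray:
    """Exact 2x mean pooling; odd sides are edge-padded to even first."""
    arr = np.asarray(img, dtype=np.float64)
    h, w = arr.shape[:2]
    pad = [(0, h % 2), (0, w % 2)] + [(0, 0)] * (arr.ndim - 2)
    if h % 2 or w % 2:
        arr = np.pad(arr, pad, mode="edge")
    pooled = (arr[0::2, 0::2] + arr[1::2, 0::2] + arr[0::2, 1::2] + arr[1::2, 1::2]) / 4.0
    if img.dtype == np.uint8:
        return np.rint(pooled).astype(np.uint8)
    return pooled.astype(img.dtype)


def build_pyramid(level0: np.ndarray, min_side: int = 64) -> SlidePyramid:
    """Build a pyramid from a level-0 RGB raster by repeated 2x pooling."""
    levels = [np.ascontiguousarray(level0, dtype=np.uint8)]
    while min(levels[-1].shape[:2]) // 2 >= min_side:
        levels.append(downsample2x(levels[-1]))
    return SlidePyramid(levels)


def write_pyramid(slide: SlidePyramid, path: str | os.PathLike) -> None:
    """Write a pyramid as a multipage TIFF (page k = level k)."""
    with tifffile.TiffWriter(path) as tif:
        for lvl in slide.levels:
            tif.write(lvl, photometric="rgb", compression="zlib")


def read_pyramid(path: str | os.PathLike) -> SlidePyramid:
    """Read a multipage-TIFF pyramid; validates the 2**k dimension rule."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    levels = []
    for pg in pages:
        if pg.ndim == 2:
            pg = np.stack([pg] * 3, axis=-1)
        levels.append(pg.astype(np.uint8))
    try:
        return SlidePyramid(levels)
    except ValueError as e:
        raise ValueError(f"malformed pyramid: {e}") from e


def write_heatmap(hm: Heatmap, path: str | os.PathLike) -> None:
    """Write a heatmap as single-channel float32 TIFF (lossless)."""
    tifffile.imwrite(
        path,
        hm.data.astype(np.float32),
        metadata={"level_scale": hm.level_scale},
    )


def read_heatmap(path: str | os.PathLike, level_scale: int | None = None) -> Heatmap:
    """Read a float32 TIFF heatmap; scale comes from metadata if present."""
    with tifffile.TiffFile(path) as tif:
        data = tif.pages[0].asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    scale = level_scale if level_scale is not None else int(meta.get("level_scale", 8))
    return Heatmap(data=np.asarray(data, dtype=np.float32), level_scale=scale)


def write_mask(mask: MaskRaster, path: str | os.PathLike) -> None:
    """Write a binary mask as 8-bit PNG with values {0, 255}."""
    Image.fromarray((mask.data * 255).astype(np.uint8), mode="L").save(path)


def read_mask(path: str | os.PathLike, level_scale: int) -> MaskRaster:
    """Read an 8-bit PNG mask; nonzero pixels become 1."""
    arr = np.asarray(Image.open(path).convert("L"))
    if arr.size == 0:
        raise ValueError("empty mask raster")
    bad = ~np.isin(arr, (0, 1, 255))
    if bad.any():
        raise ValueError("mask file contains values other than {0, 1, 255}")
    return MaskRaster(data=(arr > 0).astype(np.uint8), level_scale=level_scale)
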