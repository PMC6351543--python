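"""Tissue/background separation by Otsu thresholding on HSV saturation.

A slide scan is mostly white glass; tissue is stained and therefore
saturated. Applying Otsu's method to the saturation channel of the
1.25x image (1/32 of the level-0 side) separates the two quickly, and
the resulting foreground positions map back to level 0 for patch
extraction. H and V channel thresholding share the same Otsu core but
the pipeline uses S, which separates stained tissue best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pyramid_io import MaskRaster, SlidePyramid, downsample2x

__all__ = [
    "OtsuResult",
    "rgb_to_hsv_channels",
    "otsu_threshold",
    "compute_tissue_mask",
]

#: The 1.25x image is 1/32 of the 40x side (40 / 32 = 1.25).
TISSUE_MASK_SCALE = 32
TISSUE_MASK_LEVEL = 5  # 2**5 == 32


@dataclass(frozen=True)
class OtsuResult:
    """Otsu threshold over a 256-bin histogram.

    ``threshold`` is the bin index t maximizing the between-class
    variance; class 0 is bins <= t. Ties are broken by the smallest t.
    """

    threshold: int
    between_class_variance: float


def rgb_to_hsv_channels(img: np.ndarray) -> dict[str, np.ndarray]:
    """Convert 8-bit RGB to integer H, S, V channels, each in [0, 255].

    Integerization keeps the 256-bin histograms exact:
    ``V = max(R,G,B)``, ``S = round(255 * (max-min) / max)`` (0 where
    max = 0, so grays including pure white have zero saturation), and
    H is the usual hue angle rescaled from [0, 360) to [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB raster")
    rgb = arr.astype(np.float64)
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    delta = mx - mn

    v = mx
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, 255.0 * delta / mx, 0.0)

        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        h = np.zeros_like(mx)
        nz = delta > 0
        rmax = nz & (mx == r)
        gmax = nz & ~rmax & (mx == g)
        bmax = nz & ~rmax & ~gmax
        h[rmax] = np.mod(((g - b) / delta)[rmax], 6.0)
        h[gmax] = ((b - r) / delta)[gmax] + 2.0
        h[bmax] = ((r - g) / delta)[bmax] + 4.0
    h = h * 60.0  # degrees in [0, 360)
    h = np.mod(h, 360.0)

    return {
        "H": np.rint(h * 255.0 / 360.0).astype(np.uint8),
        "S": np.rint(s).astype(np.uint8),
        "V": np.rint(v).astype(np.uint8),
    }


def otsu_threshold(hist: np.ndarray) -> OtsuResult:
    """Exhaustive Otsu threshold over a 256-bin count histogram.

    Maximizes the between-class variance
    ``sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` over all 256
    candidate thresholds, breaking ties by the smallest t. Raises on a
    degenerate histogram (all mass in one bin), where no threshold
    separates two classes.
    """
    h = np.asarray(hist, dtype=np.float64)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if h.sum() <= 0:
        raise ValueError("histogram total count must be positive")
    if np.count_nonzero(h) < 2:
        raise ValueError("degenerate histogram")

    total = h.sum()
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(h)            # mass of class 0 = bins <= t
    m0 = np.cumsum(h * bins)     # unnormalized first moment of class 0
    w1 = total - w0
    m_total = m0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (m_total - m0) / w1
        sigma_b = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    t = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    return OtsuResult(threshold=t, between_class_variance=float(sigma_b[t]))


def _image_at_scale32(slide: SlidePyramid) -> np.ndarray:
    """The 1.25x RGB image: level 5 if present, else pooled down to it."""
    if slide.n_levels > TISSUE_MASK_LEVEL:
        return slide.levels[TISSUE_MASK_LEVEL]
    img = slide.levels[slide.n_levels - 1]
    for _ in range(TISSUE_MASK_LEVEL - (slide.n_levels - 1)):
        img = downsample2x(img)
    return img


def compute_tissue_mask(slide: SlidePyramid) -> MaskRaster:
    """Foreground tissue mask at 1/32 scale via Otsu on the S channel.

    Foreground is the high-saturation side (``S > t``): tissue is
    stained, background is near-gray. Foreground positions map into
    level 0 via ``map_coords(p, 32, 1)``.
    """
    img = _image_at_scale32(slide)
    s = rgb_to_hsv_channels(img)["S"]
    hist = np.bincount(s.ravel(), minlength=256).astype(np.int64)
    res = otsu_threshold(hist)
    return MaskRaster(data=(s > res.threshold).astype(np.uint8), level_scale=TISSUE_MASK_SCALE)
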