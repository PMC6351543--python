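"""Seeded synthetic pyramidal slides with ground-truth tumor masks.

The generator emulates the features of a stained lymph-node scan that
the pipeline relies on: a near-white glass background, tissue built
from smoothed random ellipses whose pink stain is clearly saturated
(so S-channel Otsu separates it), and tumor lesions as smooth
purple-stained blobs strictly inside the tissue, several rough-heatmap
cells across, with a level-0 binary ground-truth mask. Pyramids are
built by exact 2x mean pooling, so a 4096-px slide carries levels down
to 1.25x and below.

Default dimensions and lesion sizes model a desk-scale stand-in for a
40x whole-slide scan: 4096 px represents a scan side at roughly 1/25
scale, making the default 300-700 px blob radii the analogue of
macro-metastases a few millimetres across.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .pyramid_io import MaskRaster, SlidePyramid, build_pyramid

__all__ = ["SynthSpec", "generate", "make_cohort"]

# Stain colors (RGB). Saturation: background ~0, tissue ~37%, tumor ~50%.
BACKGROUND_RGB = (245, 245, 245)
TISSUE_RGB = (231, 146, 169)   # eosin-pink
TUMOR_RGB = (150, 92, 185)     # hematoxylin-purple
COLOR_NOISE_SD = 6.0           # per-pixel stain variation


@dataclass
class SynthSpec:
    """Parameters of one synthetic slide."""

    width0: int = 4096
    height0: int = 4096
    tissue_fraction: float = 0.40
    n_tumor_blobs: int = 2
    blob_radius_range: tuple[int, int] = (300, 700)
    seed: int = 0
    #: tolerance on the realized tissue fraction
    tissue_tol: float = 0.03


@dataclass
class SlideMetadata:
    tissue_fraction: float
    tumor_fraction: float
    blob_centroids: list[tuple[float, float]] = field(default_factory=list)
    n_lesions: int = 0


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float,
                  rx: float, ry: float, angle: float) -> np.ndarray:
    """Rotated filled ellipse; evaluated only on its bounding box."""
    h, w = shape
    rmax = max(rx, ry)
    x0, x1 = max(0, int(cx - rmax) - 1), min(w, int(cx + rmax) + 2)
    y0, y1 = max(0, int(cy - rmax) - 1), min(h, int(cy + rmax) + 2)
    out = np.zeros((h, w), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    out[y0:y1, x0:x1] = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return out


def _smooth_binary(mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a binary mask and re-threshold at 0.5.

    Smoothing is restricted to the mask's bounding box (padded by the
    kernel support) for speed; the result is identical to filtering
    the full raster because the field is zero elsewhere.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return mask.astype(bool)
    pad = int(4 * sigma) + 2
    y0, y1 = max(0, ys.min() - pad), min(mask.shape[0], ys.max() + 1 + pad)
    x0, x1 = max(0, xs.min() - pad), min(mask.shape[1], xs.max() + 1 + pad)
    out = np.zeros_like(mask, dtype=bool)
    out[y0:y1, x0:x1] = gaussian_filter(
        mask[y0:y1, x0:x1].astype(np.float32), sigma, mode="constant"
    ) > 0.5
    return out


def _tissue_region(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of smoothed random ellipses hitting the target fraction."""
    h, w = spec.height0, spec.width0
    target = spec.tissue_fraction
    if not 0.0 < target < 0.95:
        raise ValueError("tissue_fraction must be in (0, 0.95)")
    tissue = np.zeros((h, w), dtype=bool)
    area = h * w
    for _ in range(200):
        frac = tissue.mean()
        if frac >= target - 0.005:
            break
        # ellipse sized to the remaining deficit, capped so one draw
        # cannot overshoot past the tolerance
        deficit = target - frac
        ell_area = min(deficit, max(0.02, deficit * 0.8)) * area
        aspect = rng.uniform(0.5, 1.0)
        rx = np.sqrt(ell_area / (np.pi * aspect))
        ry = rx * aspect
        cx = rng.uniform(rx * 0.5, w - rx * 0.5)
        cy = rng.uniform(ry * 0.5, h - ry * 0.5)
        tissue |= _ellipse_mask((h, w), cx, cy, rx, ry, rng.uniform(0, np.pi))
    tissue = _smooth_binary(tissue, sigma=min(h, w) / 200.0)
    if abs(tissue.mean() - target) > spec.tissue_tol:
        raise ValueError(
            f"could not hit tissue fraction {target} "
            f"(got {tissue.mean():.3f}); spec may be infeasible"
        )
    return tissue


def _tumor_blobs(spec: SynthSpec, tissue: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Smooth random blobs strictly inside the tissue region."""
    h, w = tissue.shape
    gt = np.zeros((h, w), dtype=bool)
    centroids: list[tuple[float, float]] = []
    if spec.n_tumor_blobs == 0:
        return gt, centroids
    r_lo, r_hi = spec.blob_radius_range
    # distance map at 1/4 scale is plenty for center placement
    ds = 4
    dist = distance_transform_edt(tissue[::ds, ::ds]) * ds
    if not (dist >= 0.7 * r_lo).any():
        raise ValueError("infeasible spec: tumor radius exceeds tissue extent")
    for _ in range(spec.n_tumor_blobs):
        r = float(rng.uniform(r_lo, r_hi))
        # centers must sit deep enough that most of the blob fits in
        # tissue; shrink toward the minimum radius if the draw is too big
        ok = dist >= 0.7 * r
        while not ok.any() and r > r_lo:
            r = max(0.8 * r, r_lo)
            ok = dist >= 0.7 * r
        ys, xs = np.nonzero(ok)
        j = rng.integers(len(ys))
        cx, cy = float(xs[j] * ds), float(ys[j] * ds)
        aspect = rng.uniform(0.6, 1.0)
        blob = _ellipse_mask((h, w), cx, cy, r, r * aspect, rng.uniform(0, np.pi))
        blob = _smooth_binary(blob, sigma=r / 10.0)
        blob &= tissue  # invariant: tumor is a subset of tissue
        gt |= blob
        by, bx = np.nonzero(blob)
        if len(by):
            centroids.append((float(bx.mean()), float(by.mean())))
    return gt, centroids


def generate(spec: SynthSpec) -> tuple[SlidePyramid, MaskRaster, SlideMetadata]:
    """Generate one synthetic slide: pyramid, level-0 ground truth, metadata.

    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_region(spec, rng)
    gt, centroids = _tumor_blobs(spec, tissue, rng)

    h, w = spec.height0, spec.width0
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = BACKGROUND_RGB
    img[tissue] = TISSUE_RGB
    img[gt] = TUMOR_RGB
    img += COLOR_NOISE_SD * rng.standard_normal(size=img.shape, dtype=np.float32)
    level0 = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    slide = build_pyramid(level0, min_side=64)
    gt_mask = MaskRaster(data=gt.astype(np.uint8), level_scale=1)
    from skimage.measure import label as cc_label

    meta = SlideMetadata(
        tissue_fraction=float(tissue.mean()),
        tumor_fraction=float(gt.mean()),
        blob_centroids=centroids,
        n_lesions=int(cc_label(gt, connectivity=2, return_num=True)[1]),
    )
    return slide, gt_mask, meta


def make_cohort(
    n_tumor_slides: int,
    n_normal_slides: int,
    template: SynthSpec | None = None,
    seed: int = 0,
) -> list[tuple[SlidePyramid, MaskRaster, SlideMetadata, int]]:
    """Seeded cohort of tumor and normal slides.

    Returns a list of (slide, ground truth, metadata, label) with
    label 1 for tumor slides. Per-slide seeds are drawn from a seed
    sequence spawned from ``seed``, so slides are mutually independent
    and the cohort is reproducible.
    """
    template = template or SynthSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        n_tumor_slides + n_normal_slides
    ) % (2**31 - 1)
    cohort = []
    for i in range(n_tumor_slides + n_normal_slides):
        tumor = i < n_tumor_slides
        spec = SynthSpec(
            width0=template.width0,
            height0=template.height0,
            tissue_fraction=template.tissue_fraction,
            n_tumor_blobs=template.n_tumor_blobs if tumor else 0,
            blob_radius_range=template.blob_radius_range,
            seed=int(child_seeds[i]),
            tissue_tol=template.tissue_tol,
        )
        slide, gt, meta = generate(spec)
        cohort.append((slide, gt, meta, int(tumor)))
    return cohort
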