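"""Training patch sets (labels, 1:1 balancing, augmentation) and tile plans.

The classifier stage consumes 299x299 patches at 40x on a stride-128
grid restricted to tissue; a patch containing at least one ground-truth
tumor pixel is a tumor patch (label 1). Training sets are balanced to a
1:1 tumor:normal ratio by subsampling normals, and augmented with
right-angle rotations, mirror flips and mild color jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pyramid_io import MaskRaster, Window, map_coords

__all__ = [
    "TilePlan",
    "LabeledPatch",
    "grid_starts",
    "plan_rough_tiles",
    "label_patches",
    "balance_1to1",
    "d4_transform",
    "augment",
]

ROUGH_PATCH_SIZE = 299  # classifier input side at 40x
ROUGH_STRIDE = 128      # one rough-heatmap cell per stride step


@dataclass
class TilePlan:
    """Row-major grid of square windows in level-0 coordinates."""

    windows: list[Window]
    size: int
    stride: int
    purpose: str = "rough"  # rough | dense | train

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class LabeledPatch:
    """Window plus tumor label; label 1 iff it contains a tumor pixel."""

    window: Window
    label: int
    slide_id: str = ""


def grid_starts(extent: int, size: int, stride: int) -> list[int]:
    """Stride-grid start offsets covering ``[0, extent)`` with ``size`` windows.

    A final start flush with the edge is appended when ``extent - size``
    is not a multiple of the stride, so no pixel is missed. For extents
    not exceeding one window, the single start 0 suffices.
    """
    if extent <= size:
        return [0]
    last = extent - size
    starts = list(range(0, last + 1, stride))
    if starts[-1] != last:
        starts.append(last)
    return starts


def plan_rough_tiles(
    mask: MaskRaster,
    slide_dims: tuple[int, int],
    size: int = ROUGH_PATCH_SIZE,
    stride: int = ROUGH_STRIDE,
) -> TilePlan:
    """Plan classifier windows over tissue.

    ``slide_dims`` is ``(width0, height0)``. Windows are laid out on a
    stride grid over the level-0 extent; a window is kept iff its
    footprint mapped to the 1/32 tissue mask contains foreground. An
    empty mask yields an empty plan with a warning.
    """
    if mask.level_scale != 32:
        raise ValueError("rough planning expects the 1/32 tissue mask")
    w0, h0 = slide_dims
    fg = mask.data
    if not fg.any():
        warnings.warn("tissue mask is empty; rough plan has no windows")
        return TilePlan(windows=[], size=size, stride=stride, purpose="rough")

    windows: list[Window] = []
    s = mask.level_scale
    for y in grid_starts(h0, size, stride):
        cy0 = y // s
        cy1 = min(-(-(y + size) // s), fg.shape[0])
        for x in grid_starts(w0, size, stride):
            cx0 = x // s
            cx1 = min(-(-(x + size) // s), fg.shape[1])
            if fg[cy0:cy1, cx0:cx1].any():
                windows.append(Window(x=x, y=y, size=size))
    return TilePlan(windows=windows, size=size, stride=stride, purpose="rough")


def label_patches(plan: TilePlan, gt: MaskRaster) -> list[LabeledPatch]:
    """Label each window: 1 iff it contains >=1 ground-truth tumor pixel.

    ``gt`` is the level-0 tumor mask; window area outside the mask
    bounds counts as normal.
    """
    if gt.level_scale != 1:
        raise ValueError("patch labeling expects the level-0 ground truth")
    g = gt.data
    out = []
    for w in plan.windows:
        y1 = min(w.y + w.size, g.shape[0])
        x1 = min(w.x + w.size, g.shape[1])
        tumor = bool(g[w.y:y1, w.x:x1].any()) if (y1 > w.y and x1 > w.x) else False
        out.append(LabeledPatch(window=w, label=int(tumor)))
    return out


def balance_1to1(patches: list[LabeledPatch], seed: int) -> list[LabeledPatch]:
    """Balance tumor:normal to 1:1 by seeded subsampling of normals.

    All tumor patches are kept; normal patches are subsampled without
    replacement down to the tumor count. If normals are already the
    minority they are all kept (cannot upsample) with a warning.
    """
    tumor = [p for p in patches if p.label == 1]
    normal = [p for p in patches if p.label == 0]
    if len(normal) <= len(tumor):
        if len(normal) < len(tumor):
            warnings.warn(
                f"only {len(normal)} normal patches for {len(tumor)} tumor patches; "
                "keeping all normals"
            )
        return tumor + normal
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(normal), size=len(tumor), replace=False)
    return tumor + [normal[i] for i in sorted(keep)]


def d4_transform(a: np.ndarray, flip: int, quarter_turns: int) -> np.ndarray:
    """Apply a dihedral-group element: flip (0 none, 1 horizontal,
    2 vertical) then ``quarter_turns`` counter-clockwise 90-degree
    rotations."""
    if flip == 1:
        a = a[:, ::-1]
    elif flip == 2:
        a = a[::-1, :]
    return np.rot90(a, k=int(quarter_turns) % 4)


def augment(
    patch: np.ndarray,
    mask: np.ndarray | None,
    seed: int,
    jitter: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Random d4 transform plus mild color jitter.

    The geometric transform — a uniform choice among {identity,
    horizontal flip, vertical flip} x {0, 90, 180, 270} degrees — is
    applied identically to image and mask. Color jitter (brightness and
    saturation scaled independently by factors in [0.9, 1.1]) touches
    the image only and can be disabled for pixel-exact pipelines.
    """
    rng = np.random.default_rng(seed)
    flip = int(rng.integers(3))
    quarter_turns = int(rng.integers(4))

    out_img = d4_transform(patch, flip, quarter_turns)
    if jitter:
        img = out_img.astype(np.float64)
        brightness = rng.uniform(0.9, 1.1)
        sat_scale = rng.uniform(0.9, 1.1)
        gray = img.mean(axis=2, keepdims=True) if img.ndim == 3 else img
        img = gray + sat_scale * (img - gray)  # scale saturation about the gray axis
        img = np.clip(img * brightness, 0, 255)
        out_img = np.rint(img).astype(patch.dtype)
    else:
        out_img = out_img.copy()

    out_mask = d4_transform(mask, flip, quarter_turns).copy() if mask is not None else None
    return out_img, out_mask
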