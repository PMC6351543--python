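"""Assemble per-patch predictions into whole-slide heatmaps.

A patch whose level-0 top-left corner is (x, y) contributes its dense
prediction at heatmap offset (x/8, y/8) (the dense heatmap has 1/8 the
level-0 side), or its scalar classifier probability at the single
rough-heatmap cell (x/128, y/128). Where patches overlap, the heatmap
value is the arithmetic mean of all contributing predictions:

    p_h(x, y) = (1/n) * sum_i p_i(x, y)   over the n patches covering (x, y)

Accumulation keeps an exact integer count raster alongside the sum, so
finalization is a single division; cells never covered stay 0.0. To
make floating-point output bit-reproducible, callers accumulate windows
in sorted row-major order (the pipeline planners emit them that way).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pyramid_io import Heatmap, Window

__all__ = [
    "HeatmapAccumulator",
    "accumulate_dense",
    "accumulate_rough",
    "finalize",
    "ensemble_average",
]


@dataclass
class HeatmapAccumulator:
    """Sum and count rasters for overlap-averaged stitching."""

    sum: np.ndarray
    count: np.ndarray
    level_scale: int

    @classmethod
    def for_slide(cls, slide_dims: tuple[int, int], level_scale: int) -> "HeatmapAccumulator":
        """Accumulator sized ceil(side0 / level_scale) for a slide."""
        if level_scale not in (8, 128):
            raise ValueError("level_scale must be 8 (dense) or 128 (rough)")
        w0, h0 = slide_dims
        shape = (-(-h0 // level_scale), -(-w0 // level_scale))
        return cls(
            sum=np.zeros(shape, dtype=np.float64),
            count=np.zeros(shape, dtype=np.int64),
            level_scale=level_scale,
        )


def accumulate_dense(acc: HeatmapAccumulator, window: Window, pred: np.ndarray) -> HeatmapAccumulator:
    """Add an (size/8)^2 patch prediction at heatmap offset (x/8, y/8).

    Window origins must be divisible by 8 (the tile planners guarantee
    this); prediction area falling outside the heatmap (overhanging
    tiles) is ignored.
    """
    if acc.level_scale != 8:
        raise ValueError("dense accumulation needs a scale-8 accumulator")
    if window.x % 8 or window.y % 8:
        raise ValueError("window origin must be divisible by 8")
    side = window.size // 8
    pred = np.asarray(pred, dtype=np.float64)
    if pred.shape != (side, side):
        raise ValueError(f"prediction shape {pred.shape} != ({side}, {side})")
    ox, oy = window.x // 8, window.y // 8
    if ox >= acc.sum.shape[1] or oy >= acc.sum.shape[0]:
        raise ValueError("patch offset outside heatmap bounds")
    y1 = min(oy + side, acc.sum.shape[0])
    x1 = min(ox + side, acc.sum.shape[1])
    acc.sum[oy:y1, ox:x1] += pred[: y1 - oy, : x1 - ox]
    acc.count[oy:y1, ox:x1] += 1
    return acc


def accumulate_rough(acc: HeatmapAccumulator, window: Window, p: float) -> HeatmapAccumulator:
    """Write a scalar classifier probability at cell (x/128, y/128).

    Each stride-128 window owns the single cell addressed by its
    top-left corner; windows mapping to the same cell (duplicates or
    flush-edge windows) are averaged by the same sum/count rule.
    """
    if acc.level_scale != 128:
        raise ValueError("rough accumulation needs a scale-128 accumulator")
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability out of [0, 1]")
    cx, cy = window.x // 128, window.y // 128
    if cy >= acc.sum.shape[0] or cx >= acc.sum.shape[1]:
        raise ValueError("cell outside heatmap bounds")
    acc.sum[cy, cx] += p
    acc.count[cy, cx] += 1
    return acc


def finalize(acc: HeatmapAccumulator) -> Heatmap:
    """Elementwise sum/count; cells with no contributions become 0.0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        data = np.where(acc.count > 0, acc.sum / np.maximum(acc.count, 1), 0.0)
    return Heatmap(
        data=np.clip(data, 0.0, 1.0).astype(np.float32),
        level_scale=acc.level_scale,
        provenance=acc.count.astype(np.int32),
    )


def ensemble_average(maps: list[Heatmap]) -> Heatmap:
    """Elementwise arithmetic mean of same-scale, same-shape heatmaps."""
    if not maps:
        raise ValueError("need at least one heatmap")
    scale = maps[0].level_scale
    shape = maps[0].data.shape
    for m in maps[1:]:
        if m.level_scale != scale or m.data.shape != shape:
            raise ValueError("heatmaps must share scale and shape")
    data = np.mean([m.data.astype(np.float64) for m in maps], axis=0)
    prov = np.sum([m.provenance for m in maps], axis=0).astype(np.int32)
    return Heatmap(data=data.astype(np.float32), level_scale=scale, provenance=prov)
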