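"""Two-stage cascade inference: rough classifier heatmap, candidate
selection, dense segmentation over candidates only.

A fast patch classifier sweeps the tissue at stride 128 and yields a
rough heatmap with 1/128 the level-0 side. Cells above threshold 0.5
become candidate tumor areas; only large segmentation tiles touching a
candidate are run through the dense segmenter, whose stitched output
has 1/8 the level-0 side. On slides where tumor (plus margin) is a
small fraction of tissue this prunes the overwhelming majority of
segmentation tiles while leaving covered-area results identical to
full-slide tiled segmentation.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from .model_contract import ClassifierModel, SegmenterModel
from .patch_sampler import TilePlan, plan_rough_tiles
from .pyramid_io import Heatmap, MaskRaster, SlidePyramid, Window, read_window
from .stitcher import HeatmapAccumulator, accumulate_dense, accumulate_rough, finalize

__all__ = [
    "rough_pass",
    "select_candidates",
    "plan_dense_tiles",
    "dense_pass",
    "run_cascade",
]

logger = logging.getLogger(__name__)

CANDIDATE_THRESHOLD = 0.5
DENSE_TILE_SIZE = 2560
DENSE_TILE_STRIDE = 1280


def _sorted_windows(windows: list[Window]) -> list[Window]:
    # Fixed row-major accumulation order keeps float sums bit-reproducible.
    return sorted(windows, key=lambda w: (w.y, w.x))


def rough_pass(
    slide: SlidePyramid,
    tissue: MaskRaster,
    model: ClassifierModel,
) -> Heatmap:
    """Classifier sweep over tissue -> rough heatmap at 1/128 scale."""
    t0 = time.perf_counter()
    plan = plan_rough_tiles(tissue, (slide.width0, slide.height0))
    acc = HeatmapAccumulator.for_slide((slide.width0, slide.height0), level_scale=128)
    for w in _sorted_windows(plan.windows):
        patch = read_window(slide, w, level=0)
        p = model.predict(patch, w)
        accumulate_rough(acc, w, p)
    hm = finalize(acc)
    logger.info(
        "rough pass: %d windows in %.2fs", len(plan.windows), time.perf_counter() - t0
    )
    return hm


def select_candidates(rough: Heatmap, thr: float = CANDIDATE_THRESHOLD) -> MaskRaster:
    """Binarize the rough heatmap: candidate cells have p_h > thr (strict)."""
    if rough.level_scale != 128:
        raise ValueError("candidate selection expects the rough (1/128) heatmap")
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return MaskRaster(data=(rough.data > thr).astype(np.uint8), level_scale=128)


def _dense_grid_starts(extent: int, size: int, stride: int) -> list[int]:
    # Origins are multiples of the stride; the last window may overhang
    # (white-fill read rule) but coverage stops once the extent is reached.
    starts = [0]
    while starts[-1] + size < extent:
        starts.append(starts[-1] + stride)
    return starts


def plan_dense_tiles(
    cand: MaskRaster,
    slide_dims: tuple[int, int],
    size: int = DENSE_TILE_SIZE,
    stride: int = DENSE_TILE_STRIDE,
) -> TilePlan:
    """Plan half-overlapping segmentation tiles over candidate areas.

    Tiles sit on an aligned stride grid (origins are multiples of the
    stride, hence of 8 as stitching requires) and a tile is kept iff
    its level-0 footprint contains at least one candidate cell. Every
    candidate cell is covered by at least one kept tile; an empty
    candidate mask yields an empty plan.
    """
    if cand.level_scale != 128:
        raise ValueError("dense planning expects the 1/128 candidate mask")
    if stride % 8 != 0 or size % 8 != 0:
        raise ValueError("tile size and stride must be divisible by 8")
    w0, h0 = slide_dims
    fg = cand.data
    windows: list[Window] = []
    if fg.any():
        cs = cand.level_scale
        for y in _dense_grid_starts(h0, size, stride):
            cy0 = min(y // cs, fg.shape[0])
            cy1 = min((y + size - 1) // cs + 1, fg.shape[0])
            for x in _dense_grid_starts(w0, size, stride):
                cx0 = min(x // cs, fg.shape[1])
                cx1 = min((x + size - 1) // cs + 1, fg.shape[1])
                if fg[cy0:cy1, cx0:cx1].any():
                    windows.append(Window(x=x, y=y, size=size))
    return TilePlan(windows=windows, size=size, stride=stride, purpose="dense")


def full_grid_tile_count(slide_dims: tuple[int, int], size: int = DENSE_TILE_SIZE,
                         stride: int = DENSE_TILE_STRIDE) -> int:
    """Number of tiles a candidates-everywhere plan would visit."""
    w0, h0 = slide_dims
    return len(_dense_grid_starts(w0, size, stride)) * len(_dense_grid_starts(h0, size, stride))


def dense_pass(
    slide: SlidePyramid,
    plan: TilePlan,
    models: SegmenterModel | list[SegmenterModel],
) -> Heatmap:
    """Segment each planned tile and stitch into the 1/8 dense heatmap.

    With several models the per-tile predictions are ensemble-averaged
    before stitching. Regions never segmented keep probability 0.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    if not models:
        raise ValueError("need at least one segmenter")
    t0 = time.perf_counter()
    acc = HeatmapAccumulator.for_slide((slide.width0, slide.height0), level_scale=8)
    for w in _sorted_windows(plan.windows):
        patch = read_window(slide, w, level=0)
        preds = [np.asarray(m.predict(patch, w), dtype=np.float64) for m in models]
        pred = preds[0] if len(preds) == 1 else np.mean(preds, axis=0)
        accumulate_dense(acc, w, pred)
    hm = finalize(acc)
    full = full_grid_tile_count((slide.width0, slide.height0), plan.size, plan.stride)
    logger.info(
        "dense pass: %d/%d tiles (%.1f%%) in %.2fs",
        len(plan.windows), full, 100.0 * len(plan.windows) / max(full, 1),
        time.perf_counter() - t0,
    )
    return hm


def run_cascade(
    slide: SlidePyramid,
    tissue: MaskRaster,
    classifier: ClassifierModel,
    segmenters: SegmenterModel | list[SegmenterModel],
    thr: float = CANDIDATE_THRESHOLD,
    tile_size: int = DENSE_TILE_SIZE,
    tile_stride: int = DENSE_TILE_STRIDE,
) -> tuple[Heatmap, Heatmap, TilePlan]:
    """Full cascade: rough heatmap -> candidates -> dense heatmap.

    Returns (rough heatmap, dense heatmap, dense tile plan).
    """
    rough = rough_pass(slide, tissue, classifier)
    cand = select_candidates(rough, thr=thr)
    plan = plan_dense_tiles(cand, (slide.width0, slide.height0), size=tile_size, stride=tile_stride)
    dense = dense_pass(slide, plan, segmenters)
    return rough, dense, plan
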