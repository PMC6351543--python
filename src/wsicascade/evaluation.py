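"""Camelyon-style evaluation: slide AUC, lesion FROC, mIoU, bootstrap CIs.

Slide-level classification is scored by ROC AUC with the maximum
heatmap probability as the per-slide score. Lesion localization is
scored by FROC: a ground-truth lesion (8-connected component of the
tumor mask at heatmap scale) counts as detected at a threshold if at
least one detection point at or above the threshold falls inside it;
detections inside no lesion are false positives, and the FROC score is
the mean sensitivity at {0.25, 0.5, 1, 2, 4, 8} average false
positives per slide (linear interpolation of the sensitivity-FP
curve). Segmentation quality is measured by per-class intersection
over union:

    IoU_c = p_cc / (sum_j p_cj + sum_j p_jc - p_cc)

with mIoU the mean over the normal and tumor classes; a class absent
from both prediction and truth scores IoU 1. Confidence intervals use
the percentile bootstrap over slides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.measure import label as cc_label
from sklearn.metrics import roc_auc_score

from .pyramid_io import Heatmap, MaskRaster

__all__ = [
    "EvaluationCounts",
    "LesionSet",
    "Detection",
    "confusion_counts",
    "miou",
    "tumor_iou",
    "slide_auc",
    "lesions_from_mask",
    "heatmap_to_detections",
    "froc",
    "bootstrap_ci",
]

FROC_FP_RATES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class Detection:
    """Candidate lesion detection: (x, y) at heatmap scale plus score."""

    x: int
    y: int
    probability: float


@dataclass
class LesionSet:
    """Connected tumor regions as a labeled raster (0 = background)."""

    labels: np.ndarray
    n_lesions: int


@dataclass(frozen=True)
class EvaluationCounts:
    """2x2 pixel confusion counts; p[i, j] = #pixels with truth i, prediction j."""

    p: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.p).shape != (2, 2):
            raise ValueError("expected a 2x2 count matrix")


def confusion_counts(gt: np.ndarray, pred: np.ndarray) -> EvaluationCounts:
    """Count pixels into the 2x2 truth-by-prediction confusion matrix."""
    gt = np.asarray(gt).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction shapes differ")
    p = np.zeros((2, 2), dtype=np.int64)
    for i in (0, 1):
        for j in (0, 1):
            p[i, j] = np.count_nonzero((gt == bool(i)) & (pred == bool(j)))
    return EvaluationCounts(p=p)


def _iou_class(p: np.ndarray, c: int) -> float:
    denom = p[c, :].sum() + p[:, c].sum() - p[c, c]
    if denom == 0:
        return 1.0  # class absent from both truth and prediction
    return float(p[c, c] / denom)


def miou(counts: EvaluationCounts) -> float:
    """Mean IoU over the normal (0) and tumor (1) classes."""
    return 0.5 * (_iou_class(counts.p, 0) + _iou_class(counts.p, 1))


def tumor_iou(counts: EvaluationCounts) -> float:
    """IoU of the tumor class."""
    return _iou_class(counts.p, 1)


def slide_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC of per-slide max-probability scores (midrank ties)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs both tumor and normal slides")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


# ---------------------------------------------------------------------------
# FROC
# ---------------------------------------------------------------------------

def lesions_from_mask(mask: MaskRaster | np.ndarray) -> LesionSet:
    """8-connected components of a binary tumor mask at heatmap scale."""
    data = mask.data if isinstance(mask, MaskRaster) else np.asarray(mask)
    labels, n = cc_label(data > 0, connectivity=2, return_num=True)
    return LesionSet(labels=labels, n_lesions=int(n))


def heatmap_to_detections(hm: Heatmap, thr: float = 0.5) -> list[Detection]:
    """One detection per connected component of ``hm > thr``.

    Each component is reported at its argmax position with its maximum
    probability as the score. Component structure (and hence the
    detection count) depends on the threshold: blobs that merge at a
    lower threshold yield a single detection.
    """
    data = hm.data
    labels, n = cc_label(data > thr, connectivity=2, return_num=True)
    out = []
    for k in range(1, n + 1):
        ys, xs = np.nonzero(labels == k)
        vals = data[ys, xs]
        i = int(np.argmax(vals))
        out.append(Detection(x=int(xs[i]), y=int(ys[i]), probability=float(vals[i])))
    return out


def _froc_curve(
    per_slide: Sequence[tuple[LesionSet, Sequence[Detection]]],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sensitivity-vs-FP/slide curve over all detection-score thresholds.

    Returns (avg FPs per slide, sensitivity, total lesions), sorted by
    increasing FP rate with duplicate FP rates collapsed to their best
    sensitivity.
    """
    n_slides = len(per_slide)
    lesion_scores: list[float] = []  # best detection score inside each lesion
    fp_scores: list[float] = []
    total_lesions = 0
    for lesions, dets in per_slide:
        total_lesions += lesions.n_lesions
        best = np.full(lesions.n_lesions + 1, -np.inf)
        for d in dets:
            lab = 0
            if 0 <= d.y < lesions.labels.shape[0] and 0 <= d.x < lesions.labels.shape[1]:
                lab = int(lesions.labels[d.y, d.x])
            if lab > 0:
                best[lab] = max(best[lab], d.probability)
            else:
                fp_scores.append(d.probability)
        lesion_scores.extend(best[1:].tolist())
    if total_lesions == 0:
        raise ValueError("FROC undefined: no tumor lesions in cohort")

    thresholds = sorted(
        {d.probability for _, dets in per_slide for d in dets}, reverse=True
    )
    lesion_arr = np.asarray(lesion_scores)
    fp_arr = np.asarray(fp_scores)
    fps, sens = [], []
    for t in thresholds:
        sens.append(np.count_nonzero(lesion_arr >= t) / total_lesions)
        fps.append(np.count_nonzero(fp_arr >= t) / n_slides)
    if not thresholds:
        return np.array([0.0]), np.array([0.0]), total_lesions

    fps = np.asarray(fps)
    sens = np.asarray(sens)
    # collapse duplicate FP rates, keeping the highest sensitivity
    order = np.argsort(fps, kind="stable")
    fps, sens = fps[order], sens[order]
    uniq_fps, idx = np.unique(fps, return_index=True)
    uniq_sens = np.array([sens[fps == f].max() for f in uniq_fps])
    return uniq_fps, uniq_sens, total_lesions


def froc(
    per_slide: Sequence[tuple[LesionSet, Sequence[Detection]]],
    fp_rates: Sequence[float] = FROC_FP_RATES,
) -> float:
    """FROC score: mean sensitivity at the stated avg-FP-per-slide rates.

    Sensitivity between curve points is linearly interpolated; below
    the smallest achieved FP rate the curve's first sensitivity is
    used, above the largest its last (the curve is a step-free
    interpolant of the achieved operating points).
    """
    fps, sens, _ = _froc_curve(per_slide)
    return float(np.mean(np.interp(np.asarray(fp_rates, dtype=float), fps, sens)))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    metric: Callable[[list], float],
    slide_data: Sequence,
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a slide-level metric.

    Resamples slides with replacement (same size as the cohort) B
    times and returns the 2.5th and 97.5th percentiles of the metric.
    Replicates where the metric is undefined (e.g. a resample with a
    single class) are skipped.
    """
    n = len(slide_data)
    if n == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(metric([slide_data[i] for i in idx]))
        except ValueError:
            continue
    if not vals:
        raise ValueError("metric undefined on all bootstrap resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)
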