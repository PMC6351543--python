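"""Model inference contracts, training losses, and oracle test doubles.

The cascade is model-agnostic: any classifier mapping a 299x299 patch
to a tumor probability, and any segmenter mapping an LxL patch to an
(L/8)x(L/8) probability raster, can drive it. Both receive the patch
pixels and the level-0 window so that ground-truth-backed oracles (for
testing the pipeline without trained networks) can look up coordinates
while real networks use the pixels.

The two losses are the cross-entropy objectives of the two stages: the
patch loss averages binary cross-entropy over patch labels in a batch;
the pixel loss averages it over the (L/8)^2 output lattice, comparing
prediction p(x, y) with the mask sampled at the stride-8 lattice point
m(8x, 8y).
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .pyramid_io import MaskRaster, Window

__all__ = [
    "ClassifierModel",
    "SegmenterModel",
    "pixel_loss",
    "patch_loss",
    "OracleClassifier",
    "OracleSegmenter",
    "oracle_classifier",
    "oracle_segmenter",
]

#: Probability clipping for the log terms.
EPS = 1e-7


@runtime_checkable
class ClassifierModel(Protocol):
    """Patch-level tumor classifier: one probability per patch."""

    def predict(self, patch: np.ndarray, window: Window) -> float: ...


@runtime_checkable
class SegmenterModel(Protocol):
    """Dense segmenter: LxL patch -> (L/8)x(L/8) probability raster."""

    def predict(self, patch: np.ndarray, window: Window) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def pixel_loss(p: np.ndarray, m: np.ndarray, L: int | None = None) -> float:
    """Per-patch segmentation loss.

    ``p`` is the (L/8)x(L/8) predicted probability raster, ``m`` the
    LxL binary mask of the input patch (tumor = 1). The mask is sampled
    at the stride-8 lattice (nearest point, no averaging) and the loss
    is

        -(8/L)^2 * sum_{x,y} [ m(8x,8y) ln p(x,y)
                               + (1 - m(8x,8y)) ln(1 - p(x,y)) ]

    with probabilities clipped to [EPS, 1-EPS].
    """
    p = np.asarray(p, dtype=np.float64)
    m = np.asarray(m)
    if L is None:
        L = m.shape[0]
    if L % 8 != 0:
        raise ValueError(f"patch side L={L} not divisible by 8")
    side = L // 8
    if p.shape != (side, side):
        raise ValueError(f"prediction shape {p.shape} != ({side}, {side})")
    if m.shape[0] < L or m.shape[1] < L:
        raise ValueError(f"mask smaller than {L}x{L}")
    m8 = m[0:L:8, 0:L:8].astype(np.float64)
    pc = np.clip(p, EPS, 1.0 - EPS)
    ll = m8 * np.log(pc) + (1.0 - m8) * np.log(1.0 - pc)
    return float(-ll.sum() / side**2)


def patch_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Batch classification loss: mean binary cross-entropy.

        -(1/n) * sum_i [ g_i ln p_i + (1 - g_i) ln(1 - p_i) ]
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape or p.size == 0:
        raise ValueError("batch must be non-empty with matching shapes")
    pc = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)))


# ---------------------------------------------------------------------------
# Oracle models
# ---------------------------------------------------------------------------

def _window_rng(seed: int, w: Window) -> np.random.Generator:
    # Per-window stream: predictions are pure functions of the window,
    # independent of call order.
    return np.random.default_rng([seed, w.x, w.y])


class OracleClassifier:
    """Ground-truth-backed classifier test double.

    With ``noise_sd = 0`` it returns 1 exactly when the window contains
    a tumor pixel, reproducing the patch labeling rule; otherwise
    Gaussian noise is added and the result clipped to [0, 1].
    """

    def __init__(self, gt: MaskRaster, noise_sd: float = 0.0, seed: int = 0):
        if gt.level_scale != 1:
            raise ValueError("oracle needs the level-0 ground truth")
        self.gt = gt
        self.noise_sd = float(noise_sd)
        self.seed = int(seed)

    def predict(self, patch: np.ndarray, window: Window) -> float:
        g = self.gt.data
        y1 = min(window.y + window.size, g.shape[0])
        x1 = min(window.x + window.size, g.shape[1])
        hit = 0.0
        if y1 > window.y and x1 > window.x:
            hit = float(g[window.y:y1, window.x:x1].any())
        if self.noise_sd > 0:
            hit += _window_rng(self.seed, window).normal(0.0, self.noise_sd)
        return float(np.clip(hit, 0.0, 1.0))


class OracleSegmenter:
    """Ground-truth-backed segmenter test double.

    Samples the ground truth at the stride-8 lattice of the window,
    flips each lattice value independently with probability
    ``flip_rate``, and maps {0, 1} to probabilities {0.1, 0.9}.
    """

    def __init__(self, gt: MaskRaster, flip_rate: float = 0.0, seed: int = 0):
        if gt.level_scale != 1:
            raise ValueError("oracle needs the level-0 ground truth")
        if not 0.0 <= flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")
        self.gt = gt
        self.flip_rate = float(flip_rate)
        self.seed = int(seed)

    def predict(self, patch: np.ndarray, window: Window) -> np.ndarray:
        if window.size % 8 != 0:
            raise ValueError("window size must be divisible by 8")
        side = window.size // 8
        g = self.gt.data
        lattice = np.zeros((side, side), dtype=np.uint8)
        y1 = min(window.y + window.size, g.shape[0])
        x1 = min(window.x + window.size, g.shape[1])
        if y1 > window.y and x1 > window.x:
            sub = g[window.y:y1:8, window.x:x1:8]
            lattice[: sub.shape[0], : sub.shape[1]] = sub
        if self.flip_rate > 0:
            flips = _window_rng(self.seed, window).random((side, side)) < self.flip_rate
            lattice = np.where(flips, 1 - lattice, lattice)
        return np.where(lattice == 1, 0.9, 0.1).astype(np.float64)


def oracle_classifier(gt: MaskRaster, noise_sd: float = 0.0, seed: int = 0) -> OracleClassifier:
    return OracleClassifier(gt, noise_sd=noise_sd, seed=seed)


def oracle_segmenter(gt: MaskRaster, flip_rate: float = 0.0, seed: int = 0) -> OracleSegmenter:
    return OracleSegmenter(gt, flip_rate=flip_rate, seed=seed)
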