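"""Evaluation metrics against independent oracles."""

import numpy as np
import pytest

from wsicascade.evaluation import (
    Detection,
    bootstrap_ci,
    confusion_counts,
    froc,
    heatmap_to_detections,
    lesions_from_mask,
    miou,
    slide_auc,
    tumor_iou,
)
from wsicascade.pyramid_io import Heatmap


def naive_miou(gt, pred):
    """Literal per-pixel counting over both classes."""
    gt, pred = np.asarray(gt).astype(int), np.asarray(pred).astype(int)
    ious = []
    for c in (0, 1):
        inter = union = 0
        for a, b in zip(gt.ravel(), pred.ravel()):
            if a == c and b == c:
                inter += 1
            if a == c or b == c:
                union += 1
        ious.append(inter / union if union else 1.0)
    return sum(ious) / 2


def mann_whitney_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_froc(per_slide, fp_rates=(0.25, 0.5, 1, 2, 4, 8)):
    """Threshold sweep with literal nested loops over lesions/detections."""
    n_slides = len(per_slide)
    total = sum(l.n_lesions for l, _ in per_slide)
    thresholds = sorted(
        {d.probability for _, dets in per_slide for d in dets}, reverse=True
    )
    if not thresholds:
        return 0.0
    pts = []
    for t in thresholds:
        hits, fps = 0, 0
        for lesions, dets in per_slide:
            found = set()
            for d in dets:
                if d.probability < t:
                    continue
                lab = int(lesions.labels[d.y, d.x])
                if lab > 0:
                    found.add(lab)
                else:
                    fps += 1
            hits += len(found)
        pts.append((fps / n_slides, hits / total))
    xs = sorted({p[0] for p in pts})
    ys = [max(s for f, s in pts if f == x) for x in xs]
    return float(np.mean(np.interp(fp_rates, xs, ys)))


class TestMiou:
    def test_perfect_prediction(self):
        gt = np.array([[1, 0], [1, 0]])
        assert miou(confusion_counts(gt, gt)) == 1.0

    def test_hand_counted_example(self):
        # GT: left column tumor; prediction: everything tumor
        gt = np.array([[1, 0], [1, 0]])
        pred = np.ones((2, 2))
        counts = confusion_counts(gt, pred)
        assert tumor_iou(counts) == 0.5
        assert miou(counts) == 0.25

    def test_complement_prediction_is_zero(self):
        gt = np.array([[1, 0], [1, 0]])
        assert miou(confusion_counts(gt, 1 - gt)) == 0.0

    def test_absent_class_scores_one(self):
        gt = np.zeros((4, 4))
        assert miou(confusion_counts(gt, gt)) == 1.0  # all-normal slide, perfect
        assert tumor_iou(confusion_counts(gt, gt)) == 1.0

    def test_matches_pixel_count_oracle(self, rng):
        for _ in range(20):
            gt = rng.random((12, 9)) > 0.6
            pred = rng.random((12, 9)) > 0.6
            assert miou(confusion_counts(gt, pred)) == pytest.approx(
                naive_miou(gt, pred), abs=1e-12
            )


class TestSlideAuc:
    def test_perfect_separation(self):
        assert slide_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_label_swap_complements(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        if len(set(labels.tolist())) < 2:
            labels[0], labels[1] = 0, 1
        a = slide_auc(scores, labels)
        b = slide_auc(scores, 1 - labels)
        assert a + b == pytest.approx(1.0)

    def test_midrank_tie_example(self):
        assert slide_auc([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_matches_mann_whitney_on_tie_free_scores(self, rng):
        scores = rng.permutation(30) / 30.0
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        assert slide_auc(scores, labels) == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            slide_auc([0.5, 0.6], [1, 1])


class TestFroc:
    def _lesions(self, shape, boxes):
        m = np.zeros(shape, dtype=np.uint8)
        for x0, y0, x1, y1 in boxes:
            m[y0:y1, x0:x1] = 1
        return lesions_from_mask(m)

    def test_all_lesions_hit_no_fps(self):
        les = self._lesions((20, 20), [(2, 2, 5, 5), (10, 10, 14, 14)])
        dets = [Detection(3, 3, 1.0), Detection(11, 11, 1.0)]
        assert froc([(les, dets)]) == 1.0

    def test_no_detections_scores_zero(self):
        les = self._lesions((20, 20), [(2, 2, 5, 5)])
        assert froc([(les, [])]) == 0.0

    def test_no_tumor_slides_is_undefined(self):
        les = self._lesions((20, 20), [])
        with pytest.raises(ValueError):
            froc([(les, [Detection(1, 1, 0.9)])])

    def test_matches_brute_force_sweep_on_constructed_case(self):
        # 2 slides, 2 lesions, mixed hits and false positives
        les1 = self._lesions((30, 30), [(2, 2, 6, 6)])
        dets1 = [Detection(3, 3, 0.9), Detection(20, 20, 0.7), Detection(25, 5, 0.3)]
        les2 = self._lesions((30, 30), [(10, 10, 16, 16)])
        dets2 = [Detection(12, 12, 0.4), Detection(1, 25, 0.8)]
        per_slide = [(les1, dets1), (les2, dets2)]
        assert froc(per_slide) == pytest.approx(brute_force_froc(per_slide), abs=1e-12)

    def test_matches_brute_force_on_random_cases(self, rng):
        for _ in range(10):
            per_slide = []
            any_lesion = False
            for _ in range(5):
                m = np.zeros((40, 40), dtype=np.uint8)
                for _ in range(int(rng.integers(0, 3))):
                    x, y = rng.integers(0, 32, 2)
                    m[y : y + 5, x : x + 5] = 1
                les = lesions_from_mask(m)
                any_lesion = any_lesion or les.n_lesions > 0
                dets = [
                    Detection(int(x), int(y), float(np.round(p, 2)))
                    for x, y, p in zip(
                        rng.integers(0, 40, 6), rng.integers(0, 40, 6), rng.random(6)
                    )
                ]
                per_slide.append((les, dets))
            if not any_lesion:
                continue
            assert froc(per_slide) == pytest.approx(
                brute_force_froc(per_slide), abs=1e-12
            )


class TestHeatmapToDetections:
    def test_single_blob_detected_at_its_max(self):
        data = np.zeros((10, 10), dtype=np.float32)
        data[2:5, 2:5] = 0.7
        data[3, 3] = 0.95
        dets = heatmap_to_detections(Heatmap(data=data, level_scale=8))
        assert len(dets) == 1
        assert (dets[0].x, dets[0].y, dets[0].probability) == (3, 3, pytest.approx(0.95))

    def test_empty_heatmap_no_detections(self):
        hm = Heatmap(data=np.zeros((5, 5), dtype=np.float32), level_scale=8)
        assert heatmap_to_detections(hm) == []

    def test_component_count_is_threshold_dependent(self):
        data = np.zeros((5, 9), dtype=np.float32)
        data[2, 1:4] = 0.8
        data[2, 5:8] = 0.8
        data[2, 4] = 0.55  # bridge visible only at low threshold
        hm = Heatmap(data=data, level_scale=8)
        assert len(heatmap_to_detections(hm, thr=0.7)) == 2
        assert len(heatmap_to_detections(hm, thr=0.5)) == 1


class TestBootstrap:
    def test_constant_metric_gives_degenerate_ci(self):
        lo, hi = bootstrap_ci(lambda d: 0.42, list(range(10)), B=200, seed=1)
        assert lo == hi == 0.42

    def test_seeded_reproducibility(self, rng):
        data = list(rng.random(20))
        m = lambda d: float(np.mean(d))  # noqa: E731
        assert bootstrap_ci(m, data, B=500, seed=7) == bootstrap_ci(m, data, B=500, seed=7)

    def test_ci_brackets_point_estimate(self, rng):
        data = list(rng.normal(5.0, 1.0, 50))
        m = lambda d: float(np.mean(d))  # noqa: E731
        lo, hi = bootstrap_ci(m, data, B=1000, seed=3)
        assert lo <= np.mean(data) <= hi
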