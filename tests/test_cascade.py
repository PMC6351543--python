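"""Cascade orchestration: rough pass, candidate selection, dense tiling."""

import numpy as np
import pytest

from conftest import make_gt
from wsicascade import SynthSpec, generate
from wsicascade.cascade import (
    dense_pass,
    full_grid_tile_count,
    plan_dense_tiles,
    rough_pass,
    run_cascade,
    select_candidates,
)
from wsicascade.model_contract import oracle_classifier, oracle_segmenter
from wsicascade.patch_sampler import TilePlan
from wsicascade.pyramid_io import Heatmap, MaskRaster, Window
from wsicascade.tissue_mask import compute_tissue_mask


def cand_mask(side, cells=()):
    data = np.zeros((side, side), dtype=np.uint8)
    for x, y in cells:
        data[y, x] = 1
    return MaskRaster(data=data, level_scale=128)


class TestSelectCandidates:
    @pytest.mark.parametrize("value,expected", [(0.4, 0), (0.6, 1), (0.5, 0)])
    def test_strict_threshold(self, value, expected):
        hm = Heatmap(data=np.full((4, 4), value, dtype=np.float32), level_scale=128)
        assert (select_candidates(hm).data == expected).all()


class TestPlanDenseTiles:
    def test_single_candidate_cell_selects_four_tiles(self):
        # cell (10,10) at scale 128 -> level-0 region [1280,1408)^2;
        # intersecting 2560-px tiles on the 1280 grid have origins {0,1280}^2
        plan = plan_dense_tiles(cand_mask(40, [(10, 10)]), (5120, 5120))
        origins = {(w.x, w.y) for w in plan.windows}
        assert origins == {(0, 0), (0, 1280), (1280, 0), (1280, 1280)}

    def test_empty_candidates_empty_plan(self):
        assert len(plan_dense_tiles(cand_mask(40), (5120, 5120))) == 0

    def test_candidates_everywhere_full_grid(self):
        full = MaskRaster(data=np.ones((40, 40), dtype=np.uint8), level_scale=128)
        plan = plan_dense_tiles(full, (5120, 5120))
        assert len(plan) == 9  # ((5120-2560)/1280 + 1)^2
        assert len(plan) == full_grid_tile_count((5120, 5120))

    def test_every_candidate_cell_covered(self, rng):
        cells = [(int(x), int(y)) for x, y in rng.integers(0, 32, size=(10, 2))]
        plan = plan_dense_tiles(cand_mask(32, cells), (4096, 4096))
        for cx, cy in cells:
            covered = any(
                w.x <= cx * 128 and cx * 128 + 128 <= w.x + w.size
                and w.y <= cy * 128 and cy * 128 + 128 <= w.y + w.size
                for w in plan.windows
            ) or any(  # edge cells may be covered only partially in-bounds
                w.x < (cx + 1) * 128 and w.x + w.size > cx * 128
                and w.y < (cy + 1) * 128 and w.y + w.size > cy * 128
                for w in plan.windows
            )
            assert covered

    def test_threshold_monotonicity(self, rng):
        hm = Heatmap(data=rng.random((32, 32)).astype(np.float32), level_scale=128)
        tiles_low = plan_dense_tiles(select_candidates(hm, 0.3), (4096, 4096))
        tiles_high = plan_dense_tiles(select_candidates(hm, 0.7), (4096, 4096))
        low = {(w.x, w.y) for w in tiles_low.windows}
        high = {(w.x, w.y) for w in tiles_high.windows}
        assert high <= low


class TestRoughPass:
    def test_zero_noise_oracle_marks_tumor_touching_cells(self, small_slide):
        slide, gt, _ = small_slide
        tissue = compute_tissue_mask(slide)
        hm = rough_pass(slide, tissue, oracle_classifier(gt))
        assert hm.level_scale == 128
        # each window writes its probability at its top-left cell: cells
        # of tumor-touching windows must be positive, all others zero
        from wsicascade.patch_sampler import label_patches, plan_rough_tiles

        plan = plan_rough_tiles(tissue, (slide.width0, slide.height0))
        tumor_cells = {
            (p.window.x // 128, p.window.y // 128)
            for p in label_patches(plan, gt)
            if p.label == 1
        }
        assert tumor_cells  # the blob is large enough to be seen
        for (cx, cy) in tumor_cells:
            assert hm.data[cy, cx] > 0
        lit = {(int(x), int(y)) for y, x in zip(*np.nonzero(hm.data))}
        assert lit.issuperset(tumor_cells)
        assert hm.data.max() == 1.0

    def test_empty_tissue_mask_gives_zero_heatmap(self, small_slide):
        slide, gt, _ = small_slide
        empty = MaskRaster(
            data=np.zeros((32, 32), dtype=np.uint8), level_scale=32
        )
        with pytest.warns(UserWarning):
            hm = rough_pass(slide, empty, oracle_classifier(gt))
        assert (hm.data == 0).all()

    def test_deterministic_across_runs(self, small_slide):
        slide, gt, _ = small_slide
        tissue = compute_tissue_mask(slide)
        clf = oracle_classifier(gt, noise_sd=0.1, seed=4)
        a = rough_pass(slide, tissue, clf)
        b = rough_pass(slide, tissue, clf)
        np.testing.assert_array_equal(a.data, b.data)


class TestDensePass:
    def test_zero_flip_oracle_recovers_lattice_ground_truth(self, small_slide):
        slide, gt, _ = small_slide
        tissue = compute_tissue_mask(slide)
        _, dense, plan = run_cascade(
            slide, tissue, oracle_classifier(gt), oracle_segmenter(gt),
            tile_size=512, tile_stride=256,
        )
        covered = dense.provenance > 0
        gt8 = gt.data[::8, ::8]
        np.testing.assert_array_equal(
            (dense.data > 0.5)[covered], gt8[covered] == 1
        )
        # all tumor lattice points are inside the covered region
        assert covered[gt8 == 1].all()

    def test_cascade_equals_full_segmentation_on_covered_area(self, small_slide):
        """Candidates-everywhere dense pass == full-slide tiled segmentation."""
        slide, gt, _ = small_slide
        dims = (slide.width0, slide.height0)
        seg = oracle_segmenter(gt, flip_rate=0.3, seed=7)  # nontrivial output
        everywhere = MaskRaster(
            data=np.ones((-(-dims[1] // 128), -(-dims[0] // 128)), dtype=np.uint8),
            level_scale=128,
        )
        plan_a = plan_dense_tiles(everywhere, dims, size=512, stride=256)
        from wsicascade.cascade import _dense_grid_starts

        full_windows = [
            Window(x, y, 512)
            for y in _dense_grid_starts(dims[1], 512, 256)
            for x in _dense_grid_starts(dims[0], 512, 256)
        ]
        plan_b = TilePlan(windows=full_windows, size=512, stride=256, purpose="dense")
        a = dense_pass(slide, plan_a, seg)
        b = dense_pass(slide, plan_b, seg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_overlapping_tiles_average_conflicting_noise(self, small_slide):
        slide, gt, _ = small_slide
        seg = oracle_segmenter(gt, flip_rate=0.4, seed=1)
        plan = TilePlan(
            windows=[Window(0, 0, 512), Window(256, 0, 512)],
            size=512, stride=256, purpose="dense",
        )
        hm = dense_pass(slide, plan, seg)
        pa = seg.predict(None, Window(0, 0, 512))
        pb = seg.predict(None, Window(256, 0, 512))
        overlap_expected = (pa[:, 32:] + pb[:, :32]) / 2.0
        np.testing.assert_allclose(
            hm.data[:64, 32:64], overlap_expected.astype(np.float32), atol=1e-7
        )

    def test_ensemble_of_identical_models_matches_single(self, small_slide):
        slide, gt, _ = small_slide
        seg = oracle_segmenter(gt, flip_rate=0.0)
        plan = TilePlan(windows=[Window(0, 0, 512)], size=512, stride=256)
        single = dense_pass(slide, plan, seg)
        double = dense_pass(slide, plan, [seg, seg])
        np.testing.assert_array_equal(single.data, double.data)
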