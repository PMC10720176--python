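"""Tiling, NMS, vignettes, mask back-projection and the frame pipeline."""

import numpy as np
import pytest

from berrytrack.detect_segment import (CONFIDENCE_THRESHOLD, MAX_TILE_SPACING,
                                       OraclePredictor, SegmentationError,
                                       TILE_SIZE, VignetteTransform,
                                       crop_vignette, filter_confidence,
                                       mask_to_ellipse, nms, plan_tiles,
                                       run_frame)
from berrytrack.geometry import Box, Ellipse, ellipse_iou, ellipse_to_bbox
from berrytrack.synthetic import render


class TestPlanTiles:
    def test_single_tile_image(self):
        plan = plan_tiles(416, 416)
        assert plan.offsets == ((0, 0),)

    def test_small_image_single_padded_tile(self):
        assert plan_tiles(400, 400).offsets == ((0, 0),)

    def test_full_frame_coverage_and_spacing(self):
        h, w = 2048, 2448
        plan = plan_tiles(h, w)
        cols = sorted({c for c, _ in plan.offsets})
        rows = sorted({r for _, r in plan.offsets})
        assert cols[0] == 0 and cols[-1] == w - TILE_SIZE
        assert rows[0] == 0 and rows[-1] == h - TILE_SIZE
        assert max(np.diff(cols)) <= MAX_TILE_SPACING
        assert max(np.diff(rows)) <= MAX_TILE_SPACING
        # oracle: boolean coverage mask fully true
        covered = np.zeros((h, w), dtype=bool)
        for c, r in plan.offsets:
            covered[r:r + TILE_SIZE, c:c + TILE_SIZE] = True
        assert covered.all()

    def test_rejects_empty_image(self):
        with pytest.raises(ValueError):
            plan_tiles(0, 100)


class TestNms:
    def test_identical_boxes_keep_best(self):
        a = Box(0, 0, 10, 10, 0.9)
        b = Box(0, 0, 10, 10, 0.8)
        assert nms([b, a]) == [a]

    def test_disjoint_kept(self):
        boxes = [Box(0, 0, 10, 10, 0.9), Box(100, 0, 10, 10, 0.5)]
        assert nms(boxes) == boxes

    def test_nested_pair_with_far_box(self):
        a = Box(0, 0, 10, 10, 0.9)
        b = Box(0, 0, 9, 9, 0.8)  # IoU vs a = 81/100 = 0.81 > 0.7
        c = Box(500, 500, 10, 10, 0.3)
        kept = nms([a, b, c])
        assert kept == [a, c]
        # brute force: no surviving pair above the threshold
        for i, x in enumerate(kept):
            for y in kept[i + 1:]:
                assert x.iou(y) <= 0.70


class TestFilterConfidence:
    def test_boundary_kept(self):
        boxes = [Box(0, 0, 1, 1, s) for s in (0.95, 0.89, 0.50)]
        kept = filter_confidence(boxes)
        assert [b.score for b in kept] == [0.95, 0.89]
        assert CONFIDENCE_THRESHOLD == 0.89

    def test_empty_and_all_kept(self):
        assert filter_confidence([]) == []
        boxes = [Box(0, 0, 1, 1, 1.0)] * 3
        assert filter_confidence(boxes) == boxes


class TestCropVignette:
    def test_box_96_at_centre(self):
        img = np.zeros((400, 400, 3), dtype=np.uint8)
        vignette, t = crop_vignette(img, Box(200, 200, 96, 96))
        assert vignette.shape == (128, 128, 3)
        assert t.crop_size == 128 and t.scale == pytest.approx(1.0)

    def test_box_48_scale_two(self):
        img = np.zeros((400, 400, 3), dtype=np.uint8)
        _, t = crop_vignette(img, Box(200, 200, 48, 48))
        assert t.crop_size == 64 and t.scale == pytest.approx(2.0)

    def test_border_crop_round_trip(self, rng):
        img = np.zeros((300, 300, 3), dtype=np.uint8)
        _, t = crop_vignette(img, Box(5, 290, 60, 80))  # hangs off two edges
        pts = rng.uniform(0, 128, (20, 2))
        cols, rows = t.to_image(pts[:, 0], pts[:, 1])
        back = np.column_stack(t.to_vignette(cols, rows))
        assert np.abs(back - pts).max() < 0.5


class TestMaskToEllipse:
    @staticmethod
    def identity_transform():
        return VignetteTransform(crop_center=(64, 64), crop_size=128,
                                 scale=1.0, crop_origin=(0, 0))

    def test_rasterized_ellipse_recovered(self):
        truth = Ellipse(40, 64, 50, 80, 0)
        cols, rows = np.meshgrid(np.arange(128) + 0.5, np.arange(128) + 0.5)
        mask = truth.contains(cols, rows)
        e = mask_to_ellipse(mask, self.identity_transform())
        assert abs(e.x_e - 40) < 1.0 and abs(e.y_e - 64) < 1.0
        assert abs(e.w_e - 50) < 1.0 and abs(e.h_e - 80) < 1.0
        d = abs(e.a_e - truth.a_e) % 180
        assert min(d, 180 - d) < 2.0

    def test_empty_mask_fails(self):
        with pytest.raises(SegmentationError):
            mask_to_ellipse(np.zeros((128, 128), bool), self.identity_transform())

    def test_largest_component_used(self):
        truth = Ellipse(64, 64, 40, 60, 30)
        cols, rows = np.meshgrid(np.arange(128) + 0.5, np.arange(128) + 0.5)
        mask = truth.contains(cols, rows)
        mask[:8, :8] = True  # small spurious blob
        e = mask_to_ellipse(mask, self.identity_transform())
        assert abs(e.x_e - 64) < 1.5 and abs(e.y_e - 64) < 1.5


class TestRunFrame:
    def test_blank_image_empty(self):
        img = np.zeros((512, 512, 3), dtype=np.uint8)
        pred = OraclePredictor([], [])
        assert run_frame(img, pred, confidence_threshold=0.5) == []

    def test_oracle_pipeline_recovers_ellipses(self, mini_render_run):
        gt = mini_render_run
        rec = gt.frames[0]
        img = render(gt, 0)
        pred = OraclePredictor(rec.ellipses, rec.visibility)
        dets = run_frame(img, pred, confidence_threshold=0.5)
        h, w = img.shape[:2]

        def inside_frame(e):
            x0, y0, x1, y1 = ellipse_to_bbox(e).bounds
            return x0 >= 0 and y0 >= 0 and x1 <= w and y1 <= h

        # berries overhanging the frame border are not measurable (their
        # box is never fully inside a tile); all interior ones must be found
        expected = [e for e, v in zip(rec.ellipses, rec.visibility)
                    if v >= 0.5 and inside_frame(e)]
        assert len(dets) == len(expected)
        for d in dets:
            best = max(ellipse_iou(d.ellipse, t) for t in expected)
            assert best >= 0.9

    def test_heavily_occluded_berry_absent(self, mini_render_run):
        gt = mini_render_run
        rec = gt.frames[0]
        img = render(gt, 0)
        # force one berry to 30% visibility
        vis = list(rec.visibility)
        vis[0] = 0.3
        pred = OraclePredictor(rec.ellipses, vis)
        dets = run_frame(img, pred, confidence_threshold=0.5)
        hidden = rec.ellipses[0]
        for d in dets:
            assert ellipse_iou(d.ellipse, hidden) < 0.9

    def test_no_redundant_pairs_survive(self, mini_render_run):
        gt = mini_render_run
        rec = gt.frames[1]
        img = render(gt, 1)
        dets = run_frame(img, OraclePredictor(rec.ellipses, rec.visibility),
                         confidence_threshold=0.5)
        boxes = [ellipse_to_bbox(d.ellipse) for d in dets]
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                assert a.iou(b) <= 0.70 + 1e-9


class TestOraclePredictor:
    def test_visibility_rule_boundary(self):
        e = Ellipse(100, 100, 30, 40, 0)
        below = OraclePredictor([e], [0.49])
        assert below.detect(np.zeros((416, 416, 3)), (0, 0)) == []
        above = OraclePredictor([e], [1.0])
        boxes = above.detect(np.zeros((416, 416, 3)), (0, 0))
        ref = ellipse_to_bbox(e)
        assert len(boxes) == 1
        assert boxes[0].w_b == pytest.approx(ref.w_b)
        assert boxes[0].h_b == pytest.approx(ref.h_b)

    def test_segment_returns_complete_shape_despite_occlusion(self):
        """The mask is the full ellipse, not the visible crescent."""
        e = Ellipse(64, 64, 50, 60, 0)
        pred = OraclePredictor([e], [0.55])
        t = VignetteTransform(crop_center=(64, 64), crop_size=128, scale=1.0,
                              crop_origin=(0, 0))
        mask = pred.segment(np.zeros((128, 128, 3)), t)
        assert mask.sum() == pytest.approx(e.area, rel=0.05)
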