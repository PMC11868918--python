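"""Annotation, detection, matching metrics and box-format interchange."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechscope import (
    AnnotationSet,
    DetectionBox,
    SceneConfig,
    auto_annotate_from_fluorescence,
    detect_brightfield,
    ground_truth_annotations,
    iou,
    match_detections,
    read_boxes,
    render_images,
    sample_scene,
    write_boxes,
)
from mechscope.scene_sim import ImageSet, TYPE_A, TYPE_B


def box(label, x0, y0, x1, y1, conf=1.0):
    return DetectionBox(label, x0, y0, x1, y1, conf)


class TestIoU:
    def test_identical_boxes(self):
        b = box(TYPE_A, 0, 0, 10, 10)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(TYPE_A, 0, 0, 5, 5), box(TYPE_A, 6, 6, 10, 10)) == 0.0

    def test_unit_offset_overlap(self):
        # pixel-counting oracle: boxes (0,0,2,2) and (1,1,3,3) share 1 of 7 pixels
        assert iou(box(TYPE_A, 0, 0, 2, 2), box(TYPE_A, 1, 1, 3, 3)) == pytest.approx(1 / 7)

    @given(
        x0=st.floats(0, 50), y0=st.floats(0, 50),
        w=st.floats(1, 30), h=st.floats(1, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_symmetric(self, x0, y0, w, h):
        a = box(TYPE_A, x0, y0, x0 + w, y0 + h)
        b = box(TYPE_A, 10, 10, 35, 28)
        assert 0.0 <= iou(a, b) <= 1.0
        assert iou(a, b) == pytest.approx(iou(b, a))


class TestMatching:
    def test_perfect_predictions(self):
        truth = AnnotationSet("img", 100, 100, [box(TYPE_A, 0, 0, 10, 10), box(TYPE_B, 20, 20, 40, 40)])
        m = match_detections(truth, truth)
        assert m.precision == 1.0 and m.recall == 1.0

    def test_empty_predictions_zero_over_zero(self):
        truth = AnnotationSet("img", 100, 100, [box(TYPE_A, 0, 0, 10, 10)])
        pred = AnnotationSet("img", 100, 100, [])
        m = match_detections(pred, truth)
        assert m.precision == 1.0  # 0/0 convention
        assert m.recall == 0.0

    def test_mislabeled_prediction_counted_both_ways(self):
        # 3 truths; 2 correct predictions + 1 mislabeled -> P = R = 2/3
        truth = AnnotationSet("img", 100, 100, [
            box(TYPE_A, 0, 0, 10, 10), box(TYPE_A, 20, 0, 30, 10), box(TYPE_B, 40, 0, 50, 10),
        ])
        pred = AnnotationSet("img", 100, 100, [
            box(TYPE_A, 0, 0, 10, 10), box(TYPE_A, 20, 0, 30, 10), box(TYPE_A, 40, 0, 50, 10),
        ])
        m = match_detections(pred, truth)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)

    def test_spurious_prediction_never_raises_precision(self):
        truth = AnnotationSet("img", 100, 100, [box(TYPE_A, 0, 0, 10, 10)])
        pred_good = AnnotationSet("img", 100, 100, [box(TYPE_A, 0, 0, 10, 10)])
        pred_extra = AnnotationSet("img", 100, 100, [box(TYPE_A, 0, 0, 10, 10), box(TYPE_A, 50, 50, 60, 60)])
        assert match_detections(pred_extra, truth).precision <= match_detections(pred_good, truth).precision

    def test_mismatched_image_refs_error(self):
        a = AnnotationSet("img1", 100, 100, [])
        b = AnnotationSet("img2", 100, 100, [])
        with pytest.raises(ValueError):
            match_detections(a, b)


class TestAutoAnnotate:
    def test_blank_channels_empty(self):
        blank = np.full((128, 128), 500, dtype=np.uint16)
        images = ImageSet(brightfield=blank, fluor_red=blank.copy(), fluor_green=blank.copy())
        ann = auto_annotate_from_fluorescence(images)
        assert ann.boxes == []

    def test_single_cell_box_contains_center(self, low_scene):
        cfg, gt, images = low_scene
        ann = auto_annotate_from_fluorescence(images)
        # every ground-truth cell center falls inside a same-type box
        for cell in gt.cells:
            cx, cy = cell.center_px
            hits = [
                b for b in ann.boxes
                if b.label == cell.cell_type and b.x_min <= cx < b.x_max and b.y_min <= cy < b.y_max
            ]
            assert hits, f"cell {cell.cell_id} not covered"

    def test_high_density_iou_ge_half_for_95pct(self, high_scene):
        cfg, gt, images = high_scene
        truth = ground_truth_annotations(gt)
        ann = auto_annotate_from_fluorescence(images)
        cells_truth = [b for b in truth.boxes if b.label != "probe"]
        matched = 0
        used = [False] * len(ann.boxes)
        for t in cells_truth:
            best, best_k = 0.0, -1
            for k, p in enumerate(ann.boxes):
                if used[k] or p.label != t.label:
                    continue
                v = iou(p, t)
                if v > best:
                    best, best_k = v, k
            if best >= 0.5:
                matched += 1
                used[best_k] = True
        assert matched / len(cells_truth) >= 0.95

    def test_never_assigns_red_label_against_overlap(self, high_scene):
        """No box is labeled typeA when its green overlap exceeds its red overlap."""
        from scipy import ndimage
        from skimage import filters

        _, _, images = high_scene
        ann = auto_annotate_from_fluorescence(images)
        red = images.fluor_red.astype(float)
        green = images.fluor_green.astype(float)
        red_fg = red > filters.threshold_otsu(red)
        green_fg = green > filters.threshold_otsu(green)
        for b in ann.boxes:
            ys = slice(int(b.y_min), int(b.y_max))
            xs = slice(int(b.x_min), int(b.x_max))
            r, g = red_fg[ys, xs].sum(), green_fg[ys, xs].sum()
            if b.label == TYPE_A:
                assert r >= g
            elif b.label == TYPE_B:
                assert g >= r


class TestDetector:
    def test_blank_image_empty(self):
        ann = detect_brightfield(np.full((160, 160), 20000, dtype=np.uint16))
        assert ann.boxes == []

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            detect_brightfield(np.zeros((10, 10, 3)))

    def test_two_isolated_cells_detected_with_labels(self):
        cfg = SceneConfig.low_density(n_cells_per_type=1)
        gt = sample_scene(cfg, seed=2)
        images = render_images(gt, cfg)
        det = detect_brightfield(images.brightfield)
        truth = ground_truth_annotations(gt)
        m = match_detections(det, truth)
        assert m.precision == 1.0 and m.recall == 1.0

    def test_deterministic(self, high_scene):
        _, _, images = high_scene
        a = detect_brightfield(images.brightfield)
        b = detect_brightfield(images.brightfield)
        assert a.boxes == b.boxes

    def test_probe_found_and_unique(self, high_scene):
        _, gt, images = high_scene
        det = detect_brightfield(images.brightfield)
        probe = det.probe_box
        assert probe is not None
        px, py = probe.center
        assert np.hypot(px - gt.probe_center_px[0], py - gt.probe_center_px[1]) < 5


class TestBoxFormats:
    @pytest.fixture()
    def annset(self):
        return AnnotationSet("img", 100, 100, [
            box(TYPE_A, 3.5, 4.25, 20, 30, 0.75),
            box(TYPE_B, 40, 40, 90, 85, 0.5),
            box("probe", 60, 5, 80, 25, 1.0),
        ])

    @pytest.mark.parametrize("fmt", ["yolo_txt", "coco_json"])
    def test_round_trip(self, tmp_path, annset, fmt):
        p = tmp_path / f"boxes.{fmt}"
        write_boxes(annset, p, fmt)
        back = read_boxes(p, fmt, width_px=100, height_px=100, image_ref="img")
        assert len(back.boxes) == 3
        for a, b in zip(annset.boxes, back.boxes):
            assert a.label == b.label
            for attr in ("x_min", "y_min", "x_max", "y_max", "confidence"):
                assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-6)

    def test_yolo_line_arithmetic(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n")
        ann = read_boxes(p, "yolo_txt", width_px=100, height_px=100)
        b = ann.boxes[0]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (40.0, 40.0, 60.0, 60.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_boxes(p, "yolo_txt", width_px=10, height_px=10).boxes == []

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\nnot a box\n")
        with pytest.raises(ValueError, match=":2"):
            read_boxes(p, "yolo_txt", width_px=10, height_px=10)


class TestBoxInvariants:
    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            DetectionBox(TYPE_A, 5, 5, 5, 10)

    def test_two_probes_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet("img", 10, 10, [box("probe", 0, 0, 2, 2), box("probe", 5, 5, 8, 8)])
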