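"""Annotation and detection of cells and the probe in co-culture images.

Two routes produce labeled bounding boxes:

* :func:`auto_annotate_from_fluorescence` — the dataset-preparation route:
  each fluorescence channel is thresholded and split into per-cell
  components, which become boxes of the channel's cell type.
* :func:`detect_brightfield` — the label-free route: a classical detector
  that works on the bright-field image alone (band-pass filtering, marker
  seeded segmentation of cell candidates, fixed linear decision rules on
  per-candidate features, annular template matching for the probe).
  Externally produced boxes (e.g., from a trained network) can be plugged in
  through :func:`read_boxes` instead; the pipeline contract is simply
  "boxes in, moves out".

Evaluation uses greedy confidence-ordered one-to-one matching at a fixed IoU
threshold with per-label precision/recall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

from .scene_sim import ImageSet, SceneGroundTruth, cell_bounding_box, TYPE_A, TYPE_B

__all__ = [
    "PROBE",
    "DetectionBox",
    "AnnotationSet",
    "DetectionMetrics",
    "DetectorConfig",
    "auto_annotate_from_fluorescence",
    "detect_brightfield",
    "iou",
    "match_detections",
    "read_boxes",
    "write_boxes",
    "ground_truth_annotations",
]

PROBE = "probe"
LABELS = (TYPE_A, TYPE_B, PROBE)


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned half-open box [x_min, x_max) x [y_min, y_max) in pixels."""

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box must have positive extent")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class AnnotationSet:
    image_ref: str
    width_px: int
    height_px: int
    boxes: list[DetectionBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_probe = sum(1 for b in self.boxes if b.label == PROBE)
        if n_probe > 1:
            raise ValueError("at most one probe box per image")

    def by_label(self, label: str) -> list[DetectionBox]:
        return [b for b in self.boxes if b.label == label]

    @property
    def probe_box(self) -> DetectionBox | None:
        boxes = self.by_label(PROBE)
        return boxes[0] if boxes else None


@dataclass(frozen=True)
class DetectionMetrics:
    """Greedy-matching detection metrics; 0/0 ratios are defined as 1."""

    tp: int
    fp: int
    fn: int
    per_label: dict
    iou_threshold: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection over union under the half-open box convention."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def ground_truth_annotations(gt: SceneGroundTruth, image_ref: str = "scene") -> AnnotationSet:
    """Truth boxes (raster-mask bounding boxes) for evaluating detections."""
    shape = (gt.image_height_px, gt.image_width_px)
    boxes = []
    for cell in gt.cells:
        x0, y0, x1, y1 = cell_bounding_box(cell, shape)
        boxes.append(DetectionBox(cell.cell_type, x0, y0, x1, y1, 1.0))
    r = gt.probe_radius_px
    cx, cy = gt.probe_center_px
    boxes.append(
        DetectionBox(
            PROBE,
            max(cx - r, 0.0),
            max(cy - r, 0.0),
            min(cx + r, gt.image_width_px),
            min(cy + r, gt.image_height_px),
            1.0,
        )
    )
    return AnnotationSet(image_ref, gt.image_width_px, gt.image_height_px, boxes)


# ---------------------------------------------------------------------------
# fluorescence-assisted annotation
# ---------------------------------------------------------------------------

def _split_components(mask: np.ndarray, min_area_px: int, min_distance: int = 8) -> list[tuple[float, float, float, float]]:
    """Boxes of per-cell components: threshold mask -> distance-transform
    watershed so touching same-type cells are split into individual boxes."""
    if not mask.any():
        return []
    dist = ndimage.distance_transform_edt(mask)
    peaks = feature.peak_local_max(dist, min_distance=min_distance, labels=mask, exclude_border=False)
    if len(peaks) == 0:
        labels = measure.label(mask)
    else:
        markers = np.zeros(mask.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-dist, markers, mask=mask)
    out = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        y0, x0, y1, x1 = region.bbox
        out.append((float(x0), float(y0), float(x1), float(y1)))
    return out


def auto_annotate_from_fluorescence(
    images: ImageSet,
    min_area_px: int = 60,
    threshold_method: Literal["otsu", "fixed"] = "otsu",
    fixed_threshold: float = 0.25 * 65535,
    image_ref: str = "scene",
) -> AnnotationSet:
    """Derive cell boxes from the fluorescence channels.

    Each channel is thresholded (Otsu by default) and split into per-cell
    components; components of area >= ``min_area_px`` become boxes labeled
    typeA (red channel) / typeB (green channel) with confidence 1.0.  A
    component visible in both channels is assigned the label with the larger
    overlap area.  Blank channels yield no boxes.
    """
    if images.fluor_red.shape != images.fluor_green.shape:
        raise ValueError("fluorescence channels must share dimensions")
    H, W = images.fluor_red.shape

    masks = {}
    for label, chan in ((TYPE_A, images.fluor_red), (TYPE_B, images.fluor_green)):
        arr = chan.astype(float)
        if threshold_method == "otsu":
            # Otsu on a blank channel just splits noise; require real contrast
            # between the two classes before accepting the foreground
            if arr.std() == 0:
                fg = np.zeros(arr.shape, dtype=bool)
            else:
                t = filters.threshold_otsu(arr)
                fg = arr > t
                if fg.any() and (~fg).any():
                    contrast = arr[fg].mean() - arr[~fg].mean()
                    if contrast < 10.0 * arr[~fg].std() or fg.mean() < 0.001:
                        fg = np.zeros(arr.shape, dtype=bool)
                else:
                    fg = np.zeros(arr.shape, dtype=bool)
        else:
            fg = arr > fixed_threshold
        fg = ndimage.binary_opening(fg, iterations=1)
        masks[label] = fg

    boxes: list[DetectionBox] = []
    for label in (TYPE_A, TYPE_B):
        other = TYPE_B if label == TYPE_A else TYPE_A
        for x0, y0, x1, y1 in _split_components(masks[label], min_area_px):
            ys, xs = slice(int(y0), int(y1)), slice(int(x0), int(x1))
            own = int(masks[label][ys, xs].sum())
            cross = int(masks[other][ys, xs].sum())
            use = label if own >= cross else other
            boxes.append(DetectionBox(use, x0, y0, x1, y1, 1.0))
    return AnnotationSet(image_ref, W, H, boxes)


# ---------------------------------------------------------------------------
# classical bright-field detector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorConfig:
    """Fixed parameters of the default classical detector.

    Radii are in pixels and bracket the expected cell sizes; the type
    decision is a linear rule on (equivalent radius, interior texture
    energy), with larger/coarser candidates called typeB.
    """

    bandpass_low_sigma: float = 2.0
    bandpass_high_sigma: float = 18.0
    min_cell_radius_px: int = 7
    max_cell_radius_px: int = 28
    min_area_px: int = 80
    peak_min_distance: int = 7
    radius_split_px: float = 14.0
    texture_weight: float = 3.0
    box_inflation: float = 1.25
    nms_iou: float = 0.5
    probe_radius_px: float = 9.2


def _nms(boxes: list[DetectionBox], iou_threshold: float) -> list[DetectionBox]:
    ordered = sorted(enumerate(boxes), key=lambda t: (-t[1].confidence, t[0]))
    kept: list[DetectionBox] = []
    for _, box in ordered:
        if all(iou(box, k) < iou_threshold for k in kept):
            kept.append(box)
    return kept


def detect_brightfield(
    brightfield: np.ndarray,
    config: DetectorConfig | None = None,
    image_ref: str = "scene",
) -> AnnotationSet:
    """Detect cells and the probe from a bright-field image alone.

    Deterministic classical pipeline: (1) difference-of-Gaussians band-pass
    removes the illumination gradient; (2) the probe is found by annular
    template matching on the rim response and masked out; (3) foreground
    thresholding plus distance-transform peak markers and watershed propose
    per-cell candidates; (4) per-candidate features (equivalent radius, ring
    contrast, interior texture energy) feed a fixed linear rule that assigns
    typeA/typeB and a confidence in [0, 1]; (5) non-maximum suppression.
    """
    bf = np.asarray(brightfield, dtype=float)
    if bf.ndim != 2:
        raise ValueError("bright-field input must be a single-channel 2-D raster")
    if config is None:
        config = DetectorConfig()
    H, W = bf.shape

    smooth = ndimage.gaussian_filter(bf, config.bandpass_low_sigma)
    background = ndimage.gaussian_filter(bf, config.bandpass_high_sigma)
    band = smooth - background

    # pixel-noise scale of the raw image, for absolute significance gates
    dpix = np.diff(bf, axis=1).ravel()
    noise_sd = 1.4826 * float(np.median(np.abs(dpix - np.median(dpix)))) / np.sqrt(2.0) if dpix.size else 0.0

    # --- probe via annular template matching ---------------------------------
    pr = config.probe_radius_px
    tsize = int(np.ceil(pr * 1.3)) * 2 + 1
    cyx = tsize // 2
    yy, xx = np.mgrid[0:tsize, 0:tsize]
    rho = np.sqrt((yy - cyx) ** 2 + (xx - cyx) ** 2) / pr
    template = np.exp(-(((rho - 1.02) / 0.08) ** 2)) - 0.5 * (rho < 0.8)
    template -= template.mean()
    resp = feature.match_template(band, template, pad_input=True, mode="reflect")
    resp = np.nan_to_num(resp)
    py, px_ = np.unravel_index(int(np.argmax(resp)), resp.shape)
    # require both a good template correlation and an absolute rim amplitude
    # well above pixel noise, so featureless images yield no probe box
    zone = band[
        max(py - int(pr), 0) : min(py + int(pr) + 1, H),
        max(px_ - int(pr), 0) : min(px_ + int(pr) + 1, W),
    ]
    probe_ok = resp[py, px_] >= 0.45 and float(np.abs(zone).max()) >= 8.0 * noise_sd
    probe_box = None
    if probe_ok:
        probe_conf = float(np.clip(0.5 + 0.5 * resp[py, px_], 0.0, 1.0))
        probe_box = DetectionBox(
            PROBE,
            max(px_ - pr, 0.0),
            max(py - pr, 0.0),
            min(px_ + pr, float(W)),
            min(py + pr, float(H)),
            probe_conf,
        )

    # --- cell candidates -----------------------------------------------------
    # dome map: cells are rendered with a bright interior dome, so a smoothed
    # band-pass response peaks near each cell center even when cells touch
    dome = ndimage.gaussian_filter(band, 3.0)
    if probe_ok:
        # suppress the probe neighbourhood so it is not proposed as a cell
        yy, xx = np.mgrid[0:H, 0:W]
        probe_zone = (yy - py) ** 2 + (xx - px_) ** 2 <= (1.4 * pr) ** 2
        dome[probe_zone] = dome[~probe_zone].min() if (~probe_zone).any() else 0.0

    if dome.std() > 0:
        thresh = filters.threshold_otsu(dome)
        fg = dome > thresh
        # absolute gate: cell domes must rise well above the pixel-noise
        # floor, otherwise Otsu is just splitting background noise
        if fg.any() and (~fg).any():
            # the pixel-difference noise estimate also absorbs intracellular
            # texture, so it overestimates sensor noise on real scenes; 3x
            # still rejects featureless images by two orders of magnitude
            contrast = float(dome[fg].mean() - dome[~fg].mean())
            if contrast < 3.0 * noise_sd:
                fg = np.zeros_like(fg)
    else:
        fg = np.zeros(dome.shape, dtype=bool)
    fg = ndimage.binary_closing(fg, iterations=1)
    fg = ndimage.binary_fill_holes(fg)
    fg = ndimage.binary_opening(fg, iterations=1)

    peaks = feature.peak_local_max(
        dome, min_distance=config.peak_min_distance, labels=fg, exclude_border=False
    )
    boxes: list[DetectionBox] = []
    if len(peaks) > 0:
        markers = np.zeros(fg.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-dome, markers, mask=fg)

        highpass = bf - ndimage.gaussian_filter(bf, 1.5)
        tex_energy = ndimage.gaussian_filter(highpass**2, 2.0)
        global_tex = float(np.sqrt(np.mean(tex_energy[fg]))) if fg.any() else 1.0

        for region in measure.regionprops(labels):
            if region.area < config.min_area_px:
                continue
            r_eq = float(np.sqrt(region.area / np.pi))
            if not (config.min_cell_radius_px * 0.6 <= r_eq <= config.max_cell_radius_px * 1.5):
                continue
            y0, x0, y1, x1 = region.bbox
            # interior texture, away from the rim ring
            interior = ndimage.binary_erosion(labels[y0:y1, x0:x1] == region.label, iterations=3)
            if interior.sum() >= 16:
                tex = float(np.sqrt(np.mean(tex_energy[y0:y1, x0:x1][interior])))
            else:
                tex = float(np.sqrt(np.mean(tex_energy[tuple(region.coords.T)])))

            # center from the dome peak (robust to watershed cropping);
            # half-width from the equivalent radius, inflated because the
            # watershed region loses its overlap zones to neighbours
            py_, px2 = (float(v) for v in peaks[region.label - 1])
            r_box = config.box_inflation * r_eq
            bx0 = max(px2 - r_box, 0.0)
            by0 = max(py_ - r_box, 0.0)
            bx1 = min(px2 + r_box, float(W))
            by1 = min(py_ + r_box, float(H))
            # linear type rule: big & smooth -> typeB, small & textured -> typeA
            tex_norm = tex / max(global_tex, 1e-9)
            score = (r_eq - config.radius_split_px) / 3.0 - config.texture_weight * (tex_norm - 1.0)
            label = TYPE_B if score > 0 else TYPE_A
            conf = float(np.clip(1.0 / (1.0 + np.exp(-abs(score))), 0.0, 1.0))
            boxes.append(DetectionBox(label, bx0, by0, bx1, by1, conf))

    boxes = _nms(boxes, config.nms_iou)
    if probe_box is not None:
        boxes = boxes + [probe_box]
    return AnnotationSet(image_ref, W, H, boxes)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def match_detections(pred: AnnotationSet, truth: AnnotationSet, iou_threshold: float = 0.5) -> DetectionMetrics:
    """Greedy confidence-ordered one-to-one matching.

    A prediction is a true positive iff it matches an unmatched truth box of
    the same label with IoU >= threshold.  Remaining predictions are false
    positives; remaining truths are false negatives.  Confidence ties break
    by box order of appearance.
    """
    if pred.image_ref != truth.image_ref:
        raise ValueError(f"image references differ: {pred.image_ref!r} vs {truth.image_ref!r}")
    per_label = {}
    tp = fp = fn = 0
    for label in LABELS:
        p = sorted(
            [b for b in pred.boxes if b.label == label],
            key=lambda b: -b.confidence,
        )
        t = [b for b in truth.boxes if b.label == label]
        matched = [False] * len(t)
        l_tp = 0
        for pb in p:
            best_j, best_iou = -1, iou_threshold
            for j, tb in enumerate(t):
                if matched[j]:
                    continue
                v = iou(pb, tb)
                if v >= best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                matched[best_j] = True
                l_tp += 1
        l_fp = len(p) - l_tp
        l_fn = len(t) - l_tp
        per_label[label] = {"tp": l_tp, "fp": l_fp, "fn": l_fn}
        tp, fp, fn = tp + l_tp, fp + l_fp, fn + l_fn
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, per_label=per_label, iou_threshold=iou_threshold)


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

_CLASS_INDEX = {TYPE_A: 0, TYPE_B: 1, PROBE: 2}
_CLASS_NAME = {v: k for k, v in _CLASS_INDEX.items()}


def write_boxes(annotations: AnnotationSet, path: str | Path, format: Literal["yolo_txt", "coco_json"]) -> None:
    """Write boxes as YOLO txt (normalized cx cy w h) or COCO-style JSON ([x, y, w, h])."""
    path = Path(path)
    if format == "yolo_txt":
        W, H = annotations.width_px, annotations.height_px
        lines = []
        for b in annotations.boxes:
            cx, cy = b.center
            w = b.x_max - b.x_min
            h = b.y_max - b.y_min
            lines.append(
                f"{_CLASS_INDEX[b.label]} {cx / W:.9f} {cy / H:.9f} {w / W:.9f} {h / H:.9f} {b.confidence:.9f}"
            )
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "coco_json":
        payload = {
            "images": [{"id": 0, "file_name": annotations.image_ref,
                        "width": annotations.width_px, "height": annotations.height_px}],
            "categories": [{"id": i, "name": n} for n, i in _CLASS_INDEX.items()],
            "annotations": [
                {
                    "id": k,
                    "image_id": 0,
                    "category_id": _CLASS_INDEX[b.label],
                    "bbox": [b.x_min, b.y_min, b.x_max - b.x_min, b.y_max - b.y_min],
                    "score": b.confidence,
                }
                for k, b in enumerate(annotations.boxes)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_boxes(
    path: str | Path,
    format: Literal["yolo_txt", "coco_json"],
    width_px: int | None = None,
    height_px: int | None = None,
    image_ref: str | None = None,
) -> AnnotationSet:
    """Read boxes written by :func:`write_boxes` (or an external detector)."""
    path = Path(path)
    if format == "yolo_txt":
        if width_px is None or height_px is None:
            raise ValueError("yolo_txt requires image width_px and height_px")
        boxes = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if cls not in _CLASS_NAME:
                raise ValueError(f"{path}:{lineno}: unknown class index {cls}")
            boxes.append(
                DetectionBox(
                    _CLASS_NAME[cls],
                    (cx - w / 2) * width_px,
                    (cy - h / 2) * height_px,
                    (cx + w / 2) * width_px,
                    (cy + h / 2) * height_px,
                    conf,
                )
            )
        return AnnotationSet(image_ref or path.stem, width_px, height_px, boxes)
    elif format == "coco_json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed JSON at line {exc.lineno}") from exc
        img = payload["images"][0]
        cat_name = {c["id"]: c["name"] for c in payload.get("categories", [])} or _CLASS_NAME
        boxes = []
        for k, ann in enumerate(payload.get("annotations", [])):
            try:
                x, y, w, h = ann["bbox"]
                boxes.append(
                    DetectionBox(
                        cat_name[ann["category_id"]],
                        float(x), float(y), float(x + w), float(y + h),
                        float(ann.get("score", 1.0)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed annotation record {k}") from exc
        return AnnotationSet(image_ref or img.get("file_name", path.stem), img["width"], img["height"], boxes)
    raise ValueError(f"unknown format {format!r}")
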