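"""Probe-to-cell positional relationship and stage move planning.

The "central area" of a target cell is operationalized as its bounding-box
center.  Pixel coordinates map to stage micrometres through a least-squares
affine calibration; stage axis handedness and any flips live entirely inside
the affine, so no hidden sign conventions exist elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotate_detect import AnnotationSet, DetectionBox, PROBE
from .scene_sim import SceneGroundTruth, TYPE_A, TYPE_B

__all__ = [
    "CalibrationError",
    "TargetingError",
    "StageCalibration",
    "MovePlan",
    "box_center",
    "fit_calibration",
    "plan_move",
    "select_targets",
    "apply_move",
]


class CalibrationError(RuntimeError):
    pass


class TargetingError(RuntimeError):
    pass


@dataclass(frozen=True)
class StageCalibration:
    """Affine map from pixel coordinates to stage micrometres.

    ``coefficients`` is 2x3: stage = A @ (x_px, y_px) + t with A the left
    2x2 block and t the last column.
    """

    coefficients: tuple  # 2x3 nested tuple
    rms_residual_um: float

    def __post_init__(self) -> None:
        A = self.matrix[:, :2]
        if abs(np.linalg.det(A)) < 1e-12:
            raise CalibrationError("calibration linear part is singular")
        if self.rms_residual_um < 0:
            raise CalibrationError("residual must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float).reshape(2, 3)

    def pixel_to_stage(self, p_px) -> np.ndarray:
        p = np.asarray(p_px, dtype=float)
        M = self.matrix
        return M[:, :2] @ p + M[:, 2]

    def stage_to_pixel(self, p_um) -> np.ndarray:
        M = self.matrix
        return np.linalg.solve(M[:, :2], np.asarray(p_um, dtype=float) - M[:, 2])

    @classmethod
    def identity(cls) -> "StageCalibration":
        return cls(((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)), 0.0)

    @classmethod
    def scaling(cls, um_per_px: float) -> "StageCalibration":
        return cls(((um_per_px, 0.0, 0.0), (0.0, um_per_px, 0.0)), 0.0)


@dataclass(frozen=True)
class MovePlan:
    target_cell_id: int
    target_label: str
    dx_um: float
    dy_um: float
    predicted_probe_center_px: tuple[float, float]


def box_center(box: DetectionBox) -> tuple[float, float]:
    """Box center ((x_min+x_max)/2, (y_min+y_max)/2) — the targeting cross."""
    return box.center


def fit_calibration(pairs) -> StageCalibration:
    """Least-squares affine fit of >=3 non-collinear (pixel, stage-um) pairs."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise CalibrationError(f"need at least 3 calibration pairs, got {len(pairs)}")
    P = np.asarray([p for p, _ in pairs], dtype=float)
    S = np.asarray([s for _, s in pairs], dtype=float)
    # collinearity check on pixel points
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise CalibrationError("calibration pixel points are collinear")
    X = np.column_stack([P, np.ones(len(P))])
    coef, _, _, _ = np.linalg.lstsq(X, S, rcond=None)  # 3x2
    M = coef.T  # 2x3
    pred = X @ coef
    rms = float(np.sqrt(np.mean(np.sum((pred - S) ** 2, axis=1))))
    return StageCalibration(tuple(map(tuple, M)), rms)


def plan_move(probe_box: DetectionBox, cell_box: DetectionBox, cal: StageCalibration, cell_id: int = -1) -> MovePlan:
    """Stage displacement that brings the probe center onto the cell center."""
    if probe_box is None:
        raise TargetingError("no probe box available for move planning")
    if probe_box.label != PROBE:
        raise TargetingError(f"probe box has label {probe_box.label!r}")
    if cell_box.label not in (TYPE_A, TYPE_B):
        raise TargetingError(f"target box has non-cell label {cell_box.label!r}")
    c_cell = np.asarray(box_center(cell_box))
    c_probe = np.asarray(box_center(probe_box))
    delta = cal.pixel_to_stage(c_cell) - cal.pixel_to_stage(c_probe)
    return MovePlan(
        target_cell_id=cell_id,
        target_label=cell_box.label,
        dx_um=float(delta[0]),
        dy_um=float(delta[1]),
        predicted_probe_center_px=(float(c_cell[0]), float(c_cell[1])),
    )


def select_targets(
    annotations: AnnotationSet,
    n_per_type: int,
    border_margin_px: int = 5,
) -> list[DetectionBox]:
    """Pick measurement targets per cell type.

    Per label, boxes sorted by descending confidence (ties broken by order of
    appearance); boxes within ``border_margin_px`` of any image edge and
    boxes whose center lies inside the probe box are excluded; at most
    ``n_per_type`` per label.  May return fewer than requested.
    """
    probe = annotations.probe_box
    W, H = annotations.width_px, annotations.height_px
    out: list[DetectionBox] = []
    for label in (TYPE_A, TYPE_B):
        candidates = []
        for i, b in enumerate(annotations.boxes):
            if b.label != label:
                continue
            if (
                b.x_min < border_margin_px
                or b.y_min < border_margin_px
                or b.x_max > W - border_margin_px
                or b.y_max > H - border_margin_px
            ):
                continue
            cx, cy = b.center
            if probe is not None and probe.x_min <= cx < probe.x_max and probe.y_min <= cy < probe.y_max:
                continue
            candidates.append((i, b))
        candidates.sort(key=lambda t: (-t[1].confidence, t[0]))
        out.extend(b for _, b in candidates[:n_per_type])
    return out


def apply_move(gt: SceneGroundTruth, plan: MovePlan, cal: StageCalibration) -> SceneGroundTruth:
    """Execute a planned stage move on the virtual scene.

    The probe center is displaced by the inverse-calibrated stage move; with
    exact calibration the new center lands on the target box center.  Raises
    :class:`TargetingError` when the move would leave the image bounds.
    """
    M = cal.matrix[:, :2]
    delta_px = np.linalg.solve(M, np.array([plan.dx_um, plan.dy_um]))
    new_center = (gt.probe_center_px[0] + float(delta_px[0]), gt.probe_center_px[1] + float(delta_px[1]))
    if not (0 <= new_center[0] < gt.image_width_px and 0 <= new_center[1] < gt.image_height_px):
        raise TargetingError(
            f"move to {new_center} exits image bounds "
            f"({gt.image_width_px}x{gt.image_height_px})"
        )
    return replace(gt, probe_center_px=new_center)
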