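"""End-to-end virtual experiment orchestration.

Reproduces the workflow shape of image-recognition-assisted AFM force
spectroscopy: generate a co-culture scene, render images, detect cells and
the probe from the bright field, select targets, and for each target plan
and execute a stage move, record ``curves_per_cell`` force curves at the
probe position, analyze them, aggregate per cell, and summarize per type.

Defaults mirror the experimental design of the study the package emulates:
50 cells measured per type, 10 force curves per cell.  The master seed
deterministically derives all stage seeds, so two runs with the same config
are byte-identical in every CSV/JSON artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import force_analysis as fa
from . import population_stats as ps
from .annotate_detect import (
    AnnotationSet,
    DetectorConfig,
    detect_brightfield,
    ground_truth_annotations,
    match_detections,
    write_boxes,
)
from .scene_sim import (
    SceneConfig,
    SceneGroundTruth,
    TYPE_A,
    TYPE_B,
    render_images,
    sample_scene,
    write_image_set,
    write_scene_json,
    _cell_mask,
)
from .targeting import StageCalibration, apply_move, plan_move, select_targets
from .virtual_afm import (
    CantileverSpec,
    ForceCurve,
    RampConfig,
    simulate_indentation,
    simulate_scfs,
    write_curve_tsv,
)

__all__ = ["RunConfig", "RunResult", "run_experiment", "report"]

logger = logging.getLogger("mechscope")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one virtual experiment."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    cantilever: CantileverSpec = field(default_factory=lambda: CantileverSpec(noise_sd_nm=1.0, drift_nm_per_um=0.4))
    ramp: RampConfig = field(default_factory=RampConfig)
    n_cells_per_type: int = 50
    curves_per_cell: int = 10
    assay: Literal["indentation", "scfs"] = "indentation"
    master_seed: int = 0
    use_ground_truth_boxes: bool = False
    nu: float = 0.5
    detach_separation_um: float = 1.5
    n_rupture_steps: int = 3
    border_margin_px: int = 5

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunResult:
    run_dir: Path
    gt: SceneGroundTruth
    detections: AnnotationSet
    measurements: list[fa.CellMeasurement]
    summaries: dict
    comparison: ps.ComparisonReport | None
    exclusions: list[dict]


def _stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a deterministic per-stage seed below 2**31 from the master seed."""
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)  # stable across processes
    ss = np.random.SeedSequence([master_seed, tag, index])
    return int(ss.generate_state(1)[0] % (2**31))


def _cell_truth_at_probe(gt: SceneGroundTruth, probe_xy: tuple[float, float]):
    """The topmost cell whose mask contains the probe center, or None.

    Cells painted later occlude earlier ones, so the last matching cell in
    z-order is the one the probe actually touches.
    """
    shape = (gt.image_height_px, gt.image_width_px)
    x, y = int(round(probe_xy[0])), int(round(probe_xy[1]))
    x = min(max(x, 0), shape[1] - 1)
    y = min(max(y, 0), shape[0] - 1)
    hit = None
    for cell in gt.cells:
        rr, cc = _cell_mask(cell, shape)
        # membership test without building a full mask
        if ((rr == y) & (cc == x)).any():
            hit = cell
    return hit


def run_experiment(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute the full virtual experiment and write all artifacts.

    Pipeline: scene -> render -> detect -> select targets -> per target
    (plan move, apply move, simulate curves, analyze, aggregate) ->
    summarize and compare the two cell types.  Every selected target either
    yields ``curves_per_cell`` analyzed curves or a logged exclusion.
    """
    t_start = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "curves").mkdir(exist_ok=True)

    (out_dir / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1, default=float))
    logger.info("run_experiment: assay=%s master_seed=%d", config.assay, config.master_seed)

    # --- scene ---------------------------------------------------------------
    scene_seed = _stage_seed(config.master_seed, "scene")
    try:
        gt = sample_scene(config.scene, scene_seed)
    except Exception:
        logger.exception("stage=scene failed")
        raise
    write_scene_json(gt, out_dir / "scene_ground_truth.json")
    images = render_images(gt, config.scene)
    write_image_set(images, out_dir, stem="scene")

    # --- detect --------------------------------------------------------------
    if config.use_ground_truth_boxes:
        detections = ground_truth_annotations(gt)
    else:
        detections = detect_brightfield(images.brightfield, config.detector)
    write_boxes(detections, out_dir / "detections.json", "coco_json")
    truth_ann = ground_truth_annotations(gt)
    metrics = match_detections(detections, truth_ann, iou_threshold=0.5)
    (out_dir / "detection_metrics.json").write_text(
        json.dumps(
            {
                "precision": metrics.precision,
                "recall": metrics.recall,
                "tp": metrics.tp,
                "fp": metrics.fp,
                "fn": metrics.fn,
                "iou_threshold": metrics.iou_threshold,
                "per_label": metrics.per_label,
            },
            indent=1,
        )
    )

    # --- targeting -----------------------------------------------------------
    cal = StageCalibration.scaling(config.scene.pixel_size_um)
    targets = select_targets(detections, config.n_cells_per_type, config.border_margin_px)
    probe_box = detections.probe_box
    if probe_box is None:
        raise RuntimeError("stage=targeting: no probe detected in the scene")

    move_rows = []
    per_curve_rows = []
    measurements: list[fa.CellMeasurement] = []
    exclusions: list[dict] = []

    for t_idx, target in enumerate(targets):
        plan = plan_move(probe_box, target, cal, cell_id=t_idx)
        move_rows.append(
            {
                "cell_id": t_idx,
                "label": target.label,
                "dx_um": plan.dx_um,
                "dy_um": plan.dy_um,
                "pred_x_px": plan.predicted_probe_center_px[0],
                "pred_y_px": plan.predicted_probe_center_px[1],
            }
        )
        try:
            moved = apply_move(gt, plan, cal)
        except Exception as exc:
            logger.warning("stage=move target=%d excluded: %s", t_idx, exc)
            exclusions.append({"cell_id": t_idx, "stage": "move", "reason": str(exc)})
            continue

        cell = _cell_truth_at_probe(gt, moved.probe_center_px)
        values = []
        n_no_contact = 0
        for c_idx in range(config.curves_per_cell):
            curve_seed = _stage_seed(config.master_seed, "curve", t_idx * 10007 + c_idx)
            if config.assay == "indentation":
                if cell is None:
                    # missed cell: record a baseline-only curve
                    curve = _baseline_only_curve(config, curve_seed)
                else:
                    curve = simulate_indentation(
                        cell.E_true_pa, config.nu, config.cantilever, config.ramp,
                        z0_true_um=0.5 * (config.ramp.z_start_um + config.ramp.z_end_um),
                        seed=curve_seed,
                    )
            else:
                if cell is None:
                    curve = _baseline_only_curve(config, curve_seed)
                else:
                    curve = simulate_scfs(
                        cell.F_adh_true_nN, config.detach_separation_um, config.n_rupture_steps,
                        config.cantilever, config.ramp, seed=curve_seed,
                    )
            curve.cell_id = t_idx
            curve.label = target.label
            write_curve_tsv(curve, out_dir / "curves" / f"cell{t_idx:03d}_curve{c_idx:02d}.tsv")

            corrected = fa.baseline_correct(curve)
            if config.assay == "indentation":
                try:
                    contact = fa.find_contact_point(corrected)
                except fa.NoContactError:
                    n_no_contact += 1
                    per_curve_rows.append(
                        {"cell_id": t_idx, "label": target.label, "curve_index": c_idx,
                         "value": np.nan, "rmse": np.nan, "converged": False}
                    )
                    continue
                fit = fa.fit_hertz(corrected, config.cantilever.tip_radius_um, config.nu, contact=contact)
                per_curve_rows.append(
                    {"cell_id": t_idx, "label": target.label, "curve_index": c_idx,
                     "value": fit.E_fit_pa, "rmse": fit.rms_residual_nN, "converged": fit.converged}
                )
                if fit.converged:
                    values.append(fit.E_fit_pa)
            else:
                adh = fa.extract_adhesion(corrected)
                per_curve_rows.append(
                    {"cell_id": t_idx, "label": target.label, "curve_index": c_idx,
                     "value": adh.F_adh_nN, "rmse": 0.0, "converged": True}
                )
                values.append(adh.F_adh_nN)

        if not values:
            reason = "no contact (probe missed the cell)" if cell is None else "no converged curves"
            logger.warning("stage=analyze target=%d excluded: %s", t_idx, reason)
            exclusions.append({"cell_id": t_idx, "stage": "analyze", "reason": reason})
            continue
        measurements.append(
            fa.aggregate_cell(t_idx, target.label, values, n_excluded=config.curves_per_cell - len(values))
        )

    pd.DataFrame(move_rows).to_csv(out_dir / "move_plans.csv", index=False)
    pd.DataFrame(per_curve_rows).to_csv(out_dir / "per_curve_results.csv", index=False)
    pd.DataFrame(
        [
            {"cell_id": m.cell_id, "label": m.label, "aggregate": m.aggregate,
             "sd": m.sd, "n_curves": m.n_curves, "n_excluded": m.n_excluded}
            for m in measurements
        ]
    ).to_csv(out_dir / "per_cell_results.csv", index=False)
    (out_dir / "exclusions.json").write_text(json.dumps(exclusions, indent=1))

    # --- population summary ----------------------------------------------------
    summaries = {}
    values_by_label = {}
    for label in (TYPE_A, TYPE_B):
        vals = [m.aggregate for m in measurements if m.label == label]
        values_by_label[label] = vals
        if len(vals) >= 2:
            summaries[label] = ps.summarize(vals, label=label)
    comparison = None
    if TYPE_A in summaries and TYPE_B in summaries:
        comparison = ps.compare_groups(
            summaries[TYPE_A], summaries[TYPE_B],
            values_a=values_by_label[TYPE_A], values_b=values_by_label[TYPE_B],
        )
    summary_payload = {
        "assay": config.assay,
        "master_seed": config.master_seed,
        "n_targets": len(targets),
        "n_measured": len(measurements),
        "n_excluded": len(exclusions),
        "populations": {k: asdict(v) for k, v in summaries.items()},
        "comparison": asdict(comparison) if comparison else None,
    }  # wall-clock timing goes to the log only, so reruns stay byte-identical
    (out_dir / "summary.json").write_text(json.dumps(summary_payload, indent=1))
    logger.info(
        "run complete: %d/%d targets measured in %.1fs",
        len(measurements), len(targets), time.time() - t_start,
    )
    return RunResult(
        run_dir=out_dir,
        gt=gt,
        detections=detections,
        measurements=measurements,
        summaries=summaries,
        comparison=comparison,
        exclusions=exclusions,
    )


def _baseline_only_curve(config: RunConfig, seed: int) -> ForceCurve:
    """Noise/drift-only curve recorded when the probe missed every cell."""
    ramp = config.ramp
    z = np.linspace(ramp.z_start_um, ramp.z_end_um, ramp.samples_per_segment)
    rng = np.random.default_rng(seed)
    cant = config.cantilever
    drift = cant.drift_nm_per_um * (z - ramp.z_start_um)
    d_app = drift + rng.normal(0, max(cant.noise_sd_nm, 1e-9), z.shape)
    d_ret = drift[::-1] + rng.normal(0, max(cant.noise_sd_nm, 1e-9), z.shape)
    return ForceCurve(
        approach_z_um=z, approach_d_nm=d_app,
        retract_z_um=z[::-1].copy(), retract_d_nm=d_ret,
        cantilever=cant, kind=config.assay, seed=seed,
    )


def report(run_dir: str | Path, make_figures: bool = True) -> dict:
    """Assemble a human-readable summary of a completed run.

    Writes ``report.md`` (tables) and, when ``make_figures`` is set, one
    histogram panel per cell type with the Gaussian overlay, plus a
    detection-overlay figure.  Raises ``FileNotFoundError`` listing the
    missing artifacts for an incomplete run.
    """
    run_dir = Path(run_dir)
    required = [
        "run_config.json", "summary.json", "per_cell_results.csv",
        "move_plans.csv", "detection_metrics.json",
    ]
    missing = [name for name in required if not (run_dir / name).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run at {run_dir}: missing {', '.join(missing)}")

    summary = json.loads((run_dir / "summary.json").read_text())
    per_cell = pd.read_csv(run_dir / "per_cell_results.csv")
    moves = pd.read_csv(run_dir / "move_plans.csv")
    det = json.loads((run_dir / "detection_metrics.json").read_text())

    unit = "Pa" if summary["assay"] == "indentation" else "nN"
    lines = [
        f"# Virtual {summary['assay']} assay report",
        "",
        f"- master seed: {summary['master_seed']}",
        f"- targets selected: {summary['n_targets']}, measured: {summary['n_measured']}, excluded: {summary['n_excluded']}",
        f"- detection: precision {det['precision']:.3f}, recall {det['recall']:.3f} at IoU {det['iou_threshold']}",
        "",
        "## Populations",
        "",
        f"| type | n | mean ({unit}) | SD ({unit}) | Gaussian mu | Gaussian sigma |",
        "|---|---|---|---|---|---|",
    ]
    for label, pop in sorted(summary["populations"].items()):
        lines.append(
            f"| {label} | {pop['n']} | {pop['mean']:.4g} | {pop['sd']:.4g} | {pop['mu']:.4g} | {pop['sigma']:.4g} |"
        )
    comp = summary.get("comparison")
    if comp:
        lines += ["", f"Ordering: **{comp['ordering']}** "
                      f"(difference of means {comp['difference']:.4g} {unit}, rank-based p = {comp['p_value']:.3g})"]
    lines += ["", "## Move plans (first 10)", "", "```", moves.head(10).to_string(index=False), "```"]
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")

    figures = []
    if make_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for label, pop in sorted(summary["populations"].items()):
            fig, ax = plt.subplots(figsize=(4, 3))
            edges = np.asarray(pop["bin_edges"])
            counts = np.asarray(pop["counts"])
            ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
                   color="tab:red" if label == TYPE_A else "tab:green", alpha=0.6, edgecolor="k")
            s = ps.PopulationSummary(**pop)
            x, y = ps.overlay_curve(s)
            ax.plot(x, y, "k-")
            ax.set_xlabel(f"{'Young’s modulus (Pa)' if unit == 'Pa' else 'Adhesion force (nN)'}")
            ax.set_ylabel("count")
            ax.set_title(f"{label}: n={pop['n']}, mean={pop['mean']:.3g} {unit}")
            fig.tight_layout()
            p = run_dir / f"hist_{label}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            figures.append(str(p))
    return {"report": str(run_dir / "report.md"), "figures": figures, "summary": summary}
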