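"""Synthetic co-culture scene generator.

Generates ground-truth scenes of two morphologically distinct adherent cell
types (typeA: smaller, fine interior texture; typeB: ~30% larger, coarse
texture — a simulator convention for detector separability, not a biological
claim) plus a spherical AFM probe tip, and renders paired bright-field and
two-channel fluorescence images.  typeA cells fluoresce only in the red
channel, typeB only in the green channel.

Density presets follow the co-culture definitions: the high-density preset
targets >= 60% surface coverage with cells of different types in physical
contact; the low-density preset targets <= 10% coverage with no two cells
touching.

Coordinate convention: image origin top-left, x rightward, y downward,
0-based pixel indices; boxes are half-open [x_min, x_max) x [y_min, y_max).
Coverage is computed on rasterized masks (pixel counting), so overlap
handling is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "CellInstance",
    "SceneGroundTruth",
    "ImageSet",
    "UnsatisfiableDensityError",
    "sample_scene",
    "render_images",
    "coverage_fraction",
    "cell_bounding_box",
    "write_scene_json",
    "read_scene_json",
    "write_image_set",
    "read_image_set",
]

SCHEMA_VERSION = 1

TYPE_A = "typeA"
TYPE_B = "typeB"


class UnsatisfiableDensityError(RuntimeError):
    """Requested density preset cannot be met for this configuration."""


@dataclass(frozen=True)
class SceneConfig:
    """Scene-generation parameters.

    Radius units are um; the default pixel size (0.65 um/px) is a simulator
    convention for a typical 10x objective.  Mechanical truth per type:
    Young's modulus is log-normal (log-mean in ln Pa), adhesion force normal
    (nN), with typeB stiffer and more adhesive than typeA so that population
    comparisons have a known ordering.
    """

    image_width_px: int = 384
    image_height_px: int = 384
    pixel_size_um: float = 0.65
    density_preset: Literal["high", "low"] = "high"
    n_cells_per_type: int | None = None  # preset default: 90 (high) / 4 (low)
    radius_mean_um: dict = field(default_factory=lambda: {TYPE_A: 8.0, TYPE_B: 10.5})
    radius_sd_um: dict = field(default_factory=lambda: {TYPE_A: 0.9, TYPE_B: 1.2})
    E_log_mean: dict = field(default_factory=lambda: {TYPE_A: np.log(2000.0), TYPE_B: np.log(4500.0)})
    E_log_sd: dict = field(default_factory=lambda: {TYPE_A: 0.25, TYPE_B: 0.25})
    F_adh_mean_nN: dict = field(default_factory=lambda: {TYPE_A: 1.2, TYPE_B: 2.4})
    F_adh_sd_nN: dict = field(default_factory=lambda: {TYPE_A: 0.25, TYPE_B: 0.4})
    probe_radius_um: float = 6.0
    max_overlap_fraction: float | None = None  # preset default: 0.18 (high) / 0.0 (low)
    min_axis_ratio: float = 0.75
    illumination_gradient: float = 0.06
    noise_sd: float = 120.0  # 16-bit counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.density_preset not in ("high", "low"):
            raise ValueError("density_preset must be 'high' or 'low'")
        if self.n_cells_per_type is None:
            object.__setattr__(self, "n_cells_per_type", 90 if self.density_preset == "high" else 4)
        if self.n_cells_per_type < 0:
            raise ValueError("n_cells_per_type must be non-negative")
        if self.max_overlap_fraction is None:
            object.__setattr__(self, "max_overlap_fraction", 0.18 if self.density_preset == "high" else 0.0)
        if self.probe_radius_um <= 0:
            raise ValueError("probe radius must be positive")
        if not 0.0 <= self.max_overlap_fraction < 1.0:
            raise ValueError("max_overlap_fraction must lie in [0, 1)")
        if self.density_preset == "high" and self.max_overlap_fraction <= 0:
            raise ValueError("high preset requires max_overlap_fraction > 0 (cell-cell contact)")

    @classmethod
    def low_density(cls, **kw) -> "SceneConfig":
        kw.setdefault("density_preset", "low")
        return cls(**kw)

    @classmethod
    def high_density(cls, **kw) -> "SceneConfig":
        kw.setdefault("density_preset", "high")
        return cls(**kw)


@dataclass(frozen=True)
class CellInstance:
    cell_id: int
    cell_type: str
    center_px: tuple[float, float]  # (x, y)
    semi_axes_px: tuple[float, float]  # (a, b)
    orientation_rad: float
    E_true_pa: float
    F_adh_true_nN: float

    def __post_init__(self) -> None:
        if self.E_true_pa <= 0:
            raise ValueError("E_true must be positive")
        if self.F_adh_true_nN < 0:
            raise ValueError("adhesion force must be non-negative")


@dataclass
class SceneGroundTruth:
    cells: list[CellInstance]
    probe_center_px: tuple[float, float]
    probe_radius_px: float
    pixel_size_um: float
    image_width_px: int
    image_height_px: int
    coverage_fraction: float
    seed: int = 0


@dataclass
class ImageSet:
    """Paired bright-field + two-channel fluorescence rasters (16-bit)."""

    brightfield: np.ndarray
    fluor_red: np.ndarray
    fluor_green: np.ndarray

    def __post_init__(self) -> None:
        if not (self.brightfield.shape == self.fluor_red.shape == self.fluor_green.shape):
            raise ValueError("image channels must share dimensions")


def _cell_mask(cell: CellInstance, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = cell.center_px
    a, b = cell.semi_axes_px
    return draw_ellipse(cy, cx, b, a, shape=shape, rotation=cell.orientation_rad)


def _union_mask(cells: list[CellInstance], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for c in cells:
        rr, cc = _cell_mask(c, shape)
        mask[rr, cc] = True
    return mask


def coverage_fraction(gt: SceneGroundTruth) -> float:
    """Pixel-exact fraction of the image covered by the union of cell masks."""
    shape = (gt.image_height_px, gt.image_width_px)
    return float(_union_mask(gt.cells, shape).sum()) / (shape[0] * shape[1])


def cell_bounding_box(cell: CellInstance, shape: tuple[int, int]) -> tuple[float, float, float, float]:
    """Axis-aligned half-open bounding box (x_min, y_min, x_max, y_max) of the raster mask."""
    rr, cc = _cell_mask(cell, shape)
    if len(rr) == 0:
        raise ValueError("cell lies entirely outside the image")
    return float(cc.min()), float(rr.min()), float(cc.max()) + 1.0, float(rr.max()) + 1.0


def _has_cross_type_contact(cells: list[CellInstance], shape: tuple[int, int]) -> bool:
    """True when a typeA and a typeB mask overlap or touch (1 px adjacency)."""
    mask_a = _union_mask([c for c in cells if c.cell_type == TYPE_A], shape)
    mask_b = _union_mask([c for c in cells if c.cell_type == TYPE_B], shape)
    return bool((ndimage.binary_dilation(mask_a) & mask_b).any())


def sample_scene(config: SceneConfig, seed: int | None = None) -> SceneGroundTruth:
    """Place cells and the probe by seed-reproducible dart throwing.

    The probe disc is placed first in a border-free zone and cells may not
    overlap it, which guarantees a cell-free probe region even at high
    density.  A candidate cell is accepted when the overlap of its mask with
    the running union stays within ``max_overlap_fraction`` of its own area
    (zero for the low preset, which additionally enforces center spacing
    beyond the sum of radii).  Radii are resampled after repeated rejections.
    Raises :class:`UnsatisfiableDensityError` when the density target is
    unreachable.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    shape = (config.image_height_px, config.image_width_px)
    H, W = shape
    px = config.pixel_size_um

    probe_r_px = config.probe_radius_um / px
    margin = probe_r_px + 2
    probe_center = (
        float(rng.uniform(margin, W - margin)),
        float(rng.uniform(margin, H - margin)),
    )
    probe_mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((probe_center[1], probe_center[0]), probe_r_px * 1.15, shape=shape)
    probe_mask[rr, cc] = True

    union = np.zeros(shape, dtype=bool)
    cells: list[CellInstance] = []
    order = [TYPE_A, TYPE_B] * config.n_cells_per_type
    rng.shuffle(order)

    cell_id = 0
    for ctype in order:
        placed = False
        for attempt in range(400):
            r_um = rng.normal(config.radius_mean_um[ctype], config.radius_sd_um[ctype])
            r_um = float(np.clip(r_um, 0.4 * config.radius_mean_um[ctype], 1.8 * config.radius_mean_um[ctype]))
            r_px = r_um / px
            ratio = rng.uniform(config.min_axis_ratio, 1.0)
            a = r_px / np.sqrt(ratio)
            b = r_px * np.sqrt(ratio)
            theta = rng.uniform(0, np.pi)
            cx = rng.uniform(0, W)
            cy = rng.uniform(0, H)
            cand = CellInstance(
                cell_id=cell_id,
                cell_type=ctype,
                center_px=(float(cx), float(cy)),
                semi_axes_px=(float(a), float(b)),
                orientation_rad=float(theta),
                E_true_pa=float(np.exp(rng.normal(config.E_log_mean[ctype], config.E_log_sd[ctype]))),
                F_adh_true_nN=float(max(rng.normal(config.F_adh_mean_nN[ctype], config.F_adh_sd_nN[ctype]), 0.05)),
            )
            rr, cc = _cell_mask(cand, shape)
            area = len(rr)
            if area < 0.8 * np.pi * a * b:  # more than mildly clipped by the border
                continue
            if probe_mask[rr, cc].any():
                continue
            if config.density_preset == "low":
                too_close = False
                for other in cells:
                    dx = cand.center_px[0] - other.center_px[0]
                    dy = cand.center_px[1] - other.center_px[1]
                    min_sep = max(cand.semi_axes_px) + max(other.semi_axes_px) + 3
                    if dx * dx + dy * dy < min_sep * min_sep:
                        too_close = True
                        break
                if too_close:
                    continue
            else:
                overlap = float(union[rr, cc].sum()) / area
                if overlap > config.max_overlap_fraction:
                    continue
            union[rr, cc] = True
            cells.append(cand)
            cell_id += 1
            placed = True
            break
        if not placed and config.density_preset == "low":
            raise UnsatisfiableDensityError(
                f"could not place cell {cell_id} without contact; image too small for "
                f"{config.n_cells_per_type} cells per type at low density"
            )
        # at high density a single failed placement is tolerated; coverage is
        # checked against the preset target below

    cov = float(union.sum()) / (H * W)
    if config.density_preset == "high" and cov < 0.60:
        raise UnsatisfiableDensityError(
            f"high-density preset reached only {cov:.1%} coverage with "
            f"{len(cells)} cells; increase n_cells_per_type or cell size"
        )
    if config.density_preset == "high" and not _has_cross_type_contact(cells, shape):
        raise UnsatisfiableDensityError(
            "high-density preset produced no contact between cells of different types"
        )
    if config.density_preset == "low" and cov > 0.10:
        raise UnsatisfiableDensityError(
            f"low-density preset exceeded 10% coverage ({cov:.1%}); decrease n_cells_per_type"
        )
    return SceneGroundTruth(
        cells=cells,
        probe_center_px=probe_center,
        probe_radius_px=float(probe_r_px),
        pixel_size_um=px,
        image_width_px=W,
        image_height_px=H,
        coverage_fraction=cov,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FULL = 65535.0


def _radial_fields(gt: SceneGroundTruth, cell: CellInstance, shape: tuple[int, int]):
    """Normalized elliptical radius field (1 at the rim) over the cell's mask."""
    rr, cc = _cell_mask(cell, shape)
    cx, cy = cell.center_px
    a, b = cell.semi_axes_px
    th = cell.orientation_rad
    dx = cc - cx
    dy = rr - cy
    # draw_ellipse rotates by +rotation around (cy, cx) with (row, col) axes
    u = (dx * np.cos(th) + dy * np.sin(th)) / a
    v = (-dx * np.sin(th) + dy * np.cos(th)) / b
    rho = np.sqrt(u * u + v * v)
    return rr, cc, np.clip(rho, 0, 1)


def render_images(gt: SceneGroundTruth, config: SceneConfig) -> ImageSet:
    """Render the bright-field and fluorescence channels for a scene.

    Bright-field: mid-gray background with a smooth illumination gradient;
    each cell has a bright interior dome plus a rim ring, with interior
    texture whose spatial frequency and amplitude differ between the types
    (typeA fine/strong, typeB coarse/weak) — the cue the default classical
    detector uses.  The probe is a dark disc with a bright rim.  Additive
    Gaussian noise last.  Fluorescence: noisy per-type indicator masks.
    """
    if (gt.image_height_px, gt.image_width_px) != (config.image_height_px, config.image_width_px):
        raise ValueError("ground truth dimensions do not match config")
    shape = (gt.image_height_px, gt.image_width_px)
    H, W = shape
    rng = np.random.default_rng(gt.seed + 104729)

    yy, xx = np.mgrid[0:H, 0:W]
    gx, gy = rng.uniform(-1, 1, 2)
    bf = 0.45 * _FULL * (1.0 + config.illumination_gradient * (gx * (xx / W - 0.5) + gy * (yy / H - 0.5)))

    # static texture fields, band-limited per type
    base_noise = rng.normal(0, 1, shape)
    tex_fine = ndimage.gaussian_filter(base_noise, 1.0)
    tex_fine /= max(tex_fine.std(), 1e-9)
    tex_coarse = ndimage.gaussian_filter(base_noise, 3.0)
    tex_coarse /= max(tex_coarse.std(), 1e-9)

    # cells are painted in z-order (later cells occlude earlier ones), the way
    # adherent cells in a monolayer hide one another rather than summing
    cell_layer = np.zeros(shape)
    for cell in gt.cells:
        rr, cc, rho = _radial_fields(gt, cell, shape)
        dome = 0.22 * _FULL * (1.0 - rho**2)  # bright interior dome
        ring = 0.18 * _FULL * np.exp(-(((rho - 0.92) / 0.06) ** 2))
        if cell.cell_type == TYPE_A:
            tex = 0.11 * _FULL * tex_fine[rr, cc] * (rho < 0.85)
            ring = ring * 1.25
        else:
            tex = 0.035 * _FULL * tex_coarse[rr, cc] * (rho < 0.85)
        cell_layer[rr, cc] = dome + ring + tex
    bf = bf + cell_layer

    # probe: dark disc, bright rim
    pr = gt.probe_radius_px
    pyx = (gt.probe_center_px[1], gt.probe_center_px[0])
    rr, cc = draw_disk(pyx, pr, shape=shape)
    dx = cc - gt.probe_center_px[0]
    dy = rr - gt.probe_center_px[1]
    rho = np.sqrt(dx * dx + dy * dy) / pr
    bf[rr, cc] = 0.45 * _FULL * (1.0 - 0.55 * (1 - rho**2))
    rr, cc = draw_disk(pyx, pr * 1.12, shape=shape)
    dx = cc - gt.probe_center_px[0]
    dy = rr - gt.probe_center_px[1]
    rho = np.sqrt(dx * dx + dy * dy) / pr
    rim = np.exp(-(((rho - 1.02) / 0.05) ** 2))
    bf[rr, cc] = bf[rr, cc] + 0.35 * _FULL * rim

    red = np.full(shape, 0.02 * _FULL)
    green = np.full(shape, 0.02 * _FULL)
    for cell in gt.cells:
        rr, cc, rho = _radial_fields(gt, cell, shape)
        signal = 0.55 * _FULL * (1.0 - 0.3 * rho**2)
        if cell.cell_type == TYPE_A:
            red[rr, cc] = np.maximum(red[rr, cc], signal)
        else:
            green[rr, cc] = np.maximum(green[rr, cc], signal)

    def finalize(img: np.ndarray) -> np.ndarray:
        noisy = img + rng.normal(0, config.noise_sd, shape)
        return np.clip(noisy, 0, _FULL).astype(np.uint16)

    return ImageSet(brightfield=finalize(bf), fluor_red=finalize(red), fluor_green=finalize(green))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_scene_json(gt: SceneGroundTruth, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "pixel_size_um": gt.pixel_size_um,
        "image_width_px": gt.image_width_px,
        "image_height_px": gt.image_height_px,
        "probe_center_px": list(gt.probe_center_px),
        "probe_radius_px": gt.probe_radius_px,
        "coverage_fraction": gt.coverage_fraction,
        "seed": gt.seed,
        "cells": [asdict(c) for c in gt.cells],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))


def read_scene_json(path: str | Path) -> SceneGroundTruth:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported scene schema version {payload.get('schema_version')}")
    cells = [
        CellInstance(
            cell_id=c["cell_id"],
            cell_type=c["cell_type"],
            center_px=tuple(c["center_px"]),
            semi_axes_px=tuple(c["semi_axes_px"]),
            orientation_rad=c["orientation_rad"],
            E_true_pa=c["E_true_pa"],
            F_adh_true_nN=c["F_adh_true_nN"],
        )
        for c in payload["cells"]
    ]
    return SceneGroundTruth(
        cells=cells,
        probe_center_px=tuple(payload["probe_center_px"]),
        probe_radius_px=payload["probe_radius_px"],
        pixel_size_um=payload["pixel_size_um"],
        image_width_px=payload["image_width_px"],
        image_height_px=payload["image_height_px"],
        coverage_fraction=payload["coverage_fraction"],
        seed=payload["seed"],
    )


def write_image_set(images: ImageSet, directory: str | Path, stem: str = "scene") -> dict[str, Path]:
    """Write each channel as 16-bit grayscale PNG; returns the paths."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, arr in (
        ("brightfield", images.brightfield),
        ("fluor_red", images.fluor_red),
        ("fluor_green", images.fluor_green),
    ):
        p = directory / f"{stem}_{name}.png"
        Image.fromarray(arr.astype(np.uint16)).save(p)
        out[name] = p
    return out


def read_image_set(directory: str | Path, stem: str = "scene") -> ImageSet:
    from PIL import Image

    directory = Path(directory)
    chans = {}
    for name in ("brightfield", "fluor_red", "fluor_green"):
        p = directory / f"{stem}_{name}.png"
        chans[name] = np.asarray(Image.open(p), dtype=np.uint16)
    return ImageSet(brightfield=chans["brightfield"], fluor_red=chans["fluor_red"], fluor_green=chans["fluor_green"])
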