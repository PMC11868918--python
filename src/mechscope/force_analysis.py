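"""Force-curve analysis: Hertz fits and adhesion extraction.

The pipeline per indentation curve is baseline_correct -> find_contact_point
-> fit_hertz; per SCFS curve it is baseline_correct -> extract_adhesion.
All forces are in nN (F = k * d with k in N/m, d in nm), z in um, E in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .virtual_afm import ForceCurve, hertz_force

__all__ = [
    "HertzFitResult",
    "AdhesionResult",
    "CellMeasurement",
    "NoContactError",
    "baseline_correct",
    "find_contact_point",
    "fit_hertz",
    "extract_adhesion",
    "aggregate_cell",
]


class NoContactError(RuntimeError):
    """Raised when a curve shows no detectable tip-sample contact."""


@dataclass(frozen=True)
class HertzFitResult:
    E_fit_pa: float
    z0_fit_um: float
    d0_fit_nm: float
    rms_residual_nN: float
    n_points: int
    delta_range_um: tuple[float, float]
    converged: bool


@dataclass(frozen=True)
class AdhesionResult:
    F_adh_nN: float
    work_fJ: float
    pulloff_z_um: float
    n_rupture_steps: int


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    label: str
    per_curve: tuple[float, ...]
    aggregate: float
    sd: float
    n_curves: int
    n_excluded: int = 0


def baseline_correct(curve: ForceCurve, baseline_fraction: float = 0.3) -> ForceCurve:
    """Subtract a straight line fitted to the far-from-contact approach start.

    The line is fitted (least squares in z) to the first ``baseline_fraction``
    of the approach segment and subtracted from both segments, removing
    deflection offset and linear drift.
    """
    n = len(curve.approach_z_um)
    n_base = int(np.floor(n * baseline_fraction))
    if n_base < 10:
        raise ValueError(f"baseline window has {n_base} samples; need >= 10")
    z_b = curve.approach_z_um[:n_base]
    d_b = curve.approach_d_nm[:n_base]
    slope, intercept = np.polyfit(z_b, d_b, 1)
    line = lambda z: slope * z + intercept  # noqa: E731
    return replace(
        curve,
        approach_d_nm=curve.approach_d_nm - line(curve.approach_z_um),
        retract_d_nm=curve.retract_d_nm - line(curve.retract_z_um),
    )


def _profiled_piecewise_score(z: np.ndarray, d_nm: np.ndarray, F: np.ndarray, j: int) -> tuple[float, float]:
    """Residual of the flat-then-Hertz model with contact at sample j.

    Before j the model is zero force; from j on it is C * delta^{3/2} with
    delta = (z - z[j]) - (d - d[j]) in um (piezo travel past contact minus
    cantilever deflection), and the prefactor C profiled out in closed form.
    Returns (total squared residual, C).
    """
    x = np.zeros_like(F)
    if j < len(z) - 1:
        delta = np.maximum((z[j:] - z[j]) - (d_nm[j:] - d_nm[j]) * 1e-3, 0.0)
        x_tail = delta**1.5
        denom = float(x_tail @ x_tail)
        C = float(x_tail @ F[j:]) / denom if denom > 0 else 0.0
        C = max(C, 0.0)
        x[j:] = C * x_tail
    else:
        C = 0.0
    resid = F - x
    return float(resid @ resid), C


def find_contact_point(curve: ForceCurve, min_improvement: float = 0.95) -> tuple[float, float]:
    """Locate the contact point on a baseline-corrected approach segment.

    Grid search over candidate contact indices scores a piecewise model
    (flat baseline, then Hertz-shaped rise with its amplitude profiled out in
    closed form); the best candidate is refined by parabolic interpolation of
    the residual.  Returns ``(z0_um, d0_nm)`` with d0 the baseline level.
    Raises :class:`NoContactError` when no candidate beats the all-baseline
    model by the required margin.
    """
    z = curve.approach_z_um
    d = curve.approach_d_nm
    F = curve.approach_force_nN
    n = len(z)
    if n < 20:
        raise ValueError("approach segment too short for contact detection")

    null_score = float(F @ F)
    scores = np.full(n, np.inf)
    lo, hi = 5, n - 10
    for j in range(lo, hi):
        scores[j], _ = _profiled_piecewise_score(z, d, F, j)
    j_best = int(np.argmin(scores[lo:hi])) + lo
    best = scores[j_best]
    if not np.isfinite(best) or best > min_improvement * null_score:
        raise NoContactError("no candidate contact point improves on the baseline-only model")

    # parabolic refinement of z0 on the residual profile
    z0 = float(z[j_best])
    if lo < j_best < hi - 1:
        s_m, s_0, s_p = scores[j_best - 1], scores[j_best], scores[j_best + 1]
        denom = s_m - 2 * s_0 + s_p
        if denom > 0:
            shift = 0.5 * (s_m - s_p) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            z0 = float(z[j_best] + shift * (z[j_best + 1] - z[j_best]))
    d0 = float(np.mean(curve.approach_d_nm[: max(j_best, 10)]))
    return z0, d0


def fit_hertz(
    curve: ForceCurve,
    R_um: float | None = None,
    nu: float = 0.5,
    delta_max_fraction: float = 0.8,
    contact: tuple[float, float] | None = None,
) -> HertzFitResult:
    """Fit the spherical Hertz model to an indentation curve.

    E is estimated on post-contact samples with indentation
    delta = (z - z0) - (d - d0)  (converted to um) capped at
    ``delta_max_fraction`` of the maximum indentation.  A closed-form linear
    estimate on F^(2/3) vs delta initializes a nonlinear refinement that
    re-optimizes (E, z0) jointly.
    """
    if R_um is None:
        R_um = curve.cantilever.tip_radius_um
    if contact is None:
        z0, d0 = find_contact_point(curve)
    else:
        z0, d0 = contact

    z = curve.approach_z_um
    d = curve.approach_d_nm - d0
    F = curve.cantilever.k_n_per_m * d

    def deltas(z0_: float) -> np.ndarray:
        return (z - z0_) - d * 1e-3  # um

    delta = deltas(z0)
    post = delta > 0
    if np.count_nonzero(post) < 10:
        return HertzFitResult(np.nan, z0, d0, np.nan, int(np.count_nonzero(post)), (0.0, 0.0), False)
    delta_cap = delta_max_fraction * float(delta[post].max())
    sel = post & (delta <= delta_cap)
    if np.count_nonzero(sel) < 10:
        sel = post

    # linear initialization: F^(2/3) = (C)^(2/3) * delta
    Fp = np.maximum(F[sel], 0.0)
    x = delta[sel]
    y = Fp ** (2.0 / 3.0)
    slope = float(x @ y) / float(x @ x)
    C0 = max(slope, 1e-12) ** 1.5  # nN per um^1.5
    E0 = _C_to_E(C0, nu, R_um)

    sel_idx = np.flatnonzero(sel)  # sample set frozen during refinement

    def residuals(p: np.ndarray) -> np.ndarray:
        logE, z0_ = p
        dd = (z[sel_idx] - z0_) - d[sel_idx] * 1e-3
        return hertz_force(dd, np.exp(logE), nu, R_um) - F[sel_idx]

    dz = float(np.mean(np.diff(z)))
    try:
        sol = optimize.least_squares(
            residuals,
            x0=np.array([np.log(max(E0, 1.0)), z0]),
            bounds=([np.log(1e-3), z0 - 20 * dz], [np.log(1e9), z0 + 20 * dz]),
            gtol=1e-10,
            xtol=1e-12,
            ftol=1e-12,
        )
        converged = bool(sol.success)
        E_fit = float(np.exp(sol.x[0]))
        z0_fit = float(sol.x[1])
        res = residuals(sol.x)
    except Exception:
        return HertzFitResult(np.nan, z0, d0, np.nan, len(sel_idx), (0.0, 0.0), False)

    if not np.isfinite(E_fit) or E_fit <= 0:
        converged = False
    dd = (z[sel_idx] - z0_fit) - d[sel_idx] * 1e-3
    return HertzFitResult(
        E_fit_pa=E_fit,
        z0_fit_um=z0_fit,
        d0_fit_nm=d0,
        rms_residual_nN=float(np.sqrt(np.mean(res**2))),
        n_points=len(sel_idx),
        delta_range_um=(float(np.min(dd)), float(np.max(dd))),
        converged=converged,
    )


def _C_to_E(C_nN_per_um15: float, nu: float, R_um: float) -> float:
    # F_nN = C * delta_um^1.5 with C = (4/3) E/(1-nu^2) sqrt(R_m) * 1e-9 * 1e9 ... invert via hertz_force at delta=1um
    unit = hertz_force(1.0, 1.0, nu, R_um)  # nN per Pa at delta = 1 um
    return C_nN_per_um15 / float(unit)


def extract_adhesion(curve: ForceCurve, noise_sd_nN: float | None = None) -> AdhesionResult:
    """Extract the adhesion force and work from a baseline-corrected retract.

    F_adh is the magnitude of the most negative retract force (clamped at 0).
    Work of adhesion integrates |F| dz over the contiguous negative-force
    region containing the minimum (1 nN.um = 1 fJ).  Rupture steps are
    upward force jumps toward baseline exceeding 5x the noise sd.
    """
    z = curve.retract_z_um
    F = curve.retract_force_nN
    i_min = int(np.argmin(F))
    F_min = float(F[i_min])
    if noise_sd_nN is None:
        noise_sd_nN = curve.cantilever.noise_sd_nm * curve.cantilever.k_n_per_m
    tol = max(3.0 * noise_sd_nN, 1e-12)
    if F_min >= -tol:
        return AdhesionResult(0.0, 0.0, float(z[i_min]), 0)

    F_adh = -F_min
    # contiguous negative region around the minimum
    neg = F < 0
    left = i_min
    while left > 0 and neg[left - 1]:
        left -= 1
    right = i_min
    while right < len(F) - 1 and neg[right + 1]:
        right += 1
    # include one bounding sample each side so the edge trapezoids count
    left = max(left - 1, 0)
    right = min(right + 1, len(F) - 1)
    zz = z[left : right + 1]
    ff = np.minimum(F[left : right + 1], 0.0)
    work = float(np.trapezoid(-ff, -zz))  # z decreasing; -z makes dx positive
    work = max(work, 0.0)

    # rupture steps: retract z decreases with index, so moving away from the
    # surface means increasing index; a release toward baseline is dF > 0
    dF = np.diff(F)
    below = F[:-1] < -tol
    jump_thresh = max(5.0 * noise_sd_nN, 1e-12)
    steps = int(np.count_nonzero((dF > jump_thresh) & below))
    return AdhesionResult(F_adh, work, float(z[i_min]), steps)


def aggregate_cell(
    cell_id: int,
    label: str,
    values: Sequence[float],
    method: Literal["mean", "median"] = "mean",
    n_excluded: int = 0,
) -> CellMeasurement:
    """Aggregate per-curve read-outs for one cell (default arithmetic mean)."""
    vals = [float(v) for v in values if np.isfinite(v)]
    dropped = len(values) - len(vals) + n_excluded
    if not vals:
        raise ValueError(f"cell {cell_id}: no converged curves to aggregate")
    arr = np.asarray(vals)
    agg = float(np.mean(arr)) if method == "mean" else float(np.median(arr))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return CellMeasurement(
        cell_id=cell_id,
        label=label,
        per_curve=tuple(vals),
        aggregate=agg,
        sd=sd,
        n_curves=len(arr),
        n_excluded=dropped,
    )
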