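"""Virtual AFM force-spectroscopy instrument.

Simulates approach/retract force curves with known ground truth so that the
analysis stage (contact-point detection, Hertz fit, adhesion extraction) can
be validated by parameter recovery instead of against opaque instrument files.

Units contract (fixed across the package):
    piezo height z   : um   (increasing toward the sample)
    deflection d     : nm
    force F = k * d  : nN   (k in N/m times d in nm is nN exactly)
    spring constant k: N/m
    probe radius R   : um
    Young's modulus E: Pa
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "CantileverSpec",
    "RampConfig",
    "ForceCurve",
    "hertz_force",
    "simulate_indentation",
    "simulate_scfs",
    "read_curve_tsv",
    "write_curve_tsv",
]


def hertz_force(delta_um: np.ndarray | float, E_pa: float, nu: float, R_um: float) -> np.ndarray:
    """Spherical-indenter Hertz force, paraboloid approximation.

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2), evaluated in SI and
    returned in nN.  Negative indentations contribute zero force.
    """
    delta_m = np.maximum(np.asarray(delta_um, dtype=float), 0.0) * 1e-6
    R_m = R_um * 1e-6
    F_newton = (4.0 / 3.0) * E_pa / (1.0 - nu**2) * np.sqrt(R_m) * delta_m**1.5
    return F_newton * 1e9  # N -> nN


@dataclass(frozen=True)
class CantileverSpec:
    """Cantilever + spherical probe parameters.

    ``drift_nm_per_um`` is a linear baseline drift in deflection per um of
    piezo travel, emulating thermal/optical drift of the photodiode zero.
    """

    k_n_per_m: float = 0.05
    tip_radius_um: float = 5.0
    noise_sd_nm: float = 0.0
    drift_nm_per_um: float = 0.0

    def __post_init__(self) -> None:
        if self.k_n_per_m <= 0:
            raise ValueError("spring constant must be positive")
        if self.tip_radius_um <= 0:
            raise ValueError("tip radius must be positive")
        if self.noise_sd_nm < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class RampConfig:
    """Piezo ramp settings for one approach/retract cycle."""

    z_start_um: float = 0.0
    z_end_um: float = 5.0
    samples_per_segment: int = 400
    setpoint_nN: float = 5.0

    def __post_init__(self) -> None:
        if self.z_end_um <= self.z_start_um:
            raise ValueError("ramp must have positive z range")
        if self.samples_per_segment < 50:
            raise ValueError("need at least 50 samples per segment")
        if self.setpoint_nN <= 0:
            raise ValueError("force setpoint must be positive")


@dataclass
class ForceCurve:
    """One approach/retract cycle: (z_um, d_nm) samples plus metadata.

    ``approach`` z is strictly increasing (toward the sample); ``retract`` z
    is strictly decreasing.
    """

    approach_z_um: np.ndarray
    approach_d_nm: np.ndarray
    retract_z_um: np.ndarray
    retract_d_nm: np.ndarray
    cantilever: CantileverSpec
    kind: Literal["indentation", "scfs"] = "indentation"
    cell_id: int = -1
    label: str = ""
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("approach_z_um", "approach_d_nm", "retract_z_um", "retract_d_nm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.approach_z_um.shape != self.approach_d_nm.shape:
            raise ValueError("approach z and d must have equal length")
        if self.retract_z_um.shape != self.retract_d_nm.shape:
            raise ValueError("retract z and d must have equal length")
        for arr in (self.approach_z_um, self.approach_d_nm, self.retract_z_um, self.retract_d_nm):
            if not np.all(np.isfinite(arr)):
                raise ValueError("force curve contains non-finite samples")
        if len(self.approach_z_um) > 1 and not np.all(np.diff(self.approach_z_um) > 0):
            raise ValueError("approach z must be strictly increasing")
        if len(self.retract_z_um) > 1 and not np.all(np.diff(self.retract_z_um) < 0):
            raise ValueError("retract z must be strictly decreasing")

    @property
    def approach_force_nN(self) -> np.ndarray:
        return self.cantilever.k_n_per_m * self.approach_d_nm

    @property
    def retract_force_nN(self) -> np.ndarray:
        return self.cantilever.k_n_per_m * self.retract_d_nm


def _solve_contact_deflection(
    z_um: np.ndarray,
    z0_um: float,
    E_pa: float,
    nu: float,
    cant: CantileverSpec,
    rel_tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Solve the cantilever-sample force balance per sample.

    For each z past contact, find deflection d (nm) with
        k * d = Hertz(delta),  delta = (z - z0) - d*1e-3   [um].
    g(d) = k*d - Hertz(delta(d)) is strictly increasing in d, so a
    safeguarded Newton iteration bracketed on [0, (z - z0)*1e3] always
    converges.  Raises on non-convergence, naming the sample index.
    """
    z_um = np.asarray(z_um, dtype=float)
    travel_um = np.maximum(z_um - z0_um, 0.0)
    k = cant.k_n_per_m
    R = cant.tip_radius_um
    d = np.zeros_like(travel_um)

    active = travel_um > 0
    if not np.any(active):
        return d

    # vectorized safeguarded Newton with per-sample brackets
    lo = np.zeros_like(travel_um)
    hi = travel_um * 1e3  # delta >= 0 means d <= travel in nm
    x = 0.5 * hi
    converged = ~active
    for _ in range(max_iter):
        delta = travel_um - x * 1e-3
        F = hertz_force(delta, E_pa, nu, R)
        g = k * x - F
        # dF/dd = -1e-3 * dF/ddelta
        dF_ddelta = np.where(
            delta > 0,
            2.0 * E_pa / (1.0 - nu**2) * np.sqrt(R * 1e-6) * np.sqrt(np.maximum(delta, 0) * 1e-6) * 1e9 * 1e-6,
            0.0,
        )  # nN per um of delta
        gprime = k + dF_ddelta * 1e-3
        lo = np.where(g < 0, x, lo)
        hi = np.where(g > 0, x, hi)
        step = g / gprime
        x_new = x - step
        # fall back to bisection when Newton leaves the bracket
        bad = (x_new <= lo) | (x_new >= hi)
        x_new = np.where(bad, 0.5 * (lo + hi), x_new)
        newly = np.abs(x_new - x) <= rel_tol * np.maximum(np.abs(x_new), 1e-6)
        x = np.where(converged, x, x_new)
        converged = converged | (newly & active)
        if np.all(converged):
            break
    else:
        idx = int(np.flatnonzero(~converged)[0])
        raise RuntimeError(f"contact solve did not converge at sample index {idx}")
    d[active] = x[active]
    return d


def _apply_noise_and_drift(
    z_um: np.ndarray, d_nm: np.ndarray, z_ref_um: float, cant: CantileverSpec, rng: np.random.Generator
) -> np.ndarray:
    # drift is linear in absolute piezo position so one line corrects both segments
    out = d_nm + cant.drift_nm_per_um * (z_um - z_ref_um)
    if cant.noise_sd_nm > 0:
        out = out + rng.normal(0.0, cant.noise_sd_nm, size=d_nm.shape)
    return out


def simulate_indentation(
    E_true_pa: float,
    nu: float,
    cant: CantileverSpec,
    ramp: RampConfig,
    z0_true_um: float,
    seed: int,
) -> ForceCurve:
    """Simulate an indentation force curve on an elastic half-space.

    Pre-contact deflection is the drift line plus noise; post-contact
    deflection solves the implicit balance k*d = Hertz((z - z0) - d).  The
    approach is truncated at the setpoint force and the retract retraces the
    elastic curve (no adhesion in indentation mode).  Noise is applied after
    the physics.
    """
    if E_true_pa <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    if not ramp.z_start_um < z0_true_um < ramp.z_end_um:
        raise ValueError("contact position must lie inside the ramp range")

    z = np.linspace(ramp.z_start_um, ramp.z_end_um, ramp.samples_per_segment)
    d_clean = _solve_contact_deflection(z, z0_true_um, E_true_pa, nu, cant)
    F = cant.k_n_per_m * d_clean

    # truncate at the setpoint like a real approach trigger
    over = np.flatnonzero(F >= ramp.setpoint_nN)
    if len(over) > 0:
        stop = over[0] + 1
        z, d_clean = z[:stop], d_clean[:stop]

    rng = np.random.default_rng(seed)
    d_app = _apply_noise_and_drift(z, d_clean, ramp.z_start_um, cant, rng)
    z_ret = z[::-1].copy()
    d_ret = _apply_noise_and_drift(z_ret, d_clean[::-1], ramp.z_start_um, cant, rng)

    return ForceCurve(
        approach_z_um=z,
        approach_d_nm=d_app,
        retract_z_um=z_ret,
        retract_d_nm=d_ret,
        cantilever=cant,
        kind="indentation",
        seed=seed,
        meta={"E_true_pa": E_true_pa, "nu": nu, "z0_true_um": z0_true_um},
    )


def simulate_scfs(
    F_adh_true_nN: float,
    detach_separation_um: float,
    n_rupture_steps: int,
    cant: CantileverSpec,
    ramp: RampConfig,
    seed: int,
    contact_E_pa: float = 800.0,
    nu: float = 0.5,
) -> ForceCurve:
    """Simulate a single-cell force spectroscopy (SCFS) curve.

    The approach is a soft elastic (Hertz) contact.  The retract carries an
    adhesive well: force descends piecewise-linearly to exactly
    ``-F_adh_true_nN`` (noise-free) just below the contact point, then
    returns to baseline through ``n_rupture_steps`` successive rupture
    drops, reaching zero at ``detach_separation_um`` below contact.
    """
    if F_adh_true_nN < 0:
        raise ValueError("adhesion force must be non-negative")
    if n_rupture_steps < 1:
        raise ValueError("need at least one rupture step")
    z0 = 0.5 * (ramp.z_start_um + ramp.z_end_um)
    if detach_separation_um <= 0 or z0 - detach_separation_um <= ramp.z_start_um:
        raise ValueError("detach separation falls outside the ramp range")

    z = np.linspace(ramp.z_start_um, ramp.z_end_um, ramp.samples_per_segment)
    d_app_clean = _solve_contact_deflection(z, z0, contact_E_pa, nu, cant)
    F_app = cant.k_n_per_m * d_app_clean
    over = np.flatnonzero(F_app >= ramp.setpoint_nN)
    if len(over) > 0:
        stop = max(int(over[0]) + 1, 60)
        z, d_app_clean = z[:stop], d_app_clean[:stop]

    z_ret = z[::-1].copy()
    F_ret = np.zeros_like(z_ret)
    k = cant.k_n_per_m
    in_contact = z_ret >= z0
    F_ret[in_contact] = k * d_app_clean[::-1][in_contact]

    # adhesive well on the separation axis s = z0 - z > 0; the minimum sits
    # at the sample nearest 35% of the detach separation so the discrete
    # retract minimum equals -F_adh exactly
    s = z0 - z_ret
    s_min = 0.35 * detach_separation_um
    candidates = np.flatnonzero((s > 0) & (s < detach_separation_um))
    if len(candidates) > 0:
        idx = candidates[np.argmin(np.abs(s[candidates] - s_min))]
        s_min = float(s[idx])
    ramp_zone = (s > 0) & (s <= s_min)
    F_ret[ramp_zone] = -F_adh_true_nN * s[ramp_zone] / s_min
    # staircase of rupture steps back to baseline
    step_zone = (s > s_min) & (s < detach_separation_um)
    if np.any(step_zone):
        frac = (s[step_zone] - s_min) / (detach_separation_um - s_min)
        level = np.ceil(frac * n_rupture_steps)  # 1..n steps released
        F_ret[step_zone] = -F_adh_true_nN * (1.0 - level / n_rupture_steps)
    F_ret[s >= detach_separation_um] = 0.0

    d_ret_clean = F_ret / k
    rng = np.random.default_rng(seed)
    d_app = _apply_noise_and_drift(z, d_app_clean, ramp.z_start_um, cant, rng)
    d_ret = _apply_noise_and_drift(z_ret, d_ret_clean, ramp.z_start_um, cant, rng)

    return ForceCurve(
        approach_z_um=z,
        approach_d_nm=d_app,
        retract_z_um=z_ret,
        retract_d_nm=d_ret,
        cantilever=cant,
        kind="scfs",
        seed=seed,
        meta={
            "F_adh_true_nN": F_adh_true_nN,
            "detach_separation_um": detach_separation_um,
            "n_rupture_steps": n_rupture_steps,
            "z0_true_um": z0,
        },
    )


# ---------------------------------------------------------------------------
# TSV dialect: '#'-prefixed key=value metadata header, then columns
#   segment  z_um  d_nm  F_nN
# ---------------------------------------------------------------------------

def write_curve_tsv(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    buf = io.StringIO()
    c = curve.cantilever
    header = {
        "kind": curve.kind,
        "cell_id": curve.cell_id,
        "label": curve.label,
        "seed": curve.seed,
        "k_n_per_m": repr(c.k_n_per_m),
        "tip_radius_um": repr(c.tip_radius_um),
        "noise_sd_nm": repr(c.noise_sd_nm),
        "drift_nm_per_um": repr(c.drift_nm_per_um),
    }
    for key, val in curve.meta.items():
        header[f"meta.{key}"] = repr(val) if isinstance(val, float) else val
    for key, val in header.items():
        buf.write(f"# {key}={val}\n")
    buf.write("segment\tz_um\td_nm\tF_nN\n")
    for seg, zs, ds in (
        ("approach", curve.approach_z_um, curve.approach_d_nm),
        ("retract", curve.retract_z_um, curve.retract_d_nm),
    ):
        for z, d in zip(zs, ds):
            buf.write(f"{seg}\t{float(z)!r}\t{float(d)!r}\t{float(c.k_n_per_m * d)!r}\n")
    path.write_text(buf.getvalue())


def read_curve_tsv(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta_raw: dict[str, str] = {}
    seg_z: dict[str, list[float]] = {"approach": [], "retract": []}
    seg_d: dict[str, list[float]] = {"approach": [], "retract": []}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line")
                key, _, val = body.partition("=")
                meta_raw[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "segment":
                continue
            if len(parts) != 4 or parts[0] not in seg_z:
                raise ValueError(f"{path}:{lineno}: malformed sample line")
            try:
                seg_z[parts[0]].append(float(parts[1]))
                seg_d[parts[0]].append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric sample") from exc
    cant = CantileverSpec(
        k_n_per_m=float(meta_raw.get("k_n_per_m", 0.05)),
        tip_radius_um=float(meta_raw.get("tip_radius_um", 5.0)),
        noise_sd_nm=float(meta_raw.get("noise_sd_nm", 0.0)),
        drift_nm_per_um=float(meta_raw.get("drift_nm_per_um", 0.0)),
    )
    meta = {}
    for key, val in meta_raw.items():
        if key.startswith("meta."):
            try:
                meta[key[5:]] = float(val)
            except ValueError:
                meta[key[5:]] = val
    return ForceCurve(
        approach_z_um=np.array(seg_z["approach"]),
        approach_d_nm=np.array(seg_d["approach"]),
        retract_z_um=np.array(seg_z["retract"]),
        retract_d_nm=np.array(seg_d["retract"]),
        cantilever=cant,
        kind=meta_raw.get("kind", "indentation"),  # type: ignore[arg-type]
        cell_id=int(meta_raw.get("cell_id", -1)),
        label=meta_raw.get("label", ""),
        seed=int(meta_raw.get("seed", 0)),
        meta=meta,
    )
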