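"""Simulate an indentation force curve and recover the Young's modulus.

A spherical-probe curve is generated at a known modulus with realistic noise
and drift, then analyzed blind: baseline correction, contact-point search,
and the Hertz fit F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2).
"""

from mechscope import (
    CantileverSpec,
    RampConfig,
    baseline_correct,
    find_contact_point,
    fit_hertz,
    simulate_indentation,
)

E_TRUE = 2500.0  # Pa
cant = CantileverSpec(k_n_per_m=0.05, tip_radius_um=5.0, noise_sd_nm=1.0, drift_nm_per_um=0.4)
ramp = RampConfig(z_start_um=0.0, z_end_um=5.0, samples_per_segment=400, setpoint_nN=5.0)

curve = simulate_indentation(E_TRUE, nu=0.5, cant=cant, ramp=ramp, z0_true_um=2.0, seed=7)
corrected = baseline_correct(curve)
z0, d0 = find_contact_point(corrected)
fit = fit_hertz(corrected, R_um=5.0, nu=0.5, contact=(z0, d0))

print(f"true modulus      : {E_TRUE:.0f} Pa (contact at z0 = 2.000 um)")
print(f"contact point     : z0 = {z0:.3f} um")
print(f"fitted modulus    : E = {fit.E_fit_pa:.0f} Pa "
      f"({100 * abs(fit.E_fit_pa - E_TRUE) / E_TRUE:.1f}% error)")
print(f"fit quality       : rms residual {fit.rms_residual_nN:.3f} nN over {fit.n_points} points, "
      f"converged = {fit.converged}")
print("\nThe fit recovers the modulus despite 1 nm deflection noise and a")
print("0.4 nm/um baseline drift, from the curve alone (no ground truth used).")
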