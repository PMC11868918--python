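"""Simulate a single-cell force spectroscopy (SCFS) curve and extract adhesion.

The retract segment carries an adhesive well with discrete rupture steps;
the analysis reports the peak adhesion force (magnitude of the most negative
retract force), the work of adhesion, and the number of rupture events.
"""

from mechscope import (
    CantileverSpec,
    RampConfig,
    baseline_correct,
    extract_adhesion,
    simulate_scfs,
)

F_TRUE = 2.0  # nN
cant = CantileverSpec(k_n_per_m=0.05, tip_radius_um=5.0, noise_sd_nm=0.5)
ramp = RampConfig(z_start_um=0.0, z_end_um=5.0, samples_per_segment=400, setpoint_nN=5.0)

curve = simulate_scfs(F_TRUE, detach_separation_um=1.5, n_rupture_steps=3,
                      cant=cant, ramp=ramp, seed=11)
res = extract_adhesion(baseline_correct(curve))

print(f"true adhesion force : {F_TRUE:.2f} nN (3 rupture steps)")
print(f"extracted           : F_adh = {res.F_adh_nN:.3f} nN")
print(f"work of adhesion    : {res.work_fJ:.3f} fJ")
print(f"rupture steps found : {res.n_rupture_steps}")
print(f"pull-off position   : z = {res.pulloff_z_um:.2f} um")
print("\nThe adhesion force is the depth of the retract-curve well — the force")
print("needed to fully separate the probe-bound cell from the target cell.")
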