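# Methods

This note documents the models behind each stage of the virtual workflow,
the defaults and why they were chosen, and what the simulations do and do
not establish about real instruments and cells.

## Units contract

Fixed once, package-wide: piezo height `z` in µm (increasing toward the
sample), cantilever deflection `d` in nm, force `F = k·d` in nN (k in N/m
times d in nm is exactly nN), spring constant `k` in N/m, probe radius `R`
in µm, Young's modulus `E` in Pa, adhesion force in nN, work of adhesion in
fJ (1 nN·µm = 1 fJ). All conversions are internal and covered by tests.

## Scene simulator

Scenes contain two adherent cell types as rotated ellipses with per-cell
mechanical truth. Cell type conventions (simulator conventions for detector
separability, not biological claims): typeB cells are ~30% larger
(radius 10.5 ± 1.2 µm vs 8.0 ± 0.9 µm) with coarse, low-amplitude interior
texture; typeA cells are smaller with fine, high-amplitude texture and a
slightly brighter rim. Mechanical truth: `E` log-normal with median 2000 Pa
(typeA) / 4500 Pa (typeB), log-SD 0.25 — the few-kPa range typical of
adherent cancer cell lines — and adhesion force normal with mean 1.2 / 2.4 nN
(SD 0.25 / 0.4 nN), floored at 0.05 nN. typeB is deliberately stiffer and
more adhesive so population-level ordering checks have a known answer.

Placement is seed-reproducible dart throwing. The probe disc is placed
first in a border-free zone and cells may not intersect it, guaranteeing a
cell-free probe region even at high density. A candidate cell is accepted
when its raster mask overlaps the running union of earlier cells by at most
`max_overlap_fraction` of its own area (high preset: 0.18; low preset: 0 plus
a center-spacing rule beyond the sum of radii). Candidates clipped by the
image border to less than 80% of their analytic area are rejected, so every
cell is at least mostly visible. Radii are resampled on rejection; a hard
`UnsatisfiableDensityError` is raised only when the preset target is
geometrically unreachable (high-preset coverage below 60% after placement,
low preset unable to place without contact, or no cross-type contact in a
high-density scene).

Density presets follow the co-culture definitions the package emulates: the
high preset (default 90 cells per type on a 384 × 384 px field at
0.65 µm/px) lands at 66–72% coverage across seeds, comfortably above the 60%
bound; the low preset (4 cells per type) stays near 3–5%, below the 10%
bound. Pixel size is a simulator convention (≈10× objective); no
magnification is asserted for any real instrument. Coverage is computed by
pixel counting on the rasterized union mask, so overlap handling is exact by
construction; the rasterizer's strict-inequality boundary convention is the
package's pixel-membership convention throughout.

Rendering paints cells in z-order (later cells occlude earlier ones, as in a
monolayer — intensities do not add), each as a bright parabolic interior
dome plus a Gaussian rim ring and band-limited interior texture; the probe
is a dark disc with a bright rim; a smooth illumination gradient and
additive Gaussian noise (SD 120 counts of the 16-bit range) are applied
last. Fluorescence channels are noisy indicator masks: red for typeA, green
for typeB. Identical (config, seed) reproduces bit-identical scenes and
images.

## Bright-field detector

A deterministic classical pipeline stands in for a trained network (which
is out of scope; external boxes can be supplied in YOLO-txt or COCO-JSON):

1. difference-of-Gaussians band-pass (σ 2 / 18 px) removes the illumination
   gradient;
2. the probe is localized by annular template matching on the band image
   and masked out; the probe box is emitted only when the correlation is
   ≥ 0.45 **and** the local band amplitude exceeds 8× a pixel-noise estimate,
   so featureless images produce no box;
3. a smoothed "dome" map (σ 3 px) peaks near each cell center even when
   cells touch; Otsu foreground (gated by an absolute contrast test at 3×
   the pixel-noise estimate — the estimate also absorbs intracellular
   texture, hence the low multiplier) plus peak proposals at minimum
   separation 7 px seed a watershed;
4. per-candidate features — equivalent radius from the watershed-region
   area, and interior texture energy measured away from the rim — feed a
   fixed linear rule (`(r − 14 px)/3 − 3·(tex − 1)`): large/smooth → typeB,
   small/textured → typeA, with confidence a logistic map of the score
   magnitude;
5. boxes are squares centered on the dome peak with half-width 1.25× the
   equivalent radius (watershed regions lose their overlap zones to
   neighbours, so raw region boxes are biased small), followed by
   non-maximum suppression at IoU 0.5.

The thresholds were calibrated against the simulator's default rendering;
on ten seeded default high-density scenes the detector achieves overall
precision and recall above 0.85 at IoU 0.5 (typically ≈0.93). This measures
the evaluation harness and the simulator's separability conventions, not
any real-microscope performance.

Fluorescence auto-annotation thresholds each channel (Otsu with a contrast
gate; blank channels yield no boxes) and splits touching same-type cells by
distance-transform watershed before emitting per-component boxes — the
plain connected-component reading would merge contacting same-type cells at
high density. Components visible in both channels take the label with the
larger overlap.

Detection metrics use greedy confidence-ordered one-to-one matching at a
configurable IoU threshold (default 0.5, stated explicitly in every report);
0/0 precision and recall are defined as 1 so empty scenes are
non-pathological.

## Targeting

The "central area" of a cell is operationalized as its detection-box center.
Pixel→stage mapping is a least-squares affine fit of ≥ 3 non-collinear
fiducial pairs; axis handedness and any flips live entirely inside the
affine. `plan_move` is the difference of the calibrated cell and probe
centers; `apply_move` displaces the virtual probe by the inverse-calibrated
move and errors if it would leave the image. With exact calibration the
round trip lands within 0.5 px of the box center for every planned move.
Targets are selected per type by descending detector confidence, excluding
boxes within 5 px of the image border and cells whose center lies under the
probe box.

## Virtual AFM

Indentation curves solve, per sample, the implicit balance
`k·d = (4/3)·E/(1−ν²)·√R·δ^{3/2}` with `δ = (z − z0) − d` — the spherical
Hertz (paraboloid-approximation) force with the cantilever's own deflection
fed back into the indentation. The left side is strictly increasing in `d`,
so a bracketed, safeguarded Newton iteration (relative tolerance 1e-12,
bisection fallback) always converges; an independent bisection solver agrees
to better than 1e-8 relative and the balance holds at every sample to 1e-9.
The approach stops at the force setpoint (default 5 nN); the retract
retraces the elastic curve (no adhesion in indentation mode). Defaults:
k = 0.05 N/m, R = 5 µm, ν = 0.5 (incompressible cell), ramp 5 µm at 400
samples per segment — a plausible soft-cantilever/microsphere configuration;
all are config fields, and none is asserted as any instrument's setting.
Drift is linear in absolute piezo position (so one fitted line corrects both
segments) and Gaussian deflection noise is applied after the physics.

SCFS retract curves are phenomenological: a soft elastic approach
(default contact modulus 800 Pa), then an adhesive well on the separation
axis that descends linearly to exactly `−F_adh` at the sample nearest 35% of
the detach separation (snapping to a sample keeps the discrete minimum
exact), followed by `n_rupture_steps` equal force releases reaching baseline
at the detach separation (default 1.5 µm, 3 steps). Receptor-bond kinetics,
tether elasticity, viscoelasticity and hydrodynamic drag are deliberately
out of scope — only the peak adhesion force (plus work and step count) is
the read-out of interest.

## Force-curve analysis

`baseline_correct` fits a straight line in `z` to the first 30% of the
approach and subtracts it from both segments (≥ 10 samples required).

`find_contact_point` scans candidate contact indices; each candidate scores
a piecewise model — zero force before, `C·δ^{3/2}` after, with
`δ = (z − z_j) − (d − d_j)` and the amplitude `C` profiled out in closed
form — and the best candidate is refined by parabolic interpolation of the
residual profile. Subtracting the deflection inside the candidate model
matters: ignoring it biases the contact point by more than a sample at soft
spring constants. A curve whose best piecewise model fails to beat the
all-baseline model by ≥ 5% raises `NoContactError`. This method was chosen
over ratio-of-variances because it shares the Hertz model with the fit and
is deterministic.

`fit_hertz` selects post-contact samples with `δ` up to 80% of the maximum
indentation (shallow-indentation practice; configurable), initializes from
the closed-form linear regression of `F^{2/3}` on `δ`, and refines
`(log E, z0)` jointly by bounded least squares (gtol 1e-10) with the sample
set frozen. Non-converged or non-positive fits are flagged, excluded from
per-cell aggregates, and counted — never imputed.

`extract_adhesion` reports `F_adh = max(0, −min F_retract)` (zero unless the
minimum clears 3× the noise level), the work as the trapezoid integral of
`|F|` over the contiguous negative region containing the minimum (including
one bounding sample per side so edge trapezoids count), and rupture steps as
baseline-ward force jumps exceeding 5× the noise SD while below baseline.

Per-cell aggregation is the arithmetic mean of the (default 10) per-curve
values, with SD; median is available. At 2% force noise the median modulus
recovery error over 200 curves spanning 0.5–50 kPa is ≤ 5% (typically ≈2%);
noise-free recovery is ≤ 0.1%.

## Population statistics

The Gaussian "fit" is maximum likelihood on the raw per-cell values
(µ = sample mean, σ = population SD), making it independent of histogram
binning; the histogram overlay is that density scaled by n·binwidth. An
all-equal sample is reported with a degenerate-fit flag rather than an
error. The two-type comparison is descriptive — difference of means, the
ordering direction, and a Mann-Whitney rank p-value — with no significance
threshold, because the claim of interest is an ordering, not a test
decision.

## Orchestration and reproducibility

`run_experiment` chains scene → render → detect → select → per target
(plan, move, simulate `curves_per_cell` curves from the ground truth of the
cell actually under the moved probe, analyze, aggregate) → summarize and
compare. Defaults mirror the emulated experimental design: 50 cells per
type, 10 curves per cell (a full indentation run takes well under a minute
on one CPU). If the probe center lands on no cell, a baseline-only curve is
recorded and the no-contact path exercises the exclusion logic; every
selected target ends as either a measured cell or a logged exclusion. All
stage seeds derive from the master seed via CRC-tagged `SeedSequence`
(stable across processes), so identical configs give byte-identical CSV/JSON
artifacts; wall-clock timings go to the log only.

## What passing tests do and do not show

The simulator establishes *internal* correctness: the analysis recovers the
parameters the generator used, the detector meets its bar on the renderer's
morphology conventions, and the pipeline is deterministic. It does not
validate against real micrographs (no phase-contrast artifacts, motility,
debris, or focus variation), real force data (no viscoelasticity, finite
cell thickness, or hydrodynamic drag), or any trained network's accuracy.
Headline biological numbers from living-cell studies (population modulus and
adhesion distributions, learned-detector precision) depend on private data
and weights and are intentionally not reproduced; the package's claims stop
at the property level.
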