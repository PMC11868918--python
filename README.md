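# mechscope

A hardware-free workbench for **image-recognition-assisted AFM single-cell
mechanics in co-culture**. It emulates, end to end in software, the workflow
in which an optical-image detector finds cells of two co-cultured types and
the AFM probe tip in a bright-field micrograph, the stage moves the probe
onto each target cell, and force spectroscopy extracts the cell's Young's
modulus (indentation assay) or adhesion force (single-cell force
spectroscopy, SCFS).

Because every stage is simulated against known ground truth, the package is
useful for validating force-curve analysis code, benchmarking cell detectors
on dense co-cultures, and prototyping automated probe-targeting logic —
without an instrument, cells, or trained network weights. Externally
produced detection boxes (e.g., from a YOLO-family network) plug in through
the YOLO-txt / COCO-JSON readers; the pipeline contract is "boxes in, moves
out".

## What it computes

- **Synthetic co-culture scenes** — two morphologically distinct adherent
  cell types with per-cell mechanical ground truth, at a *high-density*
  preset (different types in physical contact, ≥ 60% surface coverage) or a
  *low-density* preset (no contact, ≤ 10% coverage), plus a spherical probe
  tip; rendered as paired bright-field and two-channel fluorescence images
  (typeA fluoresces red, typeB green).
- **Detection** — a deterministic classical detector (band-pass filtering,
  dome-peak proposals, watershed, fixed linear type rules, annular template
  match for the probe) working on the bright field alone; plus
  fluorescence-assisted auto-annotation for dataset preparation; evaluated
  by greedy IoU-0.5 matching (precision/recall).
- **Targeting** — least-squares affine pixel→stage calibration and move
  plans that land the probe on each target's bounding-box center.
- **Force curves** — a virtual AFM solving the implicit cantilever–sample
  balance `k·d = (4/3)·E/(1−ν²)·√R·δ^{3/2}` with `δ = (z − z0) − d`
  per sample (spherical Hertz contact), and phenomenological SCFS retract
  curves whose well depth equals the true adhesion force exactly.
- **Analysis** — baseline correction, profiled piecewise contact-point
  search, nonlinear Hertz fit for `E`, adhesion force / work / rupture-step
  extraction, per-cell aggregation (default: mean of 10 curves).
- **Population statistics** — per-type histograms with maximum-likelihood
  Gaussian fits and a descriptive two-group comparison.

## Worked example

```sh
python examples/06_full_experiment.py
```

runs a reduced indentation experiment (8 cells per type, 10 curves per
cell) and prints:

```
measured 16 cells (0 excluded)
  typeA: n=8, E = 1735 +/- 295 Pa (Gaussian fit mu=1735, sigma=276)
  typeB: n=8, E = 4566 +/- 1301 Pa (Gaussian fit mu=4566, sigma=1217)
  ordering: typeB > typeA (difference 2831 Pa, rank-based p = 0.000155)
```

Each line is the per-type population of per-cell moduli: each cell's value
is the mean of 10 Hertz fits to independently noisy force curves simulated
at that cell's true modulus. typeB cells are generated stiffer than typeA,
so a correct pipeline must order typeB above typeA — which the comparison
report confirms. The other examples (`examples/01…05`) demonstrate scene
generation, detection and its evaluation, move planning, a single Hertz fit,
and SCFS adhesion extraction, one capability each.

The same workflow is scriptable from the shell:

```sh
mechscope run-experiment --assay indentation --seed 1 --out runs/demo
mechscope report --run-dir runs/demo
```

with subcommands `simulate-scene`, `annotate`, `detect`,
`evaluate-detection`, `plan-moves`, `run-experiment`, `analyze-curves`,
`stats`, `report`.

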