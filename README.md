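# scpmech

Continuum-level material modelling toolkit for the spinal cord–pia mater
complex: a hyper-viscoelastic (Ogden + quasi-linear viscoelastic) model for
spinal cord white matter, a hyperelastic Ogden model for the pia mater, and
everything needed to calibrate and evaluate them against uniaxial tissue
tests and transverse pellet-impact trajectories.

## What is included

- **`scpmech.constitutive`** — Ogden strain energy with a hydrostatic
  penalty, closed-form incompressible uniaxial nominal stress, normalized
  Prony reduced relaxation, and hereditary-integral QLV stress evaluation by
  per-term exponential recurrence.
- **`scpmech.simulation`** — constant-rate single-element compression and
  tension tests, and an explicitly reduced-order single-degree-of-freedom
  pellet-impact surrogate (cord foundation + pia membrane strips). Only
  orderings, sensitivities and energy conservation of the surrogate are
  meaningful, not absolute displacements.
- **`scpmech.calibration`** — constrained multi-rate parameter
  identification for the cord (equal rate weighting, `sum(G_i) <= 1`
  enforced by a stick-breaking reparameterization, staged or joint modes
  with deterministic restarts) and a single-term Ogden fit for the pia that
  maximizes R².
- **`scpmech.metrics`** — R², RMSE, a two-component (size/shape, 0.5/0.5)
  curve-correlation rating, and observed-order Richardson extrapolation.
- **`scpmech.kinematics`** — trajectory phase segmentation
  (loading/rebound/unloading), per-phase polynomial fitting, pointwise
  averaging, and summary extraction (peak, time to peak, initial velocity).
- **`scpmech.synthetic`** — seeded generators for every input the pipeline
  consumes: multi-rate cord curves, pia tension curves, trajectory replicate
  sets, and mesh-convergence series.
- **`scpmech.cli`** — `scpmech` command with subcommands `make-synthetic`,
  `simulate-curve`, `simulate-impact`, `fit-cord`, `fit-pia`, `evaluate`,
  `trajectory`, `richardson`, `demo`.

## CLI examples

```sh
# end-to-end recovery study (generate -> fit -> evaluate), deterministic per seed
scpmech demo --seed 1 --out demo_out/

# simulate a single-element cord compression curve and fit it back
scpmech simulate-curve --material cord --rate 0.32 --out slow.csv
scpmech simulate-curve --material cord --rate 77.22 --out fast.csv
scpmech fit-cord --curves slow.csv --curves fast.csv --out fit.json

# pia tension fit
scpmech simulate-curve --material pia --rate 0.05 --out pia.csv
scpmech fit-pia --curve pia.csv

# curve/trajectory comparison and mesh convergence
scpmech evaluate --ref a.csv --cand b.csv --metric cora
scpmech richardson --h 0.8,0.4,0.2 --f 5.96,5.24,5.06
```

Fit and synthetic-data parameters can be given as YAML/JSON config files
(`--config` / `--params`); unknown keys are rejected with exit code 2,
numerical failures exit 1. Curve CSVs carry `strain,stress_pa,rate_per_s`;
trajectory CSVs carry `time_s,displacement_mm`.

## Conventions

Stress is nominal (engineering) in Pa; strain is engineering strain, with
compression curves exported as positive strain/stress. Stretch λ < 1 in
compression. The reduced relaxation function is normalized so g(0) = 1 with
long-term fraction 1 − ΣGᵢ; an `overstress` formulation switch (viscous part
riding on the full elastic stress) is available on `QLVMaterial`.
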