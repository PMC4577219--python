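# ireplan

Voxel-based treatment-planning simulator for irreversible electroporation
(IRE) of liver tumors near major vessels. It reproduces the full planning
chain on synthetic scenes:

* **scene** — voxel grids, tissue label maps (liver / tumor / vessel /
  electrodes), rasterization of ellipsoids, capsules and needle
  electrodes, electrode-pair geometry, and closed-form planning volumes
  (safety-margin ellipsoid, cylinder hot-zone estimate). Includes a
  deterministic synthetic four-needle case whose pairwise tip distances
  match the reference configuration (18, 14, 12, 15, 12, 17 mm).
* **materials** — electrical and thermal tissue parameters (liver
  0.091→0.45 S/m, tumor 0.4→1.6 S/m, vessel 0.7→1.05 S/m, thermal
  coefficient 1.5 %/K, perfusion 0.018 1/s, Arrhenius kinetics), with
  field-dependent conductivity σ(E) as a linear ramp (smoothstep variant
  available) between the reversible onset and the IRE threshold.
* **efield** — stationary solve of ∇·(σ(E)∇φ) = 0 per energized electrode
  pair: cell-centered finite volumes with harmonic face averaging,
  Jacobi-preconditioned conjugate gradients, six outer iterations with a
  monotone (never-decreasing) conductivity update, floating inactive
  electrodes, and dual current estimators (volume Joule integral vs anode
  surface flux) as a conservation check. Each solve also records the
  *exposure field* — the voxelwise maximum field over the iterations —
  which is the field against which electroporation thresholds are judged.
* **sequence** — pulse protocols (the 18-train reference schedule ships as
  a CSV fixture), per-train solves combined by voxelwise maximum, coverage
  curves, lesion volumes at per-tissue thresholds (700 V/cm liver,
  800 V/cm tumor), and duty-cycle / power bookkeeping.
* **thermal** — transient perfused bioheat equation with duty-cycle-scaled
  Joule heating, implicit Euler stepping, Arrhenius damage integral Ω,
  damage probability 1−exp(−Ω), and temperature/damage exceedance volumes.
  No boiling model: temperatures above 100 °C are reported with a warning.
* **report** — measured-vs-computed current comparison (per-train percent
  errors, RMSE), headline volumes, and a deterministic JSON + text report.

## CLI

```sh
ireplan synth-case --spacing 0.5 --out scene/
ireplan solve --scene scene/ --pair 1,2 --voltage 3000 --out fields/
ireplan coverage --scene scene/ --protocol fixtures/protocol_table3.csv --out cov/
ireplan thermal --scene scene/ --out thermal/
ireplan report --run cov/
ireplan all --out run/ --spacing 1.0   # chains everything
```

Volumes are written as NIfTI (`.nii.gz`) or MetaImage (`.mha`) with JSON
sidecars naming the labels; protocols and coverage curves are CSV.

## Notes

* Internal computation is SI (m, S/m, K); interfaces use mm, V/cm and cm³.
* The reversible-onset thresholds E_rev are not part of the published
  parameter set; defaults are E_irr/2 (liver 350, tumor 400, vessel
  350 V/cm) and configurable. Tumor perfusion defaults to half the liver
  value. Both are documented assumptions.
* Default grid for tests is 1 mm spacing; use 0.5 mm for production runs.
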