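# cxlsim

Patient-specific biomechanical simulation of corneal cross-linking (CXL)
induced geometry changes: synthetic keratoconic topography → labeled
quadratic tetrahedral mesh → pre-stressed anisotropic hyperelastic inflation
→ spatially graded weakening/stiffening fields → post-treatment curvature
metrics → agreement statistics.

## What it does

- **`cxlsim.synthetic`** — reproducible keratoconic topographies (rotated
  biconic base + localized cone protrusion + thinning + optional noise) and a
  plain-text CSV grid dialect with round-trip I/O.
- **`cxlsim.metrics`** — tangential curvature maps (local best-fitting
  sphere, keratometric index 1.3375), Kmax-t / KmaxMean3, rotated-biconic
  fits over 8 mm (index 1.376: sphere, cylinder, axis, spherical
  equivalent), minimum pachymetry, percentile-based cone detection.
- **`cxlsim.meshing`** — graded quadratic (10-node) tetrahedral extrusion of
  the corneal dome between the two surfaces, with anterior/posterior/limbus
  labels, normalized depth, curved boundary, Gmsh MSH 2.2 I/O, and a closed
  spherical-shell builder for solver verification.
- **`cxlsim.constitutive`** — two-fiber-family dispersed exponential
  hyperelastic law (isochoric split, tension-only fibers, volumetric
  penalty), linear through-depth stiffness scale (anterior/posterior 1.68,
  unit mean), keratoconus weakening and CXL stiffening multipliers.
- **`cxlsim.fields`** — the three treatment fields: standard (9 mm zone,
  peak ×16.3, Gaussian radial weight reaching 10% at 90% of the zone radius,
  linear depth decay to 1 at 300 µm), custom-standard (same, centered on the
  cone), custom-ELZA (extra 4 mm central zone, ×1.33 peak, 400 µm depth).
- **`cxlsim.solver`** — total-Lagrangian Newton FEM with follower pressure,
  sliding limbal boundary, stress-free geometry recovery
  (backward-displacement fixed point with Aitken relaxation), and the
  apical-rise tangential-modulus estimator.
- **`cxlsim.pipeline`** — end-to-end protocol simulation (pre/post metrics
  and deltas), IOP × α_KC sensitivity grids, cohort summaries with
  ANOVA/Tukey.
- **`cxlsim.stats`** — Lin's concordance correlation and Bland–Altman limits
  of agreement.

## CLI

```sh
cxlsim generate --config spec.yaml --out cornea.csv --seed 1
cxlsim metrics cornea.csv --report metrics.json
cxlsim fields cornea.csv --protocol custom_elza --out field.csv
cxlsim simulate cornea.csv --protocol standard --iop 15 --alpha 0.429 --report out.json
cxlsim sensitivity --cohort dir/ --protocol custom_elza --out table.csv
cxlsim agree truth.csv model.csv --out agree.json
```

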