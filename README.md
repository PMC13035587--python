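# vertefem

Voxel finite-element analysis of vertebral bodies with lytic defects and
cement augmentation.

Metastatic (lytic) lesions hollow out vertebral bodies; vertebroplasty
fills the lesion with bone cement. Conventional PMMA cement (~2500 MPa) is
far stiffer than the trabecular bone it replaces, and the clinical concern
is stress shielding: the stiff implant restores strength but concentrates
stress in the adjacent bone. This package implements the calibrated
QCT-based finite-element workflow used to study that trade-off —
fully runnable on synthetic specimens, since the cadaveric scans such
studies use are not public.

## The model

A specimen is a voxel density volume (g/cm³) with labels for bone, PMMA
embedding caps, defect and augmentation. Each voxel becomes one 8-node
hexahedral element (2×2×2 Gauss points) with

- elastic modulus `E = a·ρ^b` (MPa; specimen-specific `a`, `b`), ν = 0.3,
- yield strain `ε_yield = 0.0081·ρ^−1.42` (ρ = ash density),
- lesions at a nominal 0.1 MPa, caps at 2500 MPa, cement at its
  per-condition modulus {50, 300, 1000, 2000, 2500} MPa (none can fail).

The inferior cap is fixed, the superior cap is driven axially in
increments; elements whose maximum absolute principal strain exceeds
`ε_yield` fail (modulus → 0.1 MPa, permanently), re-solving within each
increment until no new failures. The fracture force is the
force–displacement peak before a substantial (20%) load drop. Elliptical
defects are sized by their transverse area fraction (20%/50%) at the
minimum-cross-section plane; von Mises stress profiles are read along
three midsagittal vertical lines at the specimen's 50%-defect fracture
force; `a` is calibrated per specimen (b fixed) so the predicted fracture
force matches an experimental target. Cohort statistics: paired t-tests of
max stress per cement vs intact, Shapiro–Wilk, and a donor random-intercept
mixed model with ICC. See `docs/methods.md` for assumptions and numerics.

## Worked example

```python
from vertefem import (SynthParams, synth_vertebra, DefectSpec, insert_defect,
                      augment, build_mesh, build_material_field,
                      PowerLawCoefficients, run_fracture)

vol = synth_vertebra(SynthParams(seed=7))          # synthetic vertebra + caps
coeffs = PowerLawCoefficients(a=7546, b=2.0)
mesh = build_mesh(vol)

for name, v in {
    "intact": vol,
    "50% defect": insert_defect(vol, DefectSpec(fraction=0.5)),
    "50% + PMMA": augment(insert_defect(vol, DefectSpec(fraction=0.5)), 2500.0),
}.items():
    mats = build_material_field(v, coeffs)
    curve, frac = run_fracture(mesh, mats)
    print(f"{name:11s} fracture force {frac.fracture_force:7.0f} N")
```

prints

```
intact      fracture force    4576 N
50% defect  fracture force    3639 N
50% + PMMA  fracture force    5673 N
```

— carving out half of the mid-plane cross-section costs this specimen about
a fifth of its strength, and filling the cavity with conventional PMMA
more than restores it. The full study (`analysis/02_run_cohort.py`) shows
the other side of the trade-off: mean maximum stress rises steeply with
cement stiffness while the strength gain saturates.

## The analysis

Numbered drivers under `analysis/` reproduce the study end-to-end, writing
tables to `results/` (volumes and caches go to `scratch/`):

1. `01_synthesize_cohort.py` — 6 vertebrae / 4 donors, 78-model design table
2. `02_run_cohort.py` — fracture forces and stress profiles for all 78 models
3. `03_calibrate_coefficients.py` — recovery of hidden per-specimen `a`
4. `04_statistics.py` — paired tests, normality, donor mixed model + ICC

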