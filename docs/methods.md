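# Methods

`vertefem` models the compression of a metastatically weakened vertebral
body between PMMA embedding blocks, asking how lytic defect size and
augmentation-cement stiffness change fracture force and internal stress.
This note records the model, its assumptions, the synthetic study
conditions, and the numerical choices.

## The digital specimen

A specimen is a voxel grid of volumetric density ρ (g/cm³) with a label
mask (background, bone, PMMA cap, defect, augmentation). The synthetic
generator emulates what a calibrated, segmented QCT reconstruction of an
embedded vertebral body provides:

- a waisted elliptic-cylinder body (transverse semi-axes shrink linearly
  from the ends to `waist_factor` at mid-height, default 0.75), so a unique
  minimum-cross-section plane exists as in a real vertebral body;
- a one-voxel cortical shell. Its density (0.45 g/cm³) is the
  partial-volume average a coarse scan reports when a thin dense cortex is
  smeared over a 2 mm voxel; at full cortical density (~0.9) the 2 mm shell
  would carry nearly the entire axial load and defects in the centrum would
  be mechanically irrelevant, which is not how vertebral bodies behave;
- a trabecular interior sampled from a Gaussian random field (white noise
  smoothed to `correlation_length` = 3 mm, rescaled to mean 0.25, sd
  0.06 g/cm³, clipped at zero), giving the patchy superior–inferior density
  heterogeneity of real centra;
- PMMA caps (2 voxels) covering the end-slice footprint at both axial ends.

Default grid: 16 × 14 × 20 voxels at 2 mm spacing (~26 × 22 mm body,
~32 mm centrum, ≈ 2 000 elements). This coarse resolution keeps a 78-model
cohort in the minutes range on one CPU; QCT-resolution grids
(0.586 × 0.586 × 0.6 mm) are available through `SynthParams`. All sample
sizes below (6 vertebrae, 4 donors, 20 %/50 % defects, five cement moduli)
are the study conditions of the analysis the package implements.

What the generator does **not** emulate: posterior elements, endplates,
cortical anisotropy, scanner physics (noise, beam hardening) and real
inter-donor biology (donors differ only through independent field
realizations and an id). Passing trend tests on these synthetics shows the
*pipeline* behaves correctly (defects weaken, cement reinforces, stiffer
cement concentrates stress); it does not validate predictions for any real
vertebra.

## Material mapping

Each voxel becomes one 8-node hexahedral element with:

- elastic modulus E = a·ρ^b (MPa), specimen-specific coefficients,
  defaults a = 7546, b = 2.0 (cohort means of published specimen-specific
  calibrations), floored at 0.1 MPa;
- Poisson's ratio 0.3 everywhere;
- yield strain ε_yield = 0.0081·ρ^−1.42 for bone; ρ is ash density, taken
  equal to the stored density by default (`ash_density_scale` exposes the
  apparent→ash conversion, default 1.0, because no conversion factor is
  part of the model statement — tune it when feeding real data);
- special regions: lytic defect 0.1 MPa (mechanically removed), PMMA caps
  2500 MPa, augmentation cement a uniform per-condition modulus. None of
  these can fail: the yield law is density-based and only meaningful for
  bone. A linear HU→density phantom calibration (`PhantomCalibration`) is
  provided for real scans; synthetic volumes are generated directly in
  density space.

## Finite-element solver

Voxel mesh (element size = voxel size), trilinear hex8 elements with
2 × 2 × 2 Gauss integration. With uniform ν, every element shares one unit
stiffness matrix scaled by its modulus, so reassembly after damage is a
vector rescale. Boundary conditions mimic the test rig: bottom face of the
inferior cap fixed in all directions, top face of the superior cap driven
axially with transverse translations free (an unconstrained crosshead). A
rigid transverse coupling was considered and rejected as default because
the free-transverse variant is both closer to a spherical-seat crosshead
and strictly defined by Dirichlet data.

Element strain is evaluated at the element centroid (equal to the Gauss
average for a box element); stress follows from the isotropic elasticity
matrix; the element scalar compared to ε_yield is the maximum absolute
principal strain by default (von Mises equivalent strain by config) — the
failure criterion needs a single scalar per element and compressive
principal strain dominates this loading mode.

Solver: Dirichlet elimination, then sparse direct factorization below
2 000 free dofs and Jacobi-preconditioned conjugate gradients (relative
tolerance 1e−8, warm-started from the previous damage state) above. On
these meshes CG is an order of magnitude faster than direct factorization
and the warm start makes the damage loop cheap. Verified against closed
forms (uniaxial compression, patch test, rigid-body motion) and an
independent dense assembly on small meshes.

## Progressive failure

Displacement is applied in increments Δu. At each increment, elements whose
strain measure exceeds their yield strain fail — modulus drops to 0.1 MPa,
permanently — and the solve repeats within the increment until no new
failures occur (cap 50 iterations), which removes first-order Δu
sensitivity. The force–displacement curve records the base reaction; the
fracture force is the running peak, reported when the force falls below
`stop_fraction` = 0.80 of it (the curve is returned for any other
threshold choice; the drop fraction is a detection convention, not a
physical parameter).

Because each damage state is linear in the prescribed displacement, the
implementation solves once per damage state at unit displacement and
scales; results are identical to re-solving every increment.

Δu defaults to 0.0125 × (minimum finite ε_yield) × specimen height
(≈ 80 increments to first shell yield). A refinement study on the synthetic
specimens showed the detected fracture force converged at this step
(halving changes it < 1 %), while 4–8× coarser steps shifted stiff-cement
conditions by several percent by merging failure cascades.

## Defects, augmentation, stress profiles

The reference plane is the transverse slice of minimum vertebral
cross-section (caps excluded, ties to the lowest slice; defect and
augmentation voxels count as cross-section so the plane is stable across
conditions of one specimen). A defect of area fraction f selects exactly
round(f × slice area) voxels of the shell-eroded interior ranked by
normalized elliptical radius (ellipse aspect follows the slice's principal
extents; ties broken lexicographically), guaranteeing the achieved fraction
to half a voxel and never breaching the shell. The footprint extrudes over
`height_fraction` (default 0.5) of the bone height — the transverse
fraction is the defined size; the vertical extent is a config choice, as is
the ellipse eccentricity. `ellipsoid` and `drilled_cylinder` (circular
bore, like experimentally drilled lesions) variants are provided.
Augmentation relabels defect voxels and records the cement modulus.

Stress profiles: the elastic solution is scaled so the base reaction equals
the specimen's 50 %-defect fracture force (the largest-defect tolerable
load, shared by all conditions of that specimen), and von Mises values are
read along three vertical lines in the central sagittal slab — through the
body centroid and offset ± 3 element lengths anterior/posterior — averaged
per vertical level. Levels intersected by no line are omitted. Profiles are
extracted from the undamaged elastic state by default; a config flag
instead accumulates progressive failure up to the target load first. The
package defaults to the elastic state because the profile is a comparative
load-path map across conditions, and at the 50 %-defect load the intact and
stiff-cement conditions are essentially undamaged.

## Calibration

Matching one scalar (the experimental fracture force) cannot identify both
a and b, so the default fixes b = 2.0 and brackets a within published
bounds ([300, 20 000] MPa), refining by safeguarded regula falsi — the
fracture force is monotone (nearly proportional) in a. Convergence:
relative force error ≤ 0.5 %. Unreachable targets return a non-converged
result with a boundary diagnosis. A 2-D grid-refinement mode explores the
(a, b) trade-off, breaking ties toward b = 2. The mesh and assembly pattern
are cached across forward evaluations; the yield-strain law is never
touched by calibration.

## Statistics

Standard routines are delegated (scipy OLS/t/Shapiro–Wilk, statsmodels
MixedLM REML); the study-specific structure is the pairing and tagging:
each cement stiffness is paired against the intact condition within
specimen (values averaged over defect sizes per specimen first), profile
peaks are tagged Upper/Lower by which half of the profile relative to the
defect center plane contains the maximum (the term has no standard
operational definition, so this one is fixed here), and the mixed model is
MaxStress ~ Condition + Group(20 %/50 %) + Region with a donor random
intercept; ICC = donor variance / (donor + residual variance). Intact rows
carry a "none" group level that is collinear with the Intact condition
dummy; the fit drops trailing fixed-effect terms until the design is full
rank. Identical pairs in the paired t return (t = 0, p = 1) as the
no-effect limit; zero-variance nonzero differences are an error. All tests
are two-sided; no multiple-testing correction is applied.

## Known limitations

Single-body linear-elastic model: no geometric nonlinearity, no contact,
no rate dependence, no post-yield softening beyond the 0.1 MPa reduction,
single lesions only, full cement filling only. The coarse default grid
resolves the stress profile at 2 mm; absolute stresses and forces on
synthetic specimens are model quantities, not predictions for any cadaver.
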