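"""Synthetic vertebral-body specimens.

Real vertebral FE pipelines start from a calibrated QCT scan: a voxel grid of
volumetric bone density (g/cm^3) segmented into the vertebral body plus the
PMMA embedding blocks used for mechanical testing.  This module generates
digital stand-ins with the same statistical structure: a waisted elliptic
body with a dense cortical shell, a spatially correlated heterogeneous
trabecular interior, and PMMA caps at both axial ends.

Axis convention: axis 0 = x (anterior-posterior), axis 1 = y (left-right),
axis 2 = z (inferior-superior, the loading axis).  The midsagittal plane is
the central y slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import SizingError

# Label codes shared by the whole pipeline.
BACKGROUND = 0
BONE = 1
PMMA_CAP = 2
DEFECT = 3
AUGMENTATION = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    BONE: "bone",
    PMMA_CAP: "pmma_cap",
    DEFECT: "defect",
    AUGMENTATION: "augmentation",
}

#: nominal physical density assigned to PMMA cap voxels (g/cm^3); the caps
#: receive a fixed modulus downstream, this value only marks them non-empty.
PMMA_DENSITY = 1.18


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic vertebral specimen.

    Defaults describe a coarse (fast) specimen: a ~26 x 22 mm elliptic body
    with a ~32 mm high centrum, a one-voxel cortical shell and
    a trabecular interior of 0.25 +/- 0.06 g/cm^3 with ~3 mm density
    patches.  The shell density (0.45 g/cm^3) is the partial-volume average
    a coarse scan reports when a thin dense cortex is smeared over a 2 mm
    voxel; modeling the shell at full cortical density would let it carry
    nearly the whole load, which coarse QCT reconstructions of vertebral
    bodies do not show.  QCT-resolution modeling
    (0.586 x 0.586 x 0.6 mm) is available by overriding ``spacing`` and
    ``grid_shape`` together.
    """

    grid_shape: tuple[int, int, int] = (16, 14, 20)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_radii: tuple[float, float] = (13.0, 11.0)  # mm, transverse semi-axes at the ends
    waist_factor: float = 0.75  # mid-height / end cross-section radius ratio
    shell_thickness: int = 1  # voxels
    shell_density: float = 0.45  # g/cm^3, partial-volume-averaged cortex at coarse voxels
    trab_mean: float = 0.25  # g/cm^3
    trab_sd: float = 0.06  # g/cm^3
    correlation_length: float = 3.0  # mm
    cap_thickness: int = 2  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (0.0 < self.waist_factor <= 1.0):
            raise ValueError("waist_factor must lie in (0, 1]")
        if self.trab_mean <= 0:
            raise ValueError("trab_mean must be positive")
        if self.trab_sd < 0:
            raise ValueError("trab_sd must be non-negative")
        if self.shell_thickness < 1 or self.cap_thickness < 1:
            raise ValueError("shell_thickness and cap_thickness must be >= 1")


@dataclass
class LabeledVolume:
    """A digital specimen: voxel density grid + label mask + spacing.

    ``density`` is volumetric density in g/cm^3; ``labels`` uses the module
    label codes.  Density is zero on background voxels.
    """

    density: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density.shape != self.labels.shape:
            raise ValueError("density and labels must share a shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(
            density=self.density.copy(),
            labels=self.labels.copy(),
            spacing=self.spacing,
            metadata=dict(self.metadata),
        )

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass
class CohortSpec:
    """A cohort of synthetic vertebrae with donor clustering.

    ``donor_assignment`` maps vertebra index -> donor index; by default
    vertebrae are distributed round-robin over ``n_donors`` donors so that
    several vertebrae share a donor, as in a cadaveric study.
    ``ground_truth_coeffs`` optionally carries per-specimen (a, b)
    density-modulus coefficients used to manufacture "experimental" fracture
    forces for calibration-recovery experiments (see
    :func:`vertefem.calibrate.simulate_experimental_forces`).
    """

    n_vertebrae: int = 6
    n_donors: int = 4
    base_params: SynthParams = field(default_factory=SynthParams)
    donor_assignment: Optional[dict[int, int]] = None
    overrides: dict[int, dict] = field(default_factory=dict)
    ground_truth_coeffs: Optional[list[tuple[float, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if not (1 <= self.n_donors <= self.n_vertebrae):
            raise ValueError("need 1 <= n_donors <= n_vertebrae")
        if self.donor_assignment is None:
            self.donor_assignment = {i: i % self.n_donors for i in range(self.n_vertebrae)}
        assigned = set(self.donor_assignment)
        if assigned != set(range(self.n_vertebrae)):
            raise ValueError("every vertebra must map to exactly one donor")
        if self.ground_truth_coeffs is not None and len(self.ground_truth_coeffs) != self.n_vertebrae:
            raise ValueError("ground_truth_coeffs must have one (a, b) pair per vertebra")


def _waist_scale(z_idx: np.ndarray, z_lo: int, z_hi: int, waist_factor: float) -> np.ndarray:
    """Radius scale factor per bone slice: 1 at both ends, waist_factor at mid-height."""
    mid = 0.5 * (z_lo + z_hi)
    half = max(mid - z_lo, 1e-9)
    frac = np.abs(z_idx - mid) / half  # 1 at ends, 0 at mid
    return waist_factor + (1.0 - waist_factor) * frac


def _bone_mask(params: SynthParams) -> tuple[np.ndarray, int, int]:
    nx, ny, nz = params.grid_shape
    dx, dy, dz = params.spacing
    z_lo = params.cap_thickness
    z_hi = nz - params.cap_thickness - 1
    n_bone_slices = z_hi - z_lo + 1
    if n_bone_slices < 3:
        raise SizingError(
            f"grid of {nz} axial voxels leaves {n_bone_slices} bone slices after "
            f"two caps of {params.cap_thickness}; need at least 3"
        )
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx, ry = params.body_radii
    if rx > (nx * dx) / 2.0 or ry > (ny * dy) / 2.0:
        raise SizingError(
            f"body radii {params.body_radii} mm do not fit a "
            f"{nx * dx:.1f} x {ny * dy:.1f} mm grid"
        )
    # interior must survive shell erosion at the waist
    waist_r = min(rx, ry) * params.waist_factor
    if waist_r / max(dx, dy) <= params.shell_thickness + 1:
        raise SizingError("waist cross-section too small to contain shell plus interior")

    x_mm = (np.arange(nx) - cx) * dx
    y_mm = (np.arange(ny) - cy) * dy
    mask = np.zeros(params.grid_shape, dtype=bool)
    z_idx = np.arange(z_lo, z_hi + 1)
    scale = _waist_scale(z_idx, z_lo, z_hi, params.waist_factor)
    X2 = (x_mm[:, None] ** 2)
    Y2 = (y_mm[None, :] ** 2)
    for z, s in zip(z_idx, scale):
        mask[:, :, z] = X2 / (s * rx) ** 2 + Y2 / (s * ry) ** 2 <= 1.0
    return mask, z_lo, z_hi


def _correlated_field(shape: tuple[int, int, int], spacing: tuple[float, float, float],
                      correlation_length: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma = [correlation_length / s for s in spacing]
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")


def interior_mask(volume_or_mask, shell_thickness: int) -> np.ndarray:
    """Trabecular interior: the bone mask eroded slice-wise by the shell thickness."""
    mask = volume_or_mask if isinstance(volume_or_mask, np.ndarray) else volume_or_mask.labels == BONE
    out = np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(2, 1)
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if sl.any():
            out[:, :, z] = ndimage.binary_erosion(sl, structure=structure,
                                                  iterations=shell_thickness)
    return out


def synth_vertebra(params: SynthParams) -> LabeledVolume:
    """Generate one synthetic vertebral specimen.

    The bone is a waisted elliptic cylinder whose transverse semi-axes shrink
    linearly from the ends to ``waist_factor`` at mid-height.  The outer
    ``shell_thickness`` voxels of every slice form a cortical shell at
    ``shell_density``; the interior is a Gaussian random field smoothed to
    ``correlation_length`` and rescaled to ``trab_mean`` / ``trab_sd``
    (clipped at zero).  PMMA caps cover the end-slice bone footprint at both
    axial ends.  Deterministic for a fixed seed.
    """
    bone, z_lo, z_hi = _bone_mask(params)
    labels = np.zeros(params.grid_shape, dtype=np.uint8)
    labels[bone] = BONE

    # caps: extrude the end-slice footprint (full, unwaisted cross-section)
    foot = bone[:, :, z_lo]
    for z in range(params.cap_thickness):
        labels[:, :, z][foot] = PMMA_CAP
    foot_top = bone[:, :, z_hi]
    for z in range(params.grid_shape[2] - params.cap_thickness, params.grid_shape[2]):
        labels[:, :, z][foot_top] = PMMA_CAP

    inner = interior_mask(bone, params.shell_thickness)
    density = np.zeros(params.grid_shape, dtype=np.float64)
    density[bone] = params.shell_density

    rng = np.random.default_rng(params.seed)
    if params.trab_sd == 0.0:
        density[inner] = params.trab_mean
    else:
        g = _correlated_field(params.grid_shape, params.spacing,
                              params.correlation_length, rng)
        vals = g[inner]
        vals = (vals - vals.mean()) / vals.std()
        density[inner] = np.clip(params.trab_mean + params.trab_sd * vals, 0.0, None)

    density[labels == PMMA_CAP] = PMMA_DENSITY

    return LabeledVolume(
        density=density,
        labels=labels,
        spacing=params.spacing,
        metadata={
            "specimen_id": f"S{params.seed:04d}",
            "donor_id": None,
            "shell_thickness": params.shell_thickness,
            "cap_thickness": params.cap_thickness,
            "seed": params.seed,
        },
    )


def synth_cohort(spec: CohortSpec) -> tuple[list[LabeledVolume], pd.DataFrame]:
    """Generate a cohort of specimens with donor metadata.

    Per-specimen seeds are derived reproducibly from the cohort seed via a
    ``SeedSequence`` spawn, so the cohort is bit-identical for a fixed seed
    and individual specimens are statistically independent.
    """
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(spec.n_vertebrae)]

    volumes: list[LabeledVolume] = []
    rows = []
    for i in range(spec.n_vertebrae):
        params = replace(spec.base_params, seed=child_seeds[i], **spec.overrides.get(i, {}))
        vol = synth_vertebra(params)
        donor = spec.donor_assignment[i]
        vol.metadata["specimen_id"] = f"V{i:02d}"
        vol.metadata["donor_id"] = f"D{donor:02d}"
        row = {"specimen": vol.metadata["specimen_id"], "donor": vol.metadata["donor_id"],
               "seed": child_seeds[i]}
        if spec.ground_truth_coeffs is not None:
            a, b = spec.ground_truth_coeffs[i]
            vol.metadata["true_coeffs"] = (a, b)
            row["a_true"], row["b_true"] = a, b
        volumes.append(vol)
        rows.append(row)
    return volumes, pd.DataFrame(rows)
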