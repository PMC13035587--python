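"""Longitudinal von Mises stress profiles on the midsagittal plane.

Stress is sampled along three vertical lines in the central sagittal slab --
the longitudinal axis through the bone centroid plus two lines offset by
three element lengths in the anterior-posterior direction -- and averaged
per vertical level.  The applied load is the specimen's 50%-defect fracture
force, so every condition of one specimen is compared under the same load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, DependencyError
from .fem import FEModel, SolverOptions, VoxelMesh, axial_compression_bc
from .materials import MaterialField
from .synth import PMMA_CAP


@dataclass
class ProfileSpec:
    """Extraction protocol: target load (N) and line offset (3 element lengths)."""

    load: float  # N, total axial force
    offset_elements: int = 3
    from_damaged_state: bool = False  # extract after progressive failure at this load

    def __post_init__(self) -> None:
        if self.load <= 0:
            raise ValueError("load must be positive")


@dataclass
class StressProfile:
    z_mm: np.ndarray  # vertical position, ascending
    stress: np.ndarray  # mean von Mises over the three lines, MPa
    max_stress: float
    n_lines: int


def average_lines(level_values: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of the per-line stress values at one vertical level."""
    nonempty = [np.atleast_1d(v) for v in level_values if np.size(v)]
    if not nonempty:
        raise DegenerateDataError("no line-intersecting elements at this level")
    return np.concatenate(nonempty).mean()


def max_stress(profile: StressProfile) -> float:
    """Maximum of the line-averaged longitudinal profile (MPa)."""
    if profile.stress.size == 0:
        raise DegenerateDataError("empty stress profile")
    return float(profile.stress.max())


def reference_load(fracture_table: pd.DataFrame, specimen: str,
                   fraction: float = 0.50) -> float:
    """The specimen's largest-defect (50%) fracture force, used as the profile load."""
    rows = fracture_table[(fracture_table["specimen"] == specimen)
                          & (fracture_table["condition"] == "defect")
                          & (np.isclose(fracture_table["fraction"], fraction))]
    if len(rows) == 0:
        raise DependencyError(
            f"no {fraction:.0%}-defect fracture result for specimen {specimen}; "
            "run the defect fracture analyses first")
    return float(rows["fracture_force_N"].iloc[0])


def extract_profile(mesh: VoxelMesh, materials: MaterialField, spec: ProfileSpec,
                    options: SolverOptions | None = None,
                    model: FEModel | None = None,
                    bc_builder=axial_compression_bc) -> StressProfile:
    """Extract the three-line averaged von Mises profile at the target load.

    The elastic solution at unit prescribed displacement is scaled so the
    total base reaction equals ``spec.load`` (linear elasticity); von Mises
    values of vertebral elements (caps excluded) lying on the three
    midsagittal lines are averaged per vertical level.  Levels intersecting
    no line are omitted.
    """
    if model is None:
        model = FEModel(mesh, nu=materials.nu, options=options)
    if spec.from_damaged_state:
        # damage accumulated up to the target load (or fracture, if earlier)
        from .failure import LoadingProtocol, run_fracture
        mats = materials.copy()
        run_fracture(mesh, mats, LoadingProtocol(stop_at_force=spec.load),
                     model=model, mutate_materials=True)
        E = mats.effective_modulus()
    else:
        E = materials.effective_modulus()
    res = model.solve(E, bc_builder(mesh, -1.0))
    if res.axial_force <= 0:
        raise DegenerateDataError("zero reaction; cannot scale to target load")
    scale = spec.load / res.axial_force
    vm = res.von_mises * scale

    body = mesh.element_labels != PMMA_CAP
    vox = mesh.element_voxels
    bx, by, bz = vox[body].T
    y_mid = int(round(by.mean()))
    x_c = int(round(bx.mean()))
    lines_x = [x_c - spec.offset_elements, x_c, x_c + spec.offset_elements]

    present_lines = 0
    per_line_sel = []
    for lx in lines_x:
        sel = body & (vox[:, 0] == lx) & (vox[:, 1] == y_mid)
        per_line_sel.append(sel)
        if sel.any():
            present_lines += 1
    if present_lines < 3:
        warnings.warn(f"only {present_lines} of 3 profile lines intersect the bone; "
                      "averaging over available lines")
    if present_lines == 0:
        raise DegenerateDataError("no profile line intersects the bone footprint")

    any_line = np.logical_or.reduce(per_line_sel)
    zs = np.unique(vox[any_line, 2])
    z_mm = np.empty(zs.size)
    stress = np.empty(zs.size)
    for n, z in enumerate(zs):
        level_vals = [vm[sel & (vox[:, 2] == z)] for sel in per_line_sel]
        z_mm[n] = (z + 0.5) * mesh.spacing[2]
        stress[n] = average_lines(level_vals)

    return StressProfile(z_mm=z_mm, stress=stress,
                         max_stress=float(stress.max()), n_lines=present_lines)
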