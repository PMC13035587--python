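"""Defect and augmentation geometry.

Lytic lesions are modeled as elliptical regions sized by the fraction of the
bone's transverse cross-sectional area they occupy at the reference plane --
the transverse slice of minimum bone cross-section.  Augmentation replaces a
defect with cement of a prescribed modulus without changing the geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GeometryError, StateError, VertefemError
from .synth import AUGMENTATION, BONE, DEFECT, LabeledVolume, interior_mask

# labels counted as vertebral cross-section when locating the reference plane;
# defect/augmentation voxels were bone before carving, so the plane is stable
# across the intact/defect/augmented conditions of one specimen.
_BODY_LABELS = (BONE, DEFECT, AUGMENTATION)


@dataclass(frozen=True)
class DefectSpec:
    """An elliptical lytic defect sized by transverse area fraction.

    ``fraction`` is defect area / bone area on the reference plane (the study
    conditions use 0.20 and 0.50).  ``shape`` selects the 3D extent:
    ``elliptic_cylinder`` (default), ``ellipsoid``, or ``drilled_cylinder``
    (circular bore, mimicking experimentally drilled defects).
    ``height_fraction`` is the fraction of bone height spanned, centered on
    the reference plane.  ``center`` overrides the transverse center (voxel
    indices); default is the bone centroid at the reference plane.
    """

    fraction: float
    shape: str = "elliptic_cylinder"
    height_fraction: float = 0.5
    center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")
        if not (0.0 < self.height_fraction <= 1.0):
            raise ValueError("height_fraction must lie in (0, 1]")
        if self.shape not in ("elliptic_cylinder", "ellipsoid", "drilled_cylinder"):
            raise ValueError(f"unknown defect shape {self.shape!r}")


@dataclass
class ExperimentDesign:
    """Enumerated cohort design: one row per (vertebra, condition) model."""

    table: pd.DataFrame
    n_intact: int
    n_defect: int
    n_augmented: int

    @property
    def total(self) -> int:
        return self.n_intact + self.n_defect + self.n_augmented


def min_cross_section_level(volume: LabeledVolume) -> int:
    """Transverse slice index of minimum vertebral cross-sectional area.

    Caps are excluded; ties are broken by the lowest slice index.
    """
    body = np.isin(volume.labels, _BODY_LABELS)
    counts = body.sum(axis=(0, 1))
    nonzero = np.nonzero(counts)[0]
    if nonzero.size == 0:
        raise VertefemError("volume contains no bone voxels")
    z = nonzero[np.argmin(counts[nonzero])]  # argmin returns first minimum
    return int(z)


def _slice_metric(spec: DefectSpec, mask: np.ndarray, spacing) -> tuple[np.ndarray, tuple[float, float]]:
    """Normalized radial metric on one transverse slice.

    Returns an array of the squared elliptical (or circular, for a drilled
    bore) radius of every voxel, measured from the defect center in units of
    the bone cross-section's principal half-extents.
    """
    xs, ys = np.nonzero(mask)
    if spec.center is not None:
        cx, cy = float(spec.center[0]), float(spec.center[1])
    else:
        cx, cy = xs.mean(), ys.mean()
    rx = max((xs.max() - xs.min() + 1) / 2.0, 0.5)
    ry = max((ys.max() - ys.min() + 1) / 2.0, 0.5)
    if spec.shape == "drilled_cylinder":
        # circular in physical units: use the mean physical half-extent
        r = 0.5 * (rx * spacing[0] + ry * spacing[1])
        rx_eff, ry_eff = r / spacing[0], r / spacing[1]
    else:
        rx_eff, ry_eff = rx, ry
    nx, ny = mask.shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    metric = ((X - cx) / rx_eff) ** 2 + ((Y - cy) / ry_eff) ** 2
    return metric, (cx, cy)


def insert_defect(volume: LabeledVolume, spec: DefectSpec) -> LabeledVolume:
    """Carve an elliptical defect into the bone, centered on the reference plane.

    The transverse footprint is chosen by ranking trabecular voxels on the
    reference slice by their normalized elliptical radius and taking exactly
    ``round(fraction * bone slice area)`` of them, so the achieved area
    fraction matches the request to within half a voxel.  The footprint is
    then extruded over ``height_fraction`` of the bone height (shrinking with
    height for the ellipsoid shape).  The defect never breaches the cortical
    shell: only voxels of the shell-eroded interior are eligible, and a
    request that cannot be met inside the shell raises :class:`GeometryError`.
    """
    out = volume.copy()
    shell = int(volume.metadata.get("shell_thickness", 1))
    ref = min_cross_section_level(volume)
    body = np.isin(volume.labels, _BODY_LABELS)

    ref_mask = body[:, :, ref]
    bone_area = int(ref_mask.sum())
    target = int(round(spec.fraction * bone_area))
    if target == 0:
        warnings.warn("requested fraction is below one voxel-area; volume unchanged")
        return out

    inner = interior_mask(body, shell)
    metric, _center = _slice_metric(spec, ref_mask, volume.spacing)

    ix, iy = np.nonzero(inner[:, :, ref])
    if ix.size < target:
        raise GeometryError(
            f"defect of {target} voxels does not fit inside the shell "
            f"({ix.size} interior voxels available on the reference slice)"
        )
    order = np.lexsort((iy, ix, metric[ix, iy]))
    chosen = order[:target]
    fx, fy = ix[chosen], iy[chosen]
    r_max = float(metric[fx, fy].max())

    footprint = np.zeros(ref_mask.shape, dtype=bool)
    footprint[fx, fy] = True

    # axial span: height_fraction of the bone height, centered on the plane
    z_body = np.nonzero(body.any(axis=(0, 1)))[0]
    z0, z1 = int(z_body[0]), int(z_body[-1])
    half_span = 0.5 * spec.height_fraction * (z1 - z0 + 1)
    z_lo = max(z0, int(np.ceil(ref - half_span + 0.5)))
    z_hi = min(z1, int(np.floor(ref + half_span - 0.5)))
    z_lo, z_hi = min(z_lo, ref), max(z_hi, ref)

    for z in range(z_lo, z_hi + 1):
        sl_inner = inner[:, :, z]
        if spec.shape == "ellipsoid" and half_span > 0.5:
            dz = (z - ref) / half_span
            shrink2 = max(1.0 - dz * dz, 0.0)
            sl_foot = footprint & (metric <= r_max * shrink2)
        else:
            sl_foot = footprint
        sel = sl_foot & sl_inner & (out.labels[:, :, z] == BONE)
        out.labels[:, :, z][sel] = DEFECT

    achieved = int(np.count_nonzero(out.labels[:, :, ref] == DEFECT))
    out.metadata.update({
        "defect_fraction": spec.fraction,
        "defect_fraction_achieved": achieved / bone_area,
        "defect_shape": spec.shape,
        "reference_level": ref,
    })
    return out


def augment(volume: LabeledVolume, modulus: float) -> LabeledVolume:
    """Fill the defect with augmentation cement of the given modulus (MPa).

    Defect voxels are relabeled augmentation; re-augmenting an already
    augmented volume just updates the recorded modulus.  Geometry is
    otherwise unchanged.
    """
    if modulus <= 0:
        raise ValueError("augmentation modulus must be positive")
    out = volume.copy()
    has_defect = (out.labels == DEFECT).any()
    has_aug = (out.labels == AUGMENTATION).any()
    if not has_defect and not has_aug:
        raise StateError("volume has no defect to augment")
    out.labels[out.labels == DEFECT] = AUGMENTATION
    out.metadata["augmentation_modulus"] = float(modulus)
    return out


def defect_connected(volume: LabeledVolume) -> bool:
    """True if the defect/augmentation region forms one connected component."""
    mask = np.isin(volume.labels, (DEFECT, AUGMENTATION))
    if not mask.any():
        return True
    _, n = ndimage.label(mask)
    return n == 1


def enumerate_design(n_vertebrae: int,
                     fractions: tuple[float, ...] = (0.20, 0.50),
                     moduli: tuple[float, ...] = (50.0, 300.0, 1000.0, 2000.0, 2500.0),
                     ) -> ExperimentDesign:
    """Full factorial condition table: intact + defects + defect x modulus.

    With 6 vertebrae, 2 defect fractions and 5 augmentation moduli this
    enumerates 78 models (6 intact, 12 defect, 60 augmented).
    """
    if n_vertebrae < 1:
        raise ValueError("n_vertebrae must be >= 1")
    rows = []
    for v in range(n_vertebrae):
        spec_id = f"V{v:02d}"
        rows.append({"specimen": spec_id, "condition": "intact",
                     "fraction": np.nan, "modulus_MPa": np.nan})
        for f in fractions:
            rows.append({"specimen": spec_id, "condition": "defect",
                         "fraction": f, "modulus_MPa": np.nan})
        for f in fractions:
            for m in moduli:
                rows.append({"specimen": spec_id, "condition": "augmented",
                             "fraction": f, "modulus_MPa": m})
    table = pd.DataFrame(rows)
    s, m = len(fractions), len(moduli)
    design = ExperimentDesign(table=table, n_intact=n_vertebrae,
                              n_defect=n_vertebrae * s,
                              n_augmented=n_vertebrae * s * m)
    assert design.total == len(table) == n_vertebrae * (1 + s + s * m)
    return design
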