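"""Density-based material mapping.

Elastic modulus follows the phenomenological power law E = a * rho^b with
specimen-specific coefficients; the failure threshold follows the empirical
yield-strain law eps_yield = 0.0081 * rho^-1.42 (rho in g/cm^3, ash density).
Lesion and failed elements carry a nominal 0.1 MPa; PMMA embedding caps are
fixed at 2500 MPa; augmentation cement gets a uniform modulus chosen per
design condition.  Poisson's ratio is 0.3 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .synth import AUGMENTATION, BACKGROUND, BONE, DEFECT, PMMA_CAP, LabeledVolume

POISSON_RATIO = 0.3
FAILED_MODULUS = 0.1  # MPa; also the lesion modulus and the global floor
CAP_MODULUS = 2500.0  # MPa, PMMA embedding blocks

YIELD_COEFF = 0.0081
YIELD_EXPONENT = -1.42


@dataclass(frozen=True)
class PowerLawCoefficients:
    """Coefficients of E = a * rho^b (E in MPa, rho in g/cm^3)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("power-law coefficients must be positive")


@dataclass(frozen=True)
class PhantomCalibration:
    """Linear HU -> density map from a scanner calibration phantom."""

    slope: float  # (g/cm^3) per HU
    intercept: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("phantom calibration slope must be positive")

    @classmethod
    def fit(cls, hu: np.ndarray, densities: np.ndarray) -> "PhantomCalibration":
        """Least-squares fit from >= 2 phantom rods of known density."""
        hu = np.asarray(hu, dtype=float)
        densities = np.asarray(densities, dtype=float)
        if hu.size < 2:
            raise ValueError("need at least two phantom rods")
        slope, intercept = np.polyfit(hu, densities, 1)
        return cls(slope=float(slope), intercept=float(intercept))


@dataclass
class MaterialField:
    """Per-element material state, ordered like the mesh element list.

    ``modulus`` already has the 0.1 MPa floor applied; ``yield_strain`` is
    +inf for elements exempt from failure (caps, lesion, cement,
    zero-density voxels).  ``failed`` is mutated by the failure loop.
    """

    modulus: np.ndarray  # MPa
    yield_strain: np.ndarray
    failable: np.ndarray  # bool
    failed: np.ndarray  # bool
    element_labels: np.ndarray
    nu: float = POISSON_RATIO

    @property
    def n_elements(self) -> int:
        return self.modulus.size

    def effective_modulus(self) -> np.ndarray:
        """Moduli with failed elements reduced to the nominal 0.1 MPa."""
        E = self.modulus.copy()
        E[self.failed] = FAILED_MODULUS
        return E

    def copy(self) -> "MaterialField":
        return MaterialField(self.modulus.copy(), self.yield_strain.copy(),
                             self.failable.copy(), self.failed.copy(),
                             self.element_labels.copy(), self.nu)


def hu_to_density(hu: np.ndarray, cal: PhantomCalibration) -> np.ndarray:
    """Map Hounsfield units to volumetric density, clipped at zero."""
    return np.clip(cal.slope * np.asarray(hu, dtype=float) + cal.intercept, 0.0, None)


def modulus_from_density(rho, coeffs: PowerLawCoefficients):
    """E = a * rho^b (MPa).  The 0.1 MPa floor is applied by the field builder."""
    rho = np.asarray(rho, dtype=float)
    out = coeffs.a * rho ** coeffs.b
    return float(out) if out.ndim == 0 else out


def yield_strain_from_density(rho):
    """eps_yield = 0.0081 * rho^-1.42; undefined (inf) at rho <= 0."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(rho > 0, YIELD_COEFF * rho ** YIELD_EXPONENT, np.inf)
    return float(out) if out.ndim == 0 else out


def element_order_densities(volume: LabeledVolume) -> tuple[np.ndarray, np.ndarray]:
    """Densities and labels of non-background voxels in canonical (C) order.

    This is the element ordering used by :func:`vertefem.fem.build_mesh`, so
    the returned arrays align one-to-one with mesh elements.
    """
    mask = volume.labels != BACKGROUND
    return volume.density[mask], volume.labels[mask]


def build_material_field(volume: LabeledVolume,
                         coeffs: PowerLawCoefficients,
                         augmentation_modulus: float | None = None,
                         ash_density_scale: float = 1.0) -> MaterialField:
    """Map a labeled volume to per-element elastic and failure properties.

    Bone elements get E = a*rho^b (floored at 0.1 MPa) and a density-based
    yield strain; lesion elements get the nominal 0.1 MPa; augmentation
    elements get the uniform cement modulus; caps get 2500 MPa.  Only bone
    elements with positive density can fail.  ``ash_density_scale`` converts
    the stored density to the ash density used by the yield law (default 1,
    i.e. a single density field drives both laws).
    """
    if augmentation_modulus is None:
        augmentation_modulus = volume.metadata.get("augmentation_modulus")
    rho, labels = element_order_densities(volume)
    if (labels == AUGMENTATION).any() and augmentation_modulus is None:
        raise ConfigError("volume has augmentation voxels but no modulus was given")

    E = np.empty(rho.shape, dtype=float)
    eps_y = np.full(rho.shape, np.inf)
    failable = np.zeros(rho.shape, dtype=bool)

    bone = labels == BONE
    E[bone] = np.maximum(modulus_from_density(rho[bone], coeffs), FAILED_MODULUS)
    ash = ash_density_scale * rho[bone]
    eps_y[bone] = yield_strain_from_density(ash)
    failable[bone] = ash > 0

    E[labels == DEFECT] = FAILED_MODULUS
    E[labels == PMMA_CAP] = CAP_MODULUS
    if (labels == AUGMENTATION).any():
        E[labels == AUGMENTATION] = float(augmentation_modulus)
    eps_y[~failable] = np.inf

    return MaterialField(modulus=E, yield_strain=eps_y, failable=failable,
                         failed=np.zeros(rho.shape, dtype=bool),
                         element_labels=labels)
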