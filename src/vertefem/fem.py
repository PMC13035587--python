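"""Voxel hexahedral linear-elasticity solver.

One 8-node trilinear hexahedral element (2x2x2 Gauss integration) per
non-background voxel, with element size matched exactly to the voxel
dimensions.  Because Poisson's ratio is uniform, every element shares one
unit stiffness matrix scaled by its modulus, which makes reassembly during
progressive failure cheap.

Boundary conditions reproduce a compression test between embedding blocks:
the bottom face of the inferior cap is fixed in all directions and the top
face of the superior cap is driven axially, transverse translations free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .exceptions import MeshError, SolverError
from .materials import MaterialField, POISSON_RATIO
from .synth import BACKGROUND, PMMA_CAP, LabeledVolume

_CORNER_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
], dtype=np.int64)

# local corner coordinates on [-1, 1]^3, same ordering
_XI = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
], dtype=float)


def _shape_gradients(xi: np.ndarray, dims: tuple[float, float, float]) -> np.ndarray:
    """Physical gradients dN_i/dx_j (8 x 3) of the trilinear shape functions."""
    g = np.empty((8, 3))
    for i in range(8):
        a, b, c = _XI[i]
        g[i, 0] = 0.125 * a * (1 + b * xi[1]) * (1 + c * xi[2])
        g[i, 1] = 0.125 * b * (1 + a * xi[0]) * (1 + c * xi[2])
        g[i, 2] = 0.125 * c * (1 + a * xi[0]) * (1 + b * xi[1])
    return g * (2.0 / np.asarray(dims))


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6 x 24), Voigt order xx, yy, zz, xy, yz, zx."""
    B = np.zeros((6, 24))
    for i in range(8):
        gx, gy, gz = grad[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix in Voigt notation (engineering shear)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


def hex8_stiffness(dims: tuple[float, float, float], E: float, nu: float) -> np.ndarray:
    """24x24 stiffness of a rectangular hex8 element, 2x2x2 Gauss points."""
    D = elasticity_matrix(E, nu)
    detJ = np.prod(dims) / 8.0
    gp = 1.0 / np.sqrt(3.0)
    Ke = np.zeros((24, 24))
    for sx in (-gp, gp):
        for sy in (-gp, gp):
            for sz in (-gp, gp):
                B = _b_matrix(_shape_gradients(np.array([sx, sy, sz]), dims))
                Ke += B.T @ D @ B * detJ
    return Ke


def hex8_b_center(dims: tuple[float, float, float]) -> np.ndarray:
    """B at the element centroid; equals the average of B over the Gauss points."""
    return _b_matrix(_shape_gradients(np.zeros(3), dims))


@dataclass
class VoxelMesh:
    """Hexahedral mesh with one element per non-background voxel."""

    nodes: np.ndarray  # (n_nodes, 3) coordinates in mm
    node_ijk: np.ndarray  # (n_nodes, 3) integer lattice indices
    connectivity: np.ndarray  # (n_elem, 8) node indices
    element_voxels: np.ndarray  # (n_elem, 3) voxel indices, canonical C order
    element_labels: np.ndarray  # (n_elem,)
    spacing: tuple[float, float, float]
    grid_shape: tuple[int, int, int]
    base_nodes: np.ndarray = field(default=None)  # bottom face of inferior cap
    top_nodes: np.ndarray = field(default=None)  # top face of superior cap

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def element_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet data: constrained dof indices and their prescribed values."""

    dofs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.dofs.size != np.unique(self.dofs).size:
            raise ValueError("boundary condition dofs must be unique")
        if self.dofs.size != self.values.size:
            raise ValueError("dofs and values must align")


def build_mesh(volume: LabeledVolume, require_caps: bool = True) -> VoxelMesh:
    """Mesh every non-background voxel as one hex8 element.

    Elements are ordered in C (row-major) voxel order, matching
    :func:`vertefem.materials.element_order_densities`.  ``require_caps``
    enforces PMMA caps at both axial ends so that the standard compression
    boundary conditions are definable.
    """
    mask = volume.labels != BACKGROUND
    if not mask.any():
        raise MeshError("volume has no meshable voxels")
    nx, ny, nz = volume.shape
    if require_caps:
        if not (volume.labels[:, :, 0] == PMMA_CAP).any() or \
           not (volume.labels[:, :, -1] == PMMA_CAP).any():
            raise MeshError("volume lacks PMMA caps at one or both axial ends; "
                            "boundary conditions are undefined")

    voxels = np.argwhere(mask)  # C order
    corners = voxels[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (N, 8, 3)
    lin = (corners[..., 0] * (ny + 1) + corners[..., 1]) * (nz + 1) + corners[..., 2]
    unique_lin, conn = np.unique(lin, return_inverse=True)
    conn = conn.reshape(lin.shape).astype(np.int64)

    k = unique_lin % (nz + 1)
    rem = unique_lin // (nz + 1)
    j = rem % (ny + 1)
    i = rem // (ny + 1)
    node_ijk = np.stack([i, j, k], axis=1)
    nodes = node_ijk * np.asarray(volume.spacing)

    return VoxelMesh(
        nodes=nodes,
        node_ijk=node_ijk,
        connectivity=conn,
        element_voxels=voxels,
        element_labels=volume.labels[mask],
        spacing=volume.spacing,
        grid_shape=volume.shape,
        base_nodes=np.nonzero(k == 0)[0],
        top_nodes=np.nonzero(k == nz)[0],
    )


def axial_compression_bc(mesh: VoxelMesh, u_applied: float) -> BoundaryConditions:
    """Standard test-rig conditions: base fully fixed, top driven axially.

    ``u_applied`` should be negative (compression); transverse translations
    of the top face are free, mimicking an unconstrained crosshead.
    """
    base = mesh.base_nodes
    top = mesh.top_nodes
    dofs = np.concatenate([3 * base, 3 * base + 1, 3 * base + 2, 3 * top + 2])
    values = np.concatenate([np.zeros(3 * base.size), np.full(top.size, u_applied)])
    return BoundaryConditions(dofs=dofs, values=values)


def frictionless_column_bc(mesh: VoxelMesh, u_applied: float) -> BoundaryConditions:
    """Uniaxial compression with frictionless supports.

    Base face held axially, top face driven axially, symmetry planes
    (minimum-x and minimum-y node sheets) held normal to themselves.  On a
    homogeneous block this reproduces the uniform uniaxial closed form.
    """
    i, j, k = mesh.node_ijk.T
    base = np.nonzero(k == k.min())[0]
    top = np.nonzero(k == k.max())[0]
    west = np.nonzero(i == i.min())[0]
    south = np.nonzero(j == j.min())[0]
    dofs = np.concatenate([3 * base + 2, 3 * top + 2, 3 * west, 3 * south + 1])
    values = np.concatenate([np.zeros(base.size), np.full(top.size, u_applied),
                             np.zeros(west.size), np.zeros(south.size)])
    return BoundaryConditions(dofs=dofs, values=values)


@dataclass
class SolverOptions:
    """Sparse solver settings: direct factorization below ``direct_threshold``
    free dofs, Jacobi-preconditioned CG (relative tolerance ``cg_tol``) above."""

    direct_threshold: int = 2000
    cg_tol: float = 1e-8
    cg_maxiter: int = 20_000


@dataclass
class ElementFieldResult:
    """Element-average strain/stress fields and support reactions."""

    displacement: np.ndarray  # (n_nodes, 3) mm
    strain: np.ndarray  # (n_elem, 6) Voigt, engineering shear
    stress: np.ndarray  # (n_elem, 6) MPa
    von_mises: np.ndarray  # (n_elem,) MPa
    principal_strains: np.ndarray  # (n_elem, 3) ascending
    failure_strain: np.ndarray  # (n_elem,) scalar measure compared to eps_yield
    reaction_base: float  # N, sum of axial nodal reactions at the base
    reaction_top: float  # N

    @property
    def axial_force(self) -> float:
        """Magnitude of the transmitted axial force (N)."""
        return abs(self.reaction_base)


def von_mises_stress(stress: np.ndarray) -> np.ndarray:
    sx, sy, sz, txy, tyz, tzx = stress.T
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))


def principal_strains(strain: np.ndarray) -> np.ndarray:
    """Eigenvalues (ascending) of the strain tensor; input uses engineering shear."""
    n = strain.shape[0]
    T = np.empty((n, 3, 3))
    T[:, 0, 0] = strain[:, 0]
    T[:, 1, 1] = strain[:, 1]
    T[:, 2, 2] = strain[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = 0.5 * strain[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = 0.5 * strain[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = 0.5 * strain[:, 5]
    return np.linalg.eigvalsh(T)


def equivalent_strain(strain: np.ndarray) -> np.ndarray:
    """Von Mises equivalent strain sqrt(2/3 e':e') of the deviatoric tensor."""
    p = principal_strains(strain)
    m = p.mean(axis=1, keepdims=True)
    d = p - m
    return np.sqrt(2.0 / 3.0 * (d ** 2).sum(axis=1))


def failure_strain_measure(strain: np.ndarray, measure: str = "principal") -> np.ndarray:
    """Scalar strain compared against the element yield strain.

    ``principal`` (default): maximum absolute principal strain;
    ``von_mises``: von Mises equivalent strain.
    """
    if measure == "principal":
        return np.abs(principal_strains(strain)).max(axis=1)
    if measure == "von_mises":
        return equivalent_strain(strain)
    raise ValueError(f"unknown strain measure {measure!r}")


class FEModel:
    """Reusable assembled model: fixed mesh and Poisson ratio, variable moduli.

    The unit element stiffness and the COO scatter pattern are computed once;
    each solve only rescales element data, which keeps the inner loop of the
    progressive-failure analysis cheap.
    """

    def __init__(self, mesh: VoxelMesh, nu: float = POISSON_RATIO,
                 options: SolverOptions | None = None):
        self.mesh = mesh
        self.nu = nu
        self.options = options or SolverOptions()
        self.Ke_unit = hex8_stiffness(mesh.spacing, 1.0, nu)
        self.B0 = hex8_b_center(mesh.spacing)
        self.D_unit = elasticity_matrix(1.0, nu)
        conn = mesh.connectivity
        edofs = (3 * conn[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 24)
        self.edofs = edofs
        self._rows = np.repeat(edofs, 24, axis=1).ravel()
        self._cols = np.tile(edofs, (1, 24)).ravel()
        self._warm_start: np.ndarray | None = None

    def assemble(self, E: np.ndarray) -> sparse.csr_matrix:
        data = (np.asarray(E)[:, None] * self.Ke_unit.ravel()[None, :]).ravel()
        K = sparse.coo_matrix((data, (self._rows, self._cols)),
                              shape=(self.mesh.n_dofs, self.mesh.n_dofs))
        return K.tocsr()

    def solve_displacement(self, E: np.ndarray, bc: BoundaryConditions) -> np.ndarray:
        """Full displacement vector under Dirichlet data (3*n_nodes,)."""
        K = self.assemble(E)
        ndof = self.mesh.n_dofs
        u = np.zeros(ndof)
        u[bc.dofs] = bc.values
        free = np.ones(ndof, dtype=bool)
        free[bc.dofs] = False
        rhs = -(K @ u)[free]
        Kff = K[free][:, free]
        nfree = int(free.sum())
        try:
            if nfree <= self.options.direct_threshold:
                uf = splu(Kff.tocsc()).solve(rhs)
            else:
                M = sparse.diags(1.0 / Kff.diagonal())
                x0 = self._warm_start[free] if self._warm_start is not None else None
                uf, info = cg(Kff, rhs, x0=x0, M=M,
                              rtol=self.options.cg_tol, maxiter=self.options.cg_maxiter)
                if info != 0:
                    raise SolverError(f"CG did not converge (info={info}); "
                                      f"residual {np.linalg.norm(Kff @ uf - rhs):.3e}")
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"singular stiffness system: {exc}") from exc
        u[free] = uf
        self._warm_start = u.copy()
        self._K = K  # kept for reaction recovery
        return u

    def recover(self, E: np.ndarray, u: np.ndarray,
                strain_measure: str = "principal") -> ElementFieldResult:
        ue = u[self.edofs]  # (n_elem, 24)
        strain = ue @ self.B0.T
        stress = (strain @ self.D_unit.T) * np.asarray(E)[:, None]
        vm = von_mises_stress(stress)
        ps = principal_strains(strain)
        fsm = failure_strain_measure(strain, strain_measure)
        r = self._K @ u
        base = float(r[3 * self.mesh.base_nodes + 2].sum())
        top = float(r[3 * self.mesh.top_nodes + 2].sum())
        return ElementFieldResult(
            displacement=u.reshape(-1, 3), strain=strain, stress=stress,
            von_mises=vm, principal_strains=ps, failure_strain=fsm,
            reaction_base=base, reaction_top=top,
        )

    def solve(self, E: np.ndarray, bc: BoundaryConditions,
              strain_measure: str = "principal") -> ElementFieldResult:
        return self.recover(E, self.solve_displacement(E, bc), strain_measure)


def solve_linear(mesh: VoxelMesh, materials: MaterialField, bc: BoundaryConditions,
                 options: SolverOptions | None = None,
                 strain_measure: str = "principal") -> ElementFieldResult:
    """Assemble and solve the elastic system; recover element fields.

    Failed elements in ``materials`` are honoured (nominal 0.1 MPa modulus).
    """
    model = FEModel(mesh, nu=materials.nu, options=options)
    return model.solve(materials.effective_modulus(), bc, strain_measure)


def stiffness_scale_check(mesh: VoxelMesh, materials: MaterialField,
                          bc_builder=axial_compression_bc,
                          options: SolverOptions | None = None) -> float:
    """Initial axial structural stiffness (N/mm) from a unit elastic solve."""
    res = solve_linear(mesh, materials, bc_builder(mesh, -1.0), options)
    return res.axial_force
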