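"""Independent dense finite-element oracle for small hex meshes.

A deliberately naive implementation kept separate from the package: general
isoparametric hex8 elements assembled one Gauss point at a time into a
dense stiffness matrix, with boundary conditions applied by explicit
row/column elimination and a dense solve.  Used to cross-check the sparse
voxel solver on meshes of a few dozen elements.
"""

import itertools

import numpy as np

# same node ordering convention as the mesh (bottom quad CCW, then top)
_LOCAL = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
], dtype=float)


def _dshape(xi):
    """dN/d(local) for all 8 trilinear shape functions: (8, 3)."""
    out = np.empty((8, 3))
    for i, (a, b, c) in enumerate(_LOCAL):
        out[i] = [a * (1 + b * xi[1]) * (1 + c * xi[2]),
                  b * (1 + a * xi[0]) * (1 + c * xi[2]),
                  c * (1 + a * xi[0]) * (1 + b * xi[1])]
    return out / 8.0


def _dmatrix(E, nu):
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 + 2 * nu)
    D = np.diag([2 * mu] * 3 + [mu] * 3).astype(float)
    D[:3, :3] += lam
    return D


def dense_element_stiffness(coords, E, nu):
    """Isoparametric hex8 stiffness by explicit Gauss-point loop."""
    D = _dmatrix(E, nu)
    Ke = np.zeros((24, 24))
    g = 1 / np.sqrt(3)
    for xi in itertools.product((-g, g), repeat=3):
        dN = _dshape(np.asarray(xi))
        J = dN.T @ coords
        dNx = dN @ np.linalg.inv(J).T
        B = np.zeros((6, 24))
        for i in range(8):
            gx, gy, gz = dNx[i]
            B[:, 3 * i:3 * i + 3] = [[gx, 0, 0], [0, gy, 0], [0, 0, gz],
                                     [gy, gx, 0], [0, gz, gy], [gz, 0, gx]]
        Ke += B.T @ D @ B * np.linalg.det(J)
    return Ke


def dense_solve(nodes, connectivity, E_per_element, nu, bc_dofs, bc_values):
    """Assemble the full dense system and solve with elimination of fixed dofs.

    Returns the full displacement vector (3 * n_nodes,).
    """
    ndof = 3 * len(nodes)
    K = np.zeros((ndof, ndof))
    for e, conn in enumerate(connectivity):
        Ke = dense_element_stiffness(nodes[conn], E_per_element[e], nu)
        dofs = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in conn])
        K[np.ix_(dofs, dofs)] += Ke
    u = np.zeros(ndof)
    u[bc_dofs] = bc_values
    free = np.setdiff1d(np.arange(ndof), bc_dofs)
    rhs = -K[np.ix_(free, bc_dofs)] @ np.asarray(bc_values)
    u[free] = np.linalg.solve(K[np.ix_(free, free)], rhs)
    return u
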