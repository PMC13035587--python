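import numpy as np
import pytest

from vertefem.exceptions import MeshError
from vertefem.fem import (BoundaryConditions, FEModel, axial_compression_bc,
                          build_mesh, frictionless_column_bc, hex8_stiffness,
                          solve_linear, stiffness_scale_check)
from vertefem.geometry import DefectSpec, insert_defect
from vertefem.materials import PowerLawCoefficients, build_material_field
from vertefem.synth import BONE, LabeledVolume

from conftest import make_block
from oracle_fem import dense_solve

COEFFS = PowerLawCoefficients(1000.0, 1.0)  # E = 1000 * rho, convenient for fixtures


class TestBuildMesh:
    def test_single_voxel(self):
        v = make_block((1, 1, 1))
        m = build_mesh(v, require_caps=False)
        assert (m.n_elements, m.n_nodes) == (1, 8)

    def test_two_voxels_share_four_nodes(self):
        m = build_mesh(make_block((2, 1, 1)), require_caps=False)
        assert (m.n_elements, m.n_nodes) == (2, 12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_full_block_node_count(self, n):
        m = build_mesh(make_block((n, n, n)), require_caps=False)
        assert (m.n_elements, m.n_nodes) == (n ** 3, (n + 1) ** 3)

    def test_missing_caps_rejected(self):
        with pytest.raises(MeshError):
            build_mesh(make_block((3, 3, 5), cap_thickness=0))
        build_mesh(make_block((3, 3, 5), cap_thickness=1))  # with caps: fine

    def test_element_order_matches_material_order(self, specimen):
        from vertefem.materials import element_order_densities
        m = build_mesh(specimen)
        rho, labels = element_order_densities(specimen)
        assert np.array_equal(labels, m.element_labels)
        assert np.array_equal(
            specimen.density[tuple(m.element_voxels.T)], rho)


class TestElementStiffness:
    def test_symmetric_positive_semidefinite(self):
        Ke = hex8_stiffness((1.2, 0.8, 1.0), 5000.0, 0.3)
        assert np.allclose(Ke, Ke.T)
        w = np.linalg.eigvalsh(Ke)
        assert w[0] > -1e-9 * w[-1]
        # exactly six rigid-body modes
        assert (np.abs(w) < 1e-9 * w[-1]).sum() == 6


class TestSolveLinear:
    def test_uniaxial_closed_form(self):
        # 10 mm cube, E = 1000 MPa, nu = 0.3, frictionless supports, u = -0.01 mm
        v = make_block((5, 5, 5), density=1.0)
        m = build_mesh(v, require_caps=False)
        mats = build_material_field(v, COEFFS)
        res = solve_linear(m, mats, frictionless_column_bc(m, -0.01))
        assert np.allclose(res.strain[:, 2], -0.001, rtol=1e-8)
        assert np.allclose(res.von_mises, 1.0, rtol=1e-8)
        assert res.axial_force == pytest.approx(100.0, rel=1e-8)  # 1 MPa x 100 mm^2

    def test_patch_constant_strain_reproduced(self, specimen):
        # linear displacement field prescribed on every boundary node must be
        # reproduced exactly in the interior (constant-strain patch test)
        v = make_block((3, 4, 5), density=0.5, spacing=(1.0, 1.3, 0.7))
        m = build_mesh(v, require_caps=False)
        mats = build_material_field(v, COEFFS)
        grad = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4], [0.0, 1e-4, 8e-4]])
        ijk = m.node_ijk
        on_boundary = ((ijk == 0).any(1) | (ijk[:, 0] == 3)
                       | (ijk[:, 1] == 4) | (ijk[:, 2] == 5))
        bnodes = np.nonzero(on_boundary)[0]
        ub = m.nodes[bnodes] @ grad.T
        dofs = np.concatenate([3 * bnodes, 3 * bnodes + 1, 3 * bnodes + 2])
        vals = np.concatenate([ub[:, 0], ub[:, 1], ub[:, 2]])
        res = solve_linear(m, mats, BoundaryConditions(dofs, vals))
        expected = m.nodes @ grad.T
        assert np.allclose(res.displacement, expected,
                           rtol=1e-10, atol=1e-10 * np.abs(expected).max())
        eps = 0.5 * (grad + grad.T)
        assert np.allclose(res.strain[:, 0], eps[0, 0], rtol=1e-10)
        assert np.allclose(res.strain[:, 3], 2 * eps[0, 1], rtol=1e-10)

    def test_rigid_translation_gives_zero_strain(self):
        v = make_block((3, 3, 3))
        m = build_mesh(v, require_caps=False)
        mats = build_material_field(v, COEFFS)
        ijk = m.node_ijk
        bnodes = np.nonzero((ijk == 0).any(1) | (ijk == 3).any(1))[0]
        dofs = np.concatenate([3 * bnodes, 3 * bnodes + 1, 3 * bnodes + 2])
        vals = np.concatenate([np.full(bnodes.size, 0.2),
                               np.full(bnodes.size, -0.1),
                               np.full(bnodes.size, 0.05)])
        res = solve_linear(m, mats, BoundaryConditions(dofs, vals))
        assert np.abs(res.strain).max() < 1e-12

    def test_dense_oracle_equivalence_heterogeneous(self):
        rng = np.random.default_rng(42)
        v = make_block((3, 3, 3), spacing=(1.1, 0.9, 1.3))
        v.density[:] = rng.uniform(0.1, 1.5, v.shape)
        m = build_mesh(v, require_caps=False)
        mats = build_material_field(v, COEFFS)
        bc = axial_compression_bc(m, -0.02)
        model = FEModel(m)
        u = model.solve_displacement(mats.effective_modulus(), bc)
        u_oracle = dense_solve(m.nodes, m.connectivity, mats.effective_modulus(),
                               mats.nu, bc.dofs, bc.values)
        assert np.allclose(u, u_oracle, rtol=1e-8, atol=1e-12)

    def test_equilibrium_base_equals_top(self, specimen):
        m = build_mesh(specimen)
        mats = build_material_field(specimen, PowerLawCoefficients(7546.0, 2.0))
        res = solve_linear(m, mats, axial_compression_bc(m, -0.1))
        assert res.reaction_base == pytest.approx(-res.reaction_top, rel=1e-6)
        assert res.axial_force > 0

    def test_mirror_symmetry(self, specimen):
        m = build_mesh(specimen)
        mats = build_material_field(specimen, PowerLawCoefficients(7546.0, 2.0))
        res = solve_linear(m, mats, axial_compression_bc(m, -0.1))

        mirrored = specimen.copy()
        mirrored.density = specimen.density[:, ::-1, :].copy()
        mirrored.labels = specimen.labels[:, ::-1, :].copy()
        m2 = build_mesh(mirrored)
        mats2 = build_material_field(mirrored, PowerLawCoefficients(7546.0, 2.0))
        res2 = solve_linear(m2, mats2, axial_compression_bc(m2, -0.1))

        # map element von Mises back to voxel space and compare mirrored fields
        vm1 = np.zeros(specimen.shape)
        vm1[tuple(m.element_voxels.T)] = res.von_mises
        vm2 = np.zeros(specimen.shape)
        vm2[tuple(m2.element_voxels.T)] = res2.von_mises
        assert np.allclose(vm1, vm2[:, ::-1, :], rtol=1e-6, atol=1e-9)


class TestStiffnessScale:
    def test_linearity_in_modulus(self):
        v = make_block((4, 4, 6), density=0.5)
        m = build_mesh(v, require_caps=False)
        k1 = stiffness_scale_check(m, build_material_field(v, COEFFS),
                                   frictionless_column_bc)
        v2 = make_block((4, 4, 6), density=1.0)
        k2 = stiffness_scale_check(m, build_material_field(v2, COEFFS),
                                   frictionless_column_bc)
        assert k2 == pytest.approx(2 * k1, rel=1e-8)

    def test_homogeneous_column_EA_over_L(self):
        v = make_block((4, 4, 8), density=1.0)  # E = 1000, A = 64, L = 16
        m = build_mesh(v, require_caps=False)
        k = stiffness_scale_check(m, build_material_field(v, COEFFS),
                                  frictionless_column_bc)
        assert k == pytest.approx(1000.0 * 64.0 / 16.0, rel=1e-8)

    def test_lesion_strictly_reduces_stiffness(self, specimen):
        m = build_mesh(specimen)
        coeffs = PowerLawCoefficients(7546.0, 2.0)
        k_intact = stiffness_scale_check(m, build_material_field(specimen, coeffs))
        lesioned = insert_defect(specimen, DefectSpec(fraction=0.5))
        k_lesion = stiffness_scale_check(m, build_material_field(lesioned, coeffs))
        assert k_lesion < k_intact


class TestStrainMeasures:
    def test_equivalent_strain_uniaxial_closed_form(self):
        from vertefem.fem import equivalent_strain, failure_strain_measure
        eps = np.array([[1e-3, 0, 0, 0, 0, 0]])
        # deviatoric von Mises equivalent of a uniaxial strain state: 2e/3
        assert equivalent_strain(eps)[0] == pytest.approx(2e-3 / 3, rel=1e-9)
        assert failure_strain_measure(eps, "principal")[0] == pytest.approx(1e-3)
        assert failure_strain_measure(eps, "von_mises")[0] == pytest.approx(2e-3 / 3)
        with pytest.raises(ValueError):
            failure_strain_measure(eps, "bogus")
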