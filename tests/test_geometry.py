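import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vertefem.exceptions import GeometryError, StateError, VertefemError
from vertefem.geometry import (DefectSpec, augment, defect_connected,
                               enumerate_design, insert_defect,
                               min_cross_section_level)
from vertefem.synth import (AUGMENTATION, BACKGROUND, BONE, DEFECT, PMMA_CAP,
                            LabeledVolume)

from conftest import make_block


def _circular_specimen(radius_vox=8, n=20, nz=16):
    """Bone cylinder with a circular cross-section (no waist, no caps)."""
    labels = np.zeros((n, n, nz), dtype=np.uint8)
    c = (n - 1) / 2
    X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (X - c) ** 2 + (Y - c) ** 2 <= radius_vox ** 2
    labels[:, :, 2:-2] = np.where(disk[:, :, None], BONE, BACKGROUND)
    dens = np.where(labels == BONE, 0.3, 0.0)
    return LabeledVolume(dens, labels, (1.0, 1.0, 1.0), {"shell_thickness": 1})


class TestMinCrossSection:
    def test_uniform_cylinder_tie_breaks_low(self):
        v = _circular_specimen()
        assert min_cross_section_level(v) == 2  # lowest bone slice

    def test_waisted_specimen_mid_height(self, specimen):
        level = min_cross_section_level(specimen)
        counts = (specimen.labels == BONE).sum(axis=(0, 1))
        zs = np.nonzero(counts)[0]
        assert counts[level] == counts[zs].min()
        assert abs(level - 0.5 * (zs[0] + zs[-1])) <= 2  # voxelization wiggle

    def test_single_slice_bone(self):
        v = _circular_specimen(nz=5)
        v.labels[:, :, 3:] = BACKGROUND
        assert min_cross_section_level(v) == 2

    def test_empty_specimen_raises(self):
        v = _circular_specimen()
        v.labels[:] = BACKGROUND
        with pytest.raises(VertefemError):
            min_cross_section_level(v)


class TestInsertDefect:
    @pytest.mark.parametrize("fraction", [0.2, 0.5])
    def test_area_fraction_accuracy(self, fraction):
        v = _circular_specimen()
        d = insert_defect(v, DefectSpec(fraction=fraction))
        ref = min_cross_section_level(v)
        bone_area = np.isin(v.labels[:, :, ref], [BONE]).sum()
        defect_area = (d.labels[:, :, ref] == DEFECT).sum()
        assert abs(defect_area / bone_area - fraction) <= 1.0 / bone_area

    def test_circular_half_area_radius(self):
        # fraction 0.5 on a circular section: defect radius ~ R * sqrt(0.5)
        v = _circular_specimen(radius_vox=8)
        d = insert_defect(v, DefectSpec(fraction=0.5))
        ref = min_cross_section_level(v)
        xs, ys = np.nonzero(d.labels[:, :, ref] == DEFECT)
        c = (v.shape[0] - 1) / 2
        r_max = np.sqrt((xs - c) ** 2 + (ys - c) ** 2).max()
        assert r_max == pytest.approx(8 * np.sqrt(0.5), abs=1.0)

    def test_label_conservation(self, specimen):
        d = insert_defect(specimen, DefectSpec(fraction=0.3))
        assert d.count(BACKGROUND) == specimen.count(BACKGROUND)
        assert d.count(PMMA_CAP) == specimen.count(PMMA_CAP)
        assert specimen.count(BONE) - d.count(BONE) == d.count(DEFECT)
        assert d.count(DEFECT) > 0

    def test_defect_centered_on_reference_plane_and_connected(self, specimen):
        d = insert_defect(specimen, DefectSpec(fraction=0.4))
        ref = d.metadata["reference_level"]
        zs = np.nonzero((d.labels == DEFECT).any(axis=(0, 1)))[0]
        assert zs[0] <= ref <= zs[-1]
        assert defect_connected(d)

    def test_idempotent(self, specimen):
        spec = DefectSpec(fraction=0.3)
        d1 = insert_defect(specimen, spec)
        d2 = insert_defect(d1, spec)
        assert np.array_equal(d1.labels, d2.labels)

    def test_below_one_voxel_warns_and_noops(self):
        v = _circular_specimen()
        with pytest.warns(UserWarning):
            d = insert_defect(v, DefectSpec(fraction=1e-4))
        assert np.array_equal(d.labels, v.labels)

    def test_unachievable_fraction_raises(self):
        v = _circular_specimen(radius_vox=5)
        v.metadata["shell_thickness"] = 3  # thick shell leaves a tiny interior
        with pytest.raises(GeometryError):
            insert_defect(v, DefectSpec(fraction=0.9))

    def test_shell_never_breached(self, specimen):
        from vertefem.synth import interior_mask
        d = insert_defect(specimen, DefectSpec(fraction=0.5))
        shell = specimen.metadata["shell_thickness"]
        body = specimen.labels == BONE
        outside_interior = (d.labels == DEFECT) & ~interior_mask(body, shell)
        assert not outside_interior.any()

    @pytest.mark.parametrize("shape", ["ellipsoid", "drilled_cylinder"])
    def test_alternate_shapes(self, specimen, shape):
        d = insert_defect(specimen, DefectSpec(fraction=0.3, shape=shape))
        assert d.count(DEFECT) > 0
        assert defect_connected(d)


class TestAugment:
    def test_relabel_conservation(self, specimen):
        d = insert_defect(specimen, DefectSpec(fraction=0.3))
        k = d.count(DEFECT)
        a = augment(d, 300.0)
        assert a.count(AUGMENTATION) == k
        assert a.count(DEFECT) == 0
        assert a.metadata["augmentation_modulus"] == 300.0

    def test_reaugment_updates_modulus_only(self, specimen):
        a1 = augment(insert_defect(specimen, DefectSpec(fraction=0.3)), 300.0)
        a2 = augment(a1, 2500.0)
        assert np.array_equal(a1.labels, a2.labels)
        assert a2.metadata["augmentation_modulus"] == 2500.0

    def test_no_defect_raises(self, specimen):
        with pytest.raises(StateError):
            augment(specimen, 300.0)


class TestEnumerateDesign:
    def test_study_design_counts(self):
        d = enumerate_design(6, (0.2, 0.5), (50.0, 300.0, 1000.0, 2000.0, 2500.0))
        assert (d.n_intact, d.n_defect, d.n_augmented) == (6, 12, 60)
        assert d.total == 78 == len(d.table)

    def test_intact_only(self):
        d = enumerate_design(1, (), ())
        assert d.total == 1

    @given(n=st.integers(1, 8), s=st.integers(0, 3), m=st.integers(0, 6))
    @settings(deadline=None, max_examples=40)
    def test_closed_form_count(self, n, s, m):
        fractions = tuple((i + 1) / 10 for i in range(s))
        moduli = tuple(100.0 * (i + 1) for i in range(m))
        d = enumerate_design(n, fractions, moduli)
        assert d.total == n * (1 + s + s * m)
        # brute-force enumeration agrees with the table
        assert (d.table["condition"] == "intact").sum() == n
        assert (d.table["condition"] == "defect").sum() == n * s
        assert (d.table["condition"] == "augmented").sum() == n * s * m
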