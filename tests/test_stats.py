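import numpy as np
import pandas as pd
import pytest

from vertefem.exceptions import DegenerateDataError
from vertefem.stats import (icc_from_variances, mixed_icc, paired_t,
                            paired_vs_intact, percent_change, regression,
                            shapiro_wilk, tag_region)


class TestRegression:
    def test_identity_perfect_fit(self):
        r = regression([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert (r.slope, r.r_squared) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_affine_exact(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        r = regression(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.1, 2.3, 2.9, 4.2, 5.0])
        y = np.array([2.0, 2.8, 4.1, 4.0, 6.3])
        X = np.column_stack([x, np.ones_like(x)])
        slope_o, intercept_o = np.linalg.solve(X.T @ X, X.T @ y)
        r = regression(x, y)
        assert r.slope == pytest.approx(slope_o, rel=1e-12)
        assert r.intercept == pytest.approx(intercept_o, rel=1e-12)
        assert r.r_squared == pytest.approx(r.r ** 2, rel=1e-12)

    def test_degenerate_predictor(self):
        with pytest.raises(DegenerateDataError):
            regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_identical_pairs_null(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_three_point_closed_form(self):
        # differences {1, 2, 3}: t = dbar / (sd / sqrt(3)) = 2 / (1/sqrt(3))
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        t, p = paired_t(x, y)
        assert t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)

    def test_sign_symmetry(self):
        x = np.array([2.0, 4.0, 7.0])
        y = np.array([1.0, 2.0, 3.0])
        t1, p1 = paired_t(x, y)
        t2, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_shift_invariance(self):
        x = np.array([2.0, 4.0, 7.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 6.0])
        t1, _ = paired_t(x, y)
        t2, _ = paired_t(x + 10.0, y + 10.0)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestShapiroWilk:
    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([1.0] * 10)

    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=200)
            _, p = shapiro_wilk(x)
            hits += p > 0.05
        assert hits >= 9

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_sample_size_limits(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([1.0, 2.0])


class TestICC:
    def test_reported_variance_components(self):
        # donor 0.738, residual 2.238 -> donor share ~ 0.25
        assert icc_from_variances(0.738, 2.238) == pytest.approx(0.738 / 2.976)
        assert icc_from_variances(0.738, 2.238) == pytest.approx(0.25, abs=0.005)

    def test_zero_donor_variance(self):
        assert icc_from_variances(0.0, 1.0) == 0.0

    def test_mixed_model_recovers_known_components(self):
        rng = np.random.default_rng(12)
        donor_sd, resid_sd = 1.0, 1.5
        truth = donor_sd ** 2 / (donor_sd ** 2 + resid_sd ** 2)
        rows = []
        conditions = ["Intact", "E300", "PMMA"]
        for d in range(20):
            u = rng.normal(0, donor_sd)
            for v in range(6):
                cond = conditions[v % 3]
                effect = {"Intact": 0.0, "E300": 0.5, "PMMA": 2.0}[cond]
                rows.append({"specimen": f"D{d}V{v}", "donor": f"D{d}",
                             "condition_label": cond,
                             "group": "20%" if v % 2 else "50%",
                             "region": "Upper" if rng.random() < 0.5 else "Lower",
                             "max_stress_MPa": 3.0 + effect + u
                             + rng.normal(0, resid_sd)})
        res = mixed_icc(pd.DataFrame(rows))
        assert res.icc == pytest.approx(truth, abs=0.05)
        assert res.donor_variance >= 0 and res.residual_variance >= 0

    def test_single_donor_rejected(self):
        df = pd.DataFrame({"donor": ["D0"] * 6, "condition_label": ["Intact"] * 6,
                           "max_stress_MPa": np.arange(6.0)})
        with pytest.raises(DegenerateDataError):
            mixed_icc(df)


class TestStudyStructure:
    def test_region_tag_by_peak_half(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        assert tag_region(z, np.array([0, 1, 5, 2.0]), center_z_mm=2.5) == "Upper"
        assert tag_region(z, np.array([5, 1, 0, 2.0]), center_z_mm=2.5) == "Lower"

    def test_percent_gain_printed_means(self):
        assert percent_change(3409.0, 4420.0) == pytest.approx(29.7, abs=0.1)

    def test_paired_vs_intact_structure(self):
        rows = []
        rng = np.random.default_rng(3)
        for s in range(6):
            base = rng.uniform(2, 3)
            rows.append({"specimen": f"V{s}", "condition_label": "Intact",
                         "max_stress_MPa": base})
            rows.append({"specimen": f"V{s}", "condition_label": "PMMA",
                         "max_stress_MPa": base + 2 + rng.normal(0, 0.1)})
            rows.append({"specimen": f"V{s}", "condition_label": "E300",
                         "max_stress_MPa": base + rng.normal(0, 0.1)})
        out = paired_vs_intact(pd.DataFrame(rows))
        assert set(out["condition"]) == {"PMMA", "E300"}
        pmma = out[out["condition"] == "PMMA"].iloc[0]
        assert pmma["p"] < 0.01 and pmma["mean_difference"] > 0
        assert (out["n_pairs"] == 6).all()
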