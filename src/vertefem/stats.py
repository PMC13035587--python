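"""Cohort statistics.

The study-specific structure lives here -- pairing each augmentation
material against the intact condition per specimen, tagging the
upper/lower region of each stress profile, and the donor random-intercept
mixed model with its intraclass correlation -- while the standard tests
(OLS, paired t, Shapiro-Wilk, REML) are delegated to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .exceptions import DegenerateDataError

CONDITION_LABELS = {0.0: "Intact", 50.0: "E50", 300.0: "E300",
                    1000.0: "E1000", 2000.0: "PPF", 2500.0: "PMMA"}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float


@dataclass
class MixedModelResult:
    fixed_effects: pd.Series
    p_values: pd.Series
    donor_variance: float
    residual_variance: float
    icc: float


def regression(predicted, target) -> RegressionResult:
    """OLS of target on predicted with Pearson correlation (R^2 = r^2)."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("regression needs >= 3 paired values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in the predictor")
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue))


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test.

    Identical pairs (every difference exactly zero) are the no-effect
    limit and return (0, 1); zero-variance nonzero differences are
    degenerate and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise DegenerateDataError("paired t-test needs >= 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateDataError("differences have zero variance")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise DegenerateDataError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def icc_from_variances(donor_variance: float, residual_variance: float) -> float:
    """Intraclass correlation: donor variance share of the total."""
    if donor_variance < 0 or residual_variance < 0:
        raise ValueError("variance components must be non-negative")
    total = donor_variance + residual_variance
    if total == 0:
        raise DegenerateDataError("both variance components are zero")
    return donor_variance / total


def condition_label(condition: str, modulus: float | None) -> str:
    if condition == "intact":
        return "Intact"
    if condition == "defect":
        return "Defect"
    return CONDITION_LABELS.get(float(modulus), f"E{modulus:g}")


def tag_region(profile_z: np.ndarray, profile_stress: np.ndarray,
               center_z_mm: float) -> str:
    """Upper/Lower tag: the half of the profile (relative to the defect
    center plane) containing the maximum averaged stress."""
    z_peak = profile_z[int(np.argmax(profile_stress))]
    return "Upper" if z_peak >= center_z_mm else "Lower"


def paired_vs_intact(table: pd.DataFrame, value: str = "max_stress_MPa"
                     ) -> pd.DataFrame:
    """Paired t-tests of each augmentation material against Intact.

    ``table`` needs columns specimen, condition_label and the value column;
    pairs are matched within specimen (augmented rows of both defect sizes
    are averaged per specimen first, mirroring a per-vertebra summary).
    """
    wide = (table.groupby(["specimen", "condition_label"])[value]
            .mean().unstack("condition_label"))
    if "Intact" not in wide:
        raise DegenerateDataError("table has no Intact condition")
    rows = []
    for cond in [c for c in wide.columns if c not in ("Intact", "Defect")]:
        sub = wide[["Intact", cond]].dropna()
        t, p = paired_t(sub[cond].to_numpy(), sub["Intact"].to_numpy())
        _, p_norm = shapiro_wilk((sub[cond] - sub["Intact"]).to_numpy()) \
            if len(sub) >= 3 else (np.nan, np.nan)
        rows.append({"condition": cond, "n_pairs": len(sub), "t": t, "p": p,
                     "shapiro_p_differences": p_norm,
                     "mean_difference": float((sub[cond] - sub["Intact"]).mean())})
    return pd.DataFrame(rows)


def mixed_icc(table: pd.DataFrame, outcome: str = "max_stress_MPa") -> MixedModelResult:
    """Donor random-intercept mixed model for maximum stress.

    Fixed effects: condition label, defect-size group (20%/50%) and region
    (Upper/Lower); random intercept per donor; REML fit.  The ICC is the
    donor variance share of donor + residual variance.
    """
    df = table.dropna(subset=[outcome]).copy()
    if df["donor"].nunique() < 2:
        raise DegenerateDataError("ICC is undefined with a single donor")
    df["y"] = df[outcome]
    terms = ["C(condition_label)"]
    if "group" in df and df["group"].nunique() > 1:
        terms.append("C(group)")
    if "region" in df and df["region"].nunique() > 1:
        terms.append("C(region)")
    fit = None
    while terms:
        model = smf.mixedlm("y ~ " + " + ".join(terms), df, groups=df["donor"])
        try:
            fit = model.fit(reml=True)
            break
        except np.linalg.LinAlgError:
            # collinear fixed effects (e.g. a group level only the intact
            # condition carries): drop the last term and refit
            terms.pop()
    if fit is None:
        raise DegenerateDataError("mixed model design is singular")
    donor_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)
    return MixedModelResult(fixed_effects=fit.fe_params, p_values=fit.pvalues,
                            donor_variance=donor_var, residual_variance=resid_var,
                            icc=icc_from_variances(donor_var, resid_var))


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after`` (e.g. 3409 -> 4420 N is +29.7%)."""
    if before == 0:
        raise ValueError("undefined percent change from zero")
    return 100.0 * (after - before) / before


def summarize(table: pd.DataFrame) -> str:
    """Human-readable cohort summary: mean force and stress per condition."""
    lines = ["condition  n  mean_force_N  mean_max_stress_MPa"]
    g = table.groupby("condition_label")
    for cond, sub in g:
        force = sub["fracture_force_N"].mean() if "fracture_force_N" in sub else np.nan
        stress = sub["max_stress_MPa"].mean() if "max_stress_MPa" in sub else np.nan
        lines.append(f"{cond:<9} {len(sub):>2}  {force:12.1f}  {stress:19.3f}")
    return "\n".join(lines)
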