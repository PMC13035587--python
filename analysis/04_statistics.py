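#!/usr/bin/env python
"""Cohort statistics: paired stress comparisons, normality, donor ICC.

Consumes results/results.csv from 02_run_cohort.py.  Pairs each cement
stiffness against the intact condition per specimen (paired t with
Shapiro-Wilk on the differences), fits the donor random-intercept mixed
model for maximum stress, and reports the ICC.  Writes
results/paired_tests.csv and results/mixed_model.txt.
"""

from pathlib import Path

import pandas as pd

from vertefem.stats import mixed_icc, paired_vs_intact, shapiro_wilk

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res_path = ROOT / "results" / "results.csv"
    if not res_path.exists():
        raise SystemExit("run analysis/02_run_cohort.py first")
    table = pd.read_csv(res_path)

    paired = paired_vs_intact(table)
    paired.to_csv(ROOT / "results" / "paired_tests.csv", index=False)
    print("paired t-tests of max stress vs Intact:")
    print(paired.round(4).to_string(index=False))

    w, p = shapiro_wilk(table["max_stress_MPa"].dropna())
    print(f"\nShapiro-Wilk on max stress: W={w:.3f}, p={p:.3f}")

    mm = mixed_icc(table)
    lines = [
        f"donor variance   {mm.donor_variance:.4f}",
        f"residual variance {mm.residual_variance:.4f}",
        f"ICC              {mm.icc:.3f}",
        "", "fixed effects (p-values):",
        mm.p_values.round(4).to_string(),
    ]
    text = "\n".join(lines)
    (ROOT / "results" / "mixed_model.txt").write_text(text + "\n")
    print("\ndonor random-intercept model:")
    print(text)


if __name__ == "__main__":
    main()
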