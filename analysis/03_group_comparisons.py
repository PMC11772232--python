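#!/usr/bin/env python
"""Univariate group comparisons.

Applies the 5-SD volumetric outlier filter, compares VPT vs FT on the
demographic/neonatal variables (pooled t, chi-square) and on the four
socio-emotional scores (Welch t, Cohen's d, BH-FDR), then fits the 20
per-measure ANCOVA models (group * age + ICV + sex + SES) with FDR
over the group and group x age terms.
"""

from pathlib import Path

import pandas as pd

import preterm_amygdala as pa

OUT = Path("results/analysis")


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    volumes = pd.read_csv(OUT / "volumes.csv")
    scores = pd.read_csv(OUT / "behavior_scores.csv")

    volumes_f, exclusions = pa.outlier_filter_5sd(volumes)
    volumes_f.to_csv(OUT / "volumes_filtered.csv", index=False)
    exclusions.to_csv(OUT / "volume_exclusions.csv", index=False)
    print(f"5-SD filter: {len(exclusions)} entries excluded")

    demo = pa.compare_demographics(cohort, scores)
    demo.to_csv(OUT / "demographics.csv", index=False)
    sig = demo[demo["p_value"] < 0.05]["variable"].tolist()
    print(f"group differences at p < 0.05: {sig}")

    ancova = pa.ancova_volumes(volumes_f, cohort)
    ancova.to_csv(OUT / "ancova.csv", index=False)
    for term in ("group", "group_x_age", "icv", "sex", "ses"):
        rows = ancova[ancova["term"] == term]
        n_sig = (rows["q_value"] < 0.05).sum() if term in (
            "group", "group_x_age") else (rows["p_value"] < 0.05).sum()
        label = "q" if term in ("group", "group_x_age") else "p"
        print(f"ANCOVA {term}: {n_sig}/20 measures at {label} < 0.05")


if __name__ == "__main__":
    main()
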