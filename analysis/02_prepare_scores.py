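#!/usr/bin/env python
"""Residualize the raw socio-emotional scores.

Regresses each instrument's raw score on its covariates (age at
testing and SES; SES only for the BRIEF emotional-control scale) and
standardizes the residuals, producing the four scores used by every
downstream analysis.  Also writes the gestational-age-adjusted variant.
"""

from pathlib import Path

import pandas as pd

import preterm_amygdala as pa

OUT = Path("results/analysis")


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    behavior = pd.read_csv(OUT / "behavior_raw.csv")

    for adjust_ga, name in ((False, "behavior_scores.csv"),
                            (True, "behavior_scores_ga_adjusted.csv")):
        scores = pa.prepare_behavior_scores(behavior, cohort,
                                            adjust_ga=adjust_ga)
        scores.to_csv(OUT / name, index=False)
        cols = list(pa.BEHAVIOR_SCORE_COLUMNS)
        print(f"{name}: n={len(scores)}, "
              f"max |mean|={scores[cols].mean().abs().max():.2e}, "
              f"max |sd-1|={(scores[cols].std() - 1).abs().max():.2e}")


if __name__ == "__main__":
    main()
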