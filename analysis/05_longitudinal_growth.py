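#!/usr/bin/env python
"""Longitudinal growth and the two secondary PLSC designs.

Computes TEA -> school-age relative growth rates, contrasts the 6-9 y
vs 10-14 y school-age bands, derives inter-age-adjusted trajectory
scores, and runs the two single-group PLSC analyses: raw TEA volumes
vs the subgroup's behavior scores, and trajectory scores vs the same
scores.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import preterm_amygdala as pa

OUT = Path("results/analysis")
SEED = 20240518


def main() -> None:
    records = pa.derive_fields(
        pd.read_csv(OUT / "longitudinal_subgroup.csv")
    )
    growth, bands, plot_data = pa.growth_summary(records)
    growth.to_csv(OUT / "growth_rates.csv", index=False)
    plot_data.to_csv(OUT / "growth_plot_data.csv", index=False)
    (OUT / "growth_band_contrast.json").write_text(
        json.dumps(bands, indent=2) + "\n"
    )
    for band, stats_ in bands.items():
        print(f"{band}: n={stats_['n']}, mean total growth "
              f"{stats_['mean_growth_rate_total']:.2f} %/month")

    trajectories = pa.trajectory_scores(records)
    trajectories.to_csv(OUT / "trajectory_scores.csv", index=False)

    raw = records[["subject_id"] + list(pa.BEHAVIOR_RAW_COLUMNS)]
    covars = records[["subject_id", "age_school_months", "ses_largo",
                      "gestational_age_weeks"]]
    scores = pa.prepare_behavior_scores(raw, covars)
    Y = scores[list(pa.BEHAVIOR_SCORE_COLUMNS)]
    groups = np.array(["VPT"] * len(records))

    for X, name, seed in (
        (records[["vol_tea_left", "vol_tea_right"]], "tea", SEED),
        (trajectories[["trajectory_left", "trajectory_right"]],
         "trajectory", SEED + 1),
    ):
        res = pa.run_plsc(X, Y, groups, n_perm=1000, n_boot=500, seed=seed)
        res.components_table().to_csv(
            OUT / f"plsc_{name}_components.csv", index=False
        )
        print(f"PLSC {name} vs behavior: LC1 p = {res.perm_p[0]:.3f} "
              f"({'significant' if res.significant[0] else 'ns'})")


if __name__ == "__main__":
    main()
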