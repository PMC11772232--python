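#!/usr/bin/env python
"""Group-wise PLSC of amygdala volumes vs socio-emotional scores.

Stacks the per-group volume-behavior cross-correlations, decomposes
them into latent components, tests component significance with 1000
permutations (robust at p < 0.01) and salience stability with 500
bootstrap resamples (robust at |BSR| >= 3).  Run twice: with the
standard scores and with the gestational-age-adjusted scores.
"""

from pathlib import Path

import pandas as pd

import preterm_amygdala as pa

OUT = Path("results/analysis")
SEED = 20240518


def run(score_file: str, tag: str) -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    volumes = pd.read_csv(OUT / "volumes_filtered.csv")
    scores = pd.read_csv(OUT / score_file)

    data = (
        volumes.dropna(subset=list(pa.MEASURES))
        .merge(scores, on="subject_id")
    )
    res = pa.run_plsc(
        data[list(pa.MEASURES)],
        data[list(pa.BEHAVIOR_SCORE_COLUMNS)],
        data["group"].to_numpy(),
        group_order=["VPT", "FT"],
        n_perm=1000,
        n_boot=500,
        seed=SEED,
    )
    res.components_table().to_csv(
        OUT / f"plsc_components{tag}.csv", index=False
    )
    res.volumetric_salience_table().to_csv(
        OUT / f"plsc_saliences_volumetric{tag}.csv", index=False
    )
    res.behavior_salience_table().to_csv(
        OUT / f"plsc_saliences_behavior{tag}.csv", index=False
    )

    print(f"[{tag or 'standard'}] LC1: singular value "
          f"{res.singular_values[0]:.3f}, p = {res.perm_p[0]:.4f}"
          f" ({'significant' if res.significant[0] else 'ns'} at "
          f"p < {res.alpha_component})")
    vol_tab = res.volumetric_salience_table()
    robust = vol_tab[(vol_tab.component == 1) & vol_tab.robust]
    print(f"  robust volumetric contributors (|BSR| >= 3): "
          f"{robust['measure'].tolist()}")
    beh_tab = res.behavior_salience_table()
    for g in res.group_order:
        rob = beh_tab[(beh_tab.component == 1) & (beh_tab.group == g)
                      & beh_tab.robust]
        print(f"  robust {g} behavioral contributors: "
              f"{rob['behavior'].tolist()}")


def main() -> None:
    run("behavior_scores.csv", "")
    run("behavior_scores_ga_adjusted.csv", "_ga_adjusted")


if __name__ == "__main__":
    main()
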