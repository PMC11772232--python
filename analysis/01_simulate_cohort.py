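#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws a 75 VPT / 41 FT cross-sectional cohort with a moderate planted
brain-behavior association, plus the 20-subject longitudinal VPT
subgroup, and writes the raw tables that the later analysis steps read.
"""

from pathlib import Path

import preterm_amygdala as pa

OUT = Path("results/analysis")
SEED = 20240518
LATENT_STRENGTH = 2.0  # moderate planted association


def main() -> None:
    cfg = pa.SimulationConfig(seed=SEED, latent_strength=LATENT_STRENGTH)
    cohort, volumes, behavior = pa.generate_cohort(cfg)
    paths = pa.simulate.write_cohort(OUT, cohort, volumes, behavior, cfg)

    subgroup = pa.generate_longitudinal_subgroup(n=20, seed=SEED)
    subgroup_path = OUT / "longitudinal_subgroup.csv"
    subgroup.to_csv(subgroup_path, index=False)

    print(f"cohort: {len(cohort)} subjects "
          f"({(cohort.group == 'VPT').sum()} VPT, "
          f"{(cohort.group == 'FT').sum()} FT)")
    print(f"volumetric measures: {len(pa.MEASURES)}")
    print(f"longitudinal subgroup: {len(subgroup)} paired TEA/school scans")
    for name, path in {**paths, "longitudinal": subgroup_path}.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
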