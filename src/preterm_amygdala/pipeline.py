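"""End-to-end orchestration of the cross-sectional and longitudinal
analyses, with reproducible seeding and a machine-readable manifest.

``run_cross_sectional`` executes: 5-SD volumetric outlier filter ->
behavior-score residualization -> demographic/behavioral group
comparisons -> 20 ANCOVA models -> group-wise PLSC.
``run_longitudinal`` executes: growth-rate and trajectory scoring ->
two single-group PLSC runs (TEA volumes vs school-age scores;
trajectory scores vs school-age scores).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .group_stats import (
    TwoSampleSummary,
    ancova_volumes,
    chi_square_2x2,
    cohens_d_pooled,
    fdr_bh,
    outlier_filter_5sd,
    pooled_t_test,
    welch_t_test,
)
from .longitudinal import derive_fields, growth_summary, trajectory_scores
from .measures import BEHAVIOR_SCORE_COLUMNS, GROUPS, MEASURES
from .plsc import run_plsc
from .scores import prepare_behavior_scores
from .simulate import (
    GrowthParams,
    SimulationConfig,
    generate_cohort,
    generate_longitudinal_subgroup,
)

log = logging.getLogger(__name__)

#: Table-1-style demographic rows compared with the pooled t-test
DEMOGRAPHIC_VARS = {
    "gestational_age_weeks": "Gestational age (weeks)",
    "birth_weight_g": "Birth weight (g)",
    "age_school_months": "Age at assessment (months)",
    "ses_largo": "SES (Largo score)",
    "intellectual_functioning": "General intellectual functioning",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulated or file inputs)."""

    out_dir: str = "results/run"
    simulation: SimulationConfig | None = None
    input_paths: dict | None = None  # cohort / volumes / behavior_raw CSVs
    longitudinal_n: int = 20
    growth_params: GrowthParams | None = None
    longitudinal_path: str | None = None
    adjust_ga: bool = False
    per_group_residuals: bool = False
    zscore: bool = True
    perm_procrustes: bool = False
    n_perm: int = 1000
    n_boot: int = 500
    seed: int = 0
    alpha_component: float = 0.01
    bsr_threshold: float = 3.0

    def validate(self) -> "RunConfig":
        if (self.simulation is None) == (self.input_paths is None):
            raise ConfigurationError(
                "provide exactly one of simulation config or input paths"
            )
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, extra: dict) -> Path:
    files = sorted(p for p in out.glob("*.csv"))
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict.pop("out_dir", None)  # not part of the analysis config
    if cfg.simulation is not None:
        cfg_dict["simulation"] = cfg.simulation.to_jsonable()
    if cfg.growth_params is not None:
        gp = dataclasses.asdict(cfg.growth_params)
        gp["behavior_salience"] = np.asarray(
            gp["behavior_salience"]
        ).tolist()
        gp["tea_age_range_months"] = list(gp["tea_age_range_months"])
        cfg_dict["growth_params"] = gp
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "files": {p.name: _sha256(p) for p in files},
        **extra,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _load_inputs(cfg: RunConfig):
    if cfg.simulation is not None:
        return generate_cohort(cfg.simulation)
    paths = cfg.input_paths
    return (
        pd.read_csv(paths["cohort"]),
        pd.read_csv(paths["volumes"]),
        pd.read_csv(paths["behavior_raw"]),
    )


def compare_demographics(
    cohort: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Table-1-style comparisons: pooled t for demographics, chi-square
    for sex, Welch t + Cohen's d + BH-FDR for the four behavior scores."""
    vpt = cohort[cohort["group"] == "VPT"]
    ft = cohort[cohort["group"] == "FT"]
    rows = []
    for var, label in DEMOGRAPHIC_VARS.items():
        x1 = vpt[var].dropna()
        x2 = ft[var].dropna()
        s = TwoSampleSummary(
            x1.mean(), x1.std(ddof=1), len(x1),
            x2.mean(), x2.std(ddof=1), len(x2),
        )
        t, df, p = pooled_t_test(s)
        rows.append(
            {
                "variable": label,
                "test": "pooled_t",
                "vpt_mean": x1.mean(),
                "vpt_sd": x1.std(ddof=1),
                "ft_mean": x2.mean(),
                "ft_sd": x2.std(ddof=1),
                "statistic": t,
                "df": df,
                "p_value": p,
                "q_value": np.nan,
                "effect_size": np.nan,
            }
        )
    counts = [
        [
            int(((cohort["group"] == g) & (cohort["sex"] == s)).sum())
            for g in GROUPS
        ]
        for s in ("F", "M")
    ]
    chi2, df, p = chi_square_2x2(counts)
    rows.append(
        {
            "variable": "Sex (F/M)",
            "test": "chi_square",
            "vpt_mean": counts[0][0],
            "vpt_sd": counts[1][0],
            "ft_mean": counts[0][1],
            "ft_sd": counts[1][1],
            "statistic": chi2,
            "df": df,
            "p_value": p,
            "q_value": np.nan,
            "effect_size": np.nan,
        }
    )
    merged = scores.merge(cohort[["subject_id", "group"]], on="subject_id",
                          how="left", suffixes=("", "_cohort"))
    if "group" not in scores.columns:
        merged["group"] = merged["group_cohort"]
    behavior_rows = []
    for col in BEHAVIOR_SCORE_COLUMNS:
        x1 = merged.loc[merged["group"] == "VPT", col].dropna()
        x2 = merged.loc[merged["group"] == "FT", col].dropna()
        t, df, p = welch_t_test(x1, x2)
        d = cohens_d_pooled(
            TwoSampleSummary(
                x1.mean(), x1.std(ddof=1), len(x1),
                x2.mean(), x2.std(ddof=1), len(x2),
            )
        )
        behavior_rows.append(
            {
                "variable": col,
                "test": "welch_t",
                "vpt_mean": x1.mean(),
                "vpt_sd": x1.std(ddof=1),
                "ft_mean": x2.mean(),
                "ft_sd": x2.std(ddof=1),
                "statistic": t,
                "df": df,
                "p_value": p,
                "q_value": np.nan,
                "effect_size": d,
            }
        )
    q = fdr_bh([r["p_value"] for r in behavior_rows])
    for r, qv in zip(behavior_rows, q):
        r["q_value"] = qv
    return pd.DataFrame(rows + behavior_rows)


def run_cross_sectional(cfg: RunConfig) -> dict:
    """Execute the full cross-sectional analysis; returns a result bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort, volumes, behavior_raw = _load_inputs(cfg)
    volumes_f, exclusions = outlier_filter_5sd(volumes)
    scores = prepare_behavior_scores(
        behavior_raw,
        cohort,
        adjust_ga=cfg.adjust_ga,
        per_group=cfg.per_group_residuals,
    )
    demographics = compare_demographics(cohort, scores)
    ancova = ancova_volumes(volumes_f, cohort)

    plsc_data = (
        volumes_f.dropna(subset=list(MEASURES))
        .merge(scores, on="subject_id", validate="1:1")
        .merge(cohort[["subject_id", "group"]].rename(
            columns={"group": "group_cohort"}), on="subject_id")
    )
    group_col = (
        plsc_data["group"]
        if "group" in plsc_data.columns
        else plsc_data["group_cohort"]
    )
    plsc = run_plsc(
        plsc_data[list(MEASURES)],
        plsc_data[list(BEHAVIOR_SCORE_COLUMNS)],
        group_col.to_numpy(),
        group_order=[g for g in GROUPS if (group_col == g).any()],
        n_perm=cfg.n_perm,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        alpha_component=cfg.alpha_component,
        bsr_threshold=cfg.bsr_threshold,
        zscore=cfg.zscore,
        perm_procrustes=cfg.perm_procrustes,
    )

    cohort.to_csv(out / "cohort.csv", index=False)
    volumes.to_csv(out / "volumes_raw.csv", index=False)
    behavior_raw.to_csv(out / "behavior_raw.csv", index=False)
    volumes_f.to_csv(out / "volumes_filtered.csv", index=False)
    exclusions.to_csv(out / "volume_exclusions.csv", index=False)
    scores.to_csv(out / "behavior_scores.csv", index=False)
    demographics.to_csv(out / "demographics.csv", index=False)
    ancova.to_csv(out / "ancova.csv", index=False)
    plsc.components_table().to_csv(out / "plsc_components.csv", index=False)
    plsc.volumetric_salience_table().to_csv(
        out / "plsc_saliences_volumetric.csv", index=False
    )
    plsc.behavior_salience_table().to_csv(
        out / "plsc_saliences_behavior.csv", index=False
    )
    pd.DataFrame(
        {
            "subject_id": plsc_data["subject_id"],
            "group": group_col,
            **{
                f"score_x_lc{k + 1}": plsc.scores_x[:, k]
                for k in range(min(3, plsc.scores_x.shape[1]))
            },
            **{
                f"score_y_lc{k + 1}": plsc.scores_y[:, k]
                for k in range(min(3, plsc.scores_y.shape[1]))
            },
        }
    ).to_csv(out / "plsc_subject_scores.csv", index=False)
    manifest = _write_manifest(
        out,
        cfg,
        {
            "analysis": "cross_sectional",
            "n_subjects": int(len(cohort)),
            "n_plsc_subjects": int(len(plsc_data)),
            "lc1_p": float(plsc.perm_p[0]),
            "lc1_significant": bool(plsc.significant[0]),
        },
    )
    return {
        "cohort": cohort,
        "volumes_filtered": volumes_f,
        "exclusions": exclusions,
        "scores": scores,
        "demographics": demographics,
        "ancova": ancova,
        "plsc": plsc,
        "manifest_path": manifest,
        "out_dir": out,
    }


def run_longitudinal(cfg: RunConfig) -> dict:
    """Execute the longitudinal analysis; returns a result bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.longitudinal_path is not None:
        records = pd.read_csv(cfg.longitudinal_path)
    else:
        records = generate_longitudinal_subgroup(
            n=cfg.longitudinal_n,
            seed=cfg.seed,
            growth_params=cfg.growth_params,
        )
    records = derive_fields(records)
    growth_table, band_contrast, plot_data = growth_summary(records)
    trajectories = trajectory_scores(records)

    raw_cols = [
        "theory_of_mind_raw",
        "affect_recognition_raw",
        "internalizing_raw",
        "emotional_control_T",
    ]
    raw = records[["subject_id"] + raw_cols]
    covars = records[
        [
            "subject_id",
            "age_school_months",
            "ses_largo",
            "gestational_age_weeks",
        ]
    ]
    scores = prepare_behavior_scores(raw, covars, adjust_ga=cfg.adjust_ga)

    groups = np.array(["VPT"] * len(records))
    common = dict(
        groups=groups,
        n_perm=cfg.n_perm,
        n_boot=cfg.n_boot,
        alpha_component=cfg.alpha_component,
        bsr_threshold=cfg.bsr_threshold,
        zscore=cfg.zscore,
        perm_procrustes=cfg.perm_procrustes,
        behavior_names=list(BEHAVIOR_SCORE_COLUMNS),
    )
    Y = scores[list(BEHAVIOR_SCORE_COLUMNS)]
    plsc_tea = run_plsc(
        records[["vol_tea_left", "vol_tea_right"]],
        Y,
        seed=cfg.seed,
        **common,
    )
    plsc_traj = run_plsc(
        trajectories[["trajectory_left", "trajectory_right"]],
        Y,
        seed=cfg.seed + 1,
        **common,
    )

    records.to_csv(out / "longitudinal_records.csv", index=False)
    growth_table.to_csv(out / "growth_rates.csv", index=False)
    plot_data.to_csv(out / "growth_plot_data.csv", index=False)
    trajectories.to_csv(out / "trajectory_scores.csv", index=False)
    scores.to_csv(out / "behavior_scores_subgroup.csv", index=False)
    plsc_tea.components_table().to_csv(
        out / "plsc_tea_components.csv", index=False
    )
    plsc_traj.components_table().to_csv(
        out / "plsc_trajectory_components.csv", index=False
    )
    manifest = _write_manifest(
        out,
        cfg,
        {
            "analysis": "longitudinal",
            "n_subjects": int(len(records)),
            "band_contrast": band_contrast,
            "tea_lc1_p": float(plsc_tea.perm_p[0]),
            "trajectory_lc1_p": float(plsc_traj.perm_p[0]),
        },
    )
    return {
        "records": records,
        "growth_table": growth_table,
        "band_contrast": band_contrast,
        "trajectories": trajectories,
        "scores": scores,
        "plsc_tea": plsc_tea,
        "plsc_trajectory": plsc_traj,
        "manifest_path": manifest,
        "out_dir": out,
    }
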