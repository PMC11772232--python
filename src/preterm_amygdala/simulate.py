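"""Synthetic cohort generator.

Emulates the statistical structure of a very-preterm (VPT) vs full-term
(FT) school-age neuroimaging cohort: group differences in gestational
age, birth weight, socio-economic status and intellectual functioning;
ICV-proportional amygdala volumes with a male > female effect on
left-lateralized nuclei; a plantable rank-1 cross-covariance between the
20 volumetric measures and the 4 raw socio-emotional scores (a common
volumetric pattern paired with group-specific behavioral patterns); and
a longitudinal subgroup with an age-decelerating amygdala growth curve
from term-equivalent age (TEA) to school age.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config, so identical configs produce bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .measures import (
    BEHAVIOR_RAW_COLUMNS,
    MEASURES,
    NUCLEUS_MEASURES,
    SEX_EFFECT_MEASURES,
    base_volume,
)

# ---------------------------------------------------------------------------
# scales of the generative model (mm^3 / score points)

#: mm^3 of volume per unit of (latent_strength * subject factor * salience)
VOL_LATENT_UNIT = 60.0
#: per-measure noise SD as a fraction of the nominal volume
VOL_NOISE_FRAC = 0.05
#: SD of the nonnegative remainder added to hemisphere totals (mm^3)
TOTAL_REMAINDER_SD = 8.0

#: per-instrument dispersion of the raw behavior scores (score points)
BEHAVIOR_SIGMA = {
    "theory_of_mind_raw": 3.5,
    "affect_recognition_raw": 3.5,
    "internalizing_raw": 2.5,
    "emotional_control_T": 10.0,
}
BEHAVIOR_LOC = {
    "theory_of_mind_raw": 18.0,
    "affect_recognition_raw": 22.0,
    "internalizing_raw": 6.0,
    "emotional_control_T": 50.0,
}
#: slope on age at testing (per month, centred at 124 mo)
BEHAVIOR_AGE_SLOPE = {
    "theory_of_mind_raw": 0.05,
    "affect_recognition_raw": 0.06,
    "internalizing_raw": -0.01,
    "emotional_control_T": 0.0,
}
#: slope on SES Largo score (centred at 3.8; higher Largo = lower SES)
BEHAVIOR_SES_SLOPE = {
    "theory_of_mind_raw": -0.35,
    "affect_recognition_raw": -0.30,
    "internalizing_raw": 0.25,
    "emotional_control_T": 0.60,
}

#: group-level summary parameters of the emulated cohort (FT reference
#: levels; VPT offsets are the configurable ``group_covariate_shifts``)
FT_LEVELS = {"ga_weeks": 39.9, "bw_g": 3460.98, "ses": 2.89, "iq": 113.88}
GROUP_SD = {
    "VPT": {"ga_weeks": 1.84, "bw_g": 368.21, "ses": 2.32, "iq": 12.6},
    "FT": {"ga_weeks": 1.34, "bw_g": 413.8, "ses": 1.29, "iq": 10.95},
}
DEFAULT_COVARIATE_SHIFTS = {
    "ga_weeks": -10.48,
    "bw_g": -2200.05,
    "ses": 1.35,
    "iq": -7.30,
}

AGE_RANGE_MONTHS = (72.0, 180.0)


def default_volumetric_salience() -> np.ndarray:
    """Unit-norm planted volumetric pattern over the 20 measures.

    Positive loadings mirror the measures reported to drive the
    brain-behavior component: accessory basal, anterior amygdaloid area
    and cortico-amygdaloid transition area bilaterally, plus the right
    lateral, basal, cortical and medial nuclei.  Hemisphere-total
    entries are set to the sum of that side's nucleus entries, because
    synthesized totals are sums of nuclei (plus a nonnegative
    remainder), so the total's effective loading is exactly that sum.
    """
    weights = {
        "left_accessory_basal": 0.30,
        "right_accessory_basal": 0.30,
        "left_anterior_amygdaloid_area": 0.25,
        "right_anterior_amygdaloid_area": 0.25,
        "left_cortico_amygdaloid_transition": 0.25,
        "right_cortico_amygdaloid_transition": 0.25,
        "right_lateral": 0.20,
        "right_basal": 0.20,
        "right_cortical": 0.10,
        "right_medial": 0.10,
    }
    v = np.array([weights.get(m, 0.0) for m in MEASURES])
    for side in ("left", "right"):
        total = sum(
            w for m, w in weights.items() if m.startswith(f"{side}_")
        )
        v[MEASURES.index(f"{side}_total")] = total
    return v / np.linalg.norm(v)


def _as_unit_vector(v, length: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (length,):
        raise ConfigurationError(f"{name} must have shape ({length},)")
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
        raise ConfigurationError(f"{name} must have unit Euclidean norm")
    return v


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cross-sectional cohort."""

    n_vpt: int = 75
    n_ft: int = 41
    seed: int = 0
    latent_strength: float = 0.0
    volumetric_salience: np.ndarray = field(
        default_factory=default_volumetric_salience
    )
    #: behavior order: theory of mind, affect recognition, internalizing,
    #: emotional control.  VPT pattern loads on emotional control,
    #: FT pattern (negatively) on affect recognition.
    behavior_salience_vpt: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0])
    )
    behavior_salience_ft: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0, 0.0, 0.0])
    )
    noise_sd: float = 1.0
    icv_mean: float = 1.45e6
    icv_sd: float = 1.2e5
    sex_effect: float = 40.0
    group_covariate_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SHIFTS)
    )

    def validate(self) -> "SimulationConfig":
        if self.n_vpt < 2 or self.n_ft < 2:
            raise ConfigurationError("n_vpt and n_ft must each be >= 2")
        if not (self.noise_sd > 0):
            raise ConfigurationError("noise_sd must be positive")
        if not (self.icv_mean > 0 and self.icv_sd > 0):
            raise ConfigurationError("icv_mean and icv_sd must be positive")
        if self.latent_strength < 0:
            raise ConfigurationError("latent_strength must be nonnegative")
        self.volumetric_salience = _as_unit_vector(
            self.volumetric_salience, len(MEASURES), "volumetric_salience"
        )
        self.behavior_salience_vpt = _as_unit_vector(
            self.behavior_salience_vpt, 4, "behavior_salience_vpt"
        )
        self.behavior_salience_ft = _as_unit_vector(
            self.behavior_salience_ft, 4, "behavior_salience_ft"
        )
        return self

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key in (
            "volumetric_salience",
            "behavior_salience_vpt",
            "behavior_salience_ft",
        ):
            d[key] = np.asarray(d[key]).tolist()
        return d


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic cohort.

    Returns ``(cohort, volumes, behavior_raw)`` — three subject-aligned
    tables keyed by ``subject_id``.  Volumes are ICV-proportional with a
    male > female additive effect on the designated left nuclei; a
    single standard-normal subject factor, scaled by
    ``latent_strength``, drives both the volumetric salience pattern and
    the group-specific behavioral patterns, so ``latent_strength = 0``
    makes volumes and behavior independent by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_vpt + config.n_ft
    group = np.array(["VPT"] * config.n_vpt + ["FT"] * config.n_ft)
    subject_id = np.array([f"S{i + 1:04d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    male = (sex == "M").astype(float)
    age = rng.uniform(*AGE_RANGE_MONTHS, size=n)

    shifts = {**DEFAULT_COVARIATE_SHIFTS, **config.group_covariate_shifts}
    vpt = group == "VPT"

    def draw(var, lo=None, hi=None):
        mean = np.where(vpt, FT_LEVELS[var] + shifts[var], FT_LEVELS[var])
        sd = np.where(vpt, GROUP_SD["VPT"][var], GROUP_SD["FT"][var])
        x = rng.normal(mean, sd)
        return np.clip(x, lo, hi)

    ga = draw("ga_weeks", 23.0, 42.0)
    # keep the generated groups consistent with their definition
    ga = np.where(vpt, np.minimum(ga, 31.9), np.maximum(ga, 36.0))
    bw = draw("bw_g", 350.0, None)
    ses = draw("ses", 1.0, 12.0)
    iq = draw("iq")
    icv = np.clip(
        rng.normal(config.icv_mean, config.icv_sd, size=n),
        0.5 * config.icv_mean,
        None,
    )

    factor = rng.standard_normal(n)  # shared latent subject factor

    sal = dict(zip(MEASURES, config.volumetric_salience))
    vols = {}
    for m in NUCLEUS_MEASURES:
        v = base_volume(m) * (icv / config.icv_mean)
        if m in SEX_EFFECT_MEASURES:
            v = v + config.sex_effect * male
        v = v + VOL_LATENT_UNIT * config.latent_strength * factor * sal[m]
        v = v + (
            VOL_NOISE_FRAC
            * base_volume(m)
            * config.noise_sd
            * rng.standard_normal(n)
        )
        vols[m] = np.maximum(v, 0.5)
    for side in ("left", "right"):
        nuclei_sum = sum(vols[m] for m in NUCLEUS_MEASURES
                         if m.startswith(f"{side}_"))
        remainder = np.abs(rng.normal(0.0, TOTAL_REMAINDER_SD, size=n))
        vols[f"{side}_total"] = nuclei_sum + remainder

    u = np.where(
        vpt[:, None],
        config.behavior_salience_vpt,
        config.behavior_salience_ft,
    )  # (n, 4) per-subject behavioral pattern
    behavior = {}
    for k, col in enumerate(BEHAVIOR_RAW_COLUMNS):
        y = (
            BEHAVIOR_LOC[col]
            + BEHAVIOR_AGE_SLOPE[col] * (age - 124.0)
            + BEHAVIOR_SES_SLOPE[col] * (ses - 3.8)
            + BEHAVIOR_SIGMA[col]
            * (
                config.latent_strength * factor * u[:, k]
                + config.noise_sd * rng.standard_normal(n)
            )
        )
        if col == "internalizing_raw":
            y = np.maximum(y, 0.0)
        behavior[col] = y

    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "sex": sex,
            "age_school_months": age,
            "gestational_age_weeks": ga,
            "birth_weight_g": bw,
            "ses_largo": ses,
            "icv_mm3": icv,
            "intellectual_functioning": iq,
        }
    )
    volumes = pd.DataFrame({"subject_id": subject_id, **vols})
    behavior_raw = pd.DataFrame({"subject_id": subject_id, **behavior})
    return cohort, volumes, behavior_raw


# ---------------------------------------------------------------------------
# longitudinal subgroup


@dataclass
class GrowthParams:
    """Saturating-growth parameters for the TEA -> school-age subgroup.

    School-age volume per side is
    ``v_tea * (1 + amplitude * t / (t + t_half) + growth_noise_sd * eps)``
    with ``t`` the age at the school-age scan (months).  The implied
    relative growth rate over the scan interval decreases with ``t``
    (deceleration), matching the qualitative pattern that younger
    children show faster relative amygdala growth.
    """

    amplitude: float = 6.0
    t_half_months: float = 30.0
    growth_noise_sd: float = 0.35
    tea_vol_mean: float = 250.0  # per side, mm^3
    tea_vol_sd: float = 35.0
    tea_age_range_months: tuple = (0.5, 1.5)
    #: optional coupling between TEA volumes and school-age behavior
    latent_strength: float = 0.0
    behavior_salience: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0])
    )
    tea_latent_unit: float = 20.0  # mm^3 per latent unit


def generate_longitudinal_subgroup(
    n: int = 20,
    seed: int = 0,
    growth_params: GrowthParams | None = None,
) -> pd.DataFrame:
    """Draw the longitudinal VPT subgroup with paired TEA / school scans.

    Returns one table per subject with TEA and school-age ages and
    left/right volumes, plus the demographic covariates and raw
    socio-emotional scores needed to residualize behavior within the
    subgroup.
    """
    if n < 2:
        raise ConfigurationError("longitudinal subgroup needs n >= 2")
    p = growth_params or GrowthParams()
    if p.amplitude < 0 or p.growth_noise_sd < 0:
        raise ConfigurationError("growth parameters must be nonnegative")
    rng = np.random.default_rng(seed)

    subject_id = np.array([f"L{i + 1:04d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age_tea = rng.uniform(*p.tea_age_range_months, size=n)
    age_school = rng.uniform(*AGE_RANGE_MONTHS, size=n)
    ses = np.clip(rng.normal(3.6, 1.76, size=n), 1.0, 12.0)
    ga = np.clip(rng.normal(28.6, 1.78, size=n), 23.0, 31.9)

    factor = rng.standard_normal(n)
    w = np.array([1.0, 1.0]) / np.sqrt(2.0)  # left/right TEA pattern
    tea = {}
    for j, side in enumerate(("left", "right")):
        asym = 1.03 if side == "right" else 1.0
        tea[side] = (
            rng.normal(asym * p.tea_vol_mean, p.tea_vol_sd, size=n)
            + p.tea_latent_unit * p.latent_strength * factor * w[j]
        )
        tea[side] = np.maximum(tea[side], 50.0)

    school = {}
    for side in ("left", "right"):
        rel_gain = (
            p.amplitude * age_school / (age_school + p.t_half_months)
            + p.growth_noise_sd * rng.standard_normal(n)
        )
        school[side] = tea[side] * (1.0 + np.maximum(rel_gain, -0.5))

    u = np.asarray(p.behavior_salience, dtype=float)
    behavior = {}
    for k, col in enumerate(BEHAVIOR_RAW_COLUMNS):
        y = (
            BEHAVIOR_LOC[col]
            + BEHAVIOR_AGE_SLOPE[col] * (age_school - 124.0)
            + BEHAVIOR_SES_SLOPE[col] * (ses - 3.8)
            + BEHAVIOR_SIGMA[col]
            * (p.latent_strength * factor * u[k] + rng.standard_normal(n))
        )
        if col == "internalizing_raw":
            y = np.maximum(y, 0.0)
        behavior[col] = y

    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "sex": sex,
            "gestational_age_weeks": ga,
            "ses_largo": ses,
            "age_tea_months": age_tea,
            "age_school_months": age_school,
            "vol_tea_left": tea["left"],
            "vol_tea_right": tea["right"],
            "vol_school_left": school["left"],
            "vol_school_right": school["right"],
            **behavior,
        }
    )


def write_cohort(
    out_dir: str | Path,
    cohort: pd.DataFrame,
    volumes: pd.DataFrame,
    behavior_raw: pd.DataFrame,
    config: SimulationConfig,
) -> dict:
    """Write the three cohort tables plus a JSON config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "volumes": out / "volumes.csv",
        "behavior_raw": out / "behavior_raw.csv",
        "config": out / "simulation_config.json",
    }
    cohort.to_csv(paths["cohort"], index=False)
    volumes.to_csv(paths["volumes"], index=False)
    behavior_raw.to_csv(paths["behavior_raw"], index=False)
    paths["config"].write_text(
        json.dumps(config.to_jsonable(), indent=2, sort_keys=True) + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
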