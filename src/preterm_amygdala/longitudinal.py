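"""TEA -> school-age amygdala growth rates and trajectory scores.

Growth is summarized per subject as the relative growth rate
``[(vol_school - vol_tea) / (age_school - age_tea)] * 100 / vol_tea``
(%/month).  Developmental trajectory scores remove scan-timing effects:
the per-side volume change is regressed on the "inter age" (the product
of mean scan age and the between-scan interval) and the standardized
residuals are the trajectory scores fed into PLSC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SingularDesignError, ValidationError
from .scores import residualize

#: school-age bands in months: 6-9 years and 10-14 years
AGE_BANDS_MONTHS = {"6-9y": (72.0, 120.0), "10-14y": (120.0, 180.0)}


def median_of_tracings(tracings, expected_count: int = 5,
                       strict: bool = True) -> float:
    """Median volume over repeated manual tracings of one structure."""
    x = np.asarray(tracings, dtype=float)
    if x.ndim != 1 or (strict and len(x) != expected_count):
        raise ValidationError(
            f"expected {expected_count} tracings, got {x.shape}"
        )
    if (x <= 0).any():
        raise ValidationError("tracing volumes must be positive")
    return float(np.median(x))


def relative_growth_rate(vol_tea, vol_school, age_tea, age_school):
    """Relative growth rate in %/month (vectorized).

    ``((vol_school - vol_tea) / (age_school - age_tea)) * 100 / vol_tea``
    """
    vol_tea = np.asarray(vol_tea, dtype=float)
    vol_school = np.asarray(vol_school, dtype=float)
    age_tea = np.asarray(age_tea, dtype=float)
    age_school = np.asarray(age_school, dtype=float)
    if np.any(vol_tea <= 0):
        raise ValidationError("TEA volume must be positive")
    if np.any(age_school <= age_tea):
        raise ValidationError("school-age scan must postdate the TEA scan")
    rate = (vol_school - vol_tea) / (age_school - age_tea) * 100.0 / vol_tea
    return rate if rate.ndim else float(rate)


def derive_fields(records: pd.DataFrame) -> pd.DataFrame:
    """Add totals, deltas, timing variables and growth rates."""
    df = records.copy()
    df["vol_tea_total"] = df["vol_tea_left"] + df["vol_tea_right"]
    df["vol_school_total"] = df["vol_school_left"] + df["vol_school_right"]
    for side in ("left", "right", "total"):
        df[f"delta_volume_{side}"] = (
            df[f"vol_school_{side}"] - df[f"vol_tea_{side}"]
        )
    df["delta_age"] = df["age_school_months"] - df["age_tea_months"]
    df["mean_age"] = (df["age_school_months"] + df["age_tea_months"]) / 2.0
    df["inter_age"] = df["mean_age"] * df["delta_age"]
    for side in ("left", "right", "total"):
        df[f"growth_rate_{side}"] = relative_growth_rate(
            df[f"vol_tea_{side}"],
            df[f"vol_school_{side}"],
            df["age_tea_months"],
            df["age_school_months"],
        )
    return df


def trajectory_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Per-side standardized-residual trajectory scores.

    For each hemisphere, the volume change (delta volume) is regressed
    on {intercept, inter_age}; the standardized residuals are the
    age-adjusted trajectory scores.
    """
    df = records
    if not {"delta_volume_left", "inter_age"} <= set(df.columns):
        df = derive_fields(df)
    if len(df) < 4:
        raise ValidationError("trajectory scores need >= 4 records")
    inter_age = df["inter_age"].to_numpy(dtype=float)
    if np.ptp(inter_age) == 0.0:
        raise SingularDesignError("inter_age is constant across records")
    X = np.column_stack([np.ones(len(df)), inter_age])
    out = {"subject_id": df["subject_id"].to_numpy()}
    for side in ("left", "right"):
        out[f"trajectory_{side}"] = residualize(
            df[f"delta_volume_{side}"].to_numpy(dtype=float), X
        )
    return pd.DataFrame(out)


def growth_summary(records: pd.DataFrame):
    """Per-subject growth table, age-band contrast, and line-plot data.

    Returns ``(growth_table, band_contrast, plot_data)`` where
    ``band_contrast`` holds the mean total relative growth rate for
    subjects scanned at 6-9 y vs 10-14 y (missing bands reported as
    NaN), and ``plot_data`` has two (age, volume) points per subject
    for spaghetti plots of total amygdala growth.
    """
    df = records if "growth_rate_total" in records.columns else (
        derive_fields(records)
    )
    if len(df) < 2:
        raise ValidationError("growth summary needs >= 2 records")
    growth_table = df[
        [
            "subject_id",
            "age_tea_months",
            "age_school_months",
            "vol_tea_total",
            "vol_school_total",
            "growth_rate_left",
            "growth_rate_right",
            "growth_rate_total",
        ]
    ].copy()

    band_contrast = {}
    for band, (lo, hi) in AGE_BANDS_MONTHS.items():
        sel = (df["age_school_months"] >= lo) & (df["age_school_months"] < hi)
        band_contrast[band] = {
            "n": int(sel.sum()),
            "mean_growth_rate_total": (
                float(df.loc[sel, "growth_rate_total"].mean())
                if sel.any()
                else float("nan")
            ),
        }

    plot_rows = []
    for _, row in df.iterrows():
        for age, vol in (
            (row["age_tea_months"], row["vol_tea_total"]),
            (row["age_school_months"], row["vol_school_total"]),
        ):
            plot_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "age_months": age,
                    "vol_total_mm3": vol,
                    "growth_rate_total": row["growth_rate_total"],
                }
            )
    return growth_table, band_contrast, pd.DataFrame(plot_rows)
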