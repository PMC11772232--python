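"""Univariate group comparisons: t-tests, effect sizes, chi-square,
per-measure ANCOVA with a group x age interaction, BH-FDR correction,
and the 5-SD volumetric outlier filter.

Demographic comparisons use the pooled two-sample t (integer df);
socio-emotional comparisons use Welch's t (Satterthwaite df).  The
ANCOVA stage fits one linear model per volumetric measure,
``volume ~ group + age + group:age + ICV + sex + SES``, with Type III
partial F-tests (sum-to-zero contrasts) and partial eta-squared effect
sizes; the FDR family is the 20 p-values of a given term across models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateStatisticError,
    ValidationError,
    SingularDesignError,
)
from .measures import MEASURES

log = logging.getLogger(__name__)


@dataclass
class TwoSampleSummary:
    """Per-group mean/SD/n summary of one variable."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def validate(self) -> "TwoSampleSummary":
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValidationError("SDs must be nonnegative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError("each group needs n >= 2")
        return self


def pooled_t_test(s: TwoSampleSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with ``t = (mean2 - mean1) / (sp * sqrt(1/n1
    + 1/n2))`` and integer ``df = n1 + n2 - 2``.
    """
    s.validate()
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    if sp2 == 0.0:
        if s.mean1 == s.mean2:
            return 0.0, df, 1.0
        raise DegenerateStatisticError(
            "zero pooled variance with unequal means"
        )
    t, p = stats.ttest_ind_from_stats(
        s.mean2, s.sd2, s.n2, s.mean1, s.sd1, s.n1, equal_var=True
    )
    return float(t), df, float(p)


def welch_t_test(x1, x2) -> tuple[float, float, float]:
    """Welch's t-test on raw samples; returns ``(t, fractional df, p)``.

    Sign convention follows mean(x1) - mean(x2).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValidationError("each sample needs n >= 2")
    if x1.var(ddof=1) == 0.0 and x2.var(ddof=1) == 0.0:
        if x1.mean() == x2.mean():
            return 0.0, float(len(x1) + len(x2) - 2), 1.0
        raise DegenerateStatisticError("zero variance with unequal means")
    res = stats.ttest_ind(x1, x2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d_pooled(s: TwoSampleSummary) -> float:
    """Cohen's d with the pooled SD denominator, reported as a magnitude."""
    s.validate()
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    if sp2 == 0.0:
        if s.mean1 == s.mean2:
            return 0.0
        raise DegenerateStatisticError("zero pooled SD")
    return abs(s.mean1 - s.mean2) / np.sqrt(sp2)


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("counts must be a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("degenerate table: a marginal total is zero")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def outlier_filter_5sd(
    volumes: pd.DataFrame, n_sd: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask per-measure values further than ``n_sd`` SDs from the mean.

    Mean and SD are computed once on the full sample (no iteration).
    Returns the filtered table (flagged entries set to NaN) and an
    exclusion log with one row per flagged entry.
    """
    numeric = [c for c in volumes.columns if c != "subject_id"]
    if len(volumes) < 3:
        raise ValidationError("need at least 3 subjects to filter outliers")
    out = volumes.copy()
    records = []
    for col in numeric:
        x = volumes[col].to_numpy(dtype=float)
        mean, sd = np.nanmean(x), np.nanstd(x, ddof=1)
        flag = np.abs(x - mean) > n_sd * sd
        flag &= ~np.isnan(x)
        for i in np.flatnonzero(flag):
            records.append(
                {
                    "subject_id": volumes["subject_id"].iloc[i],
                    "measure": col,
                    "value": x[i],
                    "sample_mean": mean,
                    "sample_sd": sd,
                }
            )
        out.loc[flag, col] = np.nan
    exclusions = pd.DataFrame(
        records,
        columns=["subject_id", "measure", "value", "sample_mean",
                 "sample_sd"],
    )
    if len(exclusions):
        log.info("outlier_filter_5sd: flagged %d entries", len(exclusions))
    return out, exclusions


ANCOVA_TERMS = {
    'C(group, Sum, levels=["VPT", "FT"])': "group",
    "age": "age",
    'C(group, Sum, levels=["VPT", "FT"]):age': "group_x_age",
    "icv": "icv",
    "C(sex, Sum)": "sex",
    "ses": "ses",
}


def ancova_volumes(
    volumes: pd.DataFrame,
    cohort: pd.DataFrame,
    center_age: bool = False,
) -> pd.DataFrame:
    """One ANCOVA per amygdala measure with group x age interaction.

    Fits ``volume ~ group * age + ICV + sex + SES`` per measure on
    complete cases, with sum-to-zero contrasts so Type III partial
    F-tests are well defined alongside the interaction.  Returns a tidy
    table (one row per measure x term) with coefficient, F, p, partial
    eta-squared, and BH-FDR q-values computed across the 20 models
    separately for the ``group`` and ``group_x_age`` terms.
    """
    measure_cols = [c for c in volumes.columns if c in MEASURES]
    data = volumes.merge(cohort, on="subject_id", validate="1:1")
    data = data.rename(
        columns={"age_school_months": "age", "icv_mm3": "icv",
                 "ses_largo": "ses"}
    )
    covars = ["group", "age", "icv", "sex", "ses"]
    data = data.dropna(subset=covars)
    if center_age:
        data["age"] = data["age"] - data["age"].mean()

    formula_rhs = (
        'C(group, Sum, levels=["VPT", "FT"]) * age + icv + C(sex, Sum) + ses'
    )
    rows = []
    for m in measure_cols:
        sub = data.dropna(subset=[m])
        n_terms = 7  # intercept + 6 model terms
        if len(sub) < n_terms + 10:
            raise ValidationError(
                f"measure {m}: need >= {n_terms + 10} complete cases, "
                f"got {len(sub)}"
            )
        model = smf.ols(f"{m} ~ {formula_rhs}", data=sub)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            raise SingularDesignError(
                f"collinear design for measure {m}: columns "
                f"{list(model.exog_names)}"
            )
        fit = model.fit()
        table = anova_lm(fit, typ=3)
        ss_resid = table.loc["Residual", "sum_sq"]
        for patsy_name, term in ANCOVA_TERMS.items():
            ss = table.loc[patsy_name, "sum_sq"]
            coef = np.nan
            for pname, value in fit.params.items():
                if term in ("age", "icv", "ses"):
                    match = pname == patsy_name
                elif term == "group_x_age":
                    match = pname.startswith("C(group, Sum") and ":age" in pname
                elif term == "group":
                    match = pname.startswith("C(group, Sum") and ":age" not in pname
                else:  # sex
                    match = pname.startswith("C(sex, Sum)")
                if match:
                    coef = value
                    break
            rows.append(
                {
                    "measure": m,
                    "term": term,
                    "coef": coef,
                    "F": table.loc[patsy_name, "F"],
                    "p_value": table.loc[patsy_name, "PR(>F)"],
                    "df_num": table.loc[patsy_name, "df"],
                    "df_den": table.loc["Residual", "df"],
                    "partial_eta_sq": ss / (ss + ss_resid),
                    "n": len(sub),
                }
            )
    result = pd.DataFrame(rows)
    result["q_value"] = np.nan
    for term in ("group", "group_x_age"):
        mask = result["term"] == term
        result.loc[mask, "q_value"] = fdr_bh(
            result.loc[mask, "p_value"].to_numpy()
        )
    return result
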