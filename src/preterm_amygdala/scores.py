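"""Standardized-residual socio-emotional scores.

Each instrument's raw score is regressed on its instrument-specific
covariates (age at testing and SES for the NEPSY-II subtests and the
SDQ internalizing sum; SES only for the BRIEF emotional-control T
score; optionally gestational age for all four) and the OLS residuals,
divided by their sample SD, are the scores used everywhere downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, SampleSizeError, SingularDesignError
from .measures import BEHAVIOR_SCORE_COLUMNS

log = logging.getLogger(__name__)

#: raw column -> (score column, covariate columns before the GA flag)
INSTRUMENT_COVARIATES = {
    "theory_of_mind_raw": (
        "theory_of_mind",
        ("age_school_months", "ses_largo"),
    ),
    "affect_recognition_raw": (
        "affect_recognition",
        ("age_school_months", "ses_largo"),
    ),
    "internalizing_raw": (
        "internalizing_problems",
        ("age_school_months", "ses_largo"),
    ),
    "emotional_control_T": ("emotional_control", ("ses_largo",)),
}


def residualize(values, covariates) -> np.ndarray:
    """Standardized OLS residuals of ``values`` on ``covariates``.

    ``covariates`` must already include the intercept column.  The
    result has mean ~0 and sample SD 1 (denominator n-1), and is
    orthogonal to every covariate column.

    Raises
    ------
    SingularDesignError
        if the covariate matrix is rank deficient.
    SampleSizeError
        if there are fewer than (columns + 2) rows.
    DegenerateFitError
        if the residual SD is zero (perfect fit).
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise SampleSizeError("values and covariates must be row-aligned")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise SingularDesignError("non-finite entries in values/covariates")
    n, k = X.shape
    if n < k + 2:
        raise SampleSizeError(
            f"need at least {k + 2} rows for {k} covariate columns, got {n}"
        )
    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=1)
    scale = max(1.0, float(np.abs(y).max()))
    if sd <= 1e-12 * scale:
        raise DegenerateFitError(
            "zero residual SD: values are an exact function of covariates"
        )
    return resid / sd


def _design(df: pd.DataFrame, covariate_cols: tuple[str, ...]) -> np.ndarray:
    """Intercept + covariates, dropping zero-variance covariate columns."""
    cols = [np.ones(len(df))]
    for c in covariate_cols:
        x = df[c].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            log.debug("covariate %s constant; dropped from design", c)
            continue
        cols.append(x)
    return np.column_stack(cols)


def prepare_behavior_scores(
    raw: pd.DataFrame,
    cohort: pd.DataFrame,
    adjust_ga: bool = False,
    per_group: bool = False,
) -> pd.DataFrame:
    """Instrument-wise standardized-residual scores for a cohort.

    Parameters
    ----------
    raw
        Table with ``subject_id`` and the four raw instrument columns.
    cohort
        Table with ``subject_id`` and the covariates (age at testing,
        SES, and gestational age when ``adjust_ga``); a ``group``
        column is required only for ``per_group``.
    adjust_ga
        Additionally regress every score on gestational age.
    per_group
        Fit the residualizing regressions within each group separately
        instead of pooling VPT and FT (default pooled).
    """
    merged = raw.merge(cohort, on="subject_id", how="inner", validate="1:1")
    needed = list(INSTRUMENT_COVARIATES) + ["age_school_months", "ses_largo"]
    if adjust_ga:
        needed.append("gestational_age_weeks")
    complete = merged.dropna(subset=[c for c in needed if c in merged])
    dropped = len(merged) - len(complete)
    if dropped:
        log.info("prepare_behavior_scores: dropped %d incomplete rows",
                 dropped)

    def _scores_for(block: pd.DataFrame) -> pd.DataFrame:
        out = {"subject_id": block["subject_id"].to_numpy()}
        for raw_col, (score_col, covs) in INSTRUMENT_COVARIATES.items():
            covariates = covs + (
                ("gestational_age_weeks",) if adjust_ga else ()
            )
            X = _design(block, covariates)
            out[score_col] = residualize(
                block[raw_col].to_numpy(dtype=float), X
            )
        return pd.DataFrame(out)

    if per_group:
        parts = [
            _scores_for(g)
            for _, g in complete.groupby("group", sort=False)
        ]
        scores = pd.concat(parts, ignore_index=True)
        scores = (
            scores.set_index("subject_id")
            .loc[complete["subject_id"]]
            .reset_index()
        )
    else:
        scores = _scores_for(complete)
    if "group" in complete.columns:
        scores.insert(1, "group", complete["group"].to_numpy())
    return scores[
        ["subject_id"]
        + (["group"] if "group" in scores.columns else [])
        + list(BEHAVIOR_SCORE_COLUMNS)
    ]
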