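"""Univariate group statistics against textbook-formula oracles and the
published summary values they must reproduce."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import preterm_amygdala as pa
from preterm_amygdala.errors import (
    DegenerateStatisticError,
    ValidationError,
    SingularDesignError,
)
from preterm_amygdala.group_stats import TwoSampleSummary


# ----------------------------------------------------------------- oracles

def pooled_t_oracle(x1, x2):
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (
        n1 + n2 - 2
    )
    t = (np.mean(x2) - np.mean(x1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, df, 2 * stats.t.sf(abs(t), df)


def welch_oracle(x1, x2):
    n1, n2 = len(x1), len(x2)
    v1, v2 = np.var(x1, ddof=1) / n1, np.var(x2, ddof=1) / n2
    t = (np.mean(x1) - np.mean(x2)) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    return chi2, stats.chi2.sf(chi2, 1)


def bh_oracle(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ------------------------------------------------------- published values

class TestPublishedSummaryStatistics:
    """Statistics recomputable from the published group summaries."""

    def test_gestational_age_pooled_t(self):
        t, df, p = pa.pooled_t_test(
            TwoSampleSummary(29.42, 1.84, 75, 39.9, 1.34, 41)
        )
        assert df == 114
        assert abs(t) == pytest.approx(32.077, abs=0.05)
        assert p < 0.001

    def test_birth_weight_pooled_t(self):
        t, df, p = pa.pooled_t_test(
            TwoSampleSummary(1260.93, 368.21, 75, 3460.98, 413.8, 41)
        )
        assert df == 114
        assert abs(t) == pytest.approx(29.435, abs=0.05)

    def test_sex_chi_square(self):
        chi2, df, p = pa.chi_square_2x2([[39, 36], [17, 24]])
        assert df == 1
        assert chi2 == pytest.approx(1.179, abs=0.005)
        assert p == pytest.approx(0.278, abs=0.005)

    def test_internalizing_cohens_d(self):
        d = pa.cohens_d_pooled(
            TwoSampleSummary(0.19, 1.04, 75, -0.37, 0.83, 41)
        )
        assert d == pytest.approx(0.576, abs=0.005)


# ------------------------------------------------------------- unit tests

class TestPooledT:
    def test_identical_summaries_give_zero(self):
        t, df, p = pa.pooled_t_test(TwoSampleSummary(5, 2, 10, 5, 2, 12))
        assert t == 0.0 and p == 1.0 and df == 20

    def test_zero_variance_equal_means(self):
        t, df, p = pa.pooled_t_test(TwoSampleSummary(3, 0, 5, 3, 0, 5))
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_is_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            pa.pooled_t_test(TwoSampleSummary(3, 0, 5, 4, 0, 5))

    def test_raw_and_summary_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x1 = rng.normal(size=15)
            x2 = rng.normal(0.3, 1.2, size=12)
            s = TwoSampleSummary(
                x1.mean(), x1.std(ddof=1), 15,
                x2.mean(), x2.std(ddof=1), 12,
            )
            t, df, p = pa.pooled_t_test(s)
            t_o, df_o, p_o = pooled_t_oracle(x1, x2)
            assert t == pytest.approx(t_o, abs=1e-10)
            assert df == df_o
            assert p == pytest.approx(p_o, abs=1e-10)


class TestWelchT:
    def test_equal_variance_equal_n_reduces_to_pooled(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=20)
        x2 = x1[::-1] + 0.5  # same variance, equal n
        t, df, p = pa.welch_t_test(x1, x2)
        assert df == pytest.approx(2 * 20 - 2)
        t_p, _, _ = pooled_t_oracle(x2, x1)  # pooled sign: mean2-mean1
        assert t == pytest.approx(t_p, abs=1e-10)

    def test_identical_samples_give_zero(self):
        x = np.random.default_rng(2).normal(size=10)
        t, _, p = pa.welch_t_test(x, x)
        assert t == 0.0

    def test_matches_satterthwaite_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x1 = rng.normal(size=rng.integers(5, 30))
            x2 = rng.normal(0.2, 2.0, size=rng.integers(5, 30))
            t, df, p = pa.welch_t_test(x1, x2)
            t_o, df_o, p_o = welch_oracle(x1, x2)
            assert t == pytest.approx(t_o, abs=1e-10)
            assert df == pytest.approx(df_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)


class TestCohensD:
    def test_equal_means_zero(self):
        assert pa.cohens_d_pooled(TwoSampleSummary(1, 2, 10, 1, 3, 10)) == 0

    def test_zero_pooled_sd_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            pa.cohens_d_pooled(TwoSampleSummary(1, 0, 10, 2, 0, 10))

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            m1, s1, m2, s2 = rng.normal(size=4) + [0, 2, 1, 2]
            n1, n2 = rng.integers(3, 40, size=2)
            s1, s2 = abs(s1) + 0.1, abs(s2) + 0.1
            sp = np.sqrt(
                ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
            )
            d = pa.cohens_d_pooled(
                TwoSampleSummary(m1, s1, int(n1), m2, s2, int(n2))
            )
            assert d == pytest.approx(abs(m1 - m2) / sp, abs=1e-12)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        chi2, _, p = pa.chi_square_2x2([[20, 20], [10, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            pa.chi_square_2x2([[0, 0], [5, 7]])

    def test_matches_hand_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            table = rng.integers(1, 50, size=(2, 2))
            chi2, _, p = pa.chi_square_2x2(table)
            chi2_o, p_o = chi2_oracle(table)
            assert chi2 == pytest.approx(chi2_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    @given(st.lists(st.integers(1, 100), min_size=4, max_size=4))
    def test_symmetric_under_transposition(self, cells):
        table = np.array(cells).reshape(2, 2)
        assert pa.chi_square_2x2(table)[0] == pytest.approx(
            pa.chi_square_2x2(table.T)[0], abs=1e-12
        )


class TestFdrBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(pa.fdr_bh([0.03]), [0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(pa.fdr_bh([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pa.fdr_bh([0.5, 1.2])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_brute_force_oracle(self, ps):
        np.testing.assert_allclose(pa.fdr_bh(ps), bh_oracle(ps), atol=1e-12)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30)
    )
    def test_monotone_and_dominating(self, ps):
        p = np.asarray(ps)
        q = pa.fdr_bh(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestOutlierFilter:
    def test_single_extreme_value_flagged(self):
        rng = np.random.default_rng(6)
        x = rng.normal(100, 5, size=100)
        x[17] = x.mean() + 8 * x.std(ddof=1)
        df = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(100)], "left_basal": x}
        )
        filtered, log = pa.outlier_filter_5sd(df)
        assert len(log) == 1
        assert log.iloc[0]["subject_id"] == "S17"
        assert np.isnan(filtered.loc[17, "left_basal"])

    def test_identical_values_not_flagged(self):
        df = pd.DataFrame(
            {"subject_id": list("abc"), "left_basal": [5.0, 5.0, 5.0]}
        )
        filtered, log = pa.outlier_filter_5sd(df)
        assert log.empty
        pd.testing.assert_frame_equal(filtered, df)

    def test_mild_deviation_untouched(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1) * 3  # max deviation 3 SD
        df = pd.DataFrame(
            {"subject_id": [str(i) for i in range(50)], "m": x}
        )
        filtered, log = pa.outlier_filter_5sd(df)
        assert log.empty


class TestAncova:
    def test_icv_proportional_volumes_absorbed(self, null_cohort):
        """Volumes that are exactly proportional to ICV (plus tiny
        noise) leave nothing for the group term even when ICV differs
        by group."""
        _, cohort, _, _ = null_cohort
        cohort = cohort.copy()
        cohort["icv_mm3"] = np.where(
            cohort["group"] == "VPT",
            cohort["icv_mm3"] - 1e5,
            cohort["icv_mm3"] + 1e5,
        )
        rng = np.random.default_rng(8)
        vol = 1e-3 * cohort["icv_mm3"] + rng.normal(0, 0.5, len(cohort))
        volumes = pd.DataFrame(
            {"subject_id": cohort["subject_id"], "left_basal": vol}
        )
        res = pa.ancova_volumes(volumes, cohort)
        row = res[(res["term"] == "group")].iloc[0]
        unadjusted_diff = (
            vol[cohort["group"] == "FT"].mean()
            - vol[cohort["group"] == "VPT"].mean()
        )
        assert abs(row["coef"]) < 0.05 * abs(unadjusted_diff)
        assert row["partial_eta_sq"] < 0.05

    def test_planted_sex_effect_detected(self, null_cohort):
        _, cohort, volumes, _ = null_cohort
        volumes = volumes.copy()
        male = (cohort["sex"] == "M").to_numpy()
        volumes["left_basal"] = volumes["left_basal"] + 200.0 * male
        res = pa.ancova_volumes(
            volumes[["subject_id", "left_basal", "right_lateral"]], cohort
        )
        sex = res[res["term"] == "sex"].set_index("measure")
        assert sex.loc["left_basal", "p_value"] < 1e-6
        assert sex.loc["right_lateral", "p_value"] > 0.01

    def test_invariant_to_row_and_column_order(self, null_cohort):
        _, cohort, volumes, _ = null_cohort
        sub = volumes[["subject_id", "left_basal", "right_lateral"]]
        res1 = pa.ancova_volumes(sub, cohort)
        shuffled = sub.sample(frac=1, random_state=0)
        reordered = shuffled[["subject_id", "right_lateral", "left_basal"]]
        res2 = pa.ancova_volumes(reordered, cohort)
        key = ["measure", "term"]
        merged = res1.merge(res2, on=key, suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["coef_a"], merged["coef_b"], rtol=1e-8
        )
        np.testing.assert_allclose(
            merged["p_value_a"], merged["p_value_b"], rtol=1e-6, atol=1e-12
        )

    def test_collinear_design_rejected(self, null_cohort):
        _, cohort, volumes, _ = null_cohort
        cohort = cohort.copy()
        cohort["ses_largo"] = cohort["age_school_months"]  # collinear? no
        cohort["ses_largo"] = 2.0 * cohort["icv_mm3"]
        with pytest.raises(SingularDesignError):
            pa.ancova_volumes(
                volumes[["subject_id", "left_basal"]], cohort
            )

    def test_group_type_i_error_calibrated(self):
        """Null cohorts: the raw group-term p rejects at the nominal
        5% rate across replicate fits."""
        hits = total = 0
        for rep in range(30):
            cfg = pa.SimulationConfig(
                n_vpt=60, n_ft=60, seed=500 + rep, latent_strength=0.0
            )
            cohort, volumes, _ = pa.generate_cohort(cfg)
            res = pa.ancova_volumes(volumes, cohort)
            p = res.loc[res["term"] == "group", "p_value"]
            hits += (p < 0.05).sum()
            total += len(p)
        rate = hits / total
        assert 0.02 <= rate <= 0.09
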