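import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ssmnet import (CovariateTable, benjamini_hochberg, blockwise_regression,
                    univariate_tract_regressions)
from ssmnet.posthoc import DEFAULT_BLOCKS


def _bh_step_up(p):
    """Independent oracle: adjusted p_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        raw = np.array([0.001, 0.01, 0.02, 0.04, 0.2])
        expected = np.array([0.005, 0.025, 1 / 30, 0.05, 0.2])
        np.testing.assert_allclose(benjamini_hochberg(raw), expected, atol=1e-12)

    def test_all_ones_fixed_point(self):
        np.testing.assert_array_equal(benjamini_hochberg(np.ones(7)), np.ones(7))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 50), st.integers(0, 10_000))
    def test_matches_explicit_step_up_construction(self, m, seed):
        p = np.random.default_rng(seed).uniform(0, 1, m)
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, _bh_step_up(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestUnivariate:
    def test_matches_statsmodels_per_tract(self, small_cohort):
        m = small_cohort.metric_matrix
        y = small_cohort.covariates.vo2max
        res = univariate_tract_regressions(m, y)
        for tract in m.tract_labels[:4]:
            j = m.tract_labels.index(tract)
            fit = sm.OLS(np.log(m.values[:, j]), sm.add_constant(y)).fit()
            row = res.table.loc[tract]
            assert row["slope"] == pytest.approx(fit.params[1], rel=1e-10)
            assert row["slope_se"] == pytest.approx(fit.bse[1], rel=1e-10)
            assert row["p_raw"] == pytest.approx(fit.pvalues[1], rel=1e-8)
            lo, hi = fit.conf_int()[1]
            assert row["ci_lower"] == pytest.approx(lo, rel=1e-8)
            assert row["ci_upper"] == pytest.approx(hi, rel=1e-8)

    def test_standardized_beta_is_correlation(self, small_cohort):
        m = small_cohort.metric_matrix
        y = small_cohort.covariates.vo2max
        res = univariate_tract_regressions(m, y)
        j = 0
        r = np.corrcoef(np.log(m.values[:, j]), y)[0, 1]
        assert res.table["beta_std"].iloc[j] == pytest.approx(r, abs=1e-12)

    def test_family_is_the_requested_subset(self, small_cohort):
        m = small_cohort.metric_matrix
        y = small_cohort.covariates.vo2max
        sub = m.tract_labels[:3]
        res = univariate_tract_regressions(m, y, tracts=sub)
        assert list(res.table.index) == sub
        full = univariate_tract_regressions(m, y)
        np.testing.assert_allclose(
            res.table["p_fdr"], _bh_step_up(full.table["p_raw"].iloc[:3]),
            atol=1e-12)

    def test_rejects_empty_or_unknown_subset(self, small_cohort):
        m = small_cohort.metric_matrix
        y = small_cohort.covariates.vo2max
        with pytest.raises(ValueError, match="empty"):
            univariate_tract_regressions(m, y, tracts=[])
        with pytest.raises(ValueError, match="unknown"):
            univariate_tract_regressions(m, y, tracts=["no-such-tract"])


class TestBlockwise:
    def test_blocks_accumulate_and_r2_monotone(self, small_cohort):
        res = blockwise_regression(small_cohort.expressions[:, 0],
                                   small_cohort.covariates)
        preds = [b.predictors for b in res.blocks]
        assert preds[0] == ("tiv",)
        for a, b in zip(preds, preds[1:]):
            assert b[: len(a)] == a
        r2 = [b.r2 for b in res.blocks]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_standardized_unstandardized_consistency(self, small_cohort):
        """beta = B * SD(x) / SD(y) for every predictor in every block."""
        e = small_cohort.expressions[:, 0]
        res = blockwise_regression(e, small_cohort.covariates)
        sdy = e.std(ddof=1)
        tab = small_cohort.covariates.table
        for block in res.blocks:
            for name, row in block.coef_table.iterrows():
                sdx = tab[name].std(ddof=1)
                assert row["beta_std"] == pytest.approx(
                    row["B"] * sdx / sdy, abs=1e-10)

    def test_recovers_generated_effects_at_large_n(self):
        """Age/WMH/vascular-risk effects planted in the expression come back
        as the corresponding standardized betas."""
        from ssmnet import GroundTruth, generate_cohort
        truth = GroundTruth.default(n_tracts=8, seed=11)
        cohort = generate_cohort(2000, 8, truth)
        res = blockwise_regression(cohort.expressions[:, 0], cohort.covariates)
        final = res.blocks[-1].coef_table["beta_std"]
        assert final["age"] == pytest.approx(-0.5, abs=0.05)
        assert final["wmh_log"] == pytest.approx(-0.25, abs=0.05)
        assert final["vascular_risk_level"] == pytest.approx(-0.15, abs=0.05)
        for null_pred in ("tiv", "sex", "apoe_e4"):
            assert abs(final[null_pred]) < 0.05

    def test_pure_noise_predictor_leaves_adjusted_r2_flat(self, small_cohort):
        """Mean adjusted-R^2 change from adding an independent noise column is
        slightly negative, never systematically positive."""
        cov_df = small_cohort.covariates.table
        n = 167
        changes = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1, n)
            x1 = rng.normal(0, 1, n)
            noise = rng.normal(0, 1, n)
            f1 = sm.OLS(y, sm.add_constant(x1)).fit()
            f2 = sm.OLS(y, sm.add_constant(np.column_stack([x1, noise]))).fit()
            changes.append(f2.rsquared_adj - f1.rsquared_adj)
        assert -0.02 < np.mean(changes) < 0.01

    def test_perfect_fit_flagged(self, small_cohort):
        cov = small_cohort.covariates
        res = blockwise_regression(cov["tiv"], cov, blocks=(("tiv",),))
        assert res.blocks[0].perfect_fit
        assert res.blocks[0].f_value == np.inf

    def test_rank_deficient_design_names_column(self, small_cohort):
        tab = small_cohort.covariates.table.copy()
        tab["tiv_copy"] = tab["tiv"] * 2.0
        cov = CovariateTable(tab)
        with pytest.raises(ValueError, match="tiv_copy|tiv"):
            blockwise_regression(small_cohort.expressions[:, 0], cov,
                                 blocks=(("tiv", "tiv_copy"),))

    def test_default_blocks_match_hierarchy(self):
        assert DEFAULT_BLOCKS == (("tiv",), ("age", "sex"),
                                  ("vascular_risk_level", "apoe_e4"),
                                  ("wmh_log",))
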