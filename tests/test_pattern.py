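import numpy as np
import pytest
import statsmodels.api as sm

from ssmnet import (GroundTruth, bic_select, combine_pattern, decompose_metric,
                    generate_cohort, tiv_adjusted_fit)


@pytest.fixture(scope="module")
def decomposition(small_cohort):
    return decompose_metric(small_cohort.metric_matrix)


class TestBicSelect:
    def test_matches_hand_computed_bic_on_small_fixture(self, rng):
        """BIC(k) = n ln(RSS/n) + (k+1) ln(n), RSS from an independently
        fitted statsmodels OLS."""
        n, n_comp = 12, 3
        scores = rng.normal(0, 1, (n, n_comp))
        y = 2.0 + 1.5 * scores[:, 0] - 0.5 * scores[:, 1] + rng.normal(0, 0.3, n)
        k_star, trace = bic_select(scores, y, k_max=3)
        for k in range(1, 4):
            fit = sm.OLS(y, sm.add_constant(scores[:, :k])).fit()
            rss = float(fit.resid @ fit.resid)
            expected = n * np.log(rss / n) + (k + 1) * np.log(n)
            assert trace[k - 1] == pytest.approx(expected, abs=1e-8)
        assert k_star == int(np.argmin(trace)) + 1

    def test_selects_one_component_when_signal_is_first_column(self, rng):
        n = 50
        scores = rng.normal(0, 1, (n, 5))
        y = 3.0 + 2.0 * scores[:, 0]
        k_star, _ = bic_select(scores, y, k_max=5)
        assert k_star == 1

    def test_rss_sequence_monotone_in_k(self, decomposition, small_cohort):
        """In-sample fit never worsens as components accumulate."""
        y = small_cohort.covariates.vo2max
        n = len(y)
        rss = []
        for k in range(1, 6):
            X = sm.add_constant(decomposition.scores[:, :k])
            rss.append(float(sm.OLS(y, X).fit().ssr))
        assert np.all(np.diff(rss) <= 1e-9)
        _, trace = bic_select(decomposition.scores, y, k_max=5)
        implied_rss = n * np.exp((trace - (np.arange(1, 6) + 1) * np.log(n)) / n)
        np.testing.assert_allclose(implied_rss, rss, rtol=1e-8)

    def test_rejects_constant_outcome_and_bad_kmax(self, decomposition):
        n = decomposition.scores.shape[0]
        with pytest.raises(ValueError, match="constant"):
            bic_select(decomposition.scores, np.ones(n), k_max=3)
        with pytest.raises(ValueError, match="k_max"):
            bic_select(decomposition.scores, np.arange(n, dtype=float),
                       k_max=decomposition.n_components + 1)


class TestCombinePattern:
    def test_single_component_identities(self, decomposition, small_cohort):
        """k=1: loadings proportional to v1, expression = +/- z(score 1), and
        |standardized beta| equals |corr(score 1, VO2max)|."""
        y = small_cohort.covariates.vo2max
        pat = combine_pattern(decomposition, 1, y)
        v1 = decomposition.loadings[:, 0]
        assert abs(abs(pat.combined_loadings_unit @ v1) - 1) < 1e-10
        s1 = decomposition.scores[:, 0]
        z1 = (s1 - s1.mean()) / s1.std(ddof=1)
        assert (np.allclose(pat.expression_scores, z1, atol=1e-10)
                or np.allclose(pat.expression_scores, -z1, atol=1e-10))
        r = np.corrcoef(s1, y)[0, 1]
        assert pat.fit.standardized_beta == pytest.approx(abs(r), abs=1e-12)

    def test_expression_z_scored_and_oriented(self, decomposition, small_cohort):
        y = small_cohort.covariates.vo2max
        for k in (1, 2, 4):
            pat = combine_pattern(decomposition, k, y)
            assert pat.expression_scores.mean() == pytest.approx(0.0, abs=1e-10)
            assert pat.expression_scores.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
            assert np.corrcoef(pat.expression_scores, y)[0, 1] >= 0

    def test_adjusted_r2_closed_form(self, decomposition, small_cohort):
        y = small_cohort.covariates.vo2max
        pat = combine_pattern(decomposition, 3, y)
        f = pat.fit
        n = f.n
        expected = 1 - (1 - f.standardized_beta ** 2) * (n - 1) / (n - 2)
        assert f.adjusted_r2 == pytest.approx(expected, abs=1e-10)

    def test_perfect_fit_limit(self):
        """Noiseless rank-1 cohort with VO2max affine in the expression:
        beta = 1 and adjusted R^2 = 1."""
        truth = GroundTruth.default(n_tracts=10, seed=6, noise_sd=1e-13,
                                    subject_scale_sd=0.0, true_k=1,
                                    signal_strength=1.0,
                                    covariate_effects={})
        cohort = generate_cohort(25, 10, truth)
        dec = decompose_metric(cohort.metric_matrix)
        pat = combine_pattern(dec, 1, cohort.covariates.vo2max)
        assert pat.fit.standardized_beta == pytest.approx(1.0, abs=1e-8)
        assert pat.fit.adjusted_r2 == pytest.approx(1.0, abs=1e-8)

    def test_k_out_of_range_rejected(self, decomposition, small_cohort):
        with pytest.raises(ValueError, match="k="):
            combine_pattern(decomposition, decomposition.n_components + 1,
                            small_cohort.covariates.vo2max)


class TestTivAdjustedFit:
    def test_tiv_equal_to_outcome_fully_explains_it(self, rng):
        """VO2max = TIV exactly: block 1 already has R^2=1, expression adds
        nothing and the adjusted-R^2 change is 0."""
        n = 40
        e = rng.normal(0, 1, n)
        tiv = rng.normal(1.4e6, 1e5, n)
        res = tiv_adjusted_fit(e, tiv.copy(), tiv)
        assert res.adjusted_r2_change == pytest.approx(0.0, abs=1e-9)
        assert abs(res.standardized_beta) < 1e-6

    def test_null_expression_contributes_nothing(self, rng):
        n = 500
        y = rng.normal(25, 5, n)
        e = rng.normal(0, 1, n)       # independent of y
        tiv = rng.normal(1.4e6, 1e5, n)
        res = tiv_adjusted_fit(e, y, tiv)
        assert abs(res.standardized_beta) < 0.15
        assert res.adjusted_r2_change <= 0.02

    def test_independent_tiv_leaves_change_near_marginal_r2(self, rng):
        """When TIV is independent of both variables, the adjusted-R^2 change
        equals the unadjusted adjusted-R^2 up to Monte-Carlo error."""
        n = 2000
        e = rng.normal(0, 1, n)
        y = 0.5 * e + rng.normal(0, np.sqrt(1 - 0.25), n)
        tiv = rng.normal(0, 1, n)
        res = tiv_adjusted_fit(e, y, tiv)
        marginal = 1 - (1 - np.corrcoef(e, y)[0, 1] ** 2) * (n - 1) / (n - 2)
        assert res.adjusted_r2_change == pytest.approx(marginal, abs=0.01)

    def test_collinear_tiv_warns(self, rng):
        n = 30
        e = rng.normal(0, 1, n)
        y = rng.normal(25, 5, n)
        with pytest.warns(UserWarning, match="collinear"):
            res = tiv_adjusted_fit(e, y, 2.0 * e)
        assert res.degenerate
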