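import numpy as np
import pytest
from dataclasses import replace

from ssmnet import GroundTruth, generate_cohort, generate_study, inject_outliers
from ssmnet.cohort import DEFAULT_COVARIATE_MODEL, random_planted_loadings
from ssmnet.ssm import log_double_center


class TestGroundTruth:
    def test_default_planted_loadings_unit_norm_and_zero_sum(self):
        t = GroundTruth.default(n_tracts=42, seed=5)
        assert abs(np.linalg.norm(t.planted_loadings) - 1.0) < 1e-12
        assert abs(t.planted_loadings.sum()) < 1e-10

    def test_validation_rejects_bad_parameters(self):
        t = GroundTruth.default(n_tracts=10, seed=0)
        with pytest.raises(ValueError, match="unit norm"):
            replace(t, planted_loadings=t.planted_loadings * 2)
        with pytest.raises(ValueError, match="noise_sd"):
            replace(t, noise_sd=0.0)
        with pytest.raises(ValueError, match="positive"):
            replace(t, baseline_profile=t.baseline_profile * -1)
        with pytest.raises(ValueError, match="signal_strength"):
            replace(t, signal_strength=1.5)
        with pytest.raises(ValueError, match="prevalence"):
            bad = dict(DEFAULT_COVARIATE_MODEL, p_apoe_e4=1.2)
            replace(t, covariate_model=bad)
        with pytest.raises(ValueError, match="squared covariate effects"):
            replace(t, covariate_effects={"age": -0.9, "wmh_log": -0.9})

    def test_yaml_round_trip(self, small_truth, tmp_path):
        path = tmp_path / "truth.yaml"
        small_truth.write_yaml(path)
        back = GroundTruth.from_yaml(path)
        np.testing.assert_allclose(back.planted_loadings,
                                   small_truth.planted_loadings, rtol=1e-15)
        assert back.covariate_effects == small_truth.covariate_effects
        assert back.component_sd_decay == small_truth.component_sd_decay


class TestGenerateCohort:
    def test_seed_determinism_byte_for_byte(self, small_truth):
        a = generate_cohort(40, 12, small_truth)
        b = generate_cohort(40, 12, small_truth)
        assert (a.metric_matrix.to_dataframe().to_csv()
                == b.metric_matrix.to_dataframe().to_csv())
        assert a.covariates.table.to_csv() == b.covariates.table.to_csv()

    def test_noiseless_rank_one_structure(self):
        """Without noise or subject scaling the centered log matrix is rank 1."""
        truth = GroundTruth.default(n_tracts=12, seed=2, noise_sd=1e-14,
                                    subject_scale_sd=0.0, true_k=1)
        cohort = generate_cohort(30, 12, truth)
        C, _ = log_double_center(cohort.metric_matrix)
        s = np.linalg.svd(C, compute_uv=False)
        assert s[0] > 1e-3
        assert s[1] < 1e-8 * s[0]

    def test_vo2max_moments_match_cohort_targets(self):
        """Sample VO2max mean/SD stay near the configured 24.43 (5.40)."""
        for seed in (0, 1, 2):
            truth = GroundTruth.default(n_tracts=42, seed=seed)
            c = generate_cohort(167, 42, truth)
            v = c.covariates.vo2max
            assert abs(v.mean() - 24.43) < 1.3
            assert abs(v.std(ddof=1) - 5.40) < 1.0

    def test_covariate_moment_recovery_large_n(self):
        """Sample moments within 3 SE of configured targets (three pooled
        n=1000 cohorts so a single unlucky draw cannot dominate)."""
        import pandas as pd
        truth = GroundTruth.default(n_tracts=12, seed=9)
        tabs = [generate_cohort(1000, 12, replace(truth, seed=s)).covariates.table
                for s in (9, 10, 11)]
        tab = pd.concat(tabs)
        n = 3000
        cm = truth.covariate_model
        checks = [
            (tab["vo2max"].mean(), cm["vo2max_mean"], cm["vo2max_sd"] / np.sqrt(n)),
            (tab["age"].mean(), 69.0, (38 / np.sqrt(12)) / np.sqrt(n)),
            (tab["sex"].mean(), cm["p_male"],
             np.sqrt(cm["p_male"] * (1 - cm["p_male"]) / n)),
            (tab["apoe_e4"].mean(), cm["p_apoe_e4"],
             np.sqrt(cm["p_apoe_e4"] * (1 - cm["p_apoe_e4"]) / n)),
            (tab["wmh_log"].mean(), cm["wmh_log_mean"], cm["wmh_log_sd"] / np.sqrt(n)),
        ]
        for value, target, se in checks:
            assert abs(value - target) < 3 * se

    def test_null_signal_gives_null_correlation(self):
        """signal_strength=0: |corr(expression, VO2max)| < 0.2 at n=500 in
        >=95% of 200 seeds."""
        ok = 0
        for seed in range(200):
            truth = GroundTruth.default(n_tracts=8, seed=seed, signal_strength=0.0)
            c = generate_cohort(500, 8, truth)
            r = np.corrcoef(c.expressions[:, 0], c.covariates.vo2max)[0, 1]
            ok += (abs(r) < 0.2)
        assert ok >= 190

    def test_signal_strength_sets_expected_correlation(self):
        truth = GroundTruth.default(n_tracts=12, seed=4, signal_strength=0.7)
        c = generate_cohort(5000, 12, truth)
        r = np.corrcoef(c.expressions[:, 0], c.covariates.vo2max)[0, 1]
        assert abs(r - 0.7) < 0.05

    def test_rejects_small_cohorts(self, small_truth):
        with pytest.raises(ValueError, match="n_participants"):
            generate_cohort(5, 12, small_truth)

    def test_study_metrics_share_participants_and_covariates(self, four_metric_study):
        ids = four_metric_study.covariates.participant_ids
        for m in four_metric_study.metric_matrices.values():
            assert m.participant_ids == ids


class TestInjectOutliers:
    def test_empty_spec_is_identity(self, four_metric_study):
        out = inject_outliers(four_metric_study, [])
        for name, m in four_metric_study.metric_matrices.items():
            assert np.array_equal(out.metric_matrices[name].values, m.values)

    def test_offsets_displace_only_named_cells(self, four_metric_study):
        out = inject_outliers(four_metric_study, [(0, 1, "AD", 0.5)])
        diff = out.metric_matrices["AD"].values - four_metric_study.metric_matrices["AD"].values
        assert diff[0, 1] == pytest.approx(0.5)
        assert np.count_nonzero(diff) == 1
        assert np.array_equal(out.metric_matrices["RD"].values,
                              four_metric_study.metric_matrices["RD"].values)

    def test_out_of_range_rejected(self, four_metric_study):
        with pytest.raises(IndexError):
            inject_outliers(four_metric_study, [(999, 0, "AD", 1.0)])
        with pytest.raises(ValueError, match="metric"):
            inject_outliers(four_metric_study, [(0, 0, "XX", 1.0)])


def test_random_planted_loadings_properties(rng):
    v = random_planted_loadings(20, rng)
    assert abs(np.linalg.norm(v) - 1) < 1e-12
    assert abs(v.sum()) < 1e-10
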