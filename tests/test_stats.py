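"""Group comparisons, correlation, ROC/Youden, and replication simulation."""

import numpy as np
import pytest

from aafai import (
    CohortSpec,
    GroupSpec,
    STUDY_COHORT,
    pearson_r,
    reproduce_study_roc,
    roc_analysis,
    sens_spec_at_threshold,
    welch_t,
    welch_t_from_summary,
)
from aafai.stats import anova_tukey, chi2_test, kruskal_dunn


class TestWelch:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(g, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_p_vanishes(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-6, 50)
        b = 1 + rng.normal(0, 1e-6, 50)
        assert welch_t(a, b).p_value < 1e-10

    def test_summary_variant_hand_formula(self):
        """Welch statistic from published summaries matches the hand-evaluated
        formula: (Δm)/√(s₁²/n₁+s₂²/n₂) ≈ 2.39 for (−60.46, 8.76, 52) vs
        (−65.37, 6.84, 17)."""
        res = welch_t_from_summary(-60.46, 8.76, 52, -65.37, 6.84, 17)
        se = np.sqrt(8.76**2 / 52 + 6.84**2 / 17)
        assert res.statistic == pytest.approx((-60.46 + 65.37) / se)
        assert res.statistic == pytest.approx(2.39, abs=0.01)

    def test_summary_variant_agrees_with_scipy_on_raw_data(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 20)
        raw = welch_t(a, b)
        summ = welch_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert summ.statistic == pytest.approx(raw.statistic)
        assert summ.df == pytest.approx(raw.df)
        assert summ.p_value == pytest.approx(raw.p_value)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_null_large_sample(self):
        rng = np.random.default_rng(1)
        assert abs(pearson_r(rng.normal(size=10_000), rng.normal(size=10_000)).statistic) < 0.05

    def test_small_worked_set_matches_covariance_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r = pearson_r(x, y).statistic
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1], ci=False)
        assert res.auc == 1.0
        assert res.cutoff == 2.5
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_analysis(scores, labels, ci=False).auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_pair_count_oracle(self):
        """Trapezoidal AUC equals the exhaustive (pos, neg) pair count
        (+½ per tie) on random instances with ties, and matches sklearn."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(30):
            n = rng.integers(6, 50)
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = roc_analysis(scores, labels, ci=False)
            pos, neg = scores[labels], scores[~labels]
            pairs = (
                np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :])
            ) / (len(pos) * len(neg))
            assert res.auc == pytest.approx(pairs, abs=1e-12)
            assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200).astype(bool)
        a = roc_analysis(scores, labels, ci=False)
        b = roc_analysis(np.exp(scores), labels, ci=False)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.sensitivity == pytest.approx(b.sensitivity)
        assert a.specificity == pytest.approx(b.specificity)

    def test_youden_cutoff_between_point_masses(self):
        res = roc_analysis([0.0] * 20 + [10.0] * 20, [0] * 20 + [1] * 20, ci=False)
        assert 0.0 < res.cutoff < 10.0

    def test_tie_break_toward_smallest_cutoff(self):
        """Two cutoffs attain maximal J; the smaller is reported."""
        # scores: neg {1, 2}, pos {3, 4}: J = 1 only at 2.5; rig a tie instead
        res = roc_analysis([1, 3, 2, 4], [0, 0, 1, 1], ci=False)
        # J at 1.5: sens 1, spec 0.5 → 0.5; at 2.5: sens 0.5, spec 0.5 → 0;
        # at 3.5: sens 0.5, spec 1 → 0.5 — tie between 1.5 and 3.5
        assert res.cutoff == 1.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2], [1, 1], ci=False)

    def test_sens_spec_at_threshold(self):
        sens, spec = sens_spec_at_threshold([-60, -50, -58, -40], [0, 1, 0, 1], -55.3)
        assert sens == 1.0  # both positives ≥ −55.3
        assert spec == 1.0  # both negatives < −55.3

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 60)])
        labels = np.array([0] * 60 + [1] * 60)
        a = roc_analysis(scores, labels, seed=9, n_boot=500)
        b = roc_analysis(scores, labels, seed=9, n_boot=500)
        assert a.auc_ci == b.auc_ci
        lo, hi = a.auc_ci
        assert lo < a.auc < hi

    def test_bootstrap_ci_coverage_of_binormal_auc(self):
        """~95% of bootstrap CIs cover the true binormal AUC Φ(Δ/√(σ₁²+σ₂²))
        over 500 simulation replicates (±3 percentage points)."""
        from scipy.stats import norm

        true_auc = norm.cdf(1.0 / np.sqrt(2.0))
        rng = np.random.default_rng(12)
        covered = 0
        reps = 500
        for _ in range(reps):
            neg = rng.normal(0, 1, 80)
            pos = rng.normal(1, 1, 80)
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * 80 + [1] * 80)
            res = roc_analysis(
                scores, labels, seed=int(rng.integers(2**31)), n_boot=500
            )
            lo, hi = res.auc_ci
            covered += lo <= true_auc <= hi
        assert 0.92 <= covered / reps <= 0.98


class TestStudyReplication:
    def test_degenerate_identical_groups_auc_half(self):
        spec = CohortSpec(
            groups=(GroupSpec("non_HCTD", -60, 8, 80), GroupSpec("MFS", -60, 8, 80))
        )
        summ = reproduce_study_roc(spec, "MFS_vs_non", replicates=100, seed=3)
        assert summ.mean_auc == pytest.approx(0.5, abs=0.02)

    def test_replicate_spread_shrinks_with_sample_size(self):
        """Doubling every group size reduces the replicate SD of the AUC by
        roughly √2."""
        base = CohortSpec(
            groups=(GroupSpec("non_HCTD", -62.02, 8.54, 159), GroupSpec("MFS", -52.9, 12.69, 36))
        )
        double = CohortSpec(
            groups=(GroupSpec("non_HCTD", -62.02, 8.54, 318), GroupSpec("MFS", -52.9, 12.69, 72))
        )
        s1 = reproduce_study_roc(base, "MFS_vs_non", replicates=400, seed=4)
        s2 = reproduce_study_roc(double, "MFS_vs_non", replicates=400, seed=5)
        ratio = s1.auc.std() / s2.auc.std()
        assert ratio == pytest.approx(np.sqrt(2), rel=0.25)

    def test_reproducible_under_seed(self):
        a = reproduce_study_roc(STUDY_COHORT, "HCTD_vs_non", replicates=20, seed=7)
        b = reproduce_study_roc(STUDY_COHORT, "HCTD_vs_non", replicates=20, seed=7)
        assert np.array_equal(a.auc, b.auc)

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            reproduce_study_roc(STUDY_COHORT, "nope", replicates=2, seed=0)


class TestOtherComparisons:
    def test_anova_tukey_three_groups(self):
        rng = np.random.default_rng(8)
        res = anova_tukey(rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(3, 1, 30))
        assert res.p_value < 1e-6
        assert res.extra["tukey_pvalues"][(0, 1)] > 0.05
        assert res.extra["tukey_pvalues"][(0, 2)] < 1e-4

    def test_kruskal_dunn_matches_kruskal_and_flags_shifted_group(self):
        rng = np.random.default_rng(9)
        res = kruskal_dunn(rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(2, 1, 40))
        assert res.p_value < 1e-6
        assert res.extra["dunn"][(0, 2)]["p_adj"] < 0.01
        assert res.extra["dunn"][(0, 1)]["p_adj"] > 0.05

    def test_chi2(self):
        res = chi2_test([[30, 10], [10, 30]])
        assert res.p_value < 0.001
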