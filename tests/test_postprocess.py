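import numpy as np
import pytest

from profilereg.postprocess import (best_partition, build_similarity,
                                    coclustering_counts, exceedance_probs,
                                    fit_residual_score, group_risk_posterior,
                                    partition_score, posterior_or,
                                    profile_deviation_intervals,
                                    summarize_groups)
from profilereg.data import CovariateSpec, ProfileDataset
from profilereg.sampler import McmcConfig, PosteriorTrace


def _toy_trace(risks, z_draws=None, X_imp=None):
    risks = np.asarray(risks, dtype=float)
    T, n = risks.shape
    counts = (coclustering_counts(z_draws) if z_draws is not None
              else np.full((n, n), float(T)))
    cfg = McmcConfig(n_iter=T + 1, burn_in=1, thin=1, truncation=2)
    return PosteriorTrace(risks=risks, coclust=counts, n_retained=T,
                          K_occupied=np.ones(T, int), alpha=np.ones(T),
                          loglik=np.zeros(T), beta=np.zeros((T, 0)),
                          X_imp_draws=X_imp, acceptance={}, config=cfg)


class TestSimilarity:
    def test_single_cluster_every_iteration_gives_all_ones(self):
        z = np.zeros((5, 4), dtype=int)
        S = build_similarity((coclustering_counts(z), 5))
        np.testing.assert_array_equal(S, np.ones((4, 4)))

    def test_never_coclustered_pair_is_zero(self):
        z = np.array([[0, 1], [0, 1], [1, 0]])
        S = build_similarity((coclustering_counts(z), 3))
        assert S[0, 1] == 0.0

    def test_two_iteration_hand_example(self):
        # iterations {12|34} and {13|24} over four subjects
        z = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        S = build_similarity((coclustering_counts(z), 2))
        expected = np.array([[1.0, 0.5, 0.5, 0.0],
                             [0.5, 1.0, 0.0, 0.5],
                             [0.5, 0.0, 1.0, 0.5],
                             [0.0, 0.5, 0.5, 1.0]])
        np.testing.assert_array_equal(S, expected)

    def test_invariant_under_cluster_relabelling(self, rng):
        z = rng.integers(0, 4, size=(50, 12))
        perm = np.array([2, 0, 3, 1])
        S1 = build_similarity((coclustering_counts(z), 50))
        S2 = build_similarity((coclustering_counts(perm[z]), 50))
        np.testing.assert_array_equal(S1, S2)

    def test_zero_retained_iterations_rejected(self):
        with pytest.raises(ValueError, match="zero retained"):
            build_similarity((np.zeros((3, 3)), 0))


class TestBestPartition:
    def test_perfect_two_block_matrix_recovered_exactly(self):
        S = np.zeros((7, 7))
        S[:4, :4] = 1.0
        S[4:, 4:] = 1.0
        part = best_partition(S, range(1, 5))
        assert part.score == 0.0
        assert part.n_groups == 2
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1

    def test_all_ones_selects_single_group(self):
        part = best_partition(np.ones((6, 6)), range(1, 4))
        assert part.n_groups == 1

    def test_heuristic_matches_enumeration_on_noisy_blocks(self, rng):
        S = np.zeros((6, 6))
        S[:3, :3] = 0.9
        S[3:, 3:] = 0.85
        S += rng.uniform(-0.1, 0.15, (6, 6))
        S = np.clip((S + S.T) / 2, 0, 1)
        np.fill_diagonal(S, 1.0)
        ex = best_partition(S, range(1, 4), method="exact")
        pm = best_partition(S, range(1, 4), method="pam")
        assert pm.score == pytest.approx(ex.score)
        np.testing.assert_array_equal(pm.labels, ex.labels)

    def test_heuristic_matches_enumeration_on_random_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            A = rng.random((n, n))
            S = (A + A.T) / 2
            np.fill_diagonal(S, 1.0)
            ex = best_partition(S, range(1, n + 1), method="exact")
            pm = best_partition(S, range(1, n + 1), method="pam")
            assert pm.score == pytest.approx(ex.score, abs=1e-9)

    def test_group_sizes_sum_to_n_and_ordered(self, rng):
        A = rng.random((9, 9))
        S = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(S, 1.0)
        part = best_partition(S, range(1, 5), method="pam")
        assert part.group_sizes.sum() == 9
        assert np.all(np.diff(part.group_sizes) <= 0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            best_partition(np.ones((4, 4)), [])


class TestGroupRisk:
    def test_single_group_equals_overall_average(self):
        tr = _toy_trace([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
        gd, ov = group_risk_posterior(tr, np.zeros(3, int))
        np.testing.assert_allclose(gd[:, 0], ov)

    def test_constant_risks_give_degenerate_posterior(self):
        tr = _toy_trace(np.full((5, 4), 0.2))
        gd, ov = group_risk_posterior(tr, np.array([0, 0, 1, 1]))
        assert np.all(gd == 0.2) and np.all(ov == 0.2)

    def test_hand_computed_group_means(self):
        tr = _toy_trace([[0.1, 0.3, 0.5], [0.2, 0.4, 0.6]])
        gd, ov = group_risk_posterior(tr, np.array([0, 0, 1]))
        np.testing.assert_allclose(gd[:, 0], [0.2, 0.3])
        np.testing.assert_allclose(gd[:, 1], [0.5, 0.6])
        np.testing.assert_allclose(ov, [0.3, 0.4])

    def test_empty_group_rejected(self):
        tr = _toy_trace(np.full((2, 3), 0.2))
        with pytest.raises(ValueError, match="empty group"):
            group_risk_posterior(tr, np.array([0, 0, 2]))


class TestExceedance:
    def test_whole_sample_group_is_all_ties(self):
        gd = np.full((10, 1), 0.3)
        ov = np.full(10, 0.3)
        p_gt, p_lt = exceedance_probs(gd, ov)
        assert p_gt[0] == 0.0 and p_lt[0] == 0.0

    def test_always_above_gives_probability_one(self):
        gd = np.array([[0.4], [0.5], [0.6]])
        ov = np.array([0.1, 0.2, 0.3])
        p_gt, p_lt = exceedance_probs(gd, ov)
        assert p_gt[0] == 1.0 and p_lt[0] == 0.0


class TestPosteriorOr:
    def test_reference_against_itself_is_exactly_one(self):
        d = np.array([0.1, 0.2, 0.3])
        o = posterior_or(d, d)
        assert o["mean"] == 1.0 and o["ci"] == (1.0, 1.0)

    def test_formula_arithmetic(self):
        o = posterior_or(np.full(4, 0.15), np.full(4, 0.09))
        assert o["mean"] == pytest.approx((0.15 * 0.91) / (0.09 * 0.85))
        assert o["mean"] == pytest.approx(1.7843, abs=1e-4)

    def test_equal_risks_give_unit_or(self):
        o = posterior_or(np.full(3, 0.5), np.full(3, 0.5))
        assert o["mean"] == 1.0

    def test_degenerate_draws_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            posterior_or(np.array([0.0, 0.5]), np.array([0.5, 0.5]))

    def test_monotone_in_group_risk(self, rng):
        ref = rng.uniform(0.05, 0.2, 100)
        g1 = rng.uniform(0.2, 0.4, 100)
        g2 = g1 + 0.1
        assert posterior_or(g2, ref)["mean"] > posterior_or(g1, ref)["mean"]


class TestProfileDeviations:
    @staticmethod
    def _trace_with_draws():
        X_imp = np.array([  # 2 iterations, 4 subjects, 1 binary covariate
            [[0], [0], [1], [1]],
            [[0], [1], [1], [1]],
        ], dtype=np.int8)
        return _toy_trace(np.full((2, 4), 0.2), X_imp=X_imp)

    def test_whole_sample_group_has_zero_deviation(self):
        tr = self._trace_with_draws()
        specs = [CovariateSpec("a", "nominal", 2)]
        data = ProfileDataset(np.array([[0], [0], [1], [1]]),
                              np.array([1, 0, 0, 0]), None, specs)
        dev = profile_deviation_intervals(tr, np.zeros(4, int), data)
        assert np.allclose(dev["mean"], 0.0)
        assert (dev["class"] == "null").all()

    def test_hand_computed_intervals(self):
        tr = self._trace_with_draws()
        specs = [CovariateSpec("a", "nominal", 2)]
        data = ProfileDataset(np.array([[0], [0], [1], [1]]),
                              np.array([1, 0, 0, 0]), None, specs)
        dev = profile_deviation_intervals(tr, np.array([0, 0, 1, 1]), data)
        # group 0, category 0: diffs are 1-0.5=0.5 and 0.5-0.25=0.25, so the
        # equal-tailed interval interpolates the two order statistics
        row = dev[(dev.group == 0) & (dev.category == 0)].iloc[0]
        assert row["mean"] == pytest.approx(0.375)
        assert row["lo"] == pytest.approx(0.25 + 0.025 * 0.25)
        assert row["hi"] == pytest.approx(0.25 + 0.975 * 0.25)
        assert row["class"] == "positive"

    def test_trace_without_draws_rejected(self):
        tr = _toy_trace(np.full((2, 3), 0.2))
        specs = [CovariateSpec("a", "nominal", 2)]
        data = ProfileDataset(np.zeros((3, 1), int), np.array([1, 0, 0]),
                              None, specs)
        with pytest.raises(ValueError, match="store_imputed"):
            profile_deviation_intervals(tr, np.zeros(3, int), data)


class TestFitScore:
    def test_perfect_probabilities_score_zero(self):
        y = np.array([1, 0, 1, 0])
        assert fit_residual_score(y.astype(float), y) == 0.0

    def test_uninformative_half_scores_quarter_n(self):
        y = np.array([1, 0, 1, 0])
        assert fit_residual_score(np.full(4, 0.5), y) == 1.0

    def test_prevalence_baseline_matches_binomial_variance(self):
        y = np.r_[np.ones(63), np.zeros(482)]
        p = 63 / 545
        score = fit_residual_score(np.full(545, p), y)
        assert score == pytest.approx(545 * p * (1 - p))
        assert score == pytest.approx(55.7, abs=0.1)


class TestSummarizeGroups:
    def test_reference_group_has_unit_or_and_sizes(self):
        risks = np.column_stack([np.full(50, 0.3), np.full(50, 0.3),
                                 np.linspace(0.05, 0.15, 50)])
        tr = _toy_trace(risks)
        out = summarize_groups(tr, np.array([0, 0, 1]))
        ref = out["reference"].iloc[0]
        assert ref == 1
        row = out[out.group == ref].iloc[0]
        assert row["or_vs_ref"] == 1.0 and row["or_lo"] == 1.0
        assert out["size"].sum() == 3
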