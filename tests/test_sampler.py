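import numpy as np
import pytest
from scipy import stats

from profilereg.data import CovariateSpec, ProfileDataset
from profilereg.sampler import (ClusterState, McmcConfig, PosteriorTrace,
                                allocation_logits, impute_missing, init_state,
                                run_mcmc, update_allocations,
                                update_weights_alpha, _stick_weights)
from profilereg.synthetic import generate_preset

from conftest import two_cluster_dataset


def _manual_state(data, config, z, probs, theta, weights=None):
    K = config.truncation
    weights = np.full(K, 1.0 / K) if weights is None else np.asarray(weights)
    V = np.ones(K)
    return ClusterState(z=np.asarray(z), V=V, weights=weights, alpha=1.0,
                        probs=probs, thresholds=[None] * data.n_covariates,
                        theta=np.asarray(theta, float), beta=np.zeros(0),
                        X_imp=data.X.copy())


class TestAllocations:
    def test_identical_clusters_allocate_by_weights_alone(self,
                                                          binary_pair_dataset):
        data = binary_pair_dataset
        cfg = McmcConfig(n_iter=10, burn_in=1, thin=1, truncation=2)
        phi = np.array([[0.7, 0.3], [0.7, 0.3]])
        st = _manual_state(data, cfg, np.zeros(data.n, int),
                           [phi.copy(), phi.copy()], [0.2, 0.2],
                           weights=[0.25, 0.75])
        logits = allocation_logits(st, data, cfg)
        diff = logits[:, 1] - logits[:, 0]
        np.testing.assert_allclose(diff, np.log(3.0), atol=1e-12)

    def test_zero_probability_category_excludes_cluster(self,
                                                        binary_pair_dataset,
                                                        rng):
        data = binary_pair_dataset
        cfg = McmcConfig(n_iter=10, burn_in=1, thin=1, truncation=2)
        # cluster 0 assigns probability 0 to category seen in subject 0
        x0 = data.X[0, 0]
        phi0 = np.array([[1.0, 0.0], [0.5, 0.5]]) if x0 == 1 else \
            np.array([[0.0, 1.0], [0.5, 0.5]])
        st = _manual_state(data, cfg, np.zeros(data.n, int),
                           [phi0, np.array([[0.5, 0.5], [0.5, 0.5]])],
                           [0.2, 0.2], weights=[0.5, 0.5])
        for _ in range(100):
            update_allocations(st, data, cfg, rng)
            assert st.z[0] == 1


class TestWeightsAlpha:
    def test_single_occupied_cluster_takes_almost_all_mass(self, rng):
        cfg = McmcConfig(n_iter=10, burn_in=1, thin=1, truncation=3)
        n = 500
        data = two_cluster_dataset(n=20)[0]
        st = init_state(data, cfg, rng)
        st.z = np.zeros(20, int)
        st.alpha = 1e-6  # alpha -> 0 limit: stick puts all mass on cluster 1
        w = []
        for _ in range(200):
            update_weights_alpha(st, cfg, rng)
            st.alpha = 1e-6
            w.append(st.weights[0])
        assert np.mean(w) > 0.95

    def test_balanced_two_cluster_stick_means(self, rng):
        # V1 ~ Beta(1+n/2, alpha+n/2), V2 ~ Beta(1+n/2, alpha); alpha = 1
        cfg = McmcConfig(n_iter=10, burn_in=1, thin=1, truncation=3,
                         alpha_scale=0.0)
        data = two_cluster_dataset(n=100)[0]
        st = init_state(data, cfg, rng)
        n = 100
        st.z = np.r_[np.zeros(50, int), np.ones(50, int)]
        w = np.zeros(3)
        reps = 10_000
        for _ in range(reps):
            st.alpha = 1.0
            update_weights_alpha(st, cfg, rng)
            w += st.weights
        w /= reps
        e_v1 = 51 / (51 + 1 + 50)
        e_v2 = 51 / 52
        np.testing.assert_allclose(w[0], e_v1, atol=0.02)
        np.testing.assert_allclose(w[1], (1 - e_v1) * e_v2, atol=0.02)

    def test_weights_sum_to_one(self, rng):
        V = np.r_[rng.random(9), 1.0]
        assert _stick_weights(V).sum() == pytest.approx(1.0)


class TestImputation:
    @staticmethod
    def _missing_dataset():
        X = np.array([[0, 0], [1, -1], [0, 1], [1, 0]])
        y = np.array([1, 0, 0, 0])
        specs = [CovariateSpec("a", "nominal", 2),
                 CovariateSpec("b", "nominal", 2)]
        return ProfileDataset(X, y, None, specs)

    def test_degenerate_phi_imputes_deterministically(self, rng):
        data = self._missing_dataset()
        cfg = McmcConfig(n_iter=10, burn_in=1, thin=1, truncation=1)
        st = _manual_state(data, cfg, np.zeros(4, int),
                           [np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]])],
                           [0.2])
        for _ in range(50):
            impute_missing(st, data, rng)
            assert st.X_imp[1, 1] == 0
        # observed entries never touched
        assert np.array_equal(st.X_imp[~data.missing_mask],
                              data.X[~data.missing_mask])

    def test_even_phi_imputes_evenly(self, rng):
        data = self._missing_dataset()
        cfg = McmcConfig(n_iter=10, burn_in=1, thin=1, truncation=1)
        st = _manual_state(data, cfg, np.zeros(4, int),
                           [np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])],
                           [0.2])
        draws = []
        for _ in range(10_000):
            impute_missing(st, data, rng)
            draws.append(st.X_imp[1, 1])
        assert abs(np.mean(draws) - 0.5) < 0.02


class TestRunMcmc:
    def test_same_seed_bit_identical(self):
        data, _, _ = generate_preset("null", seed=1, n=80)
        cfg = McmcConfig(n_iter=300, burn_in=100, thin=2, truncation=5)
        t1 = run_mcmc(data, cfg, seed=9)
        t2 = run_mcmc(data, cfg, seed=9)
        np.testing.assert_array_equal(t1.risks, t2.risks)
        np.testing.assert_array_equal(t1.coclust, t2.coclust)
        np.testing.assert_array_equal(t1.K_occupied, t2.K_occupied)
        np.testing.assert_array_equal(t1.alpha, t2.alpha)

    def test_single_cluster_theta_matches_conjugate_posterior(self):
        data, _, _ = generate_preset("null", seed=3, n=150)
        cfg = McmcConfig(n_iter=6_000, burn_in=1_000, thin=1, truncation=1,
                         store_imputed=False)
        tr = run_mcmc(data, cfg, seed=4)
        D, _ = stats.kstest(tr.risks[:, 0],
                            stats.beta(1 + data.n_cases,
                                       1 + data.n_controls).cdf)
        assert D < 0.05

    def test_two_planted_clusters_recovered(self):
        data, labels, _ = two_cluster_dataset(n=300, sep=0.92, seed=7)
        cfg = McmcConfig(n_iter=1_500, burn_in=500, thin=2, truncation=10)
        tr = run_mcmc(data, cfg, seed=8)
        from profilereg.postprocess import best_partition, build_similarity
        part = best_partition(build_similarity(tr), range(1, 6))
        # map partition groups to planted labels by majority
        agree = 0
        for g in range(part.n_groups):
            members = labels[part.labels == g]
            agree += max((members == c).sum() for c in (0, 1))
        assert agree / data.n >= 0.95

    def test_coclustering_counts_symmetric_with_full_diagonal(self):
        data, _, _ = generate_preset("null", seed=2, n=60)
        cfg = McmcConfig(n_iter=200, burn_in=100, thin=2, truncation=5)
        tr = run_mcmc(data, cfg, seed=1)
        np.testing.assert_array_equal(tr.coclust, tr.coclust.T)
        np.testing.assert_array_equal(np.diag(tr.coclust),
                                      np.full(data.n, tr.n_retained))

    def test_retained_count_and_risk_range(self):
        data, _, _ = generate_preset("null", seed=2, n=60)
        cfg = McmcConfig(n_iter=500, burn_in=200, thin=3, truncation=5)
        tr = run_mcmc(data, cfg, seed=1)
        assert tr.n_retained == (500 - 200) // 3 == tr.risks.shape[0]
        assert np.all((tr.risks > 0) & (tr.risks < 1))

    def test_plain_mode_rejects_confounders(self):
        data, _, _ = generate_preset("null", seed=2, n=60)
        data.W = np.ones((60, 1))
        cfg = McmcConfig(n_iter=100, burn_in=10, thin=1, truncation=3)
        with pytest.raises(ValueError, match="logistic"):
            run_mcmc(data, cfg, seed=0)

    def test_trace_save_load_roundtrip(self, tmp_path):
        data, _, _ = generate_preset("null", seed=2, n=40)
        cfg = McmcConfig(n_iter=120, burn_in=40, thin=2, truncation=4)
        tr = run_mcmc(data, cfg, seed=5)
        tr.save(tmp_path / "trace")
        tr2 = PosteriorTrace.load(tmp_path / "trace")
        np.testing.assert_array_equal(tr.risks, tr2.risks)
        np.testing.assert_array_equal(tr.coclust, tr2.coclust)
        np.testing.assert_array_equal(tr.X_imp_draws, tr2.X_imp_draws)
        assert tr2.config == tr.config
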