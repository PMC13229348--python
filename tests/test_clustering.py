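"""Clustering: merge criterion, update equations, diagnostics, validity."""

import numpy as np
import pytest

from spinemorph.clustering import (
    FCMConfig,
    GMMConfig,
    chull_elbow,
    fcm_cluster,
    fcm_memberships,
    first_silhouette_peak,
    gmm_cluster,
    hard_validity,
    k_selection_diagnostics,
    soft_validity,
    ward_cluster,
    ward_merge_costs,
)
from spinemorph.datatypes import SoftPartition

from .conftest import blobs
from .oracles import (
    calinski_harabasz_oracle,
    davies_bouldin_oracle,
    silhouette_oracle,
    soft_metrics_oracle,
)


class TestWard:
    def test_singleton_merge_cost_is_half_squared_distance(self):
        delta = 3.7
        Z = np.array([[0.0, 0.0], [delta, 0.0]])
        costs = ward_merge_costs(Z)
        assert costs[0] == pytest.approx(delta**2 / 2, abs=1e-12)

    def test_two_blobs_recovered_exactly(self):
        Z, truth = blobs(10, [[0, 0], [20, 20]], sd=0.5, seed=1)
        part = ward_cluster(Z, K=2)
        hard = part.hard_labels
        # partition equality up to label swap
        agree = max(np.mean(hard == truth), np.mean(hard == 1 - truth))
        assert agree == 1.0
        assert np.array_equal(np.sort(np.unique(part.membership)), [0.0, 1.0])

    def test_all_singletons_breaks_downstream_validity(self):
        Z = np.random.default_rng(2).normal(size=(6, 2))
        part = ward_cluster(Z, K=6)
        with pytest.raises(ValueError, match="own cluster"):
            hard_validity(Z, part.hard_labels)

    def test_k_out_of_range_rejected(self):
        Z = np.zeros((4, 2))
        with pytest.raises(ValueError):
            ward_cluster(Z, K=5)


class TestFCM:
    def test_default_fuzzifier_is_two(self):
        assert FCMConfig().m == 2.0

    def test_equidistant_point_gets_even_membership(self):
        """Symmetric centroids: the midpoint's update is exactly (1/2, 1/2)."""
        C = np.array([[-2.0, 0.0], [2.0, 0.0]])
        Z = np.array([[0.0, 0.0]])
        U = fcm_memberships(Z, C, m=2.0)
        assert U[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert U[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_coincident_point_takes_full_membership(self):
        C = np.array([[-2.0, 0.0], [2.0, 0.0]])
        U = fcm_memberships(np.array([[2.0, 0.0]]), C, m=2.0)
        assert U[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_objective_descends_on_seeded_random_data(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Z = rng.normal(size=(60, 3))
            part = fcm_cluster(Z, K=3, cfg=FCMConfig(seed=seed))
            tr = part.objective_trace
            assert all(b <= a + 1e-8 for a, b in zip(tr, tr[1:])), seed

    def test_sharpness_approaches_one_as_m_tends_to_one(self):
        Z, _ = blobs(20, [[0, 0], [15, 15]], sd=0.5, seed=3)
        part = fcm_cluster(Z, K=2, cfg=FCMConfig(m=1.05, seed=0))
        _, sharp, _ = soft_validity(part)
        assert sharp > 0.95

    def test_entropy_grows_with_fuzzifier(self):
        Z, _ = blobs(25, [[0, 0], [4, 4]], sd=1.0, seed=4)
        ents = []
        for m in (1.5, 2.0, 3.0):
            part = fcm_cluster(Z, K=2, cfg=FCMConfig(m=m, seed=0))
            ents.append(soft_validity(part)[0])
        assert ents[0] < ents[1] < ents[2]

    def test_invalid_fuzzifier_rejected(self):
        with pytest.raises(ValueError, match="m must be > 1"):
            FCMConfig(m=1.0)


class TestGMM:
    def test_identical_components_give_even_responsibilities(self):
        """E-step with equal weights and identical components: γ = 1/2."""
        from scipy.special import logsumexp

        from spinemorph.clustering import _log_gaussian

        rng = np.random.default_rng(5)
        Z = rng.normal(size=(30, 2))
        mu, cov = Z.mean(axis=0), np.cov(Z.T)
        logp = np.stack(
            [np.log(0.5) + _log_gaussian(Z, mu, cov, False) for _ in range(2)], axis=1
        )
        gamma = np.exp(logp - logsumexp(logp, axis=1)[:, None])
        assert np.allclose(gamma, 0.5, atol=1e-12)

    def test_far_separated_components_assign_confidently(self):
        Z, _ = blobs(200, [[0, 0], [10, 0]], sd=1.0, seed=6)
        part = gmm_cluster(Z, GMMConfig(K=2, seed=0))
        _, _, avg_max = soft_validity(part)
        assert avg_max > 0.99

    def test_loglik_trace_non_decreasing_on_seeded_runs(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Z = rng.normal(size=(80, 2))
            part = gmm_cluster(Z, GMMConfig(K=3, seed=seed, n_init=1))
            tr = part.objective_trace
            assert all(b >= a - 1e-8 for a, b in zip(tr, tr[1:])), seed

    def test_agrees_with_reference_em_on_separated_blobs(self):
        """Cross-check against an independent mixture implementation."""
        from sklearn.metrics import adjusted_rand_score
        from sklearn.mixture import GaussianMixture

        Z, truth = blobs(80, [[0, 0], [8, 8], [0, 8]], sd=0.7, seed=7)
        ours = gmm_cluster(Z, GMMConfig(K=3, seed=0))
        ref = GaussianMixture(n_components=3, random_state=0).fit_predict(Z)
        assert adjusted_rand_score(ours.hard_labels, ref) > 0.99
        assert adjusted_rand_score(ours.hard_labels, truth) > 0.99

    def test_insufficient_samples_rejected(self):
        Z = np.zeros((8, 3))
        with pytest.raises(ValueError, match="N > K"):
            gmm_cluster(Z, GMMConfig(K=2))


class TestKSelection:
    def test_three_blobs_choose_three(self):
        Z, _ = blobs(30, [[0, 0], [12, 0], [6, 10]], sd=0.8, seed=8)
        diag = k_selection_diagnostics(Z, method="ward", K_grid=range(2, 8))
        assert diag.first_peak_K == 3
        assert diag.chosen_K == 3

    def test_equal_cluster_sizes_have_zero_std(self):
        Z, _ = blobs(20, [[0, 0], [50, 50]], sd=0.5, seed=9)
        diag = k_selection_diagnostics(Z, method="ward", K_grid=[2, 3])
        assert diag.size_std_by_K[2] == 0.0

    def test_piecewise_linear_curve_elbow_detected(self):
        K = list(range(2, 11))
        # sharp bend at K=5: steep improvement before, flat after
        distortion = [100 - 20 * min(k, 5) - 0.5 * max(0, k - 5) for k in K]
        assert chull_elbow(K, distortion) == 5

    def test_first_peak_one_sided_at_grid_ends(self):
        assert first_silhouette_peak([2, 3, 4], [0.9, 0.5, 0.4]) == 2
        assert first_silhouette_peak([2, 3, 4], [0.3, 0.5, 0.7]) == 4

    def test_empty_grid_rejected(self):
        Z = np.random.default_rng(10).normal(size=(20, 2))
        with pytest.raises(ValueError, match="empty K grid"):
            k_selection_diagnostics(Z, K_grid=[])


class TestHardValidity:
    def test_tight_far_blobs(self):
        Z, labels = blobs(15, [[0, 0], [30, 30]], sd=0.3, seed=11)
        sil, db, ch = hard_validity(Z, labels)
        assert sil > 0.9
        assert db < 0.2
        assert sil == pytest.approx(silhouette_oracle(Z, labels), abs=1e-9)
        assert db == pytest.approx(davies_bouldin_oracle(Z, labels), abs=1e-9)
        assert ch == pytest.approx(calinski_harabasz_oracle(Z, labels), rel=1e-9)

    def test_coincident_points_give_zero_ch(self):
        Z = np.zeros((10, 2))
        labels = [0] * 5 + [1] * 5
        _, _, ch = hard_validity(Z, labels)
        assert ch == 0.0

    def test_agrees_with_reference_library_implementations(self):
        from sklearn.metrics import (
            calinski_harabasz_score,
            davies_bouldin_score,
            silhouette_score,
        )

        rng = np.random.default_rng(13)
        Z = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        sil, db, ch = hard_validity(Z, labels)
        assert sil == pytest.approx(silhouette_score(Z, labels), abs=1e-6)
        assert db == pytest.approx(davies_bouldin_score(Z, labels), abs=1e-6)
        assert ch == pytest.approx(calinski_harabasz_score(Z, labels), rel=1e-6)

    def test_hand_instance_matches_all_three_oracles(self):
        rng = np.random.default_rng(12)
        Z = rng.normal(size=(10, 2))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        sil, db, ch = hard_validity(Z, labels)
        assert sil == pytest.approx(silhouette_oracle(Z, labels), abs=1e-9)
        assert db == pytest.approx(davies_bouldin_oracle(Z, labels), abs=1e-9)
        assert ch == pytest.approx(calinski_harabasz_oracle(Z, labels), rel=1e-9)


class TestSoftValidity:
    def test_one_hot_extremes(self):
        part = SoftPartition.from_hard_labels([0, 1, 2, 0], method="ward")
        ent, sharp, mx = soft_validity(part)
        assert (ent, sharp, mx) == (0.0, 1.0, 1.0)

    def test_uniform_maximum_entropy(self):
        P = np.full((4, 5), 0.2)
        part = SoftPartition(membership=P, K=5, method="fcm")
        ent, sharp, mx = soft_validity(part)
        assert ent == pytest.approx(np.log(5), abs=1e-12)
        assert sharp == pytest.approx(0.0, abs=1e-12)
        assert mx == pytest.approx(0.2, abs=1e-12)

    def test_hand_rows_match_direct_formula(self):
        P = np.array([[0.7, 0.3], [0.5, 0.5]])
        part = SoftPartition(membership=P, K=2, method="gmm")
        got = soft_validity(part)
        expected = soft_metrics_oracle(P)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_rejected(self):
        part = SoftPartition(membership=np.ones((3, 1)), K=1, method="fcm")
        with pytest.raises(ValueError, match="K=1"):
            soft_validity(part)
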