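"""Correlation-distance k-means, elbow selection, state matching and per-state FNC."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import dfncstates as d
from dfncstates.states import standardize_rows
from dfncstates.windows import pair_index


def _gaussian_clouds(rng, n_clusters, per_cluster=120, p=10, sep=10.0):
    # equidistant centers (scaled one-hot) so no pair of clouds is closer
    # than any other — the elbow is unambiguous at the true count
    centers = np.zeros((n_clusters, p))
    centers[np.arange(n_clusters), np.arange(n_clusters)] = sep
    X = np.vstack([centers[i] + rng.standard_normal((per_cluster, p)) for i in range(n_clusters)])
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    return X, labels


class TestDistanceEquivalence:
    def test_correlation_distance_is_half_squared_euclidean(self, rng):
        X = rng.standard_normal((20, 15))
        Xs = standardize_rows(X)
        for i, j in itertools.combinations(range(10), 2):
            expected = 1.0 - np.corrcoef(X[i], X[j])[0, 1]
            got = 0.5 * np.sum((Xs[i] - Xs[j]) ** 2)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_rows(np.vstack([np.ones(5), np.arange(5.0)]))


class TestClusterWindows:
    def test_well_separated_clouds_recovered(self, rng):
        X, truth = _gaussian_clouds(rng, 3)
        model = d.cluster_windows(X, 3, seed=0)
        assert adjusted_rand_score(truth, model.labels_) >= 0.99

    def test_k_equals_one(self, rng):
        X = rng.standard_normal((50, 8))
        model = d.cluster_windows(X, 1, seed=0)
        assert np.all(model.labels_ == 0)
        np.testing.assert_allclose(model.centroids_[0], X.mean(axis=0), atol=1e-10)

    def test_deterministic_given_seed(self, rng):
        X, _ = _gaussian_clouds(rng, 3)
        a = d.cluster_windows(X, 3, seed=7)
        b = d.cluster_windows(X, 3, seed=7)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.centroids_, b.centroids_)

    def test_too_few_samples_fail(self, rng):
        with pytest.raises(ValueError):
            d.cluster_windows(rng.standard_normal((3, 5)), 3, seed=0)

    def test_label_permutation_consistency(self, rng):
        # relabeling states permutes centroids and downstream features together
        X, _ = _gaussian_clouds(rng, 3)
        model = d.cluster_windows(X, 3, seed=1)
        perm, corrs = d.match_states(model.centroids_, model.centroids_[[2, 0, 1]])
        np.testing.assert_array_equal(perm, [1, 2, 0])
        np.testing.assert_allclose(corrs, 1.0)


class TestStateRecovery:
    def test_centroids_recover_planted_covariances(self, recovery_cohort):
        swc = d.SlidingWindowConnectivity().fit()
        pooled = np.vstack([swc.transform(tc) for tc in recovery_cohort.scans])
        model = d.cluster_windows(pooled, 3, n_replicates=10, seed=2)
        rows, cols = pair_index(20)
        truth = np.vstack([sc.matrix[rows, cols] for sc in recovery_cohort.state_covariances])
        _, corrs = d.match_states(truth, model.centroids_)
        assert corrs.min() >= 0.95

    def test_group_wise_clustering_matches_across_groups(self):
        # clustering healthy-only and impaired-only windows separately yields
        # pairwise-matchable states; each group needs enough visits to its
        # rare state, so this runs at 50 scans per group and full C = 53
        cohort = d.generate_cohort(50, 50, c=53, seed=303)
        swc = d.SlidingWindowConnectivity().fit()
        meta = cohort.metadata.set_index("scan_id")
        by_group = {"healthy": [], "impaired": []}
        for tc in cohort.scans:
            by_group[meta.loc[tc.scan_id, "group"]].append(swc.transform(tc))
        model_h = d.cluster_windows(np.vstack(by_group["healthy"]), 3, n_replicates=10, seed=3)
        model_i = d.cluster_windows(np.vstack(by_group["impaired"]), 3, n_replicates=10, seed=3)
        _, corrs = d.match_states(model_h.centroids_, model_i.centroids_)
        assert corrs.min() >= 0.95


class TestElbow:
    def test_selects_three_on_three_clouds(self, rng):
        X, _ = _gaussian_clouds(rng, 3, per_cluster=100)
        result = d.elbow_select_k(X, range(2, 8), n_replicates=5, seed=0)
        assert result.selected_k == 3
        assert not result.low_confidence

    def test_selects_five_on_five_clouds(self, rng):
        X, _ = _gaussian_clouds(rng, 5, per_cluster=80)
        result = d.elbow_select_k(X, range(2, 9), n_replicates=5, seed=0)
        assert result.selected_k == 5

    def test_single_cloud_flagged_low_confidence(self, rng):
        X = rng.standard_normal((400, 10))
        result = d.elbow_select_k(X, range(2, 8), n_replicates=5, seed=0)
        assert result.low_confidence

    def test_k_range_too_small(self, rng):
        with pytest.raises(ValueError):
            d.elbow_select_k(rng.standard_normal((50, 5)), [2, 3], seed=0)


class TestAssignStateVectors:
    def test_round_trip_per_scan(self):
        labels = np.array([0, 1, 1, 2, 0, 1])
        out = d.assign_state_vectors(labels, {"a": 3, "b": 3})
        np.testing.assert_array_equal(out["a"], [0, 1, 1])
        np.testing.assert_array_equal(out["b"], [2, 0, 1])

    def test_count_mismatch_is_error_not_silent(self):
        with pytest.raises(ValueError, match="account"):
            d.assign_state_vectors(np.zeros(5, dtype=int), {"a": 3, "b": 3})

    def test_paper_scale_window_counts(self):
        labels = np.zeros(278, dtype=int)
        out = d.assign_state_vectors(labels, {"a": 139, "b": 139})
        assert out["a"].shape == (139,) and out["b"].shape == (139,)


class TestSubjectStateFNC:
    def test_single_state_mean_and_missing(self, rng):
        wv = rng.standard_normal((10, 6))
        sv = np.zeros(10, dtype=int)
        out = d.subject_state_fnc(wv, sv, k=3)
        np.testing.assert_allclose(out[0], wv.mean(axis=0))
        assert np.isnan(out[1]).all() and np.isnan(out[2]).all()

    def test_two_window_average_exact(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([3.0, 2.0, 1.0])
        out = d.subject_state_fnc(np.vstack([v, w]), np.array([1, 1]), k=2)
        np.testing.assert_array_equal(out[1], (v + w) / 2)
        assert np.isnan(out[0]).all()

    def test_state_means_recover_true_correlations(self, recovery_cohort):
        swc = d.SlidingWindowConnectivity().fit()
        rows, cols = pair_index(20)
        tc = recovery_cohort.scans[0]
        wv = swc.transform(tc)
        regime = recovery_cohort.regimes[tc.scan_id]
        # ground-truth per-window labels: majority regime within the window
        sv = np.array(
            [np.bincount(regime[s : s + 20]).argmax() for s in range(wv.shape[0])]
        )
        out = d.subject_state_fnc(wv, sv, k=3)
        for s in range(3):
            if np.isnan(out[s]).all():
                continue
            truth = recovery_cohort.state_covariances[s].matrix[rows, cols]
            # windows straddle regime boundaries, so agreement is loose but real
            assert np.corrcoef(out[s], truth)[0, 1] > 0.8


class TestMatchStates:
    def test_identity(self, rng):
        A = rng.standard_normal((4, 12))
        perm, corrs = d.match_states(A, A)
        np.testing.assert_array_equal(perm, np.arange(4))
        np.testing.assert_allclose(corrs, 1.0, atol=1e-12)

    def test_recovers_row_permutation(self, rng):
        A = rng.standard_normal((5, 30))
        order = np.array([3, 0, 4, 1, 2])
        perm, corrs = d.match_states(A, A[order])
        np.testing.assert_array_equal(order[perm], np.arange(5))
        np.testing.assert_allclose(corrs, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        A = rng.standard_normal((4, 10))
        B = rng.standard_normal((4, 10))
        perm, corrs = d.match_states(A, B)
        corr = np.array([[np.corrcoef(a, b)[0, 1] for b in B] for a in A])
        best = max(itertools.permutations(range(4)), key=lambda p: sum(corr[i, p[i]] for i in range(4)))
        assert corr[np.arange(4), list(best)].sum() == pytest.approx(corrs.sum(), abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            d.match_states(rng.standard_normal((3, 5)), rng.standard_normal((4, 5)))
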