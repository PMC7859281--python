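"""ADASYN oversampling, the polynomial kernel, confusion metrics, evaluation."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import dfncstates as d
from dfncstates.classify import ConfusionCounts


class TestADASYN:
    def test_exact_synthetic_count_85_40(self, rng):
        X, y = d.generate_classification_cohort(85, 40, n_features=10, seed=0)
        X_syn, info = d.adasyn_oversample(X, y, beta=1.0, random_state=1)
        assert X_syn.shape == (45, 10)
        assert info["G"] == 45

    def test_balanced_classes_emit_nothing(self, rng):
        X = rng.standard_normal((40, 4))
        y = np.repeat([0, 1], 20)
        X_syn, info = d.adasyn_oversample(X, y, beta=1.0, random_state=0)
        assert X_syn.shape[0] == 0

    def test_density_concentrates_on_boundary_point(self):
        # constructed 2-D layout: one minority point surrounded by majority,
        # one isolated inside a minority cluster. Hand computation with k=5:
        # the surrounded point has r=5/5, the interior cluster points r=0.
        minority_cluster = np.array(
            [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [0.05, 0.05], [0.05, 0.0]]
        )
        surrounded = np.array([[10.0, 10.0]])
        majority = np.vstack(
            [
                10.0 + 0.1 * np.array([[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1]]),
                np.random.default_rng(0).uniform(20, 30, size=(10, 2)),
            ]
        )
        X = np.vstack([minority_cluster, surrounded, majority])
        y = np.array([1] * 7 + [0] * 15)
        X_syn, info = d.adasyn_oversample(X, y, k_neighbors=5, random_state=0)
        density = info["density"]
        assert density[6] == pytest.approx(1.0)  # all weight on the surrounded point
        np.testing.assert_allclose(density[:6], 0.0)

    def test_synthetic_points_are_convex_combinations(self, rng):
        X, y = d.generate_classification_cohort(60, 25, n_features=5, seed=3)
        X_syn, info = d.adasyn_oversample(X, y, random_state=4)
        X_min = X[y == 1]
        for s, (i, z) in zip(X_syn, info["parents"]):
            lo = np.minimum(X_min[i], X_min[z])
            hi = np.maximum(X_min[i], X_min[z])
            assert np.all(s >= lo - 1e-12) and np.all(s <= hi + 1e-12)

    def test_interior_minority_falls_back_uniform(self, rng):
        # minority cluster far from majority: every r_i = 0
        X_min = rng.standard_normal((10, 3))
        X_maj = rng.standard_normal((30, 3)) + 100.0
        X = np.vstack([X_maj, X_min])
        y = np.array([0] * 30 + [1] * 10)
        with pytest.warns(RuntimeWarning, match="uniform"):
            X_syn, info = d.adasyn_oversample(X, y, random_state=0)
        assert info["uniform_fallback"]
        assert X_syn.shape[0] == 20

    def test_minority_too_small(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ValueError, match="k_neighbors"):
            d.adasyn_oversample(X, y, k_neighbors=5)

    def test_fit_resample_appends_synthetic_last(self):
        X, y = d.generate_classification_cohort(50, 20, n_features=4, seed=7)
        sampler = d.ADASYN(random_state=0)
        X_res, y_res = sampler.fit_resample(X, y)
        assert X_res.shape[0] == 70 + 30
        np.testing.assert_array_equal(X_res[:70], X)
        assert np.all(y_res[70:] == 1)


class TestPolynomialKernel:
    def test_orthogonal_vectors(self):
        assert d.polynomial_kernel(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 3) == 1.0

    def test_worked_example(self):
        assert d.polynomial_kernel(np.array([1.0, 1.0]), np.array([1.0, 1.0]), 2) == 9.0

    def test_matches_explicit_feature_map_degree3(self, rng):
        # (1 + x.y)^3 equals the inner product of explicit monomial features
        # sqrt(multinomial) * x1^a x2^b in 2-D
        x1 = rng.standard_normal(2)
        x2 = rng.standard_normal(2)

        def feature_map(v):
            phi = []
            for a in range(4):
                for b in range(4 - a):
                    c = 3 - a - b  # exponent of the constant 1
                    coef = math.sqrt(math.factorial(3) / (math.factorial(a) * math.factorial(b) * math.factorial(c)))
                    phi.append(coef * v[0] ** a * v[1] ** b)
            return np.array(phi)

        expected = feature_map(x1) @ feature_map(x2)
        assert d.polynomial_kernel(x1, x2, 3) == pytest.approx(expected, rel=1e-12)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            d.polynomial_kernel(np.zeros(2), np.zeros(2), 0)


class TestConfusionMetrics:
    def test_worked_example(self):
        acc, sens, spec = d.confusion_metrics(ConfusionCounts(tp=7, fn=3, tn=8, fp=2))
        assert (acc, sens, spec) == (0.75, 0.70, 0.80)

    def test_perfect_classifier(self):
        acc, sens, spec = d.confusion_metrics(ConfusionCounts(tp=5, fn=0, tn=9, fp=0))
        assert acc == sens == spec == 1.0

    def test_zero_denominator_is_missing(self):
        acc, sens, spec = d.confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=4, fp=1))
        assert math.isnan(sens) and spec == 0.8

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 2, size=20)
            pred = rng.integers(0, 2, size=20)
            tp = int(np.sum((truth == 1) & (pred == 1)))
            fn = int(np.sum((truth == 1) & (pred == 0)))
            tn = int(np.sum((truth == 0) & (pred == 0)))
            fp = int(np.sum((truth == 0) & (pred == 1)))
            acc, sens, spec = d.confusion_metrics(ConfusionCounts(tp, fn, tn, fp))
            # independent tally by direct enumeration
            assert acc == pytest.approx(np.mean(truth == pred))
            if tp + fn:
                assert sens == pytest.approx(np.mean(pred[truth == 1] == 1))
            if tn + fp:
                assert spec == pytest.approx(np.mean(pred[truth == 0] == 0))


class TestEvaluateConversion:
    def test_separated_classes_high_accuracy(self):
        X, y = d.generate_classification_cohort(85, 40, n_features=10, effect_size=5.0, seed=11)
        report = d.evaluate_conversion(X, y, n_repeats=3, seed=0)
        assert report.mean_accuracy >= 0.95
        assert report.n_synthetic == 45

    def test_no_synthetic_sample_in_any_test_set(self):
        X, y = d.generate_classification_cohort(60, 30, n_features=6, effect_size=2.0, seed=5)
        report = d.evaluate_conversion(X, y, n_repeats=4, seed=1)
        for test_rows in report.test_indices:
            assert test_rows.max() < X.shape[0]  # synthetic rows would exceed this
            assert np.unique(test_rows).size == test_rows.size

    def test_auc_invariant_to_monotone_score_transform(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, size=100)
        a = roc_auc_score(labels, scores)
        b = roc_auc_score(labels, np.exp(scores))
        assert a == pytest.approx(b, abs=1e-12)

    def test_stratified_protocol_runs(self):
        X, y = d.generate_classification_cohort(40, 20, n_features=5, effect_size=3.0, seed=2)
        report = d.evaluate_conversion(
            X, y, n_repeats=2, folds=3, protocol="stratified_cv", seed=3
        )
        assert len(report.accuracy) == 2
        assert report.mean_accuracy > 0.7

    def test_flip_positive_swaps_sensitivity_and_specificity(self):
        X, y = d.generate_classification_cohort(60, 30, n_features=6, effect_size=3.0, seed=9)
        a = d.evaluate_conversion(X, y, n_repeats=2, seed=4)
        b = d.evaluate_conversion(X, y, n_repeats=2, seed=4, flip_positive=True)
        assert a.mean_sensitivity == pytest.approx(b.mean_specificity)
        assert a.mean_specificity == pytest.approx(b.mean_sensitivity)

    def test_effect_zero_auc_near_chance_under_stratified_cv(self):
        # the unbiased null check: ADASYN applied inside training folds only,
        # so evaluation folds are untouched real data. A single 125-sample
        # dataset carries ~0.05 of dataset-level AUC noise, so the null mean
        # is estimated over several independent null datasets.
        aucs = []
        for seed in range(4):
            X, y = d.generate_classification_cohort(
                85, 40, n_features=10, effect_size=0.0, seed=100 + seed
            )
            report = d.evaluate_conversion(X, y, n_repeats=2, protocol="stratified_cv", seed=seed)
            aucs.append(report.mean_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_literal_protocol_is_optimistic_under_null(self):
        # training on synthetic interpolations of the minority points that are
        # later evaluated inflates null performance; this documents the bias
        # of the train-on-synthetic/test-on-real protocol rather than hiding it
        X, y = d.generate_classification_cohort(85, 40, n_features=10, effect_size=0.0, seed=21)
        report = d.evaluate_conversion(X, y, n_repeats=6, seed=6)
        assert report.mean_auc > 0.55
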