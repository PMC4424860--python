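import numpy as np
import pytest
from sklearn.svm import SVC

import icsift as ic
from icsift.svm import (
    GridSearchSpec,
    artifact_overlap_rate,
    estimate_sigma,
    grid_search,
    kernel_matrix,
    metrics,
    rbf_kernel,
    train,
)


def _separable(seed=0, n=40, gap=6.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 5))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, 0] += gap
    return X, y


class TestKernel:
    def test_identity_pair_is_one(self):
        x = np.arange(5, dtype=float)
        assert rbf_kernel(x, x, sigma=0.38) == 1.0

    def test_unit_distance_value(self):
        x = np.zeros(5)
        y = np.zeros(5)
        y[0] = 1.0
        assert rbf_kernel(x, y, 0.38) == pytest.approx(np.exp(-0.38))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x, y = rng.standard_normal((2, 5))
            assert rbf_kernel(x, y, 0.5) == pytest.approx(rbf_kernel(y, x, 0.5))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel(np.zeros(5), np.zeros(4), 0.5)

    def test_kernel_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            X = np.random.default_rng(seed).standard_normal((20, 5))
            K = kernel_matrix(X, X, sigma=0.7)
            eigvals = np.linalg.eigvalsh(K)
            assert eigvals.min() >= -1e-8


class TestEstimateSigma:
    def test_two_points_deterministic(self):
        X = np.array([[0.0, 0, 0, 0, 0], [2.0, 0, 0, 0, 0]])
        sigma = estimate_sigma(X, seed=0)
        assert sigma == pytest.approx(1.0 / 4.0)  # both quantiles collapse to 1/d^2

    def test_seed_reproducible(self):
        X = np.random.default_rng(3).standard_normal((30, 5))
        assert estimate_sigma(X, seed=11) == estimate_sigma(X, seed=11)

    def test_within_quantile_bracket(self):
        for seed in range(30):
            X = np.random.default_rng(seed).standard_normal((25, 5))
            rng = np.random.default_rng(seed)
            n = X.shape[0]
            i = rng.integers(0, n, size=2 * n)
            j = rng.integers(0, n, size=2 * n)
            d2 = np.sum((X[i] - X[j]) ** 2, axis=1)
            inv = 1.0 / d2[d2 > 0]
            lo, hi = np.quantile(inv, [0.1, 0.9])
            sigma = estimate_sigma(X, seed=seed)
            assert lo <= sigma <= hi

    def test_degenerate_geometry_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_sigma(np.ones((10, 5)), seed=0)


class TestTrain:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = _separable(seed=4)
        model = train(X, y, sigma=0.5)
        assert np.mean(model.predict(X) == y) == 1.0
        assert model.n_support <= len(y)

    def test_decision_function_matches_sklearn(self):
        X, y = _separable(seed=5, gap=2.0)
        svc = SVC(C=100.0, kernel="rbf", gamma=0.5, class_weight={1: 10.0, 0: 1.0})
        svc.fit(X, y)
        model = train(X, y, cost=100.0, sigma=0.5)
        probe = np.random.default_rng(6).standard_normal((50, 5))
        np.testing.assert_allclose(
            model.decision_function(probe), svc.decision_function(probe), atol=1e-10
        )
        np.testing.assert_array_equal(model.predict(probe), svc.predict(probe))

    def test_decision_invariant_to_training_order(self):
        X, y = _separable(seed=7, gap=2.0)
        perm = np.random.default_rng(8).permutation(len(y))
        a = train(X, y, sigma=0.4)
        b = train(X[perm], y[perm], sigma=0.4)
        probe = np.random.default_rng(9).standard_normal((30, 5))
        # identical up to the QP solver's convergence tolerance
        np.testing.assert_allclose(a.decision_function(probe), b.decision_function(probe), atol=1e-2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 5))
        with pytest.raises(ValueError, match="both classes"):
            train(X, np.ones(10), sigma=0.5)

    def test_rfn_weight_never_hurts_sensitivity(self):
        # heavier penalty on the positive class can only help recall
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 5))
            y = rng.integers(0, 2, 40)
            y[:3], y[-3:] = 1, 0
            X[y == 1, 0] += 1.0  # weakly separable: errors exist
            sens = []
            for w in (1.0, 10.0):
                model = train(X, y, sigma=0.5, class_weights=(w, 1.0))
                pred = model.predict(X)
                sens.append(np.mean(pred[y == 1] == 1))
            assert sens[1] >= sens[0]

    def test_serialization_round_trip(self, tmp_path):
        X, y = _separable(seed=10, gap=2.0)
        model = train(X, y, sigma=0.6)
        model.save(tmp_path / "model.json")
        back = ic.ClassifierModel.load(tmp_path / "model.json")
        probe = np.random.default_rng(11).standard_normal((100, 5))
        np.testing.assert_array_equal(model.predict(probe), back.predict(probe))
        np.testing.assert_allclose(
            model.decision_function(probe), back.decision_function(probe), rtol=1e-15
        )


class TestGridSearch:
    def test_spec_counts_grid_nodes(self):
        spec = GridSearchSpec()
        assert spec.c_values().size == 100
        assert spec.sigma_values().size == 10
        assert spec.n_points == 1000

    def test_ties_broken_by_smallest_c_then_sigma(self):
        X, y = _separable(seed=12, gap=8.0)  # easy: plateau of optima
        spec = GridSearchSpec(c_range=(10, 50), c_step=10, sigma_range=(0.1, 0.5), sigma_step=0.1)
        result = grid_search(X, y, spec, seed=1)
        assert result.best_c == 10.0
        assert result.best_sigma == 0.1
        assert result.sensitivity_constraint_met

    def test_same_seed_identical_cv_table(self):
        X, y = _separable(seed=13, gap=2.0)
        spec = GridSearchSpec(c_range=(10, 30), c_step=10, sigma_range=(0.1, 0.3), sigma_step=0.1)
        a = grid_search(X, y, spec, seed=3)
        b = grid_search(X, y, spec, seed=3)
        assert a.table.equals(b.table)


class TestMetrics:
    def test_group_result_with_one_false_positive(self):
        # 30 components, one artifact called a network: precision 15/16,
        # specificity 14/15, accuracy 29/30
        truth = ic.LabelTable({i: ic.RFN if i < 15 else ic.ART for i in range(30)})
        pred = ic.LabelTable({i: ic.RFN if i < 16 else ic.ART for i in range(30)})
        counts, m = metrics(pred, truth)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (15, 1, 14, 0)
        assert round(m.precision, 2) == 0.94
        assert round(m.sensitivity, 2) == 1.00
        assert round(m.specificity, 2) == 0.93
        assert round(m.accuracy, 2) == 0.97

    def test_perfect_agreement(self):
        truth = ic.LabelTable({i: ic.RFN if i < 17 else ic.ART for i in range(30)})
        counts, m = metrics(truth, truth)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (17, 0, 13, 0)
        assert m.precision == m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_perfect_disagreement(self):
        truth = ic.LabelTable({i: ic.RFN if i < 5 else ic.ART for i in range(10)})
        flipped = ic.LabelTable({i: ic.ART if i < 5 else ic.RFN for i in range(10)})
        _, m = metrics(flipped, truth)
        assert m.accuracy == 0.0
        assert m.sensitivity == 0.0

    def test_undefined_ratio_flagged_not_zeroed(self):
        truth = ic.LabelTable({0: ic.ART, 1: ic.ART})
        pred = ic.LabelTable({0: ic.ART, 1: ic.ART})
        _, m = metrics(pred, truth)
        assert np.isnan(m.precision) and np.isnan(m.sensitivity)
        assert "precision" in m.undefined and "sensitivity" in m.undefined
        assert m.specificity == 1.0

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="same component ids"):
            metrics(ic.LabelTable({0: ic.RFN}), ic.LabelTable({1: ic.RFN}))


class TestClassifySet:
    def test_cross_corpus_accuracy(self, trained_model, test_corpus, gm):
        ica_set, truth = test_corpus
        pred, counts = ic.classify_set(trained_model, ica_set, gm)
        assert counts.nic == ica_set.nic
        assert counts.n_rfn + counts.n_art == ica_set.nic
        _, m = metrics(pred, truth)
        assert m.accuracy >= 0.9

    def test_empty_set(self, trained_model, gm):
        labels, counts = ic.classify_set(trained_model, ic.ICASet([]), gm)
        assert len(labels) == 0
        assert (counts.n_rfn, counts.n_art) == (0, 0)

    def test_classification_is_idempotent(self, trained_model, test_corpus, gm):
        ica_set, _ = test_corpus
        first, _ = ic.classify_set(trained_model, ica_set, gm)
        second, _ = ic.classify_set(trained_model, ica_set, gm)
        assert first == second

    def test_degenerate_component_forced_to_art(self, trained_model, small_cfg, gm):
        rng = np.random.default_rng(31)
        comps = [
            ic.Component(
                i,
                ic.StatMap(small_cfg.grid, 0.5 * rng.standard_normal(small_cfg.dims)),
                ic.ICTimeCourse(rng.standard_normal(small_cfg.n_timepoints), small_cfg.tr),
            )
            for i in range(2)
        ]
        labels, counts = ic.classify_set(trained_model, ic.ICASet(comps), gm)
        assert counts.n_art == 2


class TestArtifactOverlapRate:
    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            artifact_overlap_rate(0, 0)
        with pytest.raises(ValueError):
            artifact_overlap_rate(10, 11)

    def test_no_misses_is_hundred_percent(self):
        assert artifact_overlap_rate(231, 0) == 100.0
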