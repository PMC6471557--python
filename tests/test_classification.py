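"""Shrinkage covariance, CSP, sLDA, mRMR and cross-validation."""

import numpy as np
import pytest

import flightload as fl
from flightload.classification import (
    fit_csp_from_covariances,
    mrmr_select,
    shrink_covariance,
    stratified_folds,
)
from flightload.features import FeatureMatrix

from conftest import make_epochs

CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4")


class TestShrinkage:
    def test_large_sample_anisotropic_lambda_is_small(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 4)) * np.array([1.0, 2.0, 3.0, 4.0])
        _, lam = shrink_covariance(X)
        assert lam < 0.05

    def test_matches_analytic_reference(self):
        from sklearn.covariance import ledoit_wolf

        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 6)) @ rng.standard_normal((6, 6))
        S, lam = shrink_covariance(X)
        S_ref, lam_ref = ledoit_wolf(X)
        assert lam == pytest.approx(lam_ref, abs=1e-12)
        assert np.allclose(S, S_ref, atol=1e-12)

    def test_duplicated_observation_forces_full_shrinkage(self):
        X = np.tile(np.array([1.0, -2.0, 0.5]), (6, 1))
        _, lam = shrink_covariance(X)
        assert lam == 1.0

    def test_eigenvalue_floor_from_convex_combination(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 8))
        S, lam = shrink_covariance(X)
        Xc = X - X.mean(axis=0)
        mu = np.trace(Xc.T @ Xc / len(X)) / 8
        assert np.linalg.eigvalsh(S).min() >= lam * mu - 1e-12

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            shrink_covariance(np.ones((1, 3)))


class TestCsp:
    def test_identical_distributions_give_half_eigenvalues(self):
        rng = np.random.default_rng(3)
        cov = np.cov(rng.standard_normal((6, 500)))
        a = make_epochs(rng.standard_normal((20, 6, 400)), channels=CHANNELS)
        b = make_epochs(rng.standard_normal((20, 6, 400)), channels=CHANNELS)
        model = fl.fit_csp(a, b, n_pairs=2)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.06)

    def test_top_filter_matches_brute_force_variance_ratio(self):
        cov_a = np.array([[9.0, 0.3], [0.3, 1.0]])
        cov_b = np.array([[1.0, -0.1], [-0.1, 1.0]])
        model = fit_csp_from_covariances(cov_a, cov_b, n_pairs=1)
        w = model.filters[:, 0]
        got = (w @ cov_a @ w) / (w @ (cov_a + cov_b) @ w)
        best = max(
            (
                np.array([np.cos(a), np.sin(a)])
                for a in np.linspace(0, np.pi, 3600)
            ),
            key=lambda v: (v @ cov_a @ v) / (v @ (cov_a + cov_b) @ v),
        )
        ref = (best @ cov_a @ best) / (best @ (cov_a + cov_b) @ best)
        assert got == pytest.approx(ref, rel=0.01)

    def test_three_channel_objective_is_global_maximum(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((3, 3))
        cov_a = A @ A.T + np.diag([5.0, 1.0, 0.2])
        B = rng.standard_normal((3, 3))
        cov_b = B @ B.T + np.eye(3)
        model = fit_csp_from_covariances(cov_a, cov_b, n_pairs=1)
        w = model.filters[:, 0]
        got = (w @ cov_a @ w) / (w @ (cov_a + cov_b) @ w)
        rng2 = np.random.default_rng(5)
        for v in rng2.standard_normal((4000, 3)):
            v /= np.linalg.norm(v)
            assert (v @ cov_a @ v) / (v @ (cov_a + cov_b) @ v) <= got + 1e-9

    def test_two_pairs_give_four_normalized_filters(self):
        rng = np.random.default_rng(6)
        a = make_epochs(rng.standard_normal((10, 6, 300)) * 2.0,
                        channels=CHANNELS)
        b = make_epochs(rng.standard_normal((10, 6, 300)), channels=CHANNELS)
        model = fl.fit_csp(a, b, n_pairs=2)
        assert model.filters.shape == (6, 4)
        comp = model.composite_covariance
        for j in range(4):
            w = model.filters[:, j]
            assert w @ comp @ w == pytest.approx(1.0, abs=1e-9)
        assert np.all((model.eigenvalues >= 0) & (model.eigenvalues <= 1))

    def test_channel_mismatch_rejected(self):
        a = make_epochs(np.random.default_rng(0).standard_normal((3, 2, 100)))
        b = make_epochs(np.random.default_rng(1).standard_normal((3, 3, 100)))
        with pytest.raises(ValueError):
            fl.fit_csp(a, b)


class TestSlda:
    def test_separable_classes_perfectly_classified(self):
        rng = np.random.default_rng(7)
        X0 = rng.standard_normal((40, 5))
        X1 = rng.standard_normal((40, 5)) + 10.0
        X = np.vstack([X0, X1])
        y = np.array(["low"] * 40 + ["high"] * 40, dtype=object)
        model = fl.fit_slda(X, y)
        assert (model.predict(X) == y).all()

    def test_symmetric_means_give_zero_bias(self):
        rng = np.random.default_rng(8)
        mu = np.array([2.0, -1.0, 0.5])
        X0 = rng.standard_normal((500, 3)) - mu
        X1 = rng.standard_normal((500, 3)) + mu
        X = np.vstack([X0, X1]) - np.vstack([X0, X1]).mean(axis=0)
        y = np.array(["low"] * 500 + ["high"] * 500, dtype=object)
        model = fl.fit_slda(X, y, shrinkage=0.0)
        assert model.bias == pytest.approx(0.0, abs=1e-9)
        direction = model.weights / np.linalg.norm(model.weights)
        diff = X[500:].mean(axis=0) - X[:500].mean(axis=0)
        cos = direction @ (diff / np.linalg.norm(diff))
        assert cos > 0.99

    def test_lambda_zero_matches_closed_form(self):
        X0 = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        X1 = X0 + np.array([3.0, 1.0])
        X = np.vstack([X0, X1])
        y = np.array(["low"] * 4 + ["high"] * 4, dtype=object)
        model = fl.fit_slda(X, y, shrinkage=0.0)
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        centered = np.vstack([X0 - mu0, X1 - mu1])
        pooled = centered.T @ centered / len(centered)
        expected = np.linalg.solve(pooled, mu1 - mu0)
        assert np.abs(model.weights - expected).max() < 1e-10

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        y = np.array(["low"] * 4, dtype=object)
        with pytest.raises(ValueError, match="2 classes"):
            fl.fit_slda(X, y)


class TestMrmr:
    def test_k_equal_feature_count_orders_by_relevance_first(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 300).astype(object)
        yf = y.astype(float)
        F = np.column_stack(
            [0.1 * rng.standard_normal(300),  # noise
             yf + 0.2 * rng.standard_normal(300)]  # informative
        )
        order = mrmr_select(F, y, k=2)
        assert order[0] == 1
        assert sorted(order) == [0, 1]

    def test_redundant_copy_deferred_after_noise(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 400)
        f1 = y + 0.3 * rng.standard_normal(400)
        F = np.column_stack([f1, f1, rng.standard_normal(400)])
        assert mrmr_select(F, y.astype(object), k=3) == [0, 2, 1]

    def test_matches_brute_force_greedy_on_toy(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 250)
        F = np.column_stack(
            [y + rng.standard_normal(250) * s for s in (0.4, 0.8, 1.5)]
            + [rng.standard_normal(250) for _ in range(3)]
        )
        got = mrmr_select(F, y.astype(object), k=4, n_bins=8)

        def binned(col):
            edges = np.quantile(col, np.linspace(0, 1, 9)[1:-1])
            return np.searchsorted(edges, col, side="right")

        B = [binned(F[:, j]) for j in range(6)]
        rel = [mutual_info_score(b, y) for b in B]
        sel = [int(np.argmax(rel))]
        while len(sel) < 4:
            scores = []
            for j in range(6):
                if j in sel:
                    scores.append(-np.inf)
                    continue
                red = np.mean([mutual_info_score(B[j], B[s]) for s in sel])
                scores.append(rel[j] - red)
            sel.append(int(np.argmax(scores)))
        assert got == sel

    def test_independent_labels_select_low_mi_feature(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 200)
        F = rng.standard_normal((200, 5))
        first = mrmr_select(F, y.astype(object), k=1)[0]

        def binned(col):
            edges = np.quantile(col, np.linspace(0, 1, 9)[1:-1])
            return np.searchsorted(edges, col, side="right")

        mi = mutual_info_score(binned(F[:, first]), y)
        null = []
        for rep in range(200):
            null.append(mutual_info_score(binned(F[:, first]),
                                          rng.permutation(y)))
        assert mi < np.quantile(null, 0.95) * 3  # same order as the null

    def test_k_exceeding_features_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mrmr_select(np.zeros((10, 3)), np.zeros(10, dtype=object), k=4)


class TestCrossValidation:
    def test_stratified_folds_preserve_class_balance(self):
        labels = np.array(["low"] * 53 + ["high"] * 47, dtype=object)
        assignment = stratified_folds(labels, 5, seed=0)
        for fold in range(5):
            mask = assignment == fold
            n_low = int((labels[mask] == "low").sum())
            assert abs(n_low - 53 / 5) <= 1

    def test_class_smaller_than_folds_rejected(self):
        labels = np.array(["low"] * 3 + ["high"] * 50, dtype=object)
        with pytest.raises(ValueError, match="fewer"):
            stratified_folds(labels, 5, seed=0)

    def test_constant_predictor_scores_exactly_half(self):
        labels = np.array(["low"] * 30 + ["high"] * 30, dtype=object)
        fm = FeatureMatrix(np.zeros((60, 1)), ["const"], labels)
        report = fl.crossvalidate(fm, n_folds=5, seed=0)
        assert report.balanced_accuracy == pytest.approx(0.5)

    def test_report_arithmetic(self, short_session):
        from flightload.preprocessing import segment_continuous
        from flightload.features import band_covariances

        _, _, rec, _ = short_session
        ep = segment_continuous(rec, 2.0).subset(np.arange(40))
        labels = np.array((["low"] * 20 + ["high"] * 20), dtype=object)
        ep.metadata["condition"] = labels
        covs = band_covariances(ep, {"alpha": (8.0, 12.0)})
        report = fl.crossvalidate(csp_data=covs, labels=labels, n_folds=5,
                                  seed=1)
        per_fold = [f.balanced_accuracy for f in report.folds]
        assert report.balanced_accuracy == pytest.approx(np.mean(per_fold),
                                                         abs=1e-12)
        for f in report.folds:
            assert f.balanced_accuracy == pytest.approx(
                (f.sensitivity + f.specificity) / 2, abs=1e-12
            )
        assert len(report.fold_assignment) == 40

    def test_no_leakage_from_test_folds(self, short_session):
        """Corrupting a test fold never changes the models fitted on train."""
        from flightload.preprocessing import segment_continuous
        from flightload.features import band_covariances

        _, _, rec, _ = short_session
        ep = segment_continuous(rec, 2.0).subset(np.arange(40))
        labels = np.array((["low"] * 20 + ["high"] * 20), dtype=object)
        ep.metadata["condition"] = labels
        covs = band_covariances(ep, {"alpha": (8.0, 12.0), "theta": (4.0, 8.0)})
        base = fl.crossvalidate(csp_data=covs, labels=labels, n_folds=4, seed=2)

        probe_fold = 1
        test_idx = np.flatnonzero(base.fold_assignment == probe_fold)
        import copy

        covs2 = copy.deepcopy(covs)
        for band in covs2.shrunk:
            covs2.shrunk[band][test_idx] = np.eye(6) * 999.0
            covs2.empirical[band][test_idx] = np.eye(6) * 999.0
        corrupted = fl.crossvalidate(csp_data=covs2, labels=labels, n_folds=4,
                                     seed=2)
        f0 = base.folds[probe_fold]
        f1 = corrupted.folds[probe_fold]
        assert np.allclose(f0.lda.weights, f1.lda.weights)
        for band in f0.csp_bank:
            assert np.allclose(f0.csp_bank[band].filters,
                               f1.csp_bank[band].filters)

    def test_fusion_selects_requested_feature_count(self, short_session):
        from flightload.preprocessing import segment_continuous
        from flightload.features import band_covariances, erp_features

        _, _, rec, _ = short_session
        ep = segment_continuous(rec, 2.0).subset(np.arange(40))
        labels = np.array((["low"] * 20 + ["high"] * 20), dtype=object)
        ep.metadata["condition"] = labels
        covs = band_covariances(ep, fl.BANDS)
        report = fl.crossvalidate(csp_data=covs, labels=labels, n_folds=5,
                                  fusion=10, seed=3)
        assert all(len(f.selected) == 10 for f in report.folds)
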