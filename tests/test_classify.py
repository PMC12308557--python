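import numpy as np
import pandas as pd
import pytest

import preshock as ps
from preshock.classify import default_ablation_subsets


def gaussian_blobs(n_per_class, sep=4.0, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_per_class, dim)), rng.normal(sep, 1, (n_per_class, dim))]
    )
    y = np.repeat([1, 2], n_per_class)
    return X, y


class TestScaler:
    def test_zero_mean_unit_population_sd(self):
        scaler = ps.fit_scaler([[0.0], [2.0]])
        out = scaler.transform([[0.0], [2.0]])
        assert out[:, 0] == pytest.approx([-1.0, 1.0])

    def test_constant_column_flagged_and_zeroed(self):
        with pytest.warns(UserWarning):
            scaler = ps.fit_scaler([[1.0, 5.0], [2.0, 5.0]])
        assert scaler.constant_mask.tolist() == [False, True]
        assert ps.apply_scaler([[1.5, 5.0]], scaler)[0, 1] == 0.0

    def test_training_statistics_reused_on_held_out_copy(self, rng):
        X = rng.normal(2.0, 3.0, (50, 4))
        scaler = ps.fit_scaler(X)
        assert np.allclose(scaler.transform(X.copy()), scaler.transform(X))
        assert np.allclose(scaler.transform(X).mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(scaler.transform(X).std(axis=0), 1.0, atol=1e-12)


class TestStratifiedSplit:
    def test_reproduces_cohort_allocation(self):
        """195/56 labels at 70% train -> 136+39 train, 59+17 test."""
        y = np.repeat([1, 2], [195, 56])
        train, test = ps.stratified_split(y, ratio=0.7, seed=0)
        assert (y[train] == 2).sum() == 39 and (y[test] == 2).sum() == 17
        assert (y[train] == 1).sum() == 136 and (y[test] == 1).sum() == 59

    def test_exact_allocation(self):
        y = np.repeat([1, 2], 10)
        train, test = ps.stratified_split(y, ratio=0.5, seed=1)
        assert (y[train] == 1).sum() == 5 and (y[train] == 2).sum() == 5

    def test_partition_property(self):
        y = np.repeat([1, 2], [31, 17])
        train, test = ps.stratified_split(y, ratio=0.7, seed=3)
        combined = np.sort(np.concatenate([train, test]))
        assert np.array_equal(combined, np.arange(48))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            ps.stratified_split(np.array([1, 1, 1, 2]), ratio=0.7, seed=0)


class TestSmote:
    def test_segment_interpolation(self):
        # minority pair (0,0)-(1,1): every synthetic point is (lam, lam)
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10.0, 0.0]] * 6)
        y = np.array([2, 2, 1, 1, 1, 1, 1, 1])
        X_aug, y_aug = ps.smote(X, y, k=1, seed=0)
        new = X_aug[len(X):]
        assert np.allclose(new[:, 0], new[:, 1])
        assert np.all((new[:, 0] >= 0) & (new[:, 0] < 1))

    def test_balances_class_counts(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.repeat([1, 2], [30, 10])
        _, y_aug = ps.smote(X, y, k=3, seed=1)
        _, counts = np.unique(y_aug, return_counts=True)
        assert counts[0] == counts[1] == 30

    def test_minority_too_small_for_k(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] * 7 + [2] * 3)
        with pytest.raises(ValueError, match="lower k"):
            ps.smote(X, y, k=5, seed=0)

    def test_synthetic_points_lie_on_true_knn_segments(self, rng):
        """Brute-force check: each synthetic point interpolates a minority
        sample with one of its true k nearest minority neighbors."""
        k = 3
        X = rng.normal(size=(60, 2))
        y = np.repeat([1, 2], [45, 15])
        X_aug, _ = ps.smote(X, y, k=k, seed=2)
        minority = X[y == 2]
        dists = np.linalg.norm(minority[:, None] - minority[None], axis=2)
        for s in X_aug[len(X):]:
            found = False
            for i, x0 in enumerate(minority):
                knn = np.argsort(dists[i])[1 : k + 1]  # brute-force neighbors
                for j in knn:
                    d = minority[j] - x0
                    denom = float(d @ d)
                    lam = float((s - x0) @ d) / denom if denom > 0 else 0.0
                    if 0 <= lam < 1 and np.allclose(x0 + lam * d, s, atol=1e-9):
                        found = True
                        break
                if found:
                    break
            assert found, f"synthetic point {s} is not on any minority k-NN segment"


class TestGridSearch:
    def test_singleton_grids_returned(self):
        X, y = gaussian_blobs(20, seed=0)
        cfg = ps.TrainConfig(c_grid=(3.0,), gamma_grid=(0.7,), imbalance="none")
        assert ps.grid_search(X, y, cfg) == (3.0, 0.7)

    def test_deterministic_selection(self):
        X, y = gaussian_blobs(30, seed=1)
        cfg = ps.TrainConfig(c_grid=(0.1, 10.0), gamma_grid=(0.1, 10.0), seed=5)
        assert ps.grid_search(X, y, cfg) == ps.grid_search(X, y, cfg)

    def test_oversized_gamma_rejected_by_cv(self):
        """On well-separated Gaussian blobs a huge RBF width loses in CV."""
        X, y = gaussian_blobs(60, sep=5.0, seed=2)
        X = ps.fit_scaler(X).transform(X)
        cfg = ps.TrainConfig(c_grid=(1.0,), gamma_grid=(0.1, 100.0), imbalance="none")
        _, gamma = ps.grid_search(X, y, cfg)
        assert gamma == 0.1

    def test_fold_count_reduced_with_warning(self):
        X, y = gaussian_blobs(3, seed=3)
        cfg = ps.TrainConfig(c_grid=(1.0,), gamma_grid=(1.0,), inner_cv_folds=5,
                             imbalance="none")
        with pytest.warns(UserWarning, match="folds"):
            ps.grid_search(X, y, cfg)


class TestFitSvm:
    def test_two_point_closed_form(self):
        """Two opposed points in 1-D: boundary at the midpoint, both SVs."""
        X = np.array([[-1.0], [1.0]])
        y = np.array([1, 2])
        cfg = ps.TrainConfig(kernel="linear", imbalance="none")
        model = ps.fit_svm(X, y, C=1e6, gamma=1.0, config=cfg)
        assert model.decision_scores([[0.0]])[0] == pytest.approx(0.0, abs=1e-6)
        assert model.estimator.support_vectors_.shape[0] == 2

    def test_xor_separable_with_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, 2, 2])
        model = ps.fit_svm(X, y, C=10.0, gamma=1.0,
                           config=ps.TrainConfig(imbalance="none"))
        assert np.array_equal(model.predict(X), y)

    def test_kkt_conditions_on_toy_fit(self):
        X, y = gaussian_blobs(20, sep=2.0, seed=4)
        C = 5.0
        model = ps.fit_svm(X, y, C=C, gamma=0.5, config=ps.TrainConfig(imbalance="none"))
        alpha_y, _ = model.dual_coefficients()
        assert np.all(np.abs(alpha_y) <= C + 1e-6)  # 0 <= alpha_i <= C
        assert abs(alpha_y.sum()) <= 1e-6  # sum alpha_i y_i = 0

    def test_predictions_use_class_codes(self):
        X, y = gaussian_blobs(10, seed=5)
        model = ps.fit_svm(X, y, C=1.0, gamma=0.1)
        assert set(model.predict(X)) <= {1, 2}
        assert model.label_names == {1: "NoROEA", 2: "ROEA"}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ps.fit_svm([[0.0], [1.0]], [1, 1], C=1.0, gamma=1.0)


class TestEvaluate:
    def test_f1_identities_from_printed_pairs(self):
        assert round(100 * ps.f1_from_precision_recall(0.99, 0.955), 1) == 97.2
        assert round(100 * ps.f1_from_precision_recall(0.839, 0.959), 1) == 89.5

    def test_perfect_predictions(self):
        y = np.array([1, 1, 2, 2, 2])
        report = ps.evaluate(y, y, scores=[-1, -1, 1, 1, 1])
        assert report.accuracy == 1.0
        assert all(m["f1"] == 1.0 for m in report.per_class.values())
        assert report.roc_auc == 1.0

    def test_internal_consistency(self, rng):
        y_true = rng.integers(1, 3, 60)
        y_pred = rng.integers(1, 3, 60)
        report = ps.evaluate(y_true, y_pred)
        assert report.accuracy == pytest.approx(np.trace(report.confusion) / 60)
        assert report.weighted["recall"] == pytest.approx(report.accuracy)
        for idx, code in enumerate(report.labels):
            row = report.confusion[idx]
            if row.sum():
                assert report.per_class[int(code)]["recall"] == pytest.approx(
                    row[idx] / row.sum()
                )

    def test_unseen_prediction_label_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            ps.evaluate([1, 2], [1, 3])


class TestLosoCv:
    def test_fold_count_and_separable_accuracy(self, fast_train_config):
        X, y = gaussian_blobs(6, sep=6.0, seed=6)
        correct, pooled = ps.loso_cv(X, y, fast_train_config)
        assert correct.size == 12  # one fold per record
        assert correct.mean() == 1.0
        assert int(pooled.confusion.sum()) == 12

    def test_too_few_records_rejected(self, fast_train_config):
        with pytest.raises(ValueError):
            ps.loso_cv([[0.0], [1.0]], [1, 2], fast_train_config)


class TestSensitivity:
    def test_zero_perturbation_zero_deviation(self):
        X, y = gaussian_blobs(20, seed=7)
        dev = ps.sensitivity(X, y, X, y, C=1.0, gamma=0.1, perturbation=0.0)
        assert dev == 0.0

    def test_separable_cohort_is_stable(self):
        X_train, y_train = gaussian_blobs(60, sep=5.0, seed=8)
        X_test, y_test = gaussian_blobs(60, sep=5.0, seed=9)
        scaler = ps.fit_scaler(X_train)
        dev = ps.sensitivity(
            scaler.transform(X_train), y_train, scaler.transform(X_test), y_test,
            C=1.0, gamma=0.5,
        )
        assert 0.0 <= dev < 0.02


class TestAblation:
    def test_default_enumeration_for_three_features(self):
        subsets = default_ablation_subsets(["a", "b", "c"])
        assert len(subsets) == 7  # full + 3 leave-one-out + 3 pairs
        assert subsets[0] == ("all", ("a", "b", "c"))

    def test_full_row_matches_direct_run(self, fast_train_config, feature_sample):
        X, y = feature_sample
        X3 = X[["amplitude_qrs", "total_power2", "lf_power2"]]
        table = ps.ablation(X3, y, config=fast_train_config)
        _, direct, _ = ps.train_and_evaluate(X3.to_numpy(), y, fast_train_config)
        assert table.loc["all", "accuracy"] == pytest.approx(direct.accuracy)
        assert len(table) == 7

    def test_removing_the_informative_feature_hurts_most(self, fast_train_config, rng):
        n = 120
        y = np.repeat([1, 2], n)
        X = pd.DataFrame(
            {
                "signal": np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)]),
                "noise_a": rng.normal(size=2 * n),
                "noise_b": rng.normal(size=2 * n),
            }
        )
        table = ps.ablation(X, y, config=fast_train_config)
        drops = table.loc[[c for c in table.index if c.startswith("without_")], "accuracy"]
        assert drops.idxmin() == "without_signal"

    def test_empty_subset_rejected(self, fast_train_config, feature_sample):
        X, y = feature_sample
        with pytest.raises(ValueError):
            ps.ablation(X, y, subsets=[("nothing", ())], config=fast_train_config)


class TestCompareClassifiers:
    def test_rows_and_metric_ranges(self, fast_train_config, feature_sample):
        X, y = feature_sample
        table = ps.compare_classifiers(
            X[["amplitude_qrs", "total_power2", "lf_power2"]], y, fast_train_config
        )
        assert list(table.index) == ["svm", "random_forest", "logistic_regression"]
        metrics = table[["accuracy", "weighted_precision", "weighted_recall", "weighted_f1"]]
        assert ((metrics >= 0) & (metrics <= 1)).all().all()

    def test_reproducible_with_seed(self, fast_train_config, feature_sample):
        X, y = feature_sample
        X3 = X[["amplitude_qrs", "total_power2", "lf_power2"]]
        a = ps.compare_classifiers(X3, y, fast_train_config)
        b = ps.compare_classifiers(X3, y, fast_train_config)
        pd.testing.assert_frame_equal(a, b)

    def test_logistic_regression_unhandicapped_on_linear_data(self, fast_train_config):
        X, y = gaussian_blobs(150, sep=4.0, seed=10)
        table = ps.compare_classifiers(pd.DataFrame(X, columns=["f1", "f2"]), y,
                                       fast_train_config)
        assert table.loc["logistic_regression", "accuracy"] >= 0.95


class TestTrainAndEvaluateLeakage:
    def test_scaler_and_smote_use_training_rows_only(self, feature_sample):
        X, y = feature_sample
        X3 = X[["amplitude_qrs", "total_power2", "lf_power2"]].to_numpy()
        cfg = ps.TrainConfig(c_grid=(10.0,), gamma_grid=(0.1,), seed=4)
        _, report, details = ps.train_and_evaluate(X3, y, cfg)
        train_idx, test_idx = details["train_idx"], details["test_idx"]
        # scaler statistics derive from training rows alone
        assert np.allclose(details["scaler"].mean, X3[train_idx].mean(axis=0))
        assert np.allclose(details["scaler"].sd, X3[train_idx].std(axis=0))
        # split is a disjoint partition; test rows were never rebalanced
        assert np.intersect1d(train_idx, test_idx).size == 0
        assert train_idx.size + test_idx.size == len(y)
        assert int(report.confusion.sum()) == test_idx.size

    def test_rebalancing_equalizes_training_classes(self, feature_sample):
        X, y = feature_sample
        X3 = X[["amplitude_qrs", "total_power2", "lf_power2"]].to_numpy()
        # make the cohort imbalanced 3:1 before training
        keep = np.concatenate([np.flatnonzero(y == 1), np.flatnonzero(y == 2)[:50]])
        cfg = ps.TrainConfig(c_grid=(10.0,), gamma_grid=(0.1,), imbalance="both", seed=0)
        _, _, details = ps.train_and_evaluate(X3[keep], y[keep], cfg)
        n_train = details["train_idx"].size
        assert details["n_train_after_rebalance"] > n_train


def test_train_config_validation():
    with pytest.raises(ValueError):
        ps.TrainConfig(split_ratio=1.5)
    with pytest.raises(ValueError):
        ps.TrainConfig(imbalance="oversample")
    with pytest.raises(ValueError):
        ps.TrainConfig(c_grid=())
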