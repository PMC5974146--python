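"""Classifier training, stratified cross-validation protocols and the
maxout network."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from plantmito import models
from plantmito.models import (DNNConfig, SVMConfig, TrainedModel,
                              TrainingError, grid_search_svm, predict,
                              run_cv, stratified_kfold, train_dnn,
                              train_dnn_ensemble, train_svm)


def _blobs(n_per_class=40, d=2, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per_class, d)),
                   rng.normal(sep, 1, (n_per_class, d))])
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestStratifiedKFold:
    def test_balanced_1000_1000_gives_100_100_folds(self):
        y = np.repeat([0, 1], 1000)
        folds = stratified_kfold(y, k=10, seed=1)
        for f in folds:
            assert len(f) == 200
            assert (y[f] == 1).sum() == 100 and (y[f] == 0).sum() == 100

    def test_unit_quota(self):
        y = np.repeat([0, 1], 10)
        folds = stratified_kfold(y, k=10, seed=0)
        assert all(len(f) == 2 for f in folds)

    def test_partition_property(self):
        y = np.array([0, 1] * 23)
        folds = stratified_kfold(y, k=5, seed=2)
        union = np.concatenate(folds)
        assert sorted(union) == list(range(len(y)))
        assert len(set(union)) == len(y)

    def test_deterministic(self):
        y = np.repeat([0, 1], 30)
        a = stratified_kfold(y, k=6, seed=9)
        b = stratified_kfold(y, k=6, seed=9)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))

    def test_k_exceeding_class_count_rejected(self):
        with pytest.raises(TrainingError):
            stratified_kfold([0, 0, 1, 1], k=3)


class TestSVM:
    def test_separable_toy_perfect_training_accuracy(self):
        X, y = _blobs(sep=6.0)
        clf = train_svm(X, y, cost=10.0, gamma="scale")
        assert ((clf.decision_function(X) >= 0).astype(int) == y).all()

    def test_duplication_invariance(self):
        X, y = _blobs(seed=3)
        a = train_svm(X, y, 10.0, 0.5).decision_function(X)
        b = train_svm(np.vstack([X, X]), np.concatenate([y, y]),
                      10.0, 0.5).decision_function(X)
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_non_finite_features_rejected(self):
        X, y = _blobs()
        X[0, 0] = np.nan
        with pytest.raises(TrainingError):
            train_svm(X, y, 1.0, 0.1)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(TrainingError):
            train_svm(X, np.zeros(10), 1.0, 0.1)

    def test_decision_values_match_dual_qp_oracle(self):
        # brute-force solve of the SVM dual on 16 points, then compare
        # decision values on fresh inputs
        rng = np.random.default_rng(5)
        n, gamma, C = 16, 0.5, 10.0
        X = rng.normal(size=(n, 2))
        y_pm = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=n) > 0, 1, -1)
        K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        Q = (y_pm[:, None] * y_pm[None, :]) * K
        res = minimize(
            lambda a: -a.sum() + 0.5 * a @ Q @ a,
            np.zeros(n),
            jac=lambda a: -np.ones(n) + Q @ a,
            bounds=[(0, C)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a @ y_pm,
                          "jac": lambda a: y_pm.astype(float)}],
            method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14})
        alpha = res.x
        margin = (alpha > 1e-8) & (alpha < C - 1e-8)
        b = np.mean([y_pm[i] - (alpha * y_pm) @ K[:, i]
                     for i in np.flatnonzero(margin)])
        Xt = rng.normal(size=(10, 2))
        Kt = np.exp(-gamma * ((Xt[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        oracle = Kt @ (alpha * y_pm) + b
        clf = train_svm(X, (y_pm > 0).astype(int), C, gamma)
        np.testing.assert_allclose(clf.decision_function(Xt), oracle, atol=1e-4)

    def test_grid_of_size_one_returned(self):
        X, y = _blobs(n_per_class=20)
        config = SVMConfig(cost_grid=(2.0,), gamma_grid=(0.3,))
        assert grid_search_svm(X, y, config, seed=0, k=4) == (2.0, 0.3)

    def test_grid_search_returns_grid_member(self):
        X, y = _blobs(n_per_class=20, sep=2.0, seed=7)
        config = SVMConfig(cost_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1, 1.0))
        c, g = grid_search_svm(X, y, config, seed=0, k=4)
        assert c in config.cost_grid and g in config.gamma_grid

    def test_default_grids_have_published_shape(self):
        config = SVMConfig()
        assert len(config.cost_grid) == 7 and len(config.gamma_grid) == 11


class TestMaxoutNetwork:
    def test_default_architecture_echo(self):
        config = DNNConfig()
        assert config.hidden_sizes == (500, 500, 300)
        assert config.maxout_pieces == 5
        assert config.dropout == 0.5
        assert config.learning_rate == 0.01
        assert (config.momentum_initial, config.momentum_final) == (0.5, 0.7)
        assert config.max_epochs == 250

    def test_separable_data_reaches_perfect_validation(self):
        X, y = _blobs(n_per_class=60, sep=4.0, seed=1)
        Xv, yv = _blobs(n_per_class=20, sep=4.0, seed=2)
        config = DNNConfig(hidden_sizes=(32, 32, 16), max_epochs=50,
                           batch_size=20, seed=0)
        net = train_dnn(X, y, Xv, yv, config)
        assert net.training_info["best_val_auc"] == 1.0
        assert net.training_info["best_epoch"] <= 50

    def test_deterministic_for_seed(self):
        X, y = _blobs(n_per_class=30, seed=4)
        Xv, yv = _blobs(n_per_class=10, seed=5)
        config = DNNConfig(hidden_sizes=(8, 8), max_epochs=10, batch_size=16, seed=3)
        s1 = train_dnn(X, y, Xv, yv, config).predict_proba(Xv)
        s2 = train_dnn(X, y, Xv, yv, config).predict_proba(Xv)
        np.testing.assert_array_equal(s1, s2)

    def test_scores_bounded_in_unit_interval(self):
        X, y = _blobs(n_per_class=30, seed=4)
        Xv, yv = _blobs(n_per_class=10, seed=5)
        config = DNNConfig(hidden_sizes=(8,), max_epochs=5, batch_size=16, seed=0)
        s = train_dnn(X, y, Xv, yv, config).predict_proba(X)
        assert ((0 <= s) & (s <= 1)).all()


class _StubMember:
    def __init__(self, value):
        self.value = value

    def predict_proba(self, X):
        return np.full(len(X), self.value)


class TestEnsemble:
    def test_member_count_is_k(self):
        X, y = _blobs(n_per_class=30, sep=4.0, seed=6)
        config = DNNConfig(hidden_sizes=(8,), max_epochs=5, batch_size=12, seed=0)
        model = train_dnn_ensemble(X, y, k=10, config=config, seed=1)
        assert model.kind == "dnn_ensemble" and len(model.members) == 10

    def test_mean_of_two_members(self):
        model = TrainedModel("dnn_ensemble", [_StubMember(0.2), _StubMember(0.8)], "")
        np.testing.assert_allclose(predict(model, np.zeros((3, 2))), 0.5)

    def test_identical_members_equal_single(self):
        model = TrainedModel("dnn_ensemble", [_StubMember(0.4)] * 10, "")
        np.testing.assert_allclose(predict(model, np.zeros((2, 1))), 0.4)

    def test_ensemble_mean_bounded_by_member_extremes(self):
        X, y = _blobs(n_per_class=30, sep=4.0, seed=6)
        config = DNNConfig(hidden_sizes=(8,), max_epochs=5, batch_size=12, seed=0)
        model = train_dnn_ensemble(X, y, k=5, config=config, seed=1)
        member_scores = np.vstack([m.predict_proba(X) for m in model.members])
        ens = predict(model, X)
        assert (ens >= member_scores.min(axis=0) - 1e-12).all()
        assert (ens <= member_scores.max(axis=0) + 1e-12).all()


class TestPredict:
    def test_empty_input(self):
        model = TrainedModel("dnn_ensemble", [_StubMember(0.5)], "any")
        assert predict(model, []).size == 0

    def test_layout_mismatch_rejected(self, small_feature_set):
        model = TrainedModel("svm", [None], fingerprint="different-layout")
        with pytest.raises(models.CompatibilityError):
            predict(model, small_feature_set.vectors[:2])

    def test_model_bundle_round_trip(self, tmp_path):
        X, y = _blobs(n_per_class=15, seed=8)
        model = models.svm_model(X, y, SVMConfig(cost=1.0, gamma=0.2), "fp")
        models.save_model(model, tmp_path / "m.joblib")
        back = models.load_model(tmp_path / "m.joblib")
        np.testing.assert_allclose(predict(back, X, fingerprint="fp"),
                                   predict(model, X, fingerprint="fp"))


class TestRunCV:
    def test_dnn_protocol_uses_each_fold_once_as_test(self):
        y = np.repeat([0, 1], 25)
        folds = stratified_kfold(y, k=5, seed=0)
        sizes = [len(f) for f in folds]
        X, yb = _blobs(n_per_class=25, sep=4.0, seed=9)
        config = DNNConfig(hidden_sizes=(8,), max_epochs=3, batch_size=10, seed=0)
        cv = run_cv(X, yb, kind="dnn", dnn_config=config, k=5, seed=0)
        assert sorted(len(s) for s in cv.fold_scores) == sorted(sizes)
        assert sum(len(s) for s in cv.fold_scores) == len(yb)

    def test_perfectly_informative_features_reach_auc_one(self):
        X, y = _blobs(n_per_class=30, sep=8.0, seed=10)
        cv = run_cv(X, y, kind="svm", k=5, seed=0)
        assert cv.mean_auc == 1.0

    def test_label_shuffled_null_centers_at_half(self):
        # permutation-null simulation: mean CV AUC over 20 shuffles ~ 0.5
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 10))
        aucs = []
        for rep in range(20):
            y = rng.permutation(np.repeat([0, 1], 40))
            cv = run_cv(X, y, kind="svm", k=4, seed=rep)
            aucs.append(cv.mean_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_deterministic_fold_assignment_and_scores(self):
        X, y = _blobs(n_per_class=20, seed=11)
        a = run_cv(X, y, kind="svm", k=4, seed=5)
        b = run_cv(X, y, kind="svm", k=4, seed=5)
        for s1, s2 in zip(a.fold_scores, b.fold_scores):
            np.testing.assert_array_equal(s1, s2)
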