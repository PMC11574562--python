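"""SVM-RBF: kernel, dual solution, scoring, CV, grid search, RFE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import metaboscreen as ms
from metaboscreen.svm import (SvmModel, _kernel_matrix, decision_scores,
                              rfe_rank)


class TestKernel:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert ms.rbf_kernel(x, x, sigma=0.37) == pytest.approx(1.0)

    def test_closed_form_at_two_sigma_squared(self):
        sigma = 1.7
        x = np.zeros(1)
        x2 = np.array([np.sqrt(2.0) * sigma])  # ||x - x'||^2 = 2 sigma^2
        assert ms.rbf_kernel(x, x2, sigma) == pytest.approx(np.exp(-1.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 6))
        assert ms.rbf_kernel(x, y, 1.3) == pytest.approx(
            ms.rbf_kernel(y, x, 1.3))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ms.rbf_kernel(np.zeros(2), np.zeros(2), 0.0)


def _toy_separable():
    X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1],
                  [10.0, 10], [10, 11], [11, 10], [11, 11]])
    y = np.array([-1.0] * 4 + [1.0] * 4)
    return X, y


class TestTrainSvm:
    def test_separable_training_accuracy_100(self):
        X, y = _toy_separable()
        model = ms.train_svm(X, y, C=10.0, sigma=3.0)
        pred = np.sign(decision_scores(model, X))
        np.testing.assert_array_equal(pred, y)

    def test_dual_feasibility_and_kkt(self):
        X, y = _toy_separable()
        model = ms.train_svm(X, y, C=1.0, sigma=3.0, tol=1e-8)
        assert np.all(model.alpha >= -1e-9)
        assert np.all(model.alpha <= model.C + 1e-9)
        assert abs(np.sum(model.alpha * model.y)) < 1e-6
        # margin support vectors (0 < alpha < C) reproduce their labels
        margin = (model.alpha > 1e-6) & (model.alpha < model.C - 1e-6)
        if margin.any():
            scores = decision_scores(model, model.support_vectors[margin])
            np.testing.assert_allclose(scores, model.y[margin], atol=1e-3)

    def test_dual_objective_matches_independent_qp(self):
        """6-point problem: libsvm's SMO vs an SLSQP solve of the dual."""
        X = np.array([[0.0, 0], [0.5, 0.5], [0, 1],
                      [2.0, 2], [2.5, 2.5], [2, 3]])
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        C, sigma = 1.0, 1.0
        model = ms.train_svm(X, y, C=C, sigma=sigma, tol=1e-10)

        K = _kernel_matrix(X, X, sigma)
        Q = (y[:, None] * y[None, :]) * K

        def neg_dual(a):
            return -(a.sum() - 0.5 * a @ Q @ a)

        res = minimize(neg_dual, np.full(6, 0.5), method="SLSQP",
                       bounds=[(0, C)] * 6,
                       constraints=[{"type": "eq",
                                     "fun": lambda a: a @ y}],
                       options={"ftol": 1e-12, "maxiter": 500})
        assert abs(model.dual_objective() - (-res.fun)) < 1e-4

    def test_duplicated_training_set_same_decision_function(self):
        X, y = _toy_separable()
        m1 = ms.train_svm(X, y, C=1.0, sigma=3.0, tol=1e-8)
        m2 = ms.train_svm(np.vstack([X, X]), np.concatenate([y, y]),
                          C=0.5, sigma=3.0, tol=1e-8)
        rng = np.random.default_rng(0)
        probes = rng.uniform(-2, 13, size=(50, 2))
        np.testing.assert_allclose(decision_scores(m1, probes),
                                   decision_scores(m2, probes), atol=1e-6)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ms.train_svm(np.ones((4, 2)), np.ones(4), C=1, sigma=1)

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _toy_separable()
        model = ms.train_svm(X, y, C=1.0, sigma=3.0)
        model.save(tmp_path / "svm")
        back = SvmModel.load(tmp_path / "svm")
        probes = np.random.default_rng(1).normal(size=(10, 2))
        np.testing.assert_allclose(decision_scores(model, probes),
                                   decision_scores(back, probes))


class TestDecisionScore:
    def test_single_support_vector_identities(self):
        x1 = np.array([1.0, 2.0])
        model = SvmModel(x1[None, :], np.array([1.0]), np.array([1.0]),
                         b=0.0, sigma=1.0, C=1.0, feature_names=["a", "b"])
        assert ms.decision_score(model, x1) == pytest.approx(1.0)
        model.b = -0.5
        assert ms.decision_score(model, x1) == pytest.approx(0.5)

    def test_matches_brute_force_sum(self):
        X, y = _toy_separable()
        model = ms.train_svm(X, y, C=1.0, sigma=2.0)
        rng = np.random.default_rng(2)
        for x in rng.uniform(-1, 12, size=(100, 2)):
            brute = sum(a * yy * ms.rbf_kernel(x, sv, model.sigma)
                        for a, yy, sv in zip(model.alpha, model.y,
                                             model.support_vectors))
            brute += model.b
            assert ms.decision_score(model, x) == pytest.approx(brute,
                                                                abs=1e-10)

    def test_length_mismatch_raises(self):
        model = SvmModel(np.ones((1, 3)), np.ones(1), np.ones(1),
                         0.0, 1.0, 1.0, ["a", "b", "c"])
        with pytest.raises(ValueError):
            ms.decision_score(model, np.ones(2))


@pytest.mark.parametrize("score,expected", [
    (1.3, "cancer"), (-0.2, "normal"), (0.0, "normal")])
def test_classify_cutoff_including_boundary(score, expected):
    assert ms.classify(score) == expected


class TestGridSearch:
    def test_singleton_grid_returned(self):
        X, y = _toy_separable()
        C, sigma, table = ms.grid_search(X, y, [7.0], [1.5],
                                         ms.CvConfig(k_folds=2, seed=0))
        assert (C, sigma) == (7.0, 1.5)
        assert len(table) == 1

    def test_separable_reaches_perfect_cv_accuracy(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)),
                       rng.normal(6, 0.3, (20, 2))])
        y = np.array([-1.0] * 20 + [1.0] * 20)
        C, sigma, table = ms.grid_search(
            X, y, [0.1, 1, 10, 100], [1.0, 3.0, 9.0],
            ms.CvConfig(k_folds=5, seed=1))
        assert table["mean_cv_accuracy"].max() == 1.0

    def test_deterministic_table(self):
        X, y = _toy_separable()
        _, _, t1 = ms.grid_search(X, y, [1, 10], [1.0, 2.0],
                                  ms.CvConfig(k_folds=2, seed=5))
        _, _, t2 = ms.grid_search(X, y, [1, 10], [1.0, 2.0],
                                  ms.CvConfig(k_folds=2, seed=5))
        pd.testing.assert_frame_equal(t1, t2)

    def test_tie_breaks_toward_smaller_c_then_larger_sigma(self):
        X, y = _toy_separable()
        C, sigma, _ = ms.grid_search(X, y, [10.0, 0.5], [1.0, 5.0],
                                     ms.CvConfig(k_folds=2, seed=0))
        # the toy problem is solved by every grid point: tie-break decides
        assert C == 0.5 and sigma == 5.0

    def test_empty_grid_raises(self):
        X, y = _toy_separable()
        with pytest.raises(ValueError):
            ms.grid_search(X, y, [], [1.0], ms.CvConfig(k_folds=2))


class TestKfoldCv:
    def test_twenty_folds_of_forty_are_disjoint_pairs(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(5, 1, (20, 2))])
        y = np.array([-1.0] * 20 + [1.0] * 20)
        cv = ms.CvConfig(k_folds=20, seed=0)
        from metaboscreen.svm import _folds
        folds = _folds(y, cv)
        test_sets = [set(te) for _, te in folds]
        assert len(folds) == 20
        assert all(len(t) == 2 for t in test_sets)
        union = set().union(*test_sets)
        assert union == set(range(40))
        assert sum(len(t) for t in test_sets) == 40

    def test_two_fold_metrics_match_hand_loop(self):
        X = np.array([[0.0, 0], [0.2, 0], [5.0, 5], [5.2, 5]])
        y = np.array([-1.0, -1, 1, 1])
        cv = ms.CvConfig(k_folds=2, seed=0)
        reports, summary = ms.kfold_cv(X, y, cv, C=10.0, sigma=2.0)
        from metaboscreen.svm import _folds
        for report, (tr, te) in zip(reports, _folds(y, cv)):
            model = ms.train_svm(X[tr], y[tr], C=10.0, sigma=2.0)
            scores = decision_scores(model, X[te])
            tp = int(np.sum((scores > 0) & (y[te] > 0)))
            fn = int(np.sum((scores <= 0) & (y[te] > 0)))
            tn = int(np.sum((scores <= 0) & (y[te] < 0)))
            fp = int(np.sum((scores > 0) & (y[te] < 0)))
            assert (report.TP, report.FN, report.TN, report.FP) == \
                (tp, fn, tn, fp)

    def test_perfectly_separable_gives_full_sensitivity_every_fold(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (10, 2)),
                       rng.normal(8, 0.2, (10, 2))])
        y = np.array([-1.0] * 10 + [1.0] * 10)
        reports, _ = ms.kfold_cv(X, y, ms.CvConfig(k_folds=5, seed=0),
                                 C=10.0, sigma=3.0)
        assert all(r.sensitivity == 100.0 for r in reports)

    def test_k_exceeding_class_count_raises(self):
        y = np.array([-1.0, -1, 1, 1])
        with pytest.raises(ValueError):
            ms.kfold_cv(np.zeros((4, 2)), y, ms.CvConfig(k_folds=3), 1.0, 1.0)


class TestRfe:
    def test_only_informative_feature_ranked_first(self):
        rng = np.random.default_rng(6)
        n = 60
        y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
        signal = y * 2 + rng.normal(0, 0.3, n)
        X = np.c_[signal, rng.normal(size=n), rng.normal(size=n)]
        ranking, rounds = rfe_rank(
            pd.DataFrame(X, columns=["A", "noise1", "noise2"]),
            y, C=1.0, sigma=2.0, step=1, seed=0)
        assert ranking.iloc[0]["metabolite_id"] == "A"
        assert len(rounds) == 3

    def test_two_features_two_rounds_permutation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        y = np.sign(X[:, 0] + 0.1 * rng.normal(size=40))
        ranking, rounds = rfe_rank(X, y, C=1.0, sigma=1.0, step=1, seed=0)
        assert sorted(ranking["rank"]) == [1, 2]
        assert set(ranking["metabolite_id"]) == {"f0", "f1"}
        assert len(rounds) == 2

    def test_constant_feature_eliminated_before_signal(self):
        rng = np.random.default_rng(8)
        n = 60
        y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
        X = np.c_[y * 2 + rng.normal(0, 0.3, n),
                  y * 1.5 + rng.normal(0, 0.3, n),
                  np.zeros(n)]
        ranking, _ = rfe_rank(
            pd.DataFrame(X, columns=["sig1", "sig2", "const"]),
            y, C=1.0, sigma=2.0, step=1, seed=0)
        const_rank = int(ranking.set_index("metabolite_id")
                         .loc["const", "rank"])
        assert const_rank == 3  # worst rank: removed first

    def test_step_larger_than_survivors_finishes_cleanly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 5))
        y = np.sign(X[:, 0])
        ranking, rounds = rfe_rank(X, y, C=1.0, sigma=1.0, step=3, seed=0)
        assert sorted(ranking["rank"]) == [1, 2, 3, 4, 5]
        assert rounds["n_features"].tolist() == [5, 2]
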