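"""Fold bookkeeping, out-of-fold stacking semantics, and evaluation metrics."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahiot.cs_stack import (FoldAssignment, bcr, classification_metrics,
                            ensemble_entropy, fit_base_oof, fit_super_learner,
                            make_folds, predict_stacked, train_stacked)
from ahiot.io_prep import DescriptorMatrix


def _matrix(values, labels):
    values = np.asarray(values, dtype=float)
    return DescriptorMatrix(
        ids=[f"m{i}" for i in range(values.shape[0])],
        feature_names=[f"f{i}" for i in range(values.shape[1])],
        values=values, labels=labels,
    )


class TestMakeFolds:
    @pytest.mark.parametrize("n,J,sizes", [(10, 5, [2] * 5), (10, 3, [4, 3, 3])])
    def test_balanced_sizes(self, n, J, sizes):
        fa = make_folds(n, J, seed=0)
        counts = sorted(collections.Counter(fa.fold_of).values(), reverse=True)
        assert counts == sorted(sizes, reverse=True)

    def test_deterministic_given_seed(self):
        a, b = make_folds(37, 4, seed=9), make_folds(37, 4, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)

    def test_stratified_class_balance(self, rng):
        y = rng.permutation([1] * 30 + [0] * 50)
        fa = make_folds(80, 5, seed=1, stratify_labels=y)
        for j in range(5):
            members = y[fa.indices(j)]
            assert abs(members.sum() - 30 / 5) <= 1
            assert abs(len(members) - 16) <= 1

    def test_errors(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)
        with pytest.raises(ValueError, match="class"):
            make_folds(10, 4, seed=0, stratify_labels=[1] * 8 + [0] * 2)


class TestFitBaseOof:
    def test_majority_predictor_demonstrates_no_leakage(self):
        # each half is predicted by a model trained on the opposite-label half
        m = _matrix([[0], [0], [1], [1]], labels=[1, 1, 0, 0])
        folds = FoldAssignment(n=4, J=2, fold_of=np.array([0, 0, 1, 1]), seed=0)
        l1 = fit_base_oof(m, ["majority_class"], folds)
        np.testing.assert_array_equal(l1.z.ravel(), [0, 0, 1, 1])

    def test_constant_predictor_ignores_folds(self, rng):
        m = _matrix(rng.normal(size=(12, 2)), labels=[0, 1] * 6)
        l1 = fit_base_oof(m, ["constant"], make_folds(12, 3, 0))
        assert (l1.z == 0.5).all()

    def test_memorizer_on_shuffled_labels_stays_at_chance(self, rng):
        # a leaky evaluation of a 1-NN memorizer would give AUC ~ 1.0
        from sklearn.metrics import roc_auc_score

        aucs = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            X = g.normal(size=(120, 5))
            y = g.permutation([0, 1] * 60)
            m = _matrix(X, labels=y)
            l1 = fit_base_oof(m, ["knn1"], make_folds(120, 5, seed, stratify_labels=y))
            aucs.append(roc_auc_score(y, l1.z[:, 0]))
        assert 0.4 <= float(np.mean(aucs)) <= 0.6


class TestSuperLearner:
    def _separable_l1(self, n=200, seed=0):
        from ahiot.cs_stack import LevelOneData

        g = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        z = np.clip(0.15 + 0.7 * y[:, None] + g.normal(0, 0.05, (n, 2)), 0, 1)
        return LevelOneData(z=z, y=y, learner_names=["a", "b"])

    def test_probabilities_sum_to_one(self):
        l1 = self._separable_l1()
        model = fit_super_learner(l1, seed=0)
        proba = model.predict_proba_z(l1.z)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_training_accuracy_on_separable_data(self):
        l1 = self._separable_l1(n=200, seed=1)
        model = fit_super_learner(l1, seed=1)
        proba = model.predict_proba_z(l1.z)
        pred = proba[:, list(model.super_model.classes_).index(1)] >= 0.5
        assert (pred == l1.y).mean() >= 0.95

    def test_shuffled_labels_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        aucs = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            from ahiot.cs_stack import LevelOneData

            z = g.uniform(size=(150, 2))
            y = g.permutation([0, 1] * 75)
            tr, te = np.arange(0, 100), np.arange(100, 150)
            model = fit_super_learner(
                LevelOneData(z=z[tr], y=y[tr], learner_names=["a", "b"]), seed=seed)
            proba = model.predict_proba_z(z[te])
            aucs.append(roc_auc_score(y[te], proba[:, list(model.super_model.classes_).index(1)]))
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_single_class_errors(self):
        from ahiot.cs_stack import LevelOneData

        l1 = LevelOneData(z=np.full((4, 2), 0.5), y=[1, 1, 1, 1], learner_names=["a", "b"])
        with pytest.raises(ValueError, match="single class"):
            fit_super_learner(l1)


class TestPredictStacked:
    def test_feature_alignment_by_name_and_tie_rule(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        m = _matrix(X, labels=y)
        model, _ = train_stacked(m, learners=["random_forest"], J=5, seed=0, epochs=20)
        proba, pred = predict_stacked(model, m)
        # permuting columns by name leaves the output unchanged
        perm = [2, 0, 3, 1]
        m2 = DescriptorMatrix(
            ids=m.ids, feature_names=[m.feature_names[i] for i in perm],
            values=m.values[:, perm], labels=y)
        proba2, pred2 = predict_stacked(model, m2)
        np.testing.assert_allclose(proba, proba2)
        np.testing.assert_array_equal(pred, (proba >= 0.5).astype(int))

    def test_missing_feature_listed(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        model, _ = train_stacked(_matrix(X, y), learners=["random_forest"],
                                 J=4, seed=0, epochs=10)
        bad = DescriptorMatrix(ids=["a"], feature_names=["f0", "f9"],
                               values=[[0.0, 1.0]])
        with pytest.raises(ValueError, match="f9"):
            predict_stacked(model, bad)


class TestMetrics:
    def test_bcr_worked_values(self):
        assert bcr(1.0, 1.0) == 1.0
        assert bcr(1.0, 0.0) == 0.0
        assert bcr(0.961, 0.988) == pytest.approx(0.94819, abs=1e-5)

    @given(se=st.floats(0, 1), sp=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_bcr_symmetric_and_bounded(self, se, sp):
        assert bcr(se, sp) == pytest.approx(bcr(sp, se))
        assert bcr(se, sp) <= (se + sp) / 2 + 1e-12
        if abs(se - sp) > 1e-9:
            assert bcr(se, sp) < (se + sp) / 2

    def test_entropy_worked_values(self):
        y = np.zeros(4, dtype=int)
        all_correct = np.zeros((4, 3), dtype=int)
        assert ensemble_entropy(all_correct, y) == 0.0
        theta_0110 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0]])
        assert ensemble_entropy(theta_0110, y) == 0.5
        one_each = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert ensemble_entropy(one_each, y) == 1.0

    def test_entropy_invariant_to_column_order(self, rng):
        preds = rng.integers(0, 2, size=(30, 5))
        y = rng.integers(0, 2, size=30)
        shuffled = preds[:, rng.permutation(5)]
        assert ensemble_entropy(preds, y) == pytest.approx(ensemble_entropy(shuffled, y))

    def test_metrics_worked_example(self):
        m = classification_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1], cut=0.5)
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.5, 0.5, 0.5)
        assert m.auc == pytest.approx(0.75)

    def test_constant_probability_gives_half_auc(self):
        m = classification_metrics([1, 0, 1, 0], [0.5] * 4)
        assert m.auc == pytest.approx(0.5)

    def test_perfect_separation_all_ones(self):
        m = classification_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc, m.bcr) == (1, 1, 1, 1, 1)

    def test_single_class_auc_undefined(self):
        m = classification_metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert m.auc is None and m.sensitivity == 1.0

    def test_auc_matches_bruteforce_pairwise(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.uniform(size=n), 2)  # ties likely
            m = classification_metrics(y, p)
            pos, neg = p[y == 1], p[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert m.auc == pytest.approx(wins / (len(pos) * len(neg)))
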