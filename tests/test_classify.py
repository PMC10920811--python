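"""Fold construction, classifiers, tuning and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdecode import (
    Fold,
    balanced_accuracy,
    compare_models,
    evaluate_pipeline,
    fit_gbm,
    fit_linear,
    make_folds,
    roc_auc,
    tune_components,
)
from eegdecode.classify import ClassificationResult


def subjects(n_m, n_h):
    d = {f"M{i:02d}": "M" for i in range(n_m)}
    d.update({f"H{i:02d}": "H" for i in range(n_h)})
    return d


class TestMakeFolds:
    def test_minimal_groups_leave_one_trainer_each(self):
        plan = make_folds(subjects(3, 3), n_folds=5, seed=0)
        for f in plan.folds:
            train_groups = sorted(s[0] for s in f.train)
            assert train_groups == ["H", "M"]
            assert len(f.val) == 2 and len(f.test) == 2

    def test_role_disjointness(self):
        plan = make_folds(subjects(6, 7), n_folds=10, seed=1)
        for f in plan.folds:
            roles = list(f.train) + list(f.val) + list(f.test)
            assert len(roles) == len(set(roles))
            assert sorted(s[0] for s in f.test) == ["H", "M"]
            assert sorted(s[0] for s in f.val) == ["H", "M"]

    def test_distinct_test_pairs_without_replacement(self):
        plan = make_folds(subjects(13, 13), n_folds=10, seed=2)
        pairs = {tuple(sorted(f.test)) for f in plan.folds}
        assert len(pairs) == 10

    def test_replacement_warns_when_pairs_exhausted(self):
        with pytest.warns(UserWarning, match="replacement"):
            make_folds(subjects(3, 3), n_folds=12, seed=3)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="need >= 3"):
            make_folds(subjects(2, 5), n_folds=3, seed=0)

    def test_deterministic(self):
        a = make_folds(subjects(5, 5), 10, seed=9)
        b = make_folds(subjects(5, 5), 10, seed=9)
        assert a.folds == b.folds

    def test_fold_rejects_overlap(self):
        with pytest.raises(ValueError, match="disjoint"):
            Fold(train=("a", "b"), val=("b", "c"), test=("d", "e"))


class TestMetrics:
    def test_balanced_accuracy_closed_form(self):
        # TP=8 FN=2 TN=6 FP=4 -> (0.8 + 0.6)/2
        y = ["M"] * 10 + ["H"] * 10
        pred = ["M"] * 8 + ["H"] * 2 + ["H"] * 6 + ["M"] * 4
        assert balanced_accuracy(y, pred) == pytest.approx(0.7, abs=1e-12)

    def test_perfect_and_constant(self):
        y = ["M", "M", "H"]
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, ["M"] * 3) == 0.5

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(["M", "M"], ["M", "H"])

    def test_auc_trivial_cases(self):
        y = ["M", "H", "M", "H"]
        assert roc_auc(y, [1.0, 0.0, 1.0, 0.0]) == 1.0
        assert roc_auc(y, [0.3] * 4) == 0.5
        with pytest.raises(ValueError):
            roc_auc(["M", "M"], [0.1, 0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_auc_matches_pair_counting(self, seed):
        """AUC equals the tie-aware fraction of concordant positive/negative
        score pairs (Mann-Whitney), on random score sets of <= 50 epochs."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        y = np.array(["M", "H"])[rng.integers(0, 2, n)]
        if len(set(y)) < 2:
            y[0], y[1] = "M", "H"
        scores = rng.integers(0, 5, n).astype(float)  # discrete -> ties happen
        pos, neg = scores[y == "M"], scores[y == "H"]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(y, scores) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_label_rename_invariance(self):
        rng = np.random.default_rng(0)
        y = np.array(["M"] * 10 + ["H"] * 10)
        s = rng.standard_normal(20)
        a = roc_auc(y, s, positive_label="M")
        # consistent renaming keeps AUC; flipping the positive class with
        # negated scores does too
        assert roc_auc(np.where(y == "M", "H", "M"), s, positive_label="H") == pytest.approx(a, abs=1e-12)
        assert roc_auc(y, -s, positive_label="H") == pytest.approx(a, abs=1e-12)


class TestTuning:
    def test_single_candidate(self):
        assert tune_components(lambda J: 0.7, [4])[0] == 4

    def test_ties_prefer_smallest(self):
        assert tune_components(lambda J: 0.8, [2, 4, 6])[0] == 2

    def test_maximizer_selected(self):
        scores = {1: 0.6, 2: 0.9, 4: 0.7}
        assert tune_components(lambda J: scores[J], [1, 2, 4])[0] == 2


class TestFitLinear:
    def test_separable_data_perfect_training(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(3, 0.3, (30, 2)), rng.normal(-3, 0.3, (30, 2))])
        y = np.array(["M"] * 30 + ["H"] * 30)
        spec, m = fit_linear(X, y, X, y, C_grid=[1e3])
        assert balanced_accuracy(y, m.predict(X)) == 1.0

    def test_extreme_penalty_shrinks_weights(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = np.array(["M", "H"] * 20)
        _spec, m = fit_linear(X, y, X, y, C_grid=[1e-10])
        assert np.all(np.abs(m.coef_) < 1e-6)
        assert np.allclose(m.predict_proba(X)[:, 1], 0.5, atol=1e-3)

    def test_mirrored_features_get_symmetric_weights(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((200, 1))
        y = np.where(base[:, 0] > 0, "M", "H")
        X = np.hstack([base, -base])  # exact mirror pair
        _spec, m = fit_linear(X, y, X, y, C_grid=[1.0])
        w = m.coef_.ravel()
        assert abs(abs(w[0]) - abs(w[1])) < 1e-6

    def test_degenerate_validation_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="validation"):
            fit_linear(X, ["M", "H", "M", "H"], X, ["M", "M", "M", "M"])


class TestFitGBM:
    def test_informative_feature_dominates_importance(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (300, 4)).astype(float)
        y = np.where(X[:, 2] > 0.5, "M", "H")
        _spec, m = fit_gbm(X, y, X[:50], y[:50], seed=0)
        imp = m.feature_importances_
        assert np.argmax(imp) == 2

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 5))
        y = np.where(X[:, 0] + rng.normal(0, 0.5, 200) > 0, "M", "H")
        _s1, m1 = fit_gbm(X[:150], y[:150], X[150:], y[150:], seed=42)
        _s2, m2 = fit_gbm(X[:150], y[:150], X[150:], y[150:], seed=42)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            fit_gbm(np.zeros((4, 2)), ["M", "H"] * 2, np.zeros((2, 2)), ["M", "H"], grid=())

    def test_shuffled_labels_give_chance_performance(self):
        """Label permutation destroys the signal: held-out BA stays near 0.5
        across 20 reshuffles."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((240, 6))
        y_true = np.where(X[:, 0] > 0, "M", "H")
        bas = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.permutation(y_true[:160])
            _s, m = fit_gbm(
                X[:120], y[:120], X[120:160], y[120:160], seed=seed,
                grid=({"learning_rate": 0.1, "num_leaves": 7, "min_child_samples": 10},),
            )
            bas.append(balanced_accuracy(y_true[160:], m.predict(X[160:])))
        assert abs(np.mean(bas) - 0.5) <= 0.1


class TestEvaluatePipeline:
    def test_unknown_pipeline(self, tiny_cohort):
        _cfg, epochs, _ = tiny_cohort
        plan = make_folds(epochs.subject_groups(), 2, seed=0)
        with pytest.raises(ValueError, match="pipeline"):
            evaluate_pipeline(epochs, "magic", plan)

    def test_deterministic_end_to_end(self, tiny_cohort):
        _cfg, epochs, _ = tiny_cohort
        plan = make_folds(epochs.subject_groups(), 2, seed=1)
        a = evaluate_pipeline(epochs, "supervised", plan, J_candidates=(2,), seed=3)
        b = evaluate_pipeline(epochs, "supervised", plan, J_candidates=(2,), seed=3)
        assert a.fold_ba == b.fold_ba and a.fold_auc == b.fold_auc
        assert a.tuned == b.tuned

    def test_result_bounds_and_fold_count(self, tiny_cohort):
        _cfg, epochs, _ = tiny_cohort
        plan = make_folds(epochs.subject_groups(), 3, seed=2)
        res = evaluate_pipeline(epochs, "riemann", plan, J_candidates=(2,), seed=0)
        assert len(res.fold_ba) == 3
        assert all(0.0 <= v <= 1.0 for v in res.fold_ba + res.fold_auc)


class TestCompareModels:
    def _res(self, ba):
        return ClassificationResult(
            pipeline=f"p{id(ba) % 97}", task="verb",
            fold_ba=list(ba), fold_auc=list(ba), fold_subject_ba=list(ba),
            tuned=[{}] * len(ba), seed=0,
        )

    def test_identical_results_degenerate_p(self):
        a = self._res([0.8] * 10)
        b = self._res([0.8] * 10)
        out = compare_models([a, b])
        assert out[0]["p"] == 1.0 and out[0]["statistic"] == 0.0

    def test_uniform_improvement_reaches_minimal_p(self):
        """One model better on all 10 folds: two-sided signed-rank p is the
        exact floor 2/2^10."""
        a = self._res([0.8 + 0.01 * i for i in range(10)])
        b = self._res([0.7 + 0.01 * i for i in range(10)])
        out = compare_models([a, b])
        assert out[0]["p"] == pytest.approx(2 / 1024, rel=1e-9)

    def test_three_pipelines_three_tests(self):
        rng = np.random.default_rng(7)
        rs = [self._res(list(rng.uniform(0.5, 1.0, 10))) for _ in range(3)]
        assert len(compare_models(rs)) == 3

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="fold counts"):
            compare_models([self._res([0.8] * 10), self._res([0.8] * 9)])
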