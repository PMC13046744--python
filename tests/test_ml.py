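"""Feature selection, evaluation metrics and Shapley attribution tests."""

import numpy as np
import pandas as pd
import pytest

from rhythmage.ml import (
    mcc_from_counts,
    mrmr_select,
    mutual_information,
    shapley_attributions,
    spearman_prune,
    split_train_val_test,
    train_and_evaluate,
)


class TestSpearmanPrune:
    def test_identical_features_collapse_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = (x > 0).astype(int)
        df = pd.DataFrame({"a": x, "b": x.copy()})
        assert len(spearman_prune(df, y)) == 1

    def test_uncorrelated_features_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 200)
        assert len(spearman_prune(df, y)) == 4

    def test_constructed_cluster_keeps_most_relevant_member(self):
        # a, b, c mutually correlated (> 0.7); b has the strongest label link;
        # d, e, f independent -> expected survivors {b, d, e, f}
        rng = np.random.default_rng(2)
        n = 500
        base = rng.normal(size=n)
        a = base + 0.1 * rng.normal(size=n)
        b = base + 0.1 * rng.normal(size=n)
        c = base + 0.1 * rng.normal(size=n)
        d, e, f = rng.normal(size=(3, n))
        y = (b + 0.3 * rng.normal(size=n) > 0).astype(int)
        df = pd.DataFrame({"a": a, "b": b, "c": c, "d": d, "e": e, "f": f})
        assert set(spearman_prune(df, y)) == {"b", "d", "e", "f"}


class TestMRMR:
    def test_single_candidate_selected_first(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"only": rng.normal(size=100)})
        y = rng.integers(0, 2, 100)
        assert mrmr_select(df, y, k=1).ranking == ["only"]

    def test_duplicate_of_top_feature_deprioritised(self):
        rng = np.random.default_rng(3)
        n = 1000
        strong = rng.normal(size=n)
        y = (strong + 0.2 * rng.normal(size=n) > 0).astype(int)
        weak = rng.normal(size=n) + 0.35 * y
        df = pd.DataFrame({"strong": strong, "strong_copy": strong.copy(),
                           "weak": weak})
        ranking = mrmr_select(df, y, k=3).ranking
        assert ranking[0] == "strong"
        assert ranking[1] == "weak"  # redundancy pushes the copy below

    def test_greedy_equals_exhaustive_mid_criterion(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        X["b"] += 0.8 * X["a"]
        y = (X["a"] + X["c"] + rng.normal(size=n) > 0).astype(int)
        ranking = mrmr_select(X, y, k=5).ranking

        # independent oracle: same MID greedy but MI via sklearn on the same
        # quantile bins
        def bins(v):
            edges = np.unique(np.quantile(v, np.linspace(0, 1, 9)[1:-1]))
            return np.searchsorted(edges, v, side="right")

        cols = sorted(X.columns)
        selected = []
        remaining = list(cols)
        by = bins(y.to_numpy())
        while remaining:
            scores = []
            for c in remaining:
                rel = mutual_info_score(bins(X[c]), by)
                red = (np.mean([mutual_info_score(bins(X[c]), bins(X[s]))
                                for s in selected]) if selected else 0.0)
                scores.append((rel - red, c))
            scores.sort(key=lambda t: (-t[0], t[1]))
            selected.append(scores[0][1])
            remaining.remove(scores[0][1])
        assert ranking == selected

    def test_k_too_large_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            mrmr_select(df, np.array([0, 1, 0]), k=2)


class TestSplit:
    def test_sizes_650_150_200(self):
        y = np.repeat([0, 1], 500)
        tr, va, te = split_train_val_test(y, seed=0)
        assert (len(tr), len(va), len(te)) == (650, 150, 200)

    def test_determinism_and_seed_sensitivity(self):
        y = np.repeat([0, 1], 100)
        s1 = split_train_val_test(y, seed=5)
        s2 = split_train_val_test(y, seed=5)
        s3 = split_train_val_test(y, seed=6)
        for a, b in zip(s1, s2):
            assert np.array_equal(a, b)
        assert any(not np.array_equal(a, b) for a, b in zip(s1, s3))

    def test_partition_is_disjoint_and_exhaustive(self):
        y = np.random.default_rng(0).integers(0, 2, 333)
        tr, va, te = split_train_val_test(y, seed=1)
        allidx = np.concatenate([tr, va, te])
        assert len(set(allidx)) == len(allidx) == 333

    def test_stratification_preserves_class_balance(self):
        y = np.r_[np.zeros(900), np.ones(100)].astype(int)
        tr, va, te = split_train_val_test(y, seed=2)
        for part in (tr, va, te):
            assert 0.05 <= y[part].mean() <= 0.15


class TestMetrics:
    def test_mcc_worked_confusion_matrix(self):
        assert mcc_from_counts(40, 10, 10, 40) == pytest.approx(0.6, abs=1e-12)

    def test_mcc_degenerate_returns_zero(self):
        assert mcc_from_counts(10, 0, 0, 0) == 0.0

    def test_separable_data_perfect_scores(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(400, 2))
        y = (x[:, 0] > 0).astype(int)
        rep = train_and_evaluate(pd.DataFrame(x, columns=["a", "b"]), y,
                                 model_family="lr", hyper_grid={"C": [1.0]},
                                 seed=0)
        assert rep.auc == 1.0
        assert rep.mcc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_and_evaluate(pd.DataFrame({"a": [1.0, 2.0]}),
                               np.array([1, 1]), "lr")


def _additive_predict(w):
    return lambda X: X @ w


class TestShapley:
    def test_additive_model_exact_attributions(self):
        rng = np.random.default_rng(0)
        w = np.array([2.0, -1.0, 0.5])
        bg = rng.normal(size=(50, 3))
        inst = rng.normal(size=(4, 3))
        attr = shapley_attributions(_additive_predict(w), bg, inst, mode="exact")
        expect = w * (inst - bg.mean(axis=0))
        assert np.allclose(attr.values, expect, atol=1e-10)

    def test_efficiency_axiom_exact_mode(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(30, 5))
        inst = rng.normal(size=(6, 5))
        predict = lambda X: np.tanh(X[:, 0] * X[:, 1]) + X[:, 2] ** 2
        attr = shapley_attributions(predict, bg, inst, mode="exact")
        total = attr.values.sum(axis=1)
        expect = predict(inst) - predict(bg).mean()
        assert np.allclose(total, expect, atol=1e-8)

    def test_symmetry_for_interchangeable_features(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(size=(40, 2))
        bg[:, 1] = bg[:, 0]  # identical background marginals
        inst = np.array([[1.3, 1.3], [-0.4, -0.4]])
        predict = lambda X: X[:, 0] + X[:, 1]
        attr = shapley_attributions(predict, bg, inst, mode="exact")
        assert np.allclose(attr.values[:, 0], attr.values[:, 1], atol=1e-10)

    def test_sampling_within_three_mc_ses_of_exact(self):
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(3)
        p = 8
        Xtr = rng.normal(size=(300, p))
        ytr = Xtr[:, 0] * 2 + (Xtr[:, 1] > 0) * 1.5 + rng.normal(size=300) * 0.1
        tree = DecisionTreeRegressor(max_depth=4, random_state=0).fit(Xtr, ytr)
        predict = tree.predict
        bg = Xtr[:40]
        inst = Xtr[300 - 5:]
        exact = shapley_attributions(predict, bg, inst, mode="exact")
        samp = shapley_attributions(predict, bg, inst, mode="sampling",
                                    n_permutations=300, seed=0)
        diff = np.abs(samp.values - exact.values)
        assert (diff <= np.maximum(3 * samp.se, 1e-6) + 1e-9).mean() > 0.95

    def test_sampling_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(20, 4))
        inst = rng.normal(size=(3, 4))
        predict = lambda X: X.sum(axis=1)
        a = shapley_attributions(predict, bg, inst, "sampling",
                                 n_permutations=20, seed=9)
        b = shapley_attributions(predict, bg, inst, "sampling",
                                 n_permutations=20, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            shapley_attributions(lambda X: X.sum(1), np.empty((0, 2)),
                                 np.ones((1, 2)))

    def test_exact_mode_feature_limit(self):
        with pytest.raises(ValueError):
            shapley_attributions(lambda X: X.sum(1), np.ones((5, 13)),
                                 np.ones((1, 13)), mode="exact")


class TestMutualInformation:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        mi = mutual_information(rng.normal(size=5000), rng.normal(size=5000))
        assert mi < 0.02

    def test_deterministic_relation_high(self):
        x = np.linspace(0, 1, 1000)
        assert mutual_information(x, x) > 1.5

    def test_constant_feature_zero(self):
        rng = np.random.default_rng(1)
        assert mutual_information(np.ones(100), rng.integers(0, 2, 100)) == 0.0
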