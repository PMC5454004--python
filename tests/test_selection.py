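"""Entropy, MDL information gain, feature ranking and the CV harness."""

import numpy as np
import pandas as pd
import pytest

import fxscreen as fx
from fxscreen.selection import optimized_profile


class TestEntropy:
    def test_maximum_binary_entropy(self):
        assert fx.entropy([0, 1] * 25) == pytest.approx(1.0)

    def test_degenerate_distribution(self):
        assert fx.entropy(["a"] * 9) == 0.0

    def test_six_of_eight(self):
        assert fx.entropy([1] * 6 + [0] * 2) == pytest.approx(0.8113, abs=1e-4)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            fx.entropy([])


class TestInformationGain:
    def test_perfect_predictor_reaches_class_entropy(self):
        y = [0] * 10 + [1] * 10
        x = [0.0] * 10 + [1.0] * 10
        r = fx.information_gain(x, y)
        assert r.gain == pytest.approx(fx.entropy(y))
        assert len(r.cut_points) == 1

    def test_constant_feature_has_zero_gain(self):
        r = fx.information_gain([3.0] * 20, [0, 1] * 10)
        assert r.gain == 0.0
        assert r.cut_points == ()

    def test_two_by_two_table_with_given_bins(self):
        # bins {A: 4, B: 4}, class purity 3:1 within each bin
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        y = [1, 1, 1, 0, 0, 0, 0, 1]
        r = fx.information_gain(x, y, cut_points=[0.5])
        assert r.gain == pytest.approx(1 - 0.8113, abs=1e-4)

    def test_constant_labels_are_error(self):
        with pytest.raises(ValueError):
            fx.information_gain([1.0, 2.0, 3.0], [1, 1, 1])

    def test_gain_bounded_by_class_entropy(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            r = fx.information_gain(x, y)
            assert 0.0 <= r.gain <= fx.entropy(y) + 1e-12

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        x = rng.normal(size=80) + y  # informative feature
        base = fx.information_gain(x, y).gain
        for f in (lambda v: 3 * v + 1, lambda v: v**3, lambda v: -v, np.exp):
            assert fx.information_gain(f(x), y).gain == pytest.approx(base)


class TestRankFeatures:
    def test_perfect_predictor_ranked_first(self, rng):
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"f{i}" for i in range(6)])
        X["oracle"] = y.astype(float)
        ranking = fx.rank_features(X, y)
        assert ranking[0].feature == "oracle"
        assert ranking[0].gain == pytest.approx(1.0)

    def test_all_noise_gets_zero_gain_under_mdl(self, rng):
        y = np.repeat([0, 1], 100)
        X = pd.DataFrame(
            rng.normal(size=(200, 20)), columns=[f"n{i}" for i in range(20)]
        )
        ranking = fx.rank_features(X, y)
        assert optimized_profile(ranking) == []

    def test_injected_informative_features_rank_in_top_ten(self, rng):
        y = np.repeat([0, 1], 50)
        X = pd.DataFrame(
            rng.normal(size=(100, 40)), columns=[f"noise{i}" for i in range(40)]
        )
        informative = [f"signal{i}" for i in range(5)]
        for name in informative:
            X[name] = rng.normal(size=100) + 2.0 * y
        ranking = fx.rank_features(X, y)
        top10 = [r.feature for r in ranking[:10]]
        assert set(informative) <= set(top10)

    def test_ties_broken_by_column_order(self, rng):
        y = np.repeat([0, 1], 10)
        X = pd.DataFrame({"a": np.zeros(20), "b": np.zeros(20)})
        ranking = fx.rank_features(X, y)
        assert [r.feature for r in ranking] == ["a", "b"]


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(3)
    y = np.repeat(["comparison", "carrier"], 30)
    X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
    X["sep"] = (y == "carrier") * 10.0 + rng.normal(scale=0.1, size=60)
    return X, y


class TestCrossValidate:

    def test_same_seed_reproduces_folds_and_metrics(self, separable):
        X, y = separable
        spec = fx.ModelSpec("logistic_regression", seed=5)
        r1 = fx.cross_validate(X, y, spec, k=5, select=False, seed=5)
        r2 = fx.cross_validate(X, y, spec, k=5, select=False, seed=5)
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        assert r1.summary == r2.summary

    @pytest.mark.parametrize(
        "algorithm", ["logistic_regression", "naive_bayes", "decision_tree",
                      "adaboost", "random_forest"]
    )
    def test_linearly_separable_data_is_learned(self, separable, algorithm):
        X, y = separable
        hp = {"n_estimators": 50} if algorithm == "random_forest" else {}
        spec = fx.ModelSpec(algorithm, hp, seed=0)
        res = fx.cross_validate(X, y, spec, k=5, select=False, seed=0)
        assert res.summary["accuracy"] == 1.0

    def test_fold_partition_invariants(self, separable):
        X, y = separable
        res = fx.cross_validate(
            X, y, fx.ModelSpec("naive_bayes"), k=7, select=False, seed=1
        )
        folds = res.fold_assignments
        assert folds.min() >= 0  # exhaustive
        sizes = np.bincount(folds, minlength=7)
        assert sizes.max() - sizes.min() <= 1
        y_bin = (np.asarray(y) == "carrier").astype(int)
        global_ratio = y_bin.mean()
        for f in range(7):
            in_fold = y_bin[folds == f]
            assert abs(in_fold.sum() - global_ratio * in_fold.size) <= 1

    def test_permuted_labels_give_chance_auc(self, rng):
        aucs = []
        for s in range(20):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(size=(60, 5)))
            y = np.repeat([0, 1], 30)
            r.shuffle(y)
            res = fx.cross_validate(
                X, y, fx.ModelSpec("logistic_regression", seed=s),
                k=5, select=False, seed=s,
            )
            aucs.append(res.summary["auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_too_few_per_class_is_error(self):
        X = pd.DataFrame(np.zeros((12, 2)))
        y = ["carrier"] * 2 + ["comparison"] * 10
        with pytest.raises(ValueError):
            fx.cross_validate(X, y, fx.ModelSpec("naive_bayes"), k=10)

    def test_selection_happens_inside_training_folds(self, separable):
        X, y = separable
        res = fx.cross_validate(
            X, y, fx.ModelSpec("decision_tree"), k=5, select=True, seed=2
        )
        assert len(res.fold_features) == 5
        # the separating feature must be selected in every fold
        assert all("sep" in feats for feats in res.fold_features)
        assert not res.mean_gains().empty


class TestIndependentEvaluation:
    def test_correct_classification_gives_f1_one(self, separable_table=None):
        rng = np.random.default_rng(9)
        y = np.repeat(["comparison", "carrier"], 20)
        X = pd.DataFrame({"sep": (y == "carrier") * 5.0 + rng.normal(0, 0.1, 40)})
        X.index = [f"train{i}" for i in range(40)]
        fitted = fx.train_model(X, y, fx.ModelSpec("logistic_regression"), select=False)
        X_test = pd.DataFrame(
            {"sep": [5.1, 4.9, 0.1, -0.1]}, index=[f"test{i}" for i in range(4)]
        )
        out = fx.evaluate_independent(fitted, X_test, ["carrier", "carrier",
                                                       "comparison", "comparison"])
        assert out["f1"] == 1.0
        assert out["auc"] == 1.0

    def test_train_test_overlap_is_error(self):
        y = np.repeat(["comparison", "carrier"], 5)
        X = pd.DataFrame({"x": np.arange(10.0)}, index=[f"p{i}" for i in range(10)])
        fitted = fx.train_model(X, y, fx.ModelSpec("naive_bayes"), select=False)
        with pytest.raises(ValueError, match="overlap"):
            fx.evaluate_independent(fitted, X.iloc[:2], y[:2])
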