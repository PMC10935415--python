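"""The eight activity-model algorithms: exact rules, invariants, round-trips."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.naive_bayes import GaussianNB as SklearnGaussianNB

from zincscreen.classifiers import (
    ASCClassifier,
    IBkClassifier,
    J48Classifier,
    NaiveBayesClassifier,
    OneRClassifier,
    ZeroRClassifier,
    fit,
    j48_best_split,
    make_classifier,
    model_from_jsonable,
    model_to_jsonable,
)


def toy(n=40, seed=0, sep=2.0, d=2):
    rng = np.random.default_rng(seed)
    y = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2))
    X = rng.normal(0, 1, (n, d))
    X[:, 0] += np.where(y == "high", sep, 0.0)
    return X, y


class TestNaiveBayes:
    def test_symmetric_toy_posterior_is_half(self):
        nb = NaiveBayesClassifier().fit(np.array([[-1.0], [1.0]]), np.array(["A", "B"]))
        proba = nb.predict_proba(np.array([[0.0]]))
        np.testing.assert_allclose(proba, [[0.5, 0.5]])

    def test_hand_computed_posterior(self):
        # priors 0.6/0.4; equal means, sigmas chosen so the densities at the
        # query are 0.5 and 0.1 -> posterior(A) = 0.3/0.34 = 0.882353
        sigma_a = 1.0 / (0.5 * math.sqrt(2 * math.pi))
        sigma_b = 1.0 / (0.1 * math.sqrt(2 * math.pi))
        nb = model_from_jsonable(
            {
                "algorithm": "nb", "sd_floor": 1e-6, "classes": ["A", "B"],
                "n_features_in": 1, "priors": [0.6, 0.4],
                "theta": [[0.0], [0.0]], "sigma": [[sigma_a], [sigma_b]],
            }
        )
        proba = nb.predict_proba(np.array([[0.0]]))
        assert proba[0, 0] == pytest.approx(0.6 * 0.5 / (0.6 * 0.5 + 0.4 * 0.1), abs=1e-12)

    def test_posteriors_sum_to_one(self):
        X, y = toy(seed=1)
        nb = NaiveBayesClassifier().fit(X, y)
        proba = nb.predict_proba(np.vstack([X, [[50.0, -50.0]]]))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_posterior_monotone_in_prior(self):
        X, y = toy(seed=2)
        nb = NaiveBayesClassifier().fit(X, y)
        q = X[:5]
        base = nb.predict_proba(q)[:, 0]
        boosted = model_to_jsonable(nb)
        boosted["priors"] = [0.9, 0.1]
        nb2 = model_from_jsonable(boosted)
        assert (nb2.predict_proba(q)[:, 0] >= base - 1e-12).all()

    def test_matches_sklearn_gaussian_nb(self):
        X, y = toy(n=60, seed=3)
        ours = NaiveBayesClassifier(sd_floor=0.0).fit(X, y)
        ref = SklearnGaussianNB(var_smoothing=0.0).fit(X, y)
        np.testing.assert_array_equal(ours.predict(X), ref.predict(X))
        np.testing.assert_allclose(
            ours.predict_proba(X), ref.predict_proba(X), atol=1e-9
        )


class TestIBk:
    def test_k1_returns_nearest_training_label(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array(["A", "A", "B", "B"])
        m = IBkClassifier(k=1).fit(X, y)
        assert list(m.predict(X)) == list(y)
        assert m.predict(np.array([[1.05]]))[0] == "A"

    def test_k_equals_n_predicts_majority_everywhere(self):
        X, y = toy(n=30, seed=4)
        y[:20] = "high"
        m = IBkClassifier(k=30).fit(X, y)
        preds = m.predict(np.array([[100.0, 100.0], [-100.0, 0.0]]))
        assert set(preds) == {"high"}

    def test_invariant_to_feature_permutation_and_affine_rescale(self):
        X, y = toy(n=30, seed=5)
        q = np.array([[0.3, -0.2], [1.5, 0.7]])
        m = IBkClassifier(k=3).fit(X, y)
        base = m.predict(q)
        perm = IBkClassifier(k=3).fit(X[:, ::-1], y)
        np.testing.assert_array_equal(perm.predict(q[:, ::-1]), base)
        scaled = X.copy()
        scaled[:, 0] = scaled[:, 0] * 7.0 - 3.0  # min-max scaling absorbs this
        qs = q.copy()
        qs[:, 0] = qs[:, 0] * 7.0 - 3.0
        np.testing.assert_array_equal(IBkClassifier(k=3).fit(scaled, y).predict(qs), base)

    def test_k_out_of_range_rejected(self):
        X, y = toy(n=10)
        with pytest.raises(ValueError):
            IBkClassifier(k=11).fit(X, y)


class TestJ48:
    def test_best_split_hand_example(self):
        t, gr = j48_best_split(np.array([1.0, 2.0, 3.0, 4.0]), np.array(list("AABB")), min_obj=1)
        assert t == 2.5
        assert gr == pytest.approx(1.0)  # 1 bit of gain / 1 bit of split info

    def test_pure_labels_give_no_split(self):
        assert j48_best_split(np.array([1.0, 2.0, 3.0]), np.array(list("AAA"))) is None
        assert j48_best_split(np.ones(5), np.array(list("AABBA"))) is None

    def test_best_split_matches_bruteforce_over_midpoints(self):
        def entropy(labels):
            _, c = np.unique(labels, return_counts=True)
            p = c / c.sum()
            return -(p * np.log2(p)).sum()

        rng = np.random.default_rng(6)
        for _ in range(25):
            x = rng.normal(0, 1, 20)
            y = rng.choice(["A", "B"], 20)
            res = j48_best_split(x, y, min_obj=2)
            xs = np.unique(x)
            best = 0.0
            for a, b in zip(xs[:-1], xs[1:]):
                t = (a + b) / 2
                left = x <= t
                nl = left.sum()
                if nl < 2 or len(x) - nl < 2:
                    continue
                gain = entropy(y) - nl / 20 * entropy(y[left]) - (20 - nl) / 20 * entropy(y[~left])
                if gain <= 1e-12:
                    continue
                si = -(nl / 20) * np.log2(nl / 20) - ((20 - nl) / 20) * np.log2((20 - nl) / 20)
                best = max(best, gain / si)
            if res is None:
                assert best == 0.0
            else:
                assert res[1] == pytest.approx(best, abs=1e-12)

    def test_min_obj_at_n_forces_majority_leaf(self):
        X, y = toy(n=20, seed=7)
        m = J48Classifier(min_obj=20).fit(X, y)
        assert m.tree_["leaf"]
        assert m.depth() == 0

    def test_training_accuracy_non_increasing_in_min_obj(self):
        X, y = toy(n=80, seed=8, sep=1.0)
        accs = []
        for mo in (1, 2, 4, 8, 16, 40):
            m = J48Classifier(min_obj=mo, pruned=False).fit(X, y)
            accs.append((m.predict(X) == y).mean())
        assert all(a >= b - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_pruning_never_deepens_tree(self):
        X, y = toy(n=80, seed=9, sep=0.5)
        grown = J48Classifier(min_obj=2, pruned=False).fit(X, y)
        pruned = J48Classifier(min_obj=2, pruned=True).fit(X, y)
        assert pruned.depth() <= grown.depth()


class TestRuleLearners:
    def test_zeror_majority(self):
        X = np.zeros((10, 1))
        y = np.array(["high"] * 7 + ["low"] * 3)
        m = ZeroRClassifier().fit(X, y)
        assert set(m.predict(np.ones((4, 1)))) == {"high"}
        np.testing.assert_allclose(m.predict_proba(X[:1]), [[0.7, 0.3]])

    def test_zeror_tie_breaks_lexicographically(self):
        m = ZeroRClassifier().fit(np.zeros((4, 1)), np.array(["b", "a", "b", "a"]))
        assert m.majority_ == "a"

    def test_oner_learns_threshold_rule(self):
        X = np.column_stack([np.arange(20.0), np.zeros(20)])
        y = np.array(["A"] * 10 + ["B"] * 10)
        m = OneRClassifier(min_bucket=3).fit(X, y)
        assert m.feature_index_ == 0
        # greedy bucketing may misplace at most one boundary instance here
        assert m.training_errors_ <= 1
        assert list(m.predict(np.array([[2.0, 9.9], [17.0, -3.0]]))) == ["A", "B"]

    def test_oner_picks_lowest_error_feature(self):
        rng = np.random.default_rng(10)
        y = np.array(["A"] * 30 + ["B"] * 30)
        X = np.column_stack([rng.normal(0, 1, 60), np.where(y == "A", 0.0, 1.0)])
        m = OneRClassifier(min_bucket=6).fit(X, y)
        assert m.feature_index_ == 1


class TestASC:
    def test_selector_returning_all_features_reproduces_base(self):
        # single informative feature: CFS keeps it (the whole feature set)
        rng = np.random.default_rng(11)
        y = np.array(["high"] * 20 + ["low"] * 20)
        X = ((y == "high") * 2.0 + rng.normal(0, 1, 40)).reshape(-1, 1)
        asc = ASCClassifier(NaiveBayesClassifier()).fit(X, y)
        nb = NaiveBayesClassifier().fit(X, y)
        np.testing.assert_array_equal(asc.predict(X), nb.predict(X))
        assert list(asc.selected_indices_) == [0]

    def test_asc_filters_noise_before_fitting(self):
        X, y = toy(n=60, seed=12, sep=3.0, d=5)
        asc = ASCClassifier(NaiveBayesClassifier()).fit(X, y)
        assert 0 in asc.selected_indices_
        assert len(asc.selected_indices_) < 5


class TestFactoryAndSerialization:
    @pytest.mark.parametrize(
        "name, params",
        [
            ("nb", {}),
            ("ibk", {"k": 3}),
            ("j48", {"min_obj": 2}),
            ("zeror", {}),
            ("oner", {"min_bucket": 4}),
            ("asc_nb", {}),
        ],
    )
    def test_json_round_trip_preserves_predictions(self, name, params):
        X, y = toy(n=40, seed=13)
        model = fit(name, X, y, hyperparams=params)
        blob = json.dumps(model_to_jsonable(model))
        back = model_from_jsonable(json.loads(blob))
        q = np.random.default_rng(0).normal(0, 2, (15, 2))
        np.testing.assert_array_equal(model.predict(q), back.predict(q))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            make_classifier("svm")

    def test_dataframe_input_aligns_columns_by_name(self):
        X, y = toy(n=30, seed=14)
        df = pd.DataFrame(X, columns=["a", "b"])
        m = NaiveBayesClassifier().fit(df, y)
        swapped = df[["b", "a"]]
        np.testing.assert_array_equal(m.predict(swapped), m.predict(df))

    def test_one_class_training_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            NaiveBayesClassifier().fit(np.zeros((5, 1)), np.array(["a"] * 5))

    def test_sklearn_clone_compatibility(self):
        for name in ("nb", "ibk", "j48", "zeror", "oner", "asc_nb"):
            est = make_classifier(name)
            cloned = clone(est)  # raises if the estimator contract is broken
            assert repr(cloned) == repr(est)
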