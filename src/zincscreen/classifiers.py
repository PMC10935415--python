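"""Interpretable classifiers for two-class activity modelling.

The activity models used throughout the pipeline favour interpretability:
a Gaussian naive Bayes (:class:`NaiveBayesClassifier`), a k-nearest-
neighbour lazy learner on min-max standardized features
(:class:`IBkClassifier`), a C4.5-style gain-ratio decision tree with
pessimistic pruning (:class:`J48Classifier`), the majority-class baseline
(:class:`ZeroRClassifier`), the single-attribute rule learner
(:class:`OneRClassifier`), and an attribute-selected meta-classifier
(:class:`ASCClassifier`) that runs correlation-based feature selection
before fitting its base learner.

All classifiers follow the scikit-learn estimator contract (``fit`` /
``predict`` / ``predict_proba`` where probabilities are defined,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) and therefore compose with pipelines and model selection.
Only binary problems are supported; class labels may be any two hashable
values and are ordered lexicographically in ``classes_``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta
from sklearn.base import BaseEstimator, ClassifierMixin, clone

__all__ = [
    "NaiveBayesClassifier",
    "IBkClassifier",
    "J48Classifier",
    "ZeroRClassifier",
    "OneRClassifier",
    "ASCClassifier",
    "make_classifier",
    "fit",
    "j48_best_split",
    "model_to_jsonable",
    "model_from_jsonable",
    "ALGORITHMS",
]

_EPS_GAIN = 1e-12


def _as_matrix(X, feature_names=None) -> np.ndarray:
    """2D float array; DataFrames are reordered to the fitted column order."""
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X[list(feature_names)]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D feature matrix")
    return arr


class _TwoClassMixin:
    """Shared fit-time validation for the binary learners."""

    def _start_fit(self, X, y, *, allow_one_class: bool = False):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xa = _as_matrix(X)
        ya = np.asarray(y)
        if len(ya) != len(Xa):
            raise ValueError("X and y length mismatch")
        if len(Xa) < 2:
            raise ValueError("need at least 2 training instances")
        classes = np.unique(ya)
        if len(classes) != 2 and not (allow_one_class and len(classes) == 1):
            raise ValueError("binary classification only: need exactly 2 classes")
        self.classes_ = classes
        self.n_features_in_ = Xa.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return Xa, ya

    def _query(self, X) -> np.ndarray:
        Xa = _as_matrix(X, getattr(self, "feature_names_in_", None))
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {Xa.shape[1]} features, model expects {self.n_features_in_}"
            )
        return Xa

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class NaiveBayesClassifier(_TwoClassMixin, ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes with per-class univariate normal densities.

    Class priors are maximum-likelihood frequencies; each feature gets a
    per-class mean and standard deviation, the latter floored at
    ``sd_floor`` to avoid singular likelihoods on constant features.
    """

    def __init__(self, sd_floor: float = 1e-6):
        self.sd_floor = sd_floor

    def fit(self, X, y):
        Xa, ya = self._start_fit(X, y)
        self.priors_ = np.array([(ya == c).mean() for c in self.classes_])
        self.theta_ = np.vstack([Xa[ya == c].mean(axis=0) for c in self.classes_])
        sds = np.vstack([Xa[ya == c].std(axis=0, ddof=0) for c in self.classes_])
        self.sigma_ = np.maximum(sds, self.sd_floor)
        return self

    def _joint_log_likelihood(self, Xa: np.ndarray) -> np.ndarray:
        jll = np.empty((len(Xa), 2))
        for k in range(2):
            z = (Xa - self.theta_[k]) / self.sigma_[k]
            log_dens = -0.5 * z**2 - np.log(self.sigma_[k]) - 0.5 * np.log(2 * np.pi)
            jll[:, k] = np.log(self.priors_[k]) + log_dens.sum(axis=1)
        return jll

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(self._query(X))
        # normalize in probability space after shifting by the row max: the
        # shifted exponentials are O(1), so the row sum is exactly 1 even when
        # the floored sd pushes |log-likelihood| far beyond float64 resolution
        shifted = np.exp(jll - jll.max(axis=1, keepdims=True))
        return shifted / shifted.sum(axis=1, keepdims=True)

    def decision_scores(self, X, positive) -> np.ndarray:
        """Posterior probability of the ``positive`` class."""
        idx = int(np.where(self.classes_ == positive)[0][0])
        return self.predict_proba(X)[:, idx]


class IBkClassifier(_TwoClassMixin, ClassifierMixin, BaseEstimator):
    """k-nearest neighbours with Euclidean distance on min-max scaled features.

    Features are standardized to [0, 1] using the training ranges (constant
    features contribute nothing to the distance). Vote ties among the k
    neighbours are broken toward the class with the smaller mean neighbour
    distance, then lexicographically.
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        Xa, ya = self._start_fit(X, y)
        if not 1 <= self.k <= len(Xa):
            raise ValueError(f"k={self.k} outside [1, n={len(Xa)}]")
        self.data_min_ = Xa.min(axis=0)
        rng = Xa.max(axis=0) - self.data_min_
        self.data_range_ = np.where(rng == 0, 1.0, rng)
        self._train_scaled = (Xa - self.data_min_) / self.data_range_
        self._train_y = ya
        return self

    def _scale(self, Xa: np.ndarray) -> np.ndarray:
        return (Xa - self.data_min_) / self.data_range_

    def predict_proba(self, X):
        Q = self._scale(self._query(X))
        out = np.zeros((len(Q), 2))
        for i, q in enumerate(Q):
            d = np.sqrt(((self._train_scaled - q) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[: self.k]
            votes = self._train_y[order]
            counts = np.array([(votes == c).sum() for c in self.classes_])
            out[i] = counts / self.k
        return out

    def predict(self, X):
        Q = self._scale(self._query(X))
        labels = []
        for q in Q:
            d = np.sqrt(((self._train_scaled - q) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[: self.k]
            votes, dists = self._train_y[order], d[order]
            counts = {c: int((votes == c).sum()) for c in self.classes_}
            best = max(counts.values())
            tied = sorted(c for c, n in counts.items() if n == best)
            if len(tied) > 1:
                mean_d = {c: float(dists[votes == c].mean()) for c in tied}
                low = min(mean_d.values())
                tied = sorted(c for c, m in mean_d.items() if m == low)
            labels.append(tied[0])
        return np.asarray(labels)


def _entropy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def j48_best_split(
    values: np.ndarray, labels: np.ndarray, min_obj: int = 2
) -> tuple[float, float] | None:
    """Best binary threshold on one numeric column by gain ratio.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; a candidate is admissible only if both sides hold at least
    ``min_obj`` instances. Returns ``(threshold, gain_ratio)`` or ``None``
    when no admissible split improves on zero information gain (including
    all-equal values and pure label columns).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    distinct = np.unique(xs)
    if len(distinct) < 2:
        return None
    h_total = _entropy(ys)
    n = len(ys)
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        t = (a + b) / 2
        left = xs <= t
        nl = int(left.sum())
        if nl < min_obj or n - nl < min_obj:
            continue
        gain = h_total - (nl / n) * _entropy(ys[left]) - ((n - nl) / n) * _entropy(ys[~left])
        if gain <= _EPS_GAIN:
            continue
        si = -(nl / n) * np.log2(nl / n) - ((n - nl) / n) * np.log2((n - nl) / n)
        gr = gain / si
        if best is None or gr > best[1] + 1e-15:
            best = (float(t), float(gr))
    return best


def _pessimistic_errors(n: int, e: int, cf: float) -> float:
    """C4.5 predicted error count: n times the binomial upper error bound."""
    if n == 0:
        return 0.0
    if e >= n:
        return float(n)
    return float(n * beta.ppf(1.0 - cf, e + 1, n - e))


class J48Classifier(_TwoClassMixin, ClassifierMixin, BaseEstimator):
    """C4.5-style binary-threshold decision tree.

    Splits maximize gain ratio subject to every leaf holding at least
    ``min_obj`` training instances; pessimistic error pruning with
    confidence ``cf`` (subtree replacement only) is applied when
    ``pruned``. ``min_obj >= n`` degenerates to a single majority leaf.
    """

    def __init__(self, min_obj: int = 2, pruned: bool = True, cf: float = 0.25):
        self.min_obj = min_obj
        self.pruned = pruned
        self.cf = cf

    def fit(self, X, y):
        Xa, ya = self._start_fit(X, y)
        if self.min_obj < 1:
            raise ValueError("min_obj must be a positive integer")
        self.tree_ = self._grow(Xa, ya)
        if self.pruned:
            self.tree_ = self._prune(self.tree_)
        return self

    def _counts(self, ya: np.ndarray) -> list[int]:
        return [int((ya == c).sum()) for c in self.classes_]

    def _leaf(self, ya: np.ndarray) -> dict:
        counts = self._counts(ya)
        best = max(counts)
        label = sorted(c for c, n in zip(self.classes_, counts) if n == best)[0]
        return {"leaf": True, "counts": counts, "label": label}

    def _grow(self, Xa: np.ndarray, ya: np.ndarray) -> dict:
        if len(np.unique(ya)) == 1 or len(ya) < 2 * self.min_obj:
            return self._leaf(ya)
        best = None  # (gain_ratio, feature, threshold)
        for j in range(Xa.shape[1]):
            res = j48_best_split(Xa[:, j], ya, self.min_obj)
            if res is not None and (best is None or res[1] > best[0] + 1e-15):
                best = (res[1], j, res[0])
        if best is None:
            return self._leaf(ya)
        _, j, t = best
        left = Xa[:, j] <= t
        return {
            "leaf": False,
            "feature": int(j),
            "threshold": float(t),
            "counts": self._counts(ya),
            "left": self._grow(Xa[left], ya[left]),
            "right": self._grow(Xa[~left], ya[~left]),
        }

    def _subtree_errors(self, node: dict) -> float:
        if node["leaf"]:
            n = sum(node["counts"])
            e = n - max(node["counts"])
            return _pessimistic_errors(n, e, self.cf)
        return self._subtree_errors(node["left"]) + self._subtree_errors(node["right"])

    def _prune(self, node: dict) -> dict:
        if node["leaf"]:
            return node
        node = {**node, "left": self._prune(node["left"]), "right": self._prune(node["right"])}
        n = sum(node["counts"])
        e_leaf = n - max(node["counts"])
        if _pessimistic_errors(n, e_leaf, self.cf) <= self._subtree_errors(node) + 1e-9:
            best = max(node["counts"])
            label = sorted(
                c for c, k in zip(self.classes_, node["counts"]) if k == best
            )[0]
            return {"leaf": True, "counts": node["counts"], "label": label}
        return node

    def _walk(self, node: dict, x: np.ndarray) -> dict:
        while not node["leaf"]:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        return node

    def predict(self, X):
        Xa = self._query(X)
        return np.asarray([self._walk(self.tree_, x)["label"] for x in Xa])

    def predict_proba(self, X):
        Xa = self._query(X)
        out = np.zeros((len(Xa), 2))
        for i, x in enumerate(Xa):
            counts = np.asarray(self._walk(self.tree_, x)["counts"], dtype=float)
            total = counts.sum()
            out[i] = counts / total if total else 0.5
        return out

    def depth(self) -> int:
        def d(node):
            return 0 if node["leaf"] else 1 + max(d(node["left"]), d(node["right"]))

        return d(self.tree_)


class ZeroRClassifier(_TwoClassMixin, ClassifierMixin, BaseEstimator):
    """Majority-class baseline; ties go to the lexicographically first label."""

    def fit(self, X, y):
        _, ya = self._start_fit(X, y, allow_one_class=True)
        values, counts = np.unique(ya, return_counts=True)
        best = counts.max()
        self.majority_ = sorted(v for v, c in zip(values, counts) if c == best)[0]
        self.class_fractions_ = {v: c / len(ya) for v, c in zip(values, counts)}
        return self

    def predict(self, X):
        Xa = self._query(X)
        return np.full(len(Xa), self.majority_, dtype=object)

    def predict_proba(self, X):
        Xa = self._query(X)
        p = np.array([self.class_fractions_.get(c, 0.0) for c in self.classes_])
        return np.tile(p, (len(Xa), 1))


class OneRClassifier(_TwoClassMixin, ClassifierMixin, BaseEstimator):
    """Single-attribute rule learner with value bucketing.

    For each feature, training instances are sorted by value and grouped
    greedily into buckets until the bucket's majority class holds at least
    ``min_bucket`` members (equal values never straddle a boundary; a
    trailing underfull bucket merges into its predecessor, and adjacent
    same-class buckets are merged). The feature whose rule makes the fewest
    training errors wins, ties going to the lower column index.
    """

    def __init__(self, min_bucket: int = 6):
        self.min_bucket = min_bucket

    def _build_rule(self, x: np.ndarray, y: np.ndarray):
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        n = len(xs)
        buckets: list[tuple[int, int]] = []
        i = 0
        while i < n:
            j = i
            counts: dict = {}
            while j < n:
                counts[ys[j]] = counts.get(ys[j], 0) + 1
                j += 1
                if max(counts.values()) >= self.min_bucket:
                    break
            while j < n and xs[j] == xs[j - 1]:
                j += 1
            if j < n or max(counts.values()) >= self.min_bucket or not buckets:
                buckets.append((i, j))
            else:  # trailing underfull bucket: merge into predecessor
                buckets[-1] = (buckets[-1][0], j)
            i = j

        def majority(seg):
            vals, cnts = np.unique(ys[seg[0] : seg[1]], return_counts=True)
            best = cnts.max()
            lab = sorted(v for v, c in zip(vals, cnts) if c == best)[0]
            return lab, int(best), seg[1] - seg[0]

        merged: list[tuple[int, int]] = []
        for seg in buckets:
            if merged and majority(merged[-1])[0] == majority(seg)[0]:
                merged[-1] = (merged[-1][0], seg[1])
            else:
                merged.append(seg)

        thresholds, labels, fractions, errors = [], [], [], 0
        for idx, seg in enumerate(merged):
            lab, best, size = majority(seg)
            labels.append(lab)
            fractions.append(best / size)
            errors += size - best
            if idx < len(merged) - 1:
                thresholds.append((xs[seg[1] - 1] + xs[seg[1]]) / 2)
        return np.asarray(thresholds), labels, fractions, errors

    def fit(self, X, y):
        Xa, ya = self._start_fit(X, y)
        best = None
        for j in range(Xa.shape[1]):
            thresholds, labels, fractions, errors = self._build_rule(Xa[:, j], ya)
            if best is None or errors < best[0]:
                best = (errors, j, thresholds, labels, fractions)
        self.training_errors_, self.feature_index_ = best[0], best[1]
        self.thresholds_, self.bucket_labels_, self.bucket_fractions_ = best[2:]
        return self

    def _bucket(self, v: float) -> int:
        return int(np.searchsorted(self.thresholds_, v, side="left"))

    def predict(self, X):
        Xa = self._query(X)
        col = Xa[:, self.feature_index_]
        return np.asarray([self.bucket_labels_[self._bucket(v)] for v in col])

    def predict_proba(self, X):
        Xa = self._query(X)
        out = np.zeros((len(Xa), 2))
        for i, v in enumerate(Xa[:, self.feature_index_]):
            b = self._bucket(v)
            lab, frac = self.bucket_labels_[b], self.bucket_fractions_[b]
            for k, c in enumerate(self.classes_):
                out[i, k] = frac if c == lab else 1.0 - frac
        return out


class ASCClassifier(_TwoClassMixin, ClassifierMixin, BaseEstimator):
    """Attribute-selected meta-classifier.

    Runs correlation-based feature selection (CFS, best-first) on the
    training data and fits a clone of ``base_estimator`` on the selected
    columns. An empty selection falls back to all features, in which case
    the meta-classifier reproduces the base learner exactly.
    """

    def __init__(self, base_estimator=None):
        self.base_estimator = base_estimator

    def fit(self, X, y):
        from .feature_selection import CfsSelector  # deferred: avoids import cycle

        Xa, ya = self._start_fit(X, y)
        selector = CfsSelector().fit(Xa, ya)
        idx = np.flatnonzero(selector.support_)
        self.selected_indices_ = idx if len(idx) else np.arange(Xa.shape[1])
        base = self.base_estimator if self.base_estimator is not None else NaiveBayesClassifier()
        self.base_ = clone(base).fit(Xa[:, self.selected_indices_], ya)
        return self

    def predict(self, X):
        Xa = self._query(X)
        return self.base_.predict(Xa[:, self.selected_indices_])

    def predict_proba(self, X):
        Xa = self._query(X)
        return self.base_.predict_proba(Xa[:, self.selected_indices_])


ALGORITHMS = ("nb", "ibk", "j48", "asc_nb", "asc_ibk", "asc_j48", "zeror", "oner")


def make_classifier(algorithm: str, **hyperparams):
    """Instantiate one of the eight algorithms by its short name.

    Recognized hyperparameters: ``k`` (ibk / asc_ibk), ``min_obj`` and
    ``pruned`` (j48 / asc_j48), ``min_bucket`` (oner), ``sd_floor`` (nb).
    """
    algorithm = algorithm.lower()
    if algorithm == "nb":
        return NaiveBayesClassifier(**hyperparams)
    if algorithm == "ibk":
        return IBkClassifier(**hyperparams)
    if algorithm == "j48":
        return J48Classifier(**hyperparams)
    if algorithm == "zeror":
        return ZeroRClassifier(**hyperparams)
    if algorithm == "oner":
        return OneRClassifier(**hyperparams)
    if algorithm.startswith("asc_"):
        return ASCClassifier(base_estimator=make_classifier(algorithm[4:], **hyperparams))
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def fit(algorithm: str, matrix, class_labels, hyperparams: dict | None = None, seed: int = 0):
    """Fit one algorithm on a feature matrix; thin wrapper over the estimators."""
    model = make_classifier(algorithm, **(hyperparams or {}))
    return model.fit(matrix, class_labels)


def _common_meta(model) -> dict:
    meta = {
        "classes": [str(c) for c in model.classes_],
        "n_features_in": int(model.n_features_in_),
    }
    if hasattr(model, "feature_names_in_"):
        meta["feature_names"] = [str(n) for n in model.feature_names_in_]
    return meta


def model_to_jsonable(model) -> dict:
    """Serialize a fitted classifier to a JSON-compatible dict."""
    if isinstance(model, NaiveBayesClassifier):
        return {
            "algorithm": "nb", "sd_floor": model.sd_floor, **_common_meta(model),
            "priors": model.priors_.tolist(),
            "theta": model.theta_.tolist(), "sigma": model.sigma_.tolist(),
        }
    if isinstance(model, IBkClassifier):
        return {
            "algorithm": "ibk", "k": model.k, **_common_meta(model),
            "data_min": model.data_min_.tolist(), "data_range": model.data_range_.tolist(),
            "train_scaled": model._train_scaled.tolist(),
            "train_y": [str(v) for v in model._train_y],
        }
    if isinstance(model, J48Classifier):
        return {
            "algorithm": "j48", "min_obj": model.min_obj, "pruned": model.pruned,
            "cf": model.cf, **_common_meta(model), "tree": model.tree_,
        }
    if isinstance(model, ZeroRClassifier):
        return {
            "algorithm": "zeror", **_common_meta(model),
            "majority": str(model.majority_),
            "class_fractions": {str(k): v for k, v in model.class_fractions_.items()},
        }
    if isinstance(model, OneRClassifier):
        return {
            "algorithm": "oner", "min_bucket": model.min_bucket, **_common_meta(model),
            "feature_index": int(model.feature_index_),
            "thresholds": np.asarray(model.thresholds_).tolist(),
            "bucket_labels": [str(v) for v in model.bucket_labels_],
            "bucket_fractions": [float(v) for v in model.bucket_fractions_],
            "training_errors": int(model.training_errors_),
        }
    if isinstance(model, ASCClassifier):
        return {
            "algorithm": "asc", **_common_meta(model),
            "selected_indices": model.selected_indices_.tolist(),
            "base": model_to_jsonable(model.base_),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_jsonable(d: dict):
    """Rebuild a fitted classifier from :func:`model_to_jsonable` output."""
    algo = d["algorithm"]
    classes = np.asarray(d["classes"], dtype=object)

    def _finish(m):
        m.classes_ = classes
        m.n_features_in_ = d["n_features_in"]
        if "feature_names" in d:
            m.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        return m

    if algo == "nb":
        m = NaiveBayesClassifier(sd_floor=d["sd_floor"])
        m.priors_ = np.asarray(d["priors"])
        m.theta_ = np.asarray(d["theta"])
        m.sigma_ = np.asarray(d["sigma"])
        return _finish(m)
    if algo == "ibk":
        m = IBkClassifier(k=d["k"])
        m.data_min_ = np.asarray(d["data_min"])
        m.data_range_ = np.asarray(d["data_range"])
        m._train_scaled = np.asarray(d["train_scaled"])
        m._train_y = np.asarray(d["train_y"], dtype=object)
        return _finish(m)
    if algo == "j48":
        m = J48Classifier(min_obj=d["min_obj"], pruned=d["pruned"], cf=d["cf"])
        m.tree_ = d["tree"]
        return _finish(m)
    if algo == "zeror":
        m = ZeroRClassifier()
        m.majority_ = d["majority"]
        m.class_fractions_ = dict(d["class_fractions"])
        return _finish(m)
    if algo == "oner":
        m = OneRClassifier(min_bucket=d["min_bucket"])
        m.feature_index_ = d["feature_index"]
        m.thresholds_ = np.asarray(d["thresholds"])
        m.bucket_labels_ = list(d["bucket_labels"])
        m.bucket_fractions_ = list(d["bucket_fractions"])
        m.training_errors_ = d["training_errors"]
        return _finish(m)
    if algo == "asc":
        m = ASCClassifier()
        m.selected_indices_ = np.asarray(d["selected_indices"], dtype=int)
        m.base_ = model_from_jsonable(d["base"])
        return _finish(m)
    raise ValueError(f"unknown serialized algorithm {algo!r}")
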