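"""Descriptor subset selection: CFS, gain ratio, wrapper, and CFS+wrapper.

Four selection regimes are provided, each as a scikit-learn transformer
(``fit`` + ``transform`` via ``SelectorMixin``) and as a thin function
returning a :class:`FeatureSubset`:

* :class:`CfsSelector` — correlation-based feature selection. Subset merit
  is ``k * r_cf / sqrt(k + k (k-1) r_ff)`` where ``r_cf`` is the mean
  absolute feature-class correlation of the subset and ``r_ff`` the mean
  absolute feature-feature inter-correlation; the subset is found by
  forward best-first search with a stale-expansion budget.
* :class:`GainRatioSelector` — ranks features by the gain ratio of their
  best supervised binary split (C4.5-style); keeps every feature with a
  positive gain ratio unless ``top_k`` caps the count.
* :class:`WrapperSelector` — forward best-first search scored by seeded
  stratified cross-validated accuracy of a base learner (Gaussian naive
  Bayes by default).
* :class:`CfsWrapperSelector` — the wrapper search restricted to the CFS
  subset.

All searches are deterministic given the seed; ties between equally scored
candidates are broken toward the lower column index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureSubset",
    "CfsSelector",
    "GainRatioSelector",
    "WrapperSelector",
    "CfsWrapperSelector",
    "cfs_select",
    "gain_ratio_rank",
    "wrapper_select",
    "cfs_then_wrapper",
    "cfs_merit",
    "gain_ratio",
]


@dataclass
class FeatureSubset:
    """A selected descriptor subset with its score and search trace."""

    method: str  # cfs | gr | wrapper | cfs_wrapper
    names: list[str]
    score: float
    trace: list[dict] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "names": list(self.names),
            "score": self.score,
            "trace": self.trace,
        }


def _point_biserial(x: np.ndarray, y01: np.ndarray) -> float:
    sx = x.std()
    if sx == 0 or y01.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y01)[0, 1])


def cfs_merit(subset: tuple[int, ...], rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit of a feature subset from precomputed |correlations|."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = np.asarray(subset)
    mean_rcf = rcf[idx].mean()
    if k == 1:
        return float(mean_rcf)
    sub = rff[np.ix_(idx, idx)]
    mean_rff = (sub.sum() - np.trace(sub)) / (k * (k - 1))
    return float(k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff))


def _best_first(
    n_features: int,
    candidates: np.ndarray,
    score_fn,
    stale_limit: int,
) -> tuple[tuple[int, ...], float, list[dict]]:
    """Forward best-first subset search with a stale-expansion budget.

    Maintains an open list of scored subsets; repeatedly expands the
    best-scoring one by single-feature additions, stopping after
    ``stale_limit`` consecutive expansions that fail to improve on the best
    subset seen. Deterministic: ties prefer smaller subsets, then
    lexicographically smaller index tuples.
    """
    start: tuple[int, ...] = ()
    best_subset, best_score = start, score_fn(start)
    open_list: dict[tuple[int, ...], float] = {start: best_score}
    visited: set[tuple[int, ...]] = {start}
    trace: list[dict] = []
    stale = 0

    while open_list and stale < stale_limit:
        expand = min(open_list, key=lambda s: (-open_list[s], len(s), s))
        open_list.pop(expand)
        improved = False
        for f in np.flatnonzero(candidates):
            if f in expand:
                continue
            child = tuple(sorted(expand + (int(f),)))
            if child in visited:
                continue
            visited.add(child)
            s = score_fn(child)
            open_list[child] = s
            if s > best_score + 1e-10:
                best_subset, best_score = child, s
                improved = True
        trace.append({"expanded": list(expand), "best_score": best_score})
        stale = 0 if improved else stale + 1
    return best_subset, best_score, trace


def _matrix_and_names(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    Xa = np.asarray(X, dtype=float)
    return Xa, [f"f{j}" for j in range(Xa.shape[1])]


class CfsSelector(SelectorMixin, BaseEstimator):
    """Correlation-based feature selection by forward best-first search."""

    def __init__(self, stale_limit: int = 5):
        self.stale_limit = stale_limit

    def fit(self, X, y):
        Xa, names = _matrix_and_names(X)
        ya = np.asarray(y)
        if Xa.shape[1] < 1:
            raise ValueError("need at least one candidate feature")
        classes = np.unique(ya)
        if len(classes) != 2:
            raise ValueError("CFS requires exactly two classes")
        y01 = (ya == classes[1]).astype(float)

        sds = Xa.std(axis=0)
        candidates = sds > 0
        if not candidates.all():
            warnings.warn(
                f"ignoring {int((~candidates).sum())} constant feature(s) in CFS"
            )
        rcf = np.zeros(Xa.shape[1])
        for j in np.flatnonzero(candidates):
            rcf[j] = abs(_point_biserial(Xa[:, j], y01))
        with np.errstate(invalid="ignore"):
            rff = np.abs(np.corrcoef(Xa, rowvar=False))
        rff = np.nan_to_num(np.atleast_2d(rff), nan=0.0)

        subset, score, trace = _best_first(
            Xa.shape[1], candidates, lambda s: cfs_merit(s, rcf, rff), self.stale_limit
        )
        self.n_features_in_ = Xa.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.zeros(Xa.shape[1], dtype=bool)
        self.support_[list(subset)] = True
        self.merit_ = score
        self.trace_ = trace
        return self

    def _get_support_mask(self):
        return self.support_

    def subset(self) -> FeatureSubset:
        names = [str(n) for n in self.feature_names_in_[self.support_]]
        return FeatureSubset("cfs", names, self.merit_, self.trace_)


def gain_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """Gain ratio of the best supervised binary split of a numeric feature.

    The threshold maximizing information gain is found over midpoints of
    consecutive distinct sorted values; the returned ratio divides that
    gain by the split information. Constant features (or zero best gain)
    score 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    distinct = np.unique(x)
    if len(distinct) < 2:
        return 0.0
    n = len(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    p = np.bincount(y_idx, minlength=len(classes)) / n
    h_total = float(-(p[p > 0] * np.log2(p[p > 0])).sum())

    def entropy(mask):
        if mask.sum() == 0:
            return 0.0
        q = np.bincount(y_idx[mask], minlength=len(classes)) / mask.sum()
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    best_gain, best_si = 0.0, 1.0
    for a, b in zip(distinct[:-1], distinct[1:]):
        t = (a + b) / 2
        left = x <= t
        nl = int(left.sum())
        gain = h_total - (nl / n) * entropy(left) - ((n - nl) / n) * entropy(~left)
        if gain > best_gain + 1e-12:
            best_gain = gain
            best_si = -(nl / n) * np.log2(nl / n) - ((n - nl) / n) * np.log2((n - nl) / n)
    if best_gain <= 1e-12:
        return 0.0
    return float(best_gain / best_si)


class GainRatioSelector(SelectorMixin, BaseEstimator):
    """Rank features by gain ratio; keep positives or the top ``top_k``."""

    def __init__(self, top_k: int | None = None):
        self.top_k = top_k

    def fit(self, X, y):
        Xa, names = _matrix_and_names(X)
        ya = np.asarray(y)
        if len(np.unique(ya)) != 2:
            raise ValueError("gain-ratio ranking requires binary labels")
        scores = np.array([gain_ratio(Xa[:, j], ya) for j in range(Xa.shape[1])])
        order = np.lexsort((np.arange(len(scores)), -scores))
        if self.top_k is not None:
            keep = order[: self.top_k]
        else:
            keep = order[scores[order] > 0]
        self.n_features_in_ = Xa.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.scores_ = scores
        self.ranking_ = order
        self.support_ = np.zeros(Xa.shape[1], dtype=bool)
        self.support_[keep] = True
        return self

    def _get_support_mask(self):
        return self.support_

    def subset(self) -> FeatureSubset:
        names = [str(self.feature_names_in_[j]) for j in self.ranking_ if self.support_[j]]
        score = float(self.scores_.max()) if len(self.scores_) else 0.0
        return FeatureSubset("gr", names, score)


class WrapperSelector(SelectorMixin, BaseEstimator):
    """Forward best-first search scored by cross-validated base-learner accuracy."""

    def __init__(self, estimator=None, folds: int = 5, seed: int = 0, stale_limit: int = 5):
        self.estimator = estimator
        self.folds = folds
        self.seed = seed
        self.stale_limit = stale_limit

    def _cv_accuracy(self, Xa: np.ndarray, ya: np.ndarray, subset: tuple[int, ...]) -> float:
        if len(subset) == 0:
            _, counts = np.unique(ya, return_counts=True)
            return float(counts.max() / len(ya))
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        correct = 0
        base = self.estimator
        if base is None:
            from .classifiers import NaiveBayesClassifier  # deferred: import cycle

            base = NaiveBayesClassifier()
        cols = list(subset)
        for train, test in skf.split(Xa, ya):
            model = clone(base).fit(Xa[np.ix_(train, cols)], ya[train])
            correct += int((model.predict(Xa[np.ix_(test, cols)]) == ya[test]).sum())
        return correct / len(ya)

    def fit(self, X, y):
        Xa, names = _matrix_and_names(X)
        ya = np.asarray(y)
        if len(Xa) < self.folds:
            raise ValueError(f"n={len(Xa)} is smaller than folds={self.folds}")
        candidates = np.ones(Xa.shape[1], dtype=bool)
        subset, score, trace = _best_first(
            Xa.shape[1],
            candidates,
            lambda s: self._cv_accuracy(Xa, ya, s),
            self.stale_limit,
        )
        self.n_features_in_ = Xa.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.zeros(Xa.shape[1], dtype=bool)
        self.support_[list(subset)] = True
        self.cv_accuracy_ = score
        self.trace_ = trace
        return self

    def _get_support_mask(self):
        return self.support_

    def subset(self) -> FeatureSubset:
        names = [str(n) for n in self.feature_names_in_[self.support_]]
        return FeatureSubset("wrapper", names, self.cv_accuracy_, self.trace_)


class CfsWrapperSelector(SelectorMixin, BaseEstimator):
    """Wrapper search restricted to the CFS-selected subset."""

    def __init__(self, estimator=None, folds: int = 5, seed: int = 0, stale_limit: int = 5):
        self.estimator = estimator
        self.folds = folds
        self.seed = seed
        self.stale_limit = stale_limit

    def fit(self, X, y):
        Xa, names = _matrix_and_names(X)
        ya = np.asarray(y)
        cfs = CfsSelector(stale_limit=self.stale_limit).fit(Xa, ya)
        cfs_idx = np.flatnonzero(cfs.support_)
        self.cfs_support_ = cfs.support_
        self.n_features_in_ = Xa.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.zeros(Xa.shape[1], dtype=bool)
        if len(cfs_idx) == 0:
            warnings.warn("CFS returned an empty subset; wrapper stage skipped")
            self.cv_accuracy_ = 0.0
            self.trace_ = []
            return self
        inner = WrapperSelector(
            estimator=self.estimator, folds=self.folds, seed=self.seed,
            stale_limit=self.stale_limit,
        ).fit(Xa[:, cfs_idx], ya)
        self.support_[cfs_idx[inner.support_]] = True
        self.cv_accuracy_ = inner.cv_accuracy_
        self.trace_ = inner.trace_
        return self

    def _get_support_mask(self):
        return self.support_

    def subset(self) -> FeatureSubset:
        names = [str(n) for n in self.feature_names_in_[self.support_]]
        return FeatureSubset("cfs_wrapper", names, self.cv_accuracy_, self.trace_)


def cfs_select(matrix, class_labels, stale_limit: int = 5) -> FeatureSubset:
    """CFS subset of a descriptor matrix (DataFrame or array)."""
    return CfsSelector(stale_limit=stale_limit).fit(matrix, class_labels).subset()


def gain_ratio_rank(matrix, class_labels, top_k: int | None = None) -> FeatureSubset:
    """Gain-ratio ranking; keeps positive-GR features or the top ``top_k``."""
    return GainRatioSelector(top_k=top_k).fit(matrix, class_labels).subset()


def wrapper_select(
    matrix, class_labels, estimator=None, folds: int = 5, seed: int = 0
) -> FeatureSubset:
    """Wrapper subset scored by CV accuracy of the base learner."""
    return (
        WrapperSelector(estimator=estimator, folds=folds, seed=seed)
        .fit(matrix, class_labels)
        .subset()
    )


def cfs_then_wrapper(
    matrix, class_labels, estimator=None, folds: int = 5, seed: int = 0
) -> FeatureSubset:
    """Wrapper search restricted to the CFS subset (Cfs&Wrapper regime)."""
    return (
        CfsWrapperSelector(estimator=estimator, folds=folds, seed=seed)
        .fit(matrix, class_labels)
        .subset()
    )


SELECTORS = {
    "cfs": cfs_select,
    "gr": gain_ratio_rank,
    "wrapper": wrapper_select,
    "cfs_wrapper": cfs_then_wrapper,
}
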