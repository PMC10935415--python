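"""Model evaluation: accuracy metrics, repeated CV, ROC/AUC, replicated splits.

The headline metrics are expressed on the percent scale used in screening
practice:

* classification accuracy = correct / total x 100,
* Active(detected)% = TP / (TP + FP) x 100 — the precision of a screen,
* hit rate HR = TP / A x 100 — recall against the A actives in the whole
  database.

Model selection follows the screening workflow: the modelling set is
re-split into train / internal-test several times, a model is built per
replicate, and the replicate with the best external-test accuracy (AUC,
then replicate index, as tie-breaks) is carried forward to library
screening. ROC curves and AUCs come from scikit-learn's rank-based
implementation (ties receive half credit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .classifiers import make_classifier
from .curation import CuratedDataset, _inner_split
from .feature_selection import SELECTORS

__all__ = [
    "EvalReport",
    "accuracy",
    "active_detected",
    "hit_rate",
    "confusion_counts",
    "cross_validate",
    "roc_auc",
    "replicate_splits",
    "ReplicateReport",
    "learning_curve",
    "plot_roc",
    "plot_learning_curve",
]

POSITIVE_CLASS = "high"


class EvaluationError(ValueError):
    pass


@dataclass
class EvalReport:
    """Confusion counts and derived percentages for one evaluated set."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def active_detected(self) -> float | None:
        return None if self.tp + self.fp == 0 else active_detected(self.tp, self.fp)


def accuracy(predictions, truths) -> float:
    """Classification accuracy in percent: correct / total x 100."""
    p, t = np.asarray(predictions), np.asarray(truths)
    if len(p) == 0 or len(p) != len(t):
        raise EvaluationError("predictions and truths must be equal-length and nonempty")
    return float(100.0 * (p == t).mean())


def active_detected(tp: int, fp: int) -> float:
    """Screen precision in percent: TP / (TP + FP) x 100."""
    if tp + fp <= 0:
        raise EvaluationError("active_detected undefined: no predicted positives")
    return 100.0 * tp / (tp + fp)


def hit_rate(tp: int, a: int) -> float:
    """Database recall in percent: TP / A x 100, A = actives in the database."""
    if a <= 0:
        raise EvaluationError("hit_rate undefined: no actives in the database")
    if tp > a:
        raise EvaluationError("TP cannot exceed the number of actives")
    return 100.0 * tp / a


def confusion_counts(predictions, truths, positive=POSITIVE_CLASS) -> EvalReport:
    p, t = np.asarray(predictions), np.asarray(truths)
    return EvalReport(
        tp=int(((p == positive) & (t == positive)).sum()),
        fp=int(((p == positive) & (t != positive)).sum()),
        tn=int(((p != positive) & (t != positive)).sum()),
        fn=int(((p != positive) & (t == positive)).sum()),
    )


def cross_validate(
    algorithm,
    matrix,
    labels,
    folds: int = 10,
    repeats: int = 10,
    seeds: list[int] | None = None,
    hyperparams: dict | None = None,
) -> dict:
    """Repeated stratified k-fold CV accuracy (percent).

    ``algorithm`` is a short name (see :func:`zincscreen.classifiers.
    make_classifier`) or an unfitted estimator. One stratified fold
    assignment is drawn per repeat from its seed; every instance is tested
    exactly once per repeat. Returns ``cv_mean``, ``cv_sd`` and the
    per-repeat accuracies.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if len(X) < folds:
        raise EvaluationError(f"n={len(X)} smaller than folds={folds}")
    proto = make_classifier(algorithm, **(hyperparams or {})) if isinstance(algorithm, str) else algorithm
    if seeds is None:
        seeds = list(range(repeats))
    per_repeat = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        correct = 0
        for train, test in skf.split(X, y):
            model = clone(proto).fit(X[train], y[train])
            correct += int((model.predict(X[test]) == y[test]).sum())
        per_repeat.append(100.0 * correct / len(y))
    return {
        "cv_mean": float(np.mean(per_repeat)),
        "cv_sd": float(np.std(per_repeat, ddof=1)) if len(per_repeat) > 1 else 0.0,
        "per_repeat": per_repeat,
        "seeds": list(seeds),
    }


def roc_auc(scores, truths, positive=POSITIVE_CLASS) -> tuple[float, pd.DataFrame]:
    """AUC (rank statistic, half credit for ties) plus the empirical curve."""
    s = np.asarray(scores, dtype=float)
    t = (np.asarray(truths) == positive).astype(int)
    if t.min() == t.max():
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(t, s, drop_intermediate=False)
    value = float(roc_auc_score(t, s))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    # rank-based AUC coincides with the trapezoidal area under this curve
    assert abs(value - float(_trapezoid_auc(fpr, tpr))) < 1e-9
    return value, curve


def _scores(model, X) -> np.ndarray:
    idx = int(np.where(model.classes_ == POSITIVE_CLASS)[0][0])
    return model.predict_proba(X)[:, idx]


@dataclass
class ReplicateReport:
    """Replicated-split validation table and the selected best replicate."""

    table: pd.DataFrame
    best_index: int  # 1-based replicate number
    best_model: object
    best_features: list[str]
    false_positives: pd.DataFrame = field(default_factory=pd.DataFrame)


def replicate_splits(
    dataset: CuratedDataset,
    matrix: pd.DataFrame,
    n_replicates: int = 10,
    selector: str = "cfs_wrapper",
    algorithm: str = "nb",
    hyperparams: dict | None = None,
    seeds: list[int] | None = None,
    resubstitution: bool = True,
) -> ReplicateReport:
    """Build one model per train/internal-test re-split and pick the best.

    For each replicate the modelling set is re-split 7:3 (cluster-based on
    the descriptor rows), descriptors are selected on the training part by
    ``selector``, the ``algorithm`` is fitted, and accuracy plus AUC are
    evaluated on the training (resubstitution by default, CV otherwise),
    internal-test and external-test sets. The best replicate has the
    highest external accuracy; ties fall to external AUC and then to the
    lowest replicate index. Failed replicates are recorded, not fatal.
    """
    if seeds is None:
        seeds = list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise EvaluationError("need one seed per replicate")

    entries = {e.ligand_id: e for e in dataset.entries}
    modeling_ids = [i for i, s in dataset.split_assignment.items() if s == "modeling"]
    external_ids = [i for i, s in dataset.split_assignment.items() if s == "external_test"]
    y_all = {i: entries[i].activity_class for i in entries}

    select_fn = SELECTORS[selector]
    rows, fitted = [], {}
    for rep, seed in enumerate(seeds, start=1):
        try:
            modeling = [entries[i] for i in modeling_ids]
            inner = _inner_split(
                modeling, matrix.loc[modeling_ids], 0.7, np.random.default_rng(seed)
            )
            train_ids = [i for i in modeling_ids if inner[i] == "train"]
            internal_ids = [i for i in modeling_ids if inner[i] == "internal_test"]
            X_train = matrix.loc[train_ids]
            y_train = np.asarray([y_all[i] for i in train_ids])

            if selector in ("wrapper", "cfs_wrapper"):
                subset = select_fn(X_train, y_train, seed=seed)
            else:
                subset = select_fn(X_train, y_train)
            feats = subset.names or list(matrix.columns)

            model = make_classifier(algorithm, **(hyperparams or {}))
            model.fit(X_train[feats], y_train)

            row = {"replicate": rep, "seed": seed, "n_features": len(feats)}
            for name, ids in (
                ("train", train_ids),
                ("internal_test", internal_ids),
                ("external_test", external_ids),
            ):
                Xs = matrix.loc[ids][feats]
                ys = np.asarray([y_all[i] for i in ids])
                if name == "train" and not resubstitution:
                    row["train_accuracy"] = cross_validate(
                        make_classifier(algorithm, **(hyperparams or {})),
                        Xs, ys, folds=min(10, len(ys)), repeats=1, seeds=[seed],
                    )["cv_mean"]
                else:
                    row[f"{name}_accuracy"] = accuracy(model.predict(Xs), ys)
                try:
                    row[f"{name}_auc"], _ = roc_auc(_scores(model, Xs), ys)
                except EvaluationError:
                    row[f"{name}_auc"] = np.nan
            fitted[rep] = (model, feats)
            rows.append(row)
        except Exception as exc:  # replicate failure recorded, not fatal
            rows.append({"replicate": rep, "seed": seed, "error": str(exc)})

    table = pd.DataFrame(rows)
    ok = table[table["error"].isna()] if "error" in table.columns else table
    if ok.empty:
        raise EvaluationError("every replicate failed")
    ranked = ok.sort_values(
        by=["external_test_accuracy", "external_test_auc", "replicate"],
        ascending=[False, False, True],
        kind="stable",
    )
    best_index = int(ranked.iloc[0]["replicate"])
    best_model, best_feats = fitted[best_index]

    X_ext = matrix.loc[external_ids][best_feats]
    y_ext = np.asarray([y_all[i] for i in external_ids])
    pred_ext = best_model.predict(X_ext)
    fp_mask = (pred_ext == POSITIVE_CLASS) & (y_ext != POSITIVE_CLASS)
    false_positives = pd.DataFrame(
        [
            {
                "ligand_id": lid,
                "structure": entries[lid].structure,
                "lg_ki": entries[lid].lg_ki,
            }
            for lid, is_fp in zip(external_ids, fp_mask)
            if is_fp
        ]
    )
    return ReplicateReport(
        table=table,
        best_index=best_index,
        best_model=best_model,
        best_features=list(best_feats),
        false_positives=false_positives,
    )


def learning_curve(
    algorithm,
    matrix,
    labels,
    fractions: list[float] | None = None,
    repeats: int = 5,
    seed: int = 0,
    holdout_fraction: float = 0.3,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Held-out accuracy versus training-set fraction.

    Per repeat, a stratified holdout is drawn; for each fraction a
    stratified subsample of the remaining data trains the model, which is
    scored on the holdout. Returns one row per fraction with the mean and
    sd over repeats.
    """
    if fractions is None:
        fractions = [0.2, 0.4, 0.6, 0.8, 0.9, 1.0]
    if not all(0 < f <= 1 for f in fractions):
        raise EvaluationError("fractions must lie in (0, 1]")
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    proto = make_classifier(algorithm, **(hyperparams or {})) if isinstance(algorithm, str) else algorithm

    acc: dict[float, list[float]] = {f: [] for f in fractions}
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        test_idx, train_idx = _stratified_draw(y, holdout_fraction, rng)
        for f in fractions:
            sub, _ = _stratified_draw(y[train_idx], f, rng)
            sub_idx = train_idx[sub]
            if len(np.unique(y[sub_idx])) < 2:
                raise EvaluationError(f"fraction {f} too small to contain both classes")
            model = clone(proto).fit(X[sub_idx], y[sub_idx])
            acc[f].append(accuracy(model.predict(X[test_idx]), y[test_idx]))
    return pd.DataFrame(
        {
            "fraction": fractions,
            "mean_accuracy": [float(np.mean(acc[f])) for f in fractions],
            "sd_accuracy": [
                float(np.std(acc[f], ddof=1)) if repeats > 1 else 0.0 for f in fractions
            ],
        }
    )


def _stratified_draw(y: np.ndarray, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """(drawn, remaining) index arrays; at least one instance per class drawn."""
    drawn = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * len(idx))))
        drawn.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
    drawn = np.sort(np.concatenate(drawn))
    remaining = np.setdiff1d(np.arange(len(y)), drawn)
    return drawn, remaining


def plot_roc(curve: pd.DataFrame, path, label: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"], label=label or None)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_learning_curve(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(table["fraction"], table["mean_accuracy"], yerr=table["sd_accuracy"], marker="o")
    ax.set_xlabel("training fraction")
    ax.set_ylabel("held-out accuracy (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
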