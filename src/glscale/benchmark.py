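"""Cross-validation benchmark harness comparing scaling methods.

For each (scaler, classifier) pair the harness runs stratified k-fold
cross-validation: the scaler is fitted on the training rows only, both
partitions are transformed, a classifier is trained, and the held-out
fold is scored.  AUROC comes from the continuous decision scores;
accuracy uses a threshold chosen on the *training* scores — the minimum
threshold attaining maximal training accuracy under the rule
"predict positive iff score >= threshold".

The harness is deliberately thin glue over scikit-learn (stratified
folds, ROC AUC, logistic regression, linear SVM); the scientific content
lives in the scalers it compares.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .curve import FitConfig
from .scalers import SCALER_METHODS, fit_scaler, transform

__all__ = [
    "CLASSIFIERS",
    "CVResult",
    "stratified_kfold",
    "auroc",
    "select_threshold",
    "run_benchmark",
]

CLASSIFIERS = ("lr", "svm")


@dataclass(frozen=True)
class CVResult:
    """Per-fold and aggregated metrics for one (scaler, classifier) pair.

    Confidence half-widths are t-intervals over the k fold values:
    t_{0.975, k-1} * sd / sqrt(k).
    """

    scaler: str
    classifier: str
    k: int
    seed: int
    fold_auroc: tuple[float, ...]
    fold_accuracy: tuple[float, ...]
    mean_auroc: float
    mean_accuracy: float
    ci_auroc: float
    ci_accuracy: float

    @classmethod
    def from_folds(cls, scaler, classifier, k, seed, aurocs, accuracies) -> "CVResult":
        aurocs = tuple(float(a) for a in aurocs)
        accuracies = tuple(float(a) for a in accuracies)
        tcrit = float(stats.t.ppf(0.975, k - 1))

        def half_width(vals):
            return tcrit * float(np.std(vals, ddof=1)) / np.sqrt(k)

        return cls(
            scaler=scaler,
            classifier=classifier,
            k=k,
            seed=seed,
            fold_auroc=aurocs,
            fold_accuracy=accuracies,
            mean_auroc=float(np.mean(aurocs)),
            mean_accuracy=float(np.mean(accuracies)),
            ci_auroc=half_width(aurocs),
            ci_accuracy=half_width(accuracies),
        )


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    return classes


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: an array of fold ids in [0, k)."""
    y = np.asarray(labels)
    classes = _check_two_classes(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < k:
        raise ValueError(f"each class needs at least k={k} members, got {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(y.shape[0], dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros((y.shape[0], 1)), y)):
        folds[test_idx] = i
    return folds


def auroc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def select_threshold(train_scores, train_labels) -> float:
    """Minimum threshold maximizing training accuracy under score >= t.

    Candidates are the distinct training scores; ties in maximal accuracy
    are broken toward the smallest threshold.
    """
    s = np.asarray(train_scores, dtype=float)
    y = np.asarray(train_labels)
    _check_two_classes(y)
    best_t, best_acc = None, -1.0
    for t in np.unique(s):  # ascending, so strict > keeps the minimum on ties
        acc = float(np.mean((s >= t) == y))
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    return best_t


def _make_classifier(name: str, seed: int):
    if name == "lr":
        return LogisticRegression(C=1.0, max_iter=10_000)
    if name == "svm":
        return LinearSVC(C=1.0, max_iter=10_000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def run_benchmark(
    matrix,
    labels,
    scalers=SCALER_METHODS,
    classifiers=CLASSIFIERS,
    k: int = 5,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> list[CVResult]:
    """Stratified k-fold comparison of scaling methods and classifiers.

    Scalers are always fitted on the training rows of each fold only;
    the same fold assignment (derived from ``seed``) is reused across all
    (scaler, classifier) pairs so the comparison is paired.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("matrix must be 2-D with one label per row")
    folds = stratified_kfold(y, k, seed)
    results = []
    for method in scalers:
        for clf_name in classifiers:
            fold_auc, fold_acc = [], []
            for f in range(k):
                test = folds == f
                train = ~test
                if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
                    raise ValueError(f"fold {f} is degenerate (single-class partition)")
                model = fit_scaler(X[train], method, config=fit_config)
                x_tr = transform(model, X[train])
                x_te = transform(model, X[test])
                clf = _make_classifier(clf_name, seed)
                clf.fit(x_tr, y[train])
                tr_scores = clf.decision_function(x_tr)
                te_scores = clf.decision_function(x_te)
                fold_auc.append(auroc(te_scores, y[test]))
                thr = select_threshold(tr_scores, y[train])
                fold_acc.append(float(np.mean((te_scores >= thr) == y[test])))
            results.append(
                CVResult.from_folds(method, clf_name, k, seed, fold_auc, fold_acc)
            )
    return results
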