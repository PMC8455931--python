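"""SVM classification under stratified k-fold CV and the four evaluation
indices (accuracy, macro sensitivity, macro specificity, kappa).

The kappa used throughout is the *uniform-chance* normalization

    kappa = (Acc - p_e) / (1 - p_e),    p_e = 1 / k

with k the number of classes (p_e = 0.2 for the five-class problem).  This
differs from textbook Cohen's kappa, whose chance rate is the product of
the marginal distributions; the uniform form is what lets accuracies of
problems with different class counts be compared on one scale.

Sensitivity and specificity generalize to k > 2 classes as macro averages
of the one-vs-rest binary rates computed from the pooled confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CVReport",
    "stratified_kfold",
    "svm_cv",
    "accuracy",
    "macro_sensitivity",
    "macro_specificity",
    "kappa",
    "kappa_table",
    "make_svm",
]


def make_svm(C: float = 1.0, gamma: str | float = "scale", random_state: int = 0):
    """Standardizer + RBF SVM pipeline (one-vs-rest decision shape)."""
    return make_pipeline(
        StandardScaler(),
        SVC(C=C, kernel="rbf", gamma=gamma, decision_function_shape="ovr",
            random_state=random_state),
    )


def stratified_kfold(y: np.ndarray, k_folds: int = 6, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k_folds-1 per observation), class-balanced
    within +-1 member and deterministic under ``seed``.

    Classes with fewer members than ``k_folds`` trigger a warning and a
    best-effort stratification (their members are spread over the first
    folds; no training split ever loses a whole class as long as every
    class has >= 2 members).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    assignment = np.empty(len(y), dtype=int)
    if counts.min() >= k_folds:
        cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        for f, (_, test) in enumerate(cv.split(np.zeros(len(y)), y)):
            assignment[test] = f
        return assignment
    warnings.warn(
        f"class with {counts.min()} < {k_folds} members: "
        "best-effort stratification"
    )
    rng = np.random.default_rng(seed)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        # rotate so remainder members don't pile onto the first folds
        offset = rng.integers(k_folds)
        assignment[idx] = (np.arange(len(idx)) + offset) % k_folds
    return assignment


@dataclass
class CVReport:
    """Aggregate and per-fold CV results."""

    acc: float  # percent
    sen: float  # percent, macro one-vs-rest
    spe: float  # percent, macro one-vs-rest
    kappa: float
    confusion: np.ndarray
    per_fold: list[dict] = field(default_factory=list)
    k: int = 0
    classes: np.ndarray | None = None

    @property
    def p_e(self) -> float:
        return 1.0 / self.k

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "kappa": self.kappa,
            "k": self.k,
            "confusion": self.confusion.tolist(),
            "per_fold": self.per_fold,
        }


def accuracy(confusion: np.ndarray) -> float:
    """100 * trace / total (multiclass accuracy in percent)."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(confusion) / total)


def _ovr_rates(confusion: np.ndarray):
    c = np.asarray(confusion, dtype=float)
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = c.sum() - tp - fn - fp
    return tp, fn, fp, tn


def macro_sensitivity(confusion: np.ndarray) -> float:
    """Mean over classes of TP/(TP+FN), in percent; zero-support classes
    are excluded with a warning."""
    tp, fn, _, _ = _ovr_rates(confusion)
    support = tp + fn
    if np.any(support == 0):
        warnings.warn("class with zero support excluded from macro sensitivity")
    keep = support > 0
    return float(100.0 * np.mean(tp[keep] / support[keep]))


def macro_specificity(confusion: np.ndarray) -> float:
    """Mean over classes of TN/(TN+FP), in percent."""
    tp, fn, fp, tn = _ovr_rates(confusion)
    support = tp + fn
    if np.any(support == 0):
        warnings.warn("class with zero support excluded from macro specificity")
    keep = support > 0
    return float(100.0 * np.mean(tn[keep] / (tn[keep] + fp[keep])))


def kappa(acc: float, k: int) -> float:
    """Uniform-chance kappa: (acc/100 - 1/k) / (1 - 1/k)."""
    if k < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= acc <= 100.0:
        raise ValueError("accuracy must be a percentage in [0, 100]")
    p_e = 1.0 / k
    return float((acc / 100.0 - p_e) / (1.0 - p_e))


def kappa_table(entries: list[tuple[float, int]]) -> list[float]:
    """Element-wise :func:`kappa` over (accuracy percent, n_classes) pairs."""
    return [kappa(a, k) for a, k in entries]


def svm_cv(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 6,
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> CVReport:
    """Stratified k-fold SVM cross-validation with pooled confusion matrix.

    Standardization is fitted on the training folds only.  Returns the
    aggregate :class:`CVReport` (per-fold reports included).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        bad = np.flatnonzero(~np.isfinite(X).all(axis=0))
        raise ValueError(f"non-finite values in feature columns {bad.tolist()}")
    if X.shape[0] < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} rows for {k_folds}-fold CV")

    classes = np.unique(y)
    k = len(classes)
    folds = stratified_kfold(y, k_folds=k_folds, seed=seed)
    pooled = np.zeros((k, k), dtype=int)
    per_fold = []
    for f in range(k_folds):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < k:
            warnings.warn(f"fold {f}: training split misses a class")
        model = make_svm(C=C, gamma=gamma, random_state=seed)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        cm = confusion_matrix(y[test], pred, labels=classes)
        pooled += cm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_fold.append(
                {
                    "fold": f,
                    "acc": accuracy(cm),
                    "sen": macro_sensitivity(cm),
                    "spe": macro_specificity(cm),
                    "kappa": kappa(accuracy(cm), k),
                    "confusion": cm.tolist(),
                }
            )

    acc = accuracy(pooled)
    return CVReport(
        acc=acc,
        sen=macro_sensitivity(pooled),
        spe=macro_specificity(pooled),
        kappa=kappa(acc, k),
        confusion=pooled,
        per_fold=per_fold,
        k=k,
        classes=classes,
    )
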