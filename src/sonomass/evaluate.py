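"""Dataset splitting, cross-validation, and classification metrics.

Metrics follow the one-vs-rest convention: the 3x3 confusion matrix (rows
actual, columns predicted, class order benign / borderline / malignant) is
collapsed per class into a 2x2 table, from which per-class accuracy
(TP+TN)/N, precision, specificity, sensitivity and F1 are derived.  AUC is
computed per class one-vs-rest by the trapezoidal rule over score
thresholds and macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CLASS_ORDER = ("benign", "borderline", "malignant")


def split_3_2(items, seed: int = 0) -> tuple[list, list]:
    """Random 3:2 train/test split.

    ``|train| = round(0.6 * n)`` with half-up rounding; the permutation is
    seeded, and train/test are disjoint and exhaustive.
    """
    items = list(items)
    n = len(items)
    if n < 5:
        raise ValueError("need at least 5 items for a 3:2 split")
    n_train = int(np.floor(0.6 * n + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


def kfold_5(items, seed: int = 0) -> list[tuple[list, list]]:
    """Five-fold rotation over the training items.

    Fold sizes differ by at most one; each item lands in exactly one
    validation fold.  Returns five (train, validation) pairs.
    """
    items = list(items)
    n = len(items)
    if n < 5:
        raise ValueError("need at least 5 items for 5 folds")
    order = np.random.default_rng(seed).permutation(n)
    folds = [list(order[i::5]) for i in range(5)]
    out = []
    for k in range(5):
        val = [items[i] for i in folds[k]]
        train = [items[i] for j in range(5) if j != k for i in folds[j]]
        out.append((train, val))
    return out


@dataclass
class ClassificationReport:
    """Confusion matrix plus per-class and overall metrics."""

    class_names: list[str]
    confusion: np.ndarray  # rows actual, cols predicted
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    auc: dict[str, float] = field(default_factory=dict)
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
        }


def _binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    n = tp + fp + fn + tn
    div = lambda a, b: a / b if b > 0 else 0.0
    p = div(tp, tp + fp)
    r = div(tp, tp + fn)
    return {
        "accuracy": div(tp + tn, n),
        "precision": p,
        "specificity": div(tn, tn + fp),
        "sensitivity": r,
        "f1": div(2 * p * r, p + r) if (p + r) > 0 else 0.0,
    }


def _auc_trapezoid(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest ROC AUC by the trapezoidal rule."""
    from sklearn.metrics import roc_curve

    if y_bin.min() == y_bin.max():
        return float("nan")
    fpr, tpr, _ = roc_curve(y_bin, scores)
    return float(np.trapezoid(tpr, fpr))


def report(
    y_true,
    y_pred,
    scores: np.ndarray | None = None,
    class_names=None,
) -> ClassificationReport:
    """Build the full classification report.

    ``scores`` (n x n_classes), when provided, enable per-class and macro
    AUC; rows must follow ``class_names`` column order.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if class_names is None:
        observed = set(y_true) | set(y_pred)
        if observed <= set(DEFAULT_CLASS_ORDER):
            class_names = [c for c in DEFAULT_CLASS_ORDER if c in observed]
        else:
            class_names = sorted(observed)
    class_names = list(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    unknown = (set(y_true) | set(y_pred)) - set(class_names)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")

    k = len(class_names)
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return report_from_confusion(cm, class_names, y_true=y_true, scores=scores)


def report_from_confusion(
    cm: np.ndarray,
    class_names,
    y_true=None,
    scores: np.ndarray | None = None,
) -> ClassificationReport:
    """Metrics from an already-tabulated confusion matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    class_names = list(class_names)
    k = len(class_names)
    if cm.shape != (k, k):
        raise ValueError("confusion matrix shape does not match class names")
    n = int(cm.sum())
    per_class = {}
    for i, name in enumerate(class_names):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = n - tp - fn - fp
        per_class[name] = _binary_metrics(tp, fp, fn, tn)
    overall = float(np.trace(cm) / n) if n else 0.0

    auc: dict[str, float] = {}
    macro = None
    if scores is not None and y_true is not None:
        scores = np.asarray(scores, dtype=float)
        y_true = np.asarray(y_true).astype(str)
        vals = []
        for i, name in enumerate(class_names):
            a = _auc_trapezoid((y_true == name).astype(int), scores[:, i])
            auc[name] = a
            if not np.isnan(a):
                vals.append(a)
        macro = float(np.mean(vals)) if vals else None
    return ClassificationReport(
        class_names=class_names,
        confusion=cm,
        per_class=per_class,
        overall_accuracy=overall,
        auc=auc,
        macro_auc=macro,
    )
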