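"""Cross-validated evaluation: confusion-matrix metrics, ROC/PR, external sets.

Stratified k-fold cross-validation pools the out-of-fold predictions into a
single confusion matrix (positive class "selected") and computes the full
metric suite from it: TPR, FPR, precision, recall, F-measure, Matthews
correlation coefficient, ROC AUC (trapezoid over a threshold sweep, which
equals the tie-corrected Mann-Whitney rank statistic) and the area under the
precision-recall curve (step interpolation). Per-class metrics and
class-size-weighted averages are emitted alongside the positive-class view.
Ratios with zero denominator are reported as 0 and flagged rather than NaN
so reports serialize cleanly.

For an independent set of sequences the evaluation is the fraction
classified positive: high on disease-associated input, low on unrelated
input if the model is selective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .descriptors import split_features
from .errors import DataError
from .model import POSITIVE_CLASS, ClassifierSpec, make_classifier, _ordered_classes

__all__ = [
    "ConfusionMatrix", "ROCCurve", "PRCurve", "EvaluationReport",
    "stratified_folds", "cross_validate", "metrics_from_confusion",
    "roc_and_pr", "external_positive_rate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts indexed (actual, predicted) with classes ordered
    (positive, negative); positive class is "selected"."""

    counts: tuple  # ((TP, FN), (FP, TN))
    classes: tuple = (POSITIVE_CLASS, "random")

    @property
    def tp(self):
        return self.counts[0][0]

    @property
    def fn(self):
        return self.counts[0][1]

    @property
    def fp(self):
        return self.counts[1][0]

    @property
    def tn(self):
        return self.counts[1][1]

    @property
    def total(self):
        return self.tp + self.fn + self.fp + self.tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.counts, dtype=int),
            index=pd.Index(self.classes, name="actual"),
            columns=pd.Index(self.classes, name="predicted"),
        )

    @classmethod
    def from_predictions(cls, actual, predicted, classes=None) -> "ConfusionMatrix":
        actual = np.asarray(actual)
        predicted = np.asarray(predicted)
        if classes is None:
            classes = _ordered_classes(actual)
        if len(classes) != 2:
            raise DataError("confusion matrix requires exactly two classes")
        pos, neg = classes
        counts = (
            (int(((actual == pos) & (predicted == pos)).sum()),
             int(((actual == pos) & (predicted == neg)).sum())),
            (int(((actual == neg) & (predicted == pos)).sum()),
             int(((actual == neg) & (predicted == neg)).sum())),
        )
        return cls(counts=counts, classes=tuple(classes))


@dataclass(frozen=True)
class ROCCurve:
    points: tuple  # ordered (fpr, tpr) pairs, (0,0) .. (1,1)
    auc: float


@dataclass(frozen=True)
class PRCurve:
    points: tuple  # ordered (recall, precision) pairs
    auprc: float


@dataclass
class EvaluationReport:
    """Confusion matrix + full metric suite for one evaluation run."""

    confusion: ConfusionMatrix
    metrics: dict
    roc: ROCCurve | None = None
    pr: PRCurve | None = None
    folds: int | None = None
    seed: int | None = None
    classifier: ClassifierSpec | None = None
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)
    predictions: np.ndarray | None = field(default=None, repr=False)

    @property
    def accuracy(self) -> float:
        cm = self.confusion
        return (cm.tp + cm.tn) / cm.total

    def to_dict(self) -> dict:
        out = {
            "confusion": [list(row) for row in self.confusion.counts],
            "classes": list(self.confusion.classes),
            "accuracy": self.accuracy,
            "metrics": {k: (v if not isinstance(v, float) else float(v))
                        for k, v in self.metrics.items()},
            "folds": self.folds,
            "seed": self.seed,
        }
        if self.classifier is not None:
            out["classifier"] = self.classifier.to_dict()
        if self.roc is not None:
            out["auc"] = self.roc.auc
        if self.pr is not None:
            out["auprc"] = self.pr.auprc
        return out

    def summary(self) -> str:
        cm = self.confusion
        lines = ["Evaluation report", "=" * 46]
        if self.classifier is not None:
            lines.append(f"classifier: {self.classifier.name} "
                         f"(seed={self.classifier.seed})")
        if self.folds:
            lines.append(f"cross-validation: {self.folds}-fold, seed={self.seed}")
        lines.append(str(cm.to_frame()))
        lines.append("-" * 46)
        lines.append(f"accuracy    {self.accuracy:.3f}")
        for key in ("tpr", "fpr", "precision", "recall", "f_measure", "mcc"):
            lines.append(f"{key:<11} {self.metrics[key]:.3f}")
        if self.roc is not None:
            lines.append(f"{'auc':<11} {self.roc.auc:.3f}")
        if self.pr is not None:
            lines.append(f"{'auprc':<11} {self.pr.auprc:.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)


def stratified_folds(labels, k: int, seed: int = 1) -> np.ndarray:
    """Assign each instance a fold index 0..k-1, stratified by class.

    Each class's instances are spread across folds as evenly as possible
    (per-class fold sizes differ by at most one); the shuffle is driven only
    by ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise DataError("k must be >= 2")
    if k > n:
        raise DataError(f"k={k} exceeds the {n} instances")
    # deal each class's shuffled instances round-robin, carrying the fold
    # cursor across classes so global fold sizes also differ by at most one;
    # handles k above the smallest class count (up to leave-one-out)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    cursor = 0
    for cls in _ordered_classes(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            assignment[j] = (cursor + i) % k
        cursor = (cursor + idx.size) % k
    return assignment


def _rates(tp, fn, fp, tn):
    """Positive-class metric set from raw counts; zero-denominator ratios
    come back as 0.0 together with a flag naming them."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    tpr = ratio(tp, tp + fn, "tpr")
    fpr = ratio(fp, fp + tn, "fpr")
    precision = ratio(tp, tp + fp, "precision")
    recall = tpr
    f_measure = ratio(2 * precision * recall, precision + recall, "f_measure")
    mcc_den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return {
        "tpr": tpr, "fpr": fpr, "precision": precision, "recall": recall,
        "f_measure": f_measure, "mcc": mcc,
    }, undefined


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Table-style metric suite from a 2x2 confusion matrix.

    Returns positive-class metrics at the top level plus ``per_class`` and
    class-size-``weighted`` variants (the weighted row is the conventional
    one-line-per-classifier summary), and an ``undefined`` list flagging any
    ratio whose denominator was zero (reported as 0).
    """
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    pos_metrics, undefined = _rates(cm.tp, cm.fn, cm.fp, cm.tn)
    # negative class = relabelled swap of the matrix
    neg_metrics, neg_undef = _rates(cm.tn, cm.fp, cm.fn, cm.tp)
    n_pos = cm.tp + cm.fn
    n_neg = cm.fp + cm.tn
    weighted = {
        key: (n_pos * pos_metrics[key] + n_neg * neg_metrics[key]) / cm.total
        for key in pos_metrics
    }
    out = dict(pos_metrics)
    out["accuracy"] = (cm.tp + cm.tn) / cm.total
    out["per_class"] = {cm.classes[0]: pos_metrics, cm.classes[1]: neg_metrics}
    out["weighted"] = weighted
    out["undefined"] = sorted(set(undefined) | {f"{cm.classes[1]}:{u}"
                                                for u in neg_undef})
    return out


def roc_and_pr(scores, labels, positive=POSITIVE_CLASS):
    """ROC and precision-recall curves from positive-class scores.

    ROC AUC is the trapezoid area of the threshold sweep (equal to the
    tie-corrected Mann-Whitney statistic); the PR area uses step
    interpolation, summing precision at each distinct recall increment.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    if y.size != scores.size:
        raise DataError("scores and labels differ in length")
    if y.min() == y.max():
        raise DataError("ROC/PR need both classes present")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
    roc = ROCCurve(points=tuple(zip(fpr.tolist(), tpr.tolist())),
                   auc=float(_trapezoid_auc(fpr, tpr)))
    precision, recall, _ = precision_recall_curve(y, scores)
    # step-interpolated area: sum precision over recall increments
    auprc = float(-np.sum(np.diff(recall) * precision[:-1]))
    pr = PRCurve(points=tuple(zip(recall.tolist(), precision.tolist())),
                 auprc=auprc)
    return roc, pr


def cross_validate(table: pd.DataFrame, spec: ClassifierSpec,
                   k: int = 10, seed: int = 1) -> EvaluationReport:
    """Stratified k-fold CV; out-of-fold predictions are pooled into one
    confusion matrix and one score set before computing any metric."""
    X, y = split_features(table)
    labels = y.to_numpy()
    classes = _ordered_classes(labels)
    if len(classes) != 2:
        raise DataError("cross-validation requires exactly two classes")
    folds = stratified_folds(labels, k, seed)
    scores = np.empty(len(labels))
    predictions = np.empty(len(labels), dtype=object)
    for fold in range(k):
        test = folds == fold
        clf = make_classifier(spec).fit(X[~test], labels[~test])
        probs = clf.predict_proba(X[test])
        pos_col = clf.classes.index(classes[0])
        scores[test] = probs[:, pos_col]
        predictions[test] = np.asarray(clf.classes, dtype=object)[
            probs.argmax(axis=1)]
    cm = ConfusionMatrix.from_predictions(labels, predictions, classes)
    metrics = metrics_from_confusion(cm)
    roc, pr = roc_and_pr(scores, labels, positive=classes[0])
    metrics["auc"] = roc.auc
    metrics["auprc"] = pr.auprc
    return EvaluationReport(
        confusion=cm, metrics=metrics, roc=roc, pr=pr, folds=k, seed=seed,
        classifier=spec, scores=scores, labels=labels, predictions=predictions,
    )


def external_positive_rate(results_or_clf, table: pd.DataFrame,
                           positive=POSITIVE_CLASS) -> float:
    """Fraction of an independent feature table classified positive.

    This is the "independent accuracy" convention for disease-associated
    input sets: predicted-positive count over total tested.
    """
    X = table.drop(columns="label") if "label" in table.columns else table
    predicted = results_or_clf.predict(X)
    return float((np.asarray(predicted) == positive).mean())
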