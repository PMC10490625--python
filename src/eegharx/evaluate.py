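"""Classification evaluation: confusion matrix, per-class precision / recall /
F1, multiclass accuracy, weighted averages, and one-vs-rest ROC / AUC.

The metric definitions are implemented directly from the confusion-matrix
cells: per class (one-vs-rest) precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R); multiclass accuracy = trace/total. AUC is computed by a
threshold sweep with trapezoid integration, which equals the Mann-Whitney U
statistic normalized by (positives x negatives), ties counted half.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray  # rows = true, columns = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self, cls: str) -> int:
        return int(self.counts[self.classes.index(cls)].sum())

    def ovr_cells(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating ``cls`` as the positive class."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(
    y_true: list[str], y_pred: list[str], classes: list[str] | None = None
) -> ConfusionMatrix:
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in idx:
            raise ValueError(f"unknown true label {t!r}")
        if p not in idx:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    classes: list[str]
    per_class: dict[str, dict[str, float]]
    accuracy: float
    weighted_avg: dict[str, float]
    confusion: ConfusionMatrix
    roc_curves: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "weighted_avg": self.weighted_avg,
            "confusion": {
                "classes": self.confusion.classes,
                "counts": self.confusion.counts.tolist(),
            },
            "roc_curves": self.roc_curves,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text_table(self) -> str:
        """Plain-text table in the per-class precision/recall/F1 layout."""
        lines = [f"Accuracy = {self.accuracy * 100:.2f}%", ""]
        lines.append(f"{'Activity Class':<16}{'Precision':>10}{'Recall':>10}{'F1-Score':>10}")
        for c in self.classes:
            m = self.per_class[c]
            lines.append(
                f"{c.capitalize():<16}{m['precision']:>10.2f}{m['recall']:>10.2f}{m['f1']:>10.2f}"
            )
        w = self.weighted_avg
        lines.append(
            f"{'Weighted Average':<16}{w['precision']:>10.2f}{w['recall']:>10.2f}{w['f1']:>10.2f}"
        )
        return "\n".join(lines)


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Per-class and weighted metrics from a confusion matrix.

    Zero-denominator cells give metric 0 with a logged flag; weighted
    averages use true-class supports as weights.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for c in cm.classes:
        tp, fp, fn, _ = cm.ovr_cells(c)
        if tp + fp == 0:
            logger.info("class %s: no predicted positives; precision set to 0", c)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        if tp + fn == 0:
            logger.info("class %s: no true positives; recall set to 0", c)
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        per_class[c] = {
            "precision": precision, "recall": recall, "f1": f1_score(precision, recall),
        }
    accuracy = float(np.trace(cm.counts)) / cm.total
    supports = np.array([cm.support(c) for c in cm.classes], dtype=float)
    weights = supports / supports.sum()
    weighted = {
        m: float(sum(w * per_class[c][m] for w, c in zip(weights, cm.classes)))
        for m in ("precision", "recall", "f1")
    }
    return EvalReport(
        classes=list(cm.classes), per_class=per_class, accuracy=accuracy,
        weighted_avg=weighted, confusion=cm,
    )


def roc_curve_points(
    y_true01: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC by descending threshold sweep over unique scores.

    Returns (fpr, tpr, auc). Tied scores collapse to one operating point, so
    the trapezoid over the tie segment credits 0.5 per tied pair and the AUC
    equals the normalized Mann-Whitney U statistic.
    """
    y = np.asarray(y_true01, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise ValueError("need at least one positive and one negative instance")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last index of each tied-score run
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / pos]
    fpr = np.r_[0.0, fp[distinct] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_auc(
    y_true: list[str], proba: np.ndarray, classes: list[str]
) -> dict[str, dict]:
    """Per-class one-vs-rest ROC points and AUC from a probability matrix."""
    proba = np.asarray(proba, dtype=float)
    if proba.shape != (len(y_true), len(classes)):
        raise ValueError("probability matrix shape mismatch")
    out: dict[str, dict] = {}
    y_arr = np.asarray(y_true)
    for j, c in enumerate(classes):
        y01 = y_arr == c
        if y01.all() or not y01.any():
            logger.warning("class %s is degenerate in the test set; AUC undefined", c)
            out[c] = {"fpr": [], "tpr": [], "auc": float("nan")}
            continue
        fpr, tpr, auc = roc_curve_points(y01, proba[:, j])
        out[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc}
    return out


def evaluate_predictions(
    y_true: list[str],
    y_pred: list[str],
    proba: np.ndarray | None = None,
    classes: list[str] | None = None,
) -> EvalReport:
    """Full evaluation surface for one set of predictions."""
    cm = confusion(y_true, y_pred, classes)
    report = metrics(cm)
    if proba is not None:
        report.roc_curves = roc_auc(y_true, proba, cm.classes)
        for c in cm.classes:
            report.per_class[c]["auc"] = report.roc_curves[c]["auc"]
    return report
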