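"""Evaluation panel: confusion matrix, per-class rates, kappa, one-vs-rest AUC.

All metrics are computed from first principles on the multiclass confusion
matrix: per class one-vs-rest TP/FP/FN/TN give precision, recall, F1 and
specificity; macro-F1 is the unweighted mean of per-class F1; Cohen's kappa
is (p_o − p_e)/(1 − p_e) with the chance agreement p_e from row/column
marginals. AUC is the Mann–Whitney U statistic with ties counted ½ — exact
tie handling, equivalent to trapezoidal ROC integration.

Zero-denominator policy: the affected rate is reported as 0 and flagged via
a logged warning, keeping report shapes stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "EvalReport", "confusion", "panel",
           "roc_auc_ovr", "full_report"]


@dataclass
class ConfusionMatrix:
    """K×K counts; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    accuracy: float
    misclassification_rate: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    specificity: np.ndarray
    macro_f1: float
    kappa: float
    auc_per_class: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy,
             "misclassification_rate": self.misclassification_rate,
             "macro_f1": self.macro_f1, "kappa": self.kappa,
             "precision": self.precision.tolist(),
             "recall": self.recall.tolist(), "f1": self.f1.tolist(),
             "specificity": self.specificity.tolist(),
             "class_names": self.class_names}
        if self.auc_per_class is not None:
            d["auc_per_class"] = [None if np.isnan(a) else float(a)
                                  for a in self.auc_per_class]
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self) -> str:
        """Human-readable per-class table."""
        names = self.class_names or [f"class_{i}" for i in range(len(self.f1))]
        width = max(len(n) for n in names)
        lines = [f"{'class':<{width}}  prec   recall f1     spec" +
                 ("   auc" if self.auc_per_class is not None else "")]
        for i, n in enumerate(names):
            row = (f"{n:<{width}}  {self.precision[i]:.4f} {self.recall[i]:.4f} "
                   f"{self.f1[i]:.4f} {self.specificity[i]:.4f}")
            if self.auc_per_class is not None:
                row += f" {self.auc_per_class[i]:.4f}"
            lines.append(row)
        lines.append(f"accuracy={self.accuracy:.4f}  macro_f1={self.macro_f1:.4f}  "
                     f"kappa={self.kappa:.4f}")
        return "\n".join(lines)


def confusion(y_true, y_pred, num_classes: int) -> ConfusionMatrix:
    """counts[i, j] = #{samples with true class i predicted as j}."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.min(initial=0) < 0 or y_true.max(initial=0) >= num_classes or \
       y_pred.min(initial=0) < 0 or y_pred.max(initial=0) >= num_classes:
        raise ValueError("labels out of range")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    ok = den > 0
    if not ok.all():
        logger.warning("zero denominator in %s for classes %s; reporting 0",
                       what, np.flatnonzero(~ok).tolist())
    out[ok] = num[ok] / den[ok]
    return out


def panel(cm: ConfusionMatrix, class_names: list[str] | None = None) -> EvalReport:
    """Full metric panel (without AUC) from a confusion matrix."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(np.float64)
    row = counts.sum(axis=1).astype(np.float64)   # true-class totals
    col = counts.sum(axis=0).astype(np.float64)   # predicted totals
    fp = col - tp
    fn = row - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    specificity = _safe_div(tn, tn + fp, "specificity")
    accuracy = tp.sum() / total
    po = accuracy
    pe = float((row * col).sum()) / total ** 2
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return EvalReport(accuracy=accuracy, misclassification_rate=1.0 - accuracy,
                      precision=precision, recall=recall, f1=f1,
                      specificity=specificity, macro_f1=float(f1.mean()),
                      kappa=kappa, class_names=class_names or [])


def roc_auc_ovr(y_true, score_matrix) -> np.ndarray:
    """One-vs-rest AUC per class via the Mann–Whitney U statistic.

    A class absent from ``y_true`` yields NaN for that class. Ties in the
    scores are counted as half-concordant.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(score_matrix, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != len(y_true):
        raise ValueError("score_matrix must be (n_samples, n_classes)")
    k = scores.shape[1]
    aucs = np.full(k, np.nan)
    for c in range(k):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(scores[:, c])  # average ranks handle ties as 1/2
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs[c] = u / (n_pos * n_neg)
    return aucs


def full_report(y_true, y_pred, score_matrix=None,
                class_names: list[str] | None = None) -> EvalReport:
    """Convenience: confusion → panel, plus per-class AUC when scores given."""
    k = len(class_names) if class_names else int(max(np.max(y_true), np.max(y_pred))) + 1
    rep = panel(confusion(y_true, y_pred, k), class_names)
    if score_matrix is not None:
        rep.auc_per_class = roc_auc_ovr(y_true, score_matrix)
    return rep
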