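"""One-vs-rest multiclass evaluation and attention-alignment scoring.

Each class in turn is treated as positive and the rest pooled as negative,
giving per-class TP/FP/TN/FN from the confusion matrix; accuracy,
precision, recall, F1 and MCC follow from those counts, Cohen's kappa from
the observed vs chance agreement of the full matrix, and AUC from the
midrank (Mann-Whitney) statistic of the one-vs-rest score ordering.
Aggregates are unweighted (macro) means by default.

Attention alignment quantifies how well the network's attention map covers
the ground-truth lesion: intersection-over-union between the lesion mask
and the attention map binarized at its Otsu level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "one_vs_rest_counts",
    "metrics_from_counts",
    "cohens_kappa",
    "ovr_auc",
    "attention_alignment",
    "classification_report",
    "multiclass_mcc",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are predicted labels, columns true labels."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.class_names:
            self.class_names = [f"class_{k}" for k in range(self.counts.shape[0])]

    @classmethod
    def from_predictions(cls, y_true, y_pred, num_classes: int,
                         class_names: list[str] | None = None) -> "ConfusionMatrix":
        counts = np.zeros((num_classes, num_classes), dtype=int)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(p), int(t)] += 1
        return cls(counts=counts, class_names=class_names or [])

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """Aggregate + per-class one-vs-rest metrics for one evaluation run."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    kappa: float
    auc: float | None
    per_class: dict[str, dict[str, float]]
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "mcc": self.mcc,
            "kappa": self.kappa, "auc": self.auc,
            "per_class": self.per_class, "n": self.n,
        }


def one_vs_rest_counts(cm: ConfusionMatrix, k: int) -> tuple[int, int, int, int]:
    """Binary (TP, FP, TN, FN) for class k against the rest.

    Rows of `cm` are predictions, so FP sits in row k off the diagonal and
    FN in column k off the diagonal.
    """
    if not 0 <= k < cm.num_classes:
        raise IndexError(f"class index {k} out of range [0, {cm.num_classes})")
    tp = int(cm.counts[k, k])
    fp = int(cm.counts[k, :].sum()) - tp
    fn = int(cm.counts[:, k].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, tn, fn


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int):
    """Accuracy, precision, recall, F1 and MCC from binary counts.

    Zero-denominator conventions: precision/recall/F1 -> 0 with a warning;
    MCC with a zero denominator -> 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all counts are zero")
    acc = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("precision denominator is zero; reporting 0")
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall denominator is zero; reporting 0")
        rec = 0.0
    else:
        rec = tp / (tp + fn)
    f1 = 0.0 if pre + rec == 0 else 2.0 * pre * rec / (pre + rec)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return acc, pre, rec, f1, mcc


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p0 - pe) / (1 - pe) of the full matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p0 = np.trace(cm.counts) / total
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    pe = float(np.sum(row * col)) / total ** 2
    if pe >= 1.0:
        raise ValueError("degenerate single-class matrix: pe = 1")
    return float((p0 - pe) / (1.0 - pe))


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Generalized single-matrix MCC (the R_K statistic)."""
    c = cm.counts.astype(float)
    t = c.sum()
    correct = np.trace(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    num = correct * t - float(row @ col)
    den = np.sqrt(t * t - float(row @ row)) * np.sqrt(t * t - float(col @ col))
    return 0.0 if den == 0 else float(num / den)


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based (midrank/Mann-Whitney) AUC for one binary problem."""
    n_pos = int(positive.sum())
    n_neg = len(scores) - n_pos
    ranks = rankdata(scores)  # midranks for ties
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ovr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean one-vs-rest AUC over classes present in `labels`.

    `scores` is (n, K) of class probabilities (rows must sum to 1 within
    1e-6); ties are handled by midrank, so label-independent scores give
    exactly 0.5. Classes with no positives or no negatives are skipped
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ValueError("scores must be (n, K) aligned with labels")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1 within 1e-6")
    aucs = []
    for k in range(scores.shape[1]):
        pos = labels == k
        if pos.sum() == 0 or pos.sum() == len(labels):
            if pos.sum() == len(labels):
                warnings.warn(f"class {k} has zero negatives; skipped")
            continue
        aucs.append(_binary_auc(scores[:, k], pos))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def attention_alignment(a_model, lesion_mask: np.ndarray,
                        threshold: str | float = "otsu") -> float:
    """IoU between the lesion mask and the binarized attention map.

    The attention map is thresholded at its own Otsu level by default
    (pass a float for a fixed threshold); IoU = |A ∩ M| / |A ∪ M|.
    """
    values = a_model.values if hasattr(a_model, "values") else np.asarray(a_model)
    lesion_mask = np.asarray(lesion_mask).astype(bool)
    if values.shape != lesion_mask.shape:
        raise ValueError(f"shapes differ: {values.shape} vs {lesion_mask.shape}")
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    if threshold == "otsu":
        if np.ptp(values) < 1e-12:
            logger.warning("constant attention map; alignment undefined, returning 0")
            return 0.0
        from skimage.filters import threshold_otsu
        level = threshold_otsu(values)
    else:
        level = float(threshold)
    binary = values > level
    union = np.logical_or(binary, lesion_mask).sum()
    inter = np.logical_and(binary, lesion_mask).sum()
    return float(inter / union) if union else 0.0


def classification_report(cm: ConfusionMatrix, scores: np.ndarray | None = None,
                          labels: np.ndarray | None = None,
                          average: str = "macro") -> MetricReport:
    """Full metric suite from a confusion matrix (+ optional AUC inputs).

    Accuracy and kappa come from the full matrix; precision/recall/F1/MCC
    are one-vs-rest per class and aggregated as an unweighted (macro) mean
    by default, or support-weighted with average='weighted'. AUC is the
    mean one-vs-rest rank AUC and requires `scores` and `labels`.
    """
    if average not in ("macro", "weighted"):
        raise ValueError("average must be 'macro' or 'weighted'")
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    pres, recs, f1s, mccs, supports = [], [], [], [], []
    for k in range(cm.num_classes):
        tp, fp, tn, fn = one_vs_rest_counts(cm, k)
        acc_k, pre, rec, f1, mcc = metrics_from_counts(tp, fp, tn, fn)
        per_class[cm.class_names[k]] = {
            "accuracy": acc_k, "precision": pre, "recall": rec,
            "f1": f1, "mcc": mcc, "support": tp + fn,
        }
        pres.append(pre)
        recs.append(rec)
        f1s.append(f1)
        mccs.append(mcc)
        supports.append(tp + fn)
    if average == "macro":
        wts = np.ones(cm.num_classes) / cm.num_classes
    else:
        wts = np.asarray(supports, dtype=float) / total
    auc = None
    if scores is not None and labels is not None:
        auc = ovr_auc(scores, labels)
    return MetricReport(
        accuracy=float(np.trace(cm.counts) / total),
        precision=float(np.dot(wts, pres)),
        recall=float(np.dot(wts, recs)),
        f1=float(np.dot(wts, f1s)),
        mcc=float(np.dot(wts, mccs)),
        kappa=cohens_kappa(cm),
        auc=auc,
        per_class=per_class,
        n=total,
    )
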