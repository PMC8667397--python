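"""Multi-label evaluation: micro/macro P, R, F1, AUC, and precision/recall@k.

Micro averaging pools TP/FP/FN over every (document, label) decision; macro
averaging computes per-label ratios and averages them uniformly over labels.
Macro-F1 is the harmonic mean of macro-P and macro-R (not the mean of
per-label F1 scores).  Per-label 0/0 ratios are defined as 0.  Macro-AUC
averages per-label ROC-AUC over labels with at least one positive and one
negative instance; degenerate labels are excluded (and counted in the
report).  Ties in AUC contribute 1/2 (Mann-Whitney convention).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class PredictionSet:
    """Ground truth and predicted probabilities for a document set."""

    y_true: np.ndarray  # binary (N, L)
    y_prob: np.ndarray  # probabilities (N, L)
    threshold: float = 0.5

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true)
        self.y_prob = np.asarray(self.y_prob, dtype=np.float64)
        if self.y_true.shape != self.y_prob.shape:
            raise ValueError("y_true and y_prob shapes differ")
        if self.y_true.ndim != 2 or self.y_true.shape[0] < 1:
            raise ValueError("expected a non-empty (N, L) matrix")

    @property
    def y_pred(self) -> np.ndarray:
        """Hard decisions: probability strictly above the threshold."""
        return (self.y_prob > self.threshold).astype(np.int8)


@dataclass
class MetricsReport:
    macro_auc: float
    micro_auc: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    precision_at_k: dict[int, float] = field(default_factory=dict)
    recall_at_k: dict[int, float] = field(default_factory=dict)
    tp: np.ndarray | None = None
    fp: np.ndarray | None = None
    fn: np.ndarray | None = None
    n_auc_labels_excluded: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("tp", "fp", "fn"):
            if d[key] is not None:
                d[key] = [int(v) for v in d[key]]
        d["precision_at_k"] = {str(k): v for k, v in self.precision_at_k.items()}
        d["recall_at_k"] = {str(k): v for k, v in self.recall_at_k.items()}
        return d

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_csv(self, path: str | Path) -> None:
        """One-row CSV in the conventional reporting column order."""
        cols = ["macro_auc", "micro_auc", "macro_f1", "micro_f1"]
        vals = [self.macro_auc, self.micro_auc, self.macro_f1, self.micro_f1]
        for k in sorted(self.precision_at_k):
            cols.append(f"p_at_{k}")
            vals.append(self.precision_at_k[k])
        for k in sorted(self.recall_at_k):
            cols.append(f"r_at_{k}")
            vals.append(self.recall_at_k[k])
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            w.writerow([f"{v:.6f}" for v in vals])


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    return np.divide(num, den, out=np.zeros_like(num), where=den != 0)


def prf_micro_macro(pred: PredictionSet) -> tuple[float, float, float, float, float, float]:
    """(micro_P, micro_R, micro_F, macro_P, macro_R, macro_F) at the threshold."""
    yp = pred.y_pred
    yt = pred.y_true
    tp = ((yp == 1) & (yt == 1)).sum(axis=0)
    fp = ((yp == 1) & (yt == 0)).sum(axis=0)
    fn = ((yp == 0) & (yt == 1)).sum(axis=0)

    micro_p = float(_safe_div(tp.sum(), tp.sum() + fp.sum()))
    micro_r = float(_safe_div(tp.sum(), tp.sum() + fn.sum()))
    micro_f = float(_safe_div(2 * micro_p * micro_r, micro_p + micro_r))

    macro_p = float(_safe_div(tp, tp + fp).mean())
    macro_r = float(_safe_div(tp, tp + fn).mean())
    macro_f = float(_safe_div(2 * macro_p * macro_r, macro_p + macro_r))
    return micro_p, micro_r, micro_f, macro_p, macro_r, macro_f


def auc_micro_macro(pred: PredictionSet) -> tuple[float, float, int]:
    """(micro_AUC, macro_AUC, #labels excluded from the macro mean).

    Micro pools every (document, label) pair; macro averages per-label AUC
    over labels with both classes present.
    """
    yt = pred.y_true
    yp = pred.y_prob
    flat_t = yt.ravel()
    if flat_t.min() == flat_t.max():
        raise ValueError("micro AUC needs at least one positive and one negative entry")
    micro = float(roc_auc_score(flat_t, yp.ravel()))
    per_label = []
    excluded = 0
    for j in range(yt.shape[1]):
        col = yt[:, j]
        if col.min() == col.max():
            excluded += 1
            continue
        per_label.append(roc_auc_score(col, yp[:, j]))
    if not per_label:
        raise ValueError("no label with both classes present for macro AUC")
    return micro, float(np.mean(per_label)), excluded


def _topk_indices(probs: np.ndarray, k: int) -> np.ndarray:
    """Top-k label indices per row, ties broken by lower label index."""
    # stable ascending sort of -p keeps original order among equal values
    return np.argsort(-probs, axis=1, kind="stable")[:, :k]


def precision_at_k(pred: PredictionSet, k: int) -> float:
    """Mean over documents of (#true labels in the top-k) / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pred.y_true.shape[1]:
        raise ValueError("k exceeds the number of labels")
    top = _topk_indices(pred.y_prob, k)
    hits = np.take_along_axis(pred.y_true, top, axis=1).sum(axis=1)
    return float((hits / k).mean())


def recall_at_k(pred: PredictionSet, k: int) -> float:
    """Mean over documents with >=1 true label of (#true in top-k) / #true."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pred.y_true.shape[1]:
        raise ValueError("k exceeds the number of labels")
    n_true = pred.y_true.sum(axis=1)
    keep = n_true > 0
    if not keep.any():
        return 0.0
    top = _topk_indices(pred.y_prob, k)
    hits = np.take_along_axis(pred.y_true, top, axis=1).sum(axis=1)
    return float((hits[keep] / n_true[keep]).mean())


def full_report(pred: PredictionSet, ks: tuple[int, ...] = (5, 8, 15)) -> MetricsReport:
    """All metrics in one report; k values above the label count are skipped."""
    micro_p, micro_r, micro_f, macro_p, macro_r, macro_f = prf_micro_macro(pred)
    micro_auc, macro_auc, excluded = auc_micro_macro(pred)
    yp = pred.y_pred
    yt = pred.y_true
    tp = ((yp == 1) & (yt == 1)).sum(axis=0)
    fp = ((yp == 1) & (yt == 0)).sum(axis=0)
    fn = ((yp == 0) & (yt == 1)).sum(axis=0)
    valid_ks = [k for k in ks if k <= pred.y_true.shape[1]]
    return MetricsReport(
        macro_auc=macro_auc,
        micro_auc=micro_auc,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f,
        precision_at_k={k: precision_at_k(pred, k) for k in valid_ks},
        recall_at_k={k: recall_at_k(pred, k) for k in valid_ks},
        tp=tp,
        fp=fp,
        fn=fn,
        n_auc_labels_excluded=excluded,
    )
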