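"""Evaluation metrics and a stratified K-fold harness.

Threshold metrics (accuracy, precision, sensitivity, specificity, MCC,
F1) come from confusion counts in closed form; zero-denominator cases
report 0 with a flag. ROC-AUC is the rank-based (Mann-Whitney)
statistic with ties at half credit, equal to the probability that a
random positive outscores a random negative. AUPR is the trapezoidal
area under the threshold-swept precision-recall curve,
sum_k (R_k - R_{k-1}) (P_k + P_{k-1}) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionCounts(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricReport:
    """Metric values for one evaluation (or one fold)."""

    acc: float
    precision: float
    sn: float
    sp: float
    mcc: float
    f1: float
    auc: float = float("nan")
    aupr: float = float("nan")
    threshold: float = 0.5
    degenerate_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ACC": self.acc,
            "Precision": self.precision,
            "SN": self.sn,
            "SP": self.sp,
            "MCC": self.mcc,
            "F1": self.f1,
            "AUC": self.auc,
            "AUPR": self.aupr,
        }


def _safe_ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts, threshold: float = 0.5) -> MetricReport:
    """Closed-form threshold metrics from confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: list[str] = []
    acc = (tp + tn) / counts.total
    precision = _safe_ratio(tp, tp + fp, flags, "precision")
    sn = _safe_ratio(tp, tp + fn, flags, "sensitivity")
    sp = _safe_ratio(tn, tn + fp, flags, "specificity")
    f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, flags, "f1")
    mcc_den = np.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _safe_ratio(tp * tn - fn * fp, mcc_den, flags, "mcc")
    return MetricReport(
        acc=acc, precision=precision, sn=sn, sp=sp, mcc=mcc, f1=f1,
        threshold=threshold, degenerate_flags=flags,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC-AUC (Mann-Whitney U / (n_pos n_neg)), ties half-credit."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined with a single class")
    ranks = rankdata(scores)  # average ranks give half credit to ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the precision-recall curve."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if labels.sum() in (0, len(labels)):
        raise ValueError("AUPR undefined with a single class")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # integrate along the threshold sweep (recall non-decreasing after
    # reversal); equal-recall segments contribute zero width
    return float(np.trapezoid(precision[::-1], recall[::-1]))


def score_report(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    """Full report: threshold metrics at ``threshold`` plus AUC/AUPR."""
    preds = (np.asarray(scores) >= threshold).astype(int)
    report = confusion_metrics(
        ConfusionCounts.from_predictions(labels, preds), threshold
    )
    report.auc = roc_auc(scores, labels)
    report.aupr = pr_auc(scores, labels)
    return report


@dataclass
class CrossValReport:
    per_fold: list[MetricReport]
    mean: dict
    sd: dict

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


def crossval_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    model_factory,
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValReport:
    """Stratified K-fold evaluation of ``model_factory()`` models.

    The factory must return an object with ``fit(X, y)`` and
    ``predict_proba(X)`` (column 1 scoring the positive class) or a
    ``predict_scores(X)`` method.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    per_fold = []
    for train_idx, test_idx in skf.split(X, y):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        if hasattr(model, "predict_proba"):
            scores = model.predict_proba(X[test_idx])[:, 1]
        else:
            scores = model.predict_scores(X[test_idx])
        per_fold.append(score_report(scores, y[test_idx], threshold))
    keys = per_fold[0].as_dict().keys()
    stacked = {k: np.array([r.as_dict()[k] for r in per_fold]) for k in keys}
    return CrossValReport(
        per_fold=per_fold,
        mean={k: float(v.mean()) for k, v in stacked.items()},
        sd={k: float(v.std(ddof=1)) for k, v in stacked.items()},
    )
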