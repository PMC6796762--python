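"""Model evaluation: stratified CV, confusion metrics, ROC/AUC, McNemar.

Metrics follow the standard confusion-matrix definitions:

    SN  = TP / (TP + FN)                    sensitivity (recall on 6mA)
    SP  = TN / (TN + FP)                    specificity
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

On a class-balanced evaluation set ACC equals (SN + SP) / 2 exactly.
AUC is the area under the ROC curve with rank-averaged tie handling,
equivalent to the normalised Mann-Whitney U statistic.

Cross-validation is stratified: each fold carries positive and negative
counts within one of the per-class quota.  :func:`cross_validate`
retrains the full pipeline inside each fold (including the KNN
reference and feature subsets) and pools the out-of-fold predictions,
so no prediction is ever made by a model that saw the record during
training.  Pooled (micro) metrics are the default; per-fold macro
averages are available behind a flag.

McNemar's chi-square test compares two classifiers on the same records
using only the discordant counts b (A right, B wrong) and c (A wrong,
B right): statistic (b - c)^2 / (b + c) on 1 df, without continuity
correction; an exact two-sided binomial variant is available for small
b + c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .seqio import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "stratified_kfold",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
    "mcnemar_test",
    "delta_acc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Sensitivity, specificity, accuracy, MCC and (optionally) AUC."""

    counts: ConfusionCounts
    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "TP": self.counts.TP,
            "TN": self.counts.TN,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "SN": self.SN,
            "SP": self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
        }
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def stratified_kfold(
    data: LabeledDataset | np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified k-fold assignments, reproducible from the seed.

    Returns ``(train_indices, test_indices)`` per fold.  Each class must
    have at least ``k`` members.
    """
    y = data.labels() if isinstance(data, LabeledDataset) else np.asarray(data, dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} records")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("predictions and labels are misaligned")
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts, auc: Optional[float] = None) -> MetricsReport:
    """SN/SP/ACC/MCC from confusion counts (MCC = 0 on a zero denominator)."""
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    if TP + FN == 0 or TN + FP == 0:
        raise ValueError("need at least one actual positive and one actual negative")
    sn = TP / (TP + FN)
    sp = TN / (TN + FP)
    acc = (TP + TN) / counts.total
    den = math.sqrt((TP + FN) * (TP + FP) * (TN + FP) * (TN + FN))
    if den == 0:
        warnings.warn("MCC denominator is zero; MCC set to 0", RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = (TP * TN - FP * FN) / den
    return MetricsReport(counts=counts, SN=sn, SP=sp, ACC=acc, MCC=mcc, AUC=auc)


def metrics_from_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> MetricsReport:
    auc = roc_auc(scores, y_true)[0] if scores is not None else None
    return compute_metrics(confusion_counts(y_true, y_pred), auc=auc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC plus ROC points ``(fpr, tpr)``; ties handled by rank-averaging."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr])


def cross_validate(
    config,
    data: LabeledDataset,
    k: int = 10,
    seed: int = 0,
    macro: bool = False,
) -> MetricsReport:
    """K-fold cross-validation of the full two-layer pipeline.

    Every fold trains a complete :class:`~sixma.ensemble.TrainedEnsemble`
    on the k-1 training folds (its KNN reference, feature subsets,
    hyperparameters and layer-1 weights are all fold-internal) and
    predicts the held-out fold.  With ``macro`` the report averages
    per-fold metrics; by default it pools the out-of-fold predictions,
    which is the stabler choice for MCC.
    """
    from .ensemble import classify, train_ensemble

    y = data.labels()
    folds = stratified_kfold(data, k=k, seed=seed)
    oof_scores = np.empty(len(data), dtype=float)
    oof_pred = np.empty(len(data), dtype=int)
    fold_reports: list[MetricsReport] = []
    for fold_idx, (tr, va) in enumerate(folds):
        try:
            model = train_ensemble(data.subset(tr), config)
            probs = model.predict_proba(data.subset(va))
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {fold_idx}: {exc}") from exc
        oof_scores[va] = probs
        oof_pred[va] = classify(probs, model.threshold)
        if macro:
            fold_reports.append(metrics_from_predictions(y[va], oof_pred[va], probs))
    if macro:
        counts = confusion_counts(y, oof_pred)
        return MetricsReport(
            counts=counts,
            SN=float(np.mean([r.SN for r in fold_reports])),
            SP=float(np.mean([r.SP for r in fold_reports])),
            ACC=float(np.mean([r.ACC for r in fold_reports])),
            MCC=float(np.mean([r.MCC for r in fold_reports])),
            AUC=float(np.mean([r.AUC for r in fold_reports])),
        )
    return metrics_from_predictions(y, oof_pred, oof_scores)


def mcnemar_test(
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    labels: Sequence[int],
    method: str = "asymptotic",
) -> tuple[float, float]:
    """McNemar's test on paired classifier predictions.

    Returns ``(statistic, p_value)`` where the statistic is
    (b - c)^2 / (b + c) without continuity correction.  ``method`` may
    be ``"asymptotic"`` (chi-square, 1 df), ``"exact"`` (two-sided
    binomial on the discordant pairs) or ``"auto"`` (exact when
    b + c < 25).  When b + c == 0 the classifiers are indistinguishable
    and p = 1.
    """
    a = np.asarray(pred_a, dtype=int)
    bp = np.asarray(pred_b, dtype=int)
    y = np.asarray(labels, dtype=int)
    if not (a.shape == bp.shape == y.shape):
        raise ValueError("predictions and labels are misaligned")
    a_right = a == y
    b_right = bp == y
    b = int((a_right & ~b_right).sum())
    c = int((~a_right & b_right).sum())
    if b + c == 0:
        return 0.0, 1.0
    stat = (b - c) ** 2 / (b + c)
    if method == "auto":
        method = "exact" if b + c < 25 else "asymptotic"
    if method == "exact":
        p = float(min(1.0, 2 * stats.binom.cdf(min(b, c), b + c, 0.5)))
    elif method == "asymptotic":
        p = float(stats.chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), p


def delta_acc(cv_report: MetricsReport, independent_report: MetricsReport) -> float:
    """|ACC_cv - ACC_independent| in percentage points (robustness summary)."""
    return abs(cv_report.ACC - independent_report.ACC) * 100.0
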