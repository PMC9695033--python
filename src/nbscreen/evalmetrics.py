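"""Confusion matrices, classification metric formulas, ROC/AUC and k-fold CV.

Metrics follow the classical contingency-table definitions with the active
class as positive:

    recall (sensitivity) = TP / (TP + FN)
    specificity          = TN / (FP + TN)
    precision            = TP / (TP + FP)
    F                    = (1 + a^2) * precision * recall / (a^2 * precision + recall)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Inactive-class precision/recall/F swap the classes; weighted averages weight
by true class sizes.  Metrics with a zero denominator are reported as NaN
with a warning, never silently 0.  AUC uses trapezoidal integration over the
full threshold sweep, equivalent to the normalized Mann-Whitney U with
half-credit for tied scores.  Cross-validation pools out-of-fold predictions
into a single confusion matrix, mirroring how single 10-fold tables are
conventionally reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import nbayes
from .nbayes import ACTIVE, FeatureVectorSet, INACTIVE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with active as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The matrix with the class roles exchanged."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f_measure: float


@dataclass(frozen=True)
class MetricsReport:
    active: ClassMetrics
    inactive: ClassMetrics
    specificity: float
    mcc: float
    weighted: ClassMetrics
    auc: Optional[float] = None


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as NaN", what)
        return float("nan")
    return num / den


def confusion(calls: Sequence[str], labels: Sequence[str]) -> ConfusionMatrix:
    """Tally calls against true labels (both "active"/"inactive")."""
    if len(calls) != len(labels):
        raise ValueError("calls and labels differ in length")
    if not calls:
        raise ValueError("empty input")
    tp = fn = fp = tn = 0
    for call, label in zip(calls, labels):
        if label == ACTIVE:
            if call == ACTIVE:
                tp += 1
            else:
                fn += 1
        else:
            if call == ACTIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _class_metrics(cm: ConfusionMatrix, alpha: float) -> ClassMetrics:
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    a2 = alpha * alpha
    f = _safe_div((1 + a2) * precision * recall, a2 * precision + recall, "F-measure")
    return ClassMetrics(precision=precision, recall=recall, f_measure=f)


def mcc(cm: ConfusionMatrix) -> float:
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        logger.warning("MCC undefined (zero denominator); reported as NaN")
        return float("nan")
    return (tp * tn - fp * fn) / den


def metrics_from_confusion(
    cm: ConfusionMatrix, alpha: float = 1.0, auc: Optional[float] = None
) -> MetricsReport:
    """Full metric report from a confusion matrix.

    *alpha* is the F-measure weighting parameter (1 gives the F1 score).
    """
    active = _class_metrics(cm, alpha)
    inactive = _class_metrics(cm.swapped(), alpha)
    specificity = _safe_div(cm.tn, cm.fp + cm.tn, "specificity")
    w_act = (cm.tp + cm.fn) / cm.total
    weighted = ClassMetrics(
        precision=w_act * active.precision + (1 - w_act) * inactive.precision,
        recall=w_act * active.recall + (1 - w_act) * inactive.recall,
        f_measure=w_act * active.f_measure + (1 - w_act) * inactive.f_measure,
    )
    return MetricsReport(
        active=active,
        inactive=inactive,
        specificity=specificity,
        mcc=mcc(cm),
        weighted=weighted,
        auc=auc,
    )


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> list[tuple[float, float]]:
    """(FPR, TPR) points over the full threshold sweep, high threshold first.

    Tied scores move together, so ties trace a diagonal segment whose
    trapezoidal area gives them half credit.
    """
    s = np.asarray(scores, dtype=float)
    y = np.array([1 if l == ACTIVE else 0 for l in labels])
    P, N = int(y.sum()), int((1 - y).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i, n = 0, len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            tp += int(y[j])
            fp += int(1 - y[j])
            j += 1
        points.append((fp / N, tp / P))
        i = j
    return points


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> tuple[float, list[tuple[float, float]]]:
    """AUC by trapezoidal integration, plus the curve points."""
    points = roc_curve(scores, labels)
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return auc, points


@dataclass
class CrossValResult:
    confusion: ConfusionMatrix
    metrics: MetricsReport
    scores: list[float]  # pooled out-of-fold scores, input order
    labels: list[str]
    fold_of: list[int]


def crossval(
    features: FeatureVectorSet,
    labels: Sequence[str],
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    penalize_unseen: bool = False,
) -> CrossValResult:
    """k-fold cross-validation of the naive Bayes classifier.

    Folds are stratified by default (sizes differ by at most one within each
    class); each fold is predicted by a model fitted on the other k-1 folds,
    and predictions are pooled into a single confusion matrix from which the
    metrics (and the out-of-fold AUC) are computed.  Deterministic per seed.
    """
    labels = list(labels)
    n = len(labels)
    if len(features) != n:
        raise ValueError("labels do not align with feature vectors")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    y = np.array([1 if l == ACTIVE else 0 for l in labels])
    if stratified:
        if min(int(y.sum()), int((1 - y).sum())) < k:
            raise ValueError("fewer samples in a class than folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    pooled_scores = [0.0] * n
    pooled_calls = [""] * n
    fold_of = [-1] * n
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        sub = FeatureVectorSet(
            ids=[features.ids[i] for i in train_idx],
            features=[features.features[i] for i in train_idx],
            bin_edges=features.bin_edges,
        )
        model = nbayes.fit(sub, [labels[i] for i in train_idx], penalize_unseen=penalize_unseen)
        for i in test_idx:
            sc = nbayes.score(model, features.features[i], features.ids[i])
            pooled_scores[i] = sc.score
            pooled_calls[i] = sc.call
            fold_of[i] = fold

    cm = confusion(pooled_calls, labels)
    auc, _ = roc_auc(pooled_scores, labels)
    report = metrics_from_confusion(cm, auc=auc)
    return CrossValResult(confusion=cm, metrics=report, scores=pooled_scores, labels=labels, fold_of=fold_of)


def export_metrics(report: MetricsReport, path) -> None:
    rows = [
        ("active", report.active),
        ("inactive", report.inactive),
        ("weighted_avg", report.weighted),
    ]
    with open(path, "w") as fh:
        fh.write("class\tprecision\trecall\tf_measure\n")
        for name, m in rows:
            fh.write(f"{name}\t{m.precision:.6f}\t{m.recall:.6f}\t{m.f_measure:.6f}\n")
        fh.write(f"# specificity\t{report.specificity:.6f}\n")
        fh.write(f"# mcc\t{report.mcc:.6f}\n")
        if report.auc is not None:
            fh.write(f"# auc\t{report.auc:.6f}\n")
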