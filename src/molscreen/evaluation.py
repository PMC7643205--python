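"""Classification metrics and statistical comparison of methods.

Implements the standard virtual-screening evaluation quantities — confusion
counts, accuracy, precision, recall, F1, the Matthews correlation coefficient
and rank-based AUROC — plus stratified k-fold cross-validation, Bonferroni
corrected t-tests between per-fold metric vectors, and Spearman rank
correlation between method performance profiles.

Any metric whose denominator contains a zero product is defined as 0 rather
than NaN, which keeps model leaderboards total-ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

LABELS = ("active", "inactive")


def _as_binary(labels: Sequence) -> np.ndarray:
    mapping = {"active": 1, "inactive": 0, 1: 1, 0: 0, True: 1, False: 0}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        key = lab.item() if isinstance(lab, np.generic) else lab
        if key not in mapping:
            raise ValueError(f"unknown label {lab!r}")
        out[i] = mapping[key]
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(truth: Sequence, predicted: Sequence) -> ConfusionCounts:
    """Exact TP/FP/TN/FN tallies over matched label vectors."""
    y, p = _as_binary(truth), _as_binary(predicted)
    if y.shape != p.shape:
        raise ValueError("truth and prediction vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def mcc_from_labels(truth: Sequence, predicted: Sequence) -> float:
    return mcc(confusion_counts(truth, predicted))


def auroc(truth: Sequence, scores: Sequence[float]) -> float:
    """Rank-based AUROC with tied scores counted one half.

    Equivalent to the Mann–Whitney U statistic normalized by the number of
    (positive, negative) pairs.  Requires both classes present.
    """
    y = _as_binary(truth)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("truth and score vectors differ in length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes in the truth vector")
    ranks = stats.rankdata(s)  # average ranks for ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def metrics_report(
    truth: Sequence, predicted: Sequence, scores: Sequence[float] | None = None
) -> MetricsReport:
    c = confusion_counts(truth, predicted)
    return MetricsReport(
        accuracy=accuracy(c),
        precision=precision(c),
        recall=recall(c),
        f1=f1(c),
        mcc=mcc(c),
        auroc=auroc(truth, scores) if scores is not None else None,
    )


def kfold_cv(
    features: Sequence,
    labels: Sequence,
    trainer: Callable,
    k: int = 10,
    seed: int = 0,
) -> list[MetricsReport]:
    """Stratified k-fold cross-validation; each item is tested exactly once.

    ``trainer(train_features, train_labels, test_features)`` must return
    ``(predicted_labels, scores)``; scores may be None.
    """
    y = _as_binary(labels)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority class size {counts.min()}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        pred, scores = trainer(
            [features[i] for i in train_idx], y[train_idx], [features[i] for i in test_idx]
        )
        reports.append(metrics_report(y[test_idx], pred, scores))
    return reports


def kfold_assignments(labels: Sequence, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index per item for a seeded stratified k-fold partition."""
    y = _as_binary(labels)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=np.int64)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def bonferroni_ttest(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    family_size: int,
    alpha: float = 0.05,
    paired: bool = True,
) -> tuple[float, float, bool]:
    """Two-sided t-test between matched per-fold metric vectors.

    Significance is declared at ``alpha / family_size`` (Bonferroni).  Folds
    are matched across methods, so the paired test is the default; Welch's
    unpaired variant is available for unmatched designs.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if paired and a.shape != b.shape:
        raise ValueError("paired test needs equal-length vectors")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two folds per method")
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    if paired:
        if np.allclose(a, b):
            return 0.0, 1.0, False
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    significant = bool(p < alpha / family_size)
    return float(t), float(p), significant


def spearman(perf_a: Sequence[float], perf_b: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties), in [-1, 1]."""
    a = np.asarray(perf_a, dtype=np.float64)
    b = np.asarray(perf_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("performance vectors differ in length")
    if len(a) < 2:
        raise ValueError("need at least two paired observations")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)
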