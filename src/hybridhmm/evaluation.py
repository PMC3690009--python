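"""Evaluation: confusion-matrix metrics, leave-one-day-out cross-validation
and paired significance tests.

Activity datasets are heavily imbalanced (one dominant class, several rare
ones), so overall accuracy is uninformative; models are compared by the
macro-averaged F-measure instead.  From a Q x Q confusion matrix (rows =
true class, columns = inferred class) with diagonal TP_i, row sums TT_i and
column sums TI_i:

    precision = (1/Q) sum_i TP_i / TI_i
    recall    = (1/Q) sum_i TP_i / TT_i
    F         = 2 * precision * recall / (precision + recall)

F is the harmonic mean of the two *aggregates*, not the mean of per-class
F scores.  Empty-denominator rule (it changes averages, so it is stated
prominently): a class never predicted contributes 0 to the precision sum,
a class never true contributes 0 to the recall sum, and the class still
counts in Q.  The idle class is scored like any other class.

The protocol is leave-one-day-out: each fold holds out one full
midnight-to-midnight day, trains on the rest, and scores the held-out day's
confusion matrix; the reported figure is the unweighted mean over folds
± standard deviation.  Model pairs are compared fold-by-fold with a paired
two-tailed t-test and a Wilcoxon signed-ranks test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ShapeError, ValidationError
from .hybrid import DaySequence, Trainer
from .sensor_data import LabelSequence

__all__ = [
    "ConfusionMatrix",
    "FoldResult",
    "PairedTestResult",
    "confusion",
    "macro_metrics",
    "leave_one_day_out",
    "summarize_folds",
    "paired_tests",
]


@dataclass
class ConfusionMatrix:
    """Q x Q count matrix; rows = true classes, columns = inferred."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        q = len(self.class_names)
        if self.counts.shape != (q, q):
            raise ShapeError("confusion counts must be Q x Q over class_names")
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class FoldResult:
    """Metrics of one held-out day."""

    day_id: int
    precision: float
    recall: float
    fmeasure: float
    confusion: ConfusionMatrix


@dataclass
class PairedTestResult:
    """Paired t-test and Wilcoxon signed-ranks comparison of fold scores.

    ``all_equal`` flags identical score vectors (both tests degenerate,
    p = 1); ``zero_variance`` flags a constant nonzero difference, where the
    t statistic diverges and the comparison is reported as a strong
    rejection rather than a finite statistic.
    """

    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    all_equal: bool = False
    zero_variance: bool = False


def confusion(y_true: LabelSequence, y_pred: LabelSequence) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #{t : y_true = i+1, y_pred = j+1}``."""
    if len(y_true) != len(y_pred):
        raise ShapeError("true and predicted label sequences differ in length")
    if y_true.class_names != y_pred.class_names:
        raise ValidationError("label sequences must share a class set")
    q = y_true.n_classes
    counts = np.zeros((q, q), dtype=np.int64)
    np.add.at(counts, (y_true.indices, y_pred.indices), 1)
    return ConfusionMatrix(counts, list(y_true.class_names))


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Macro precision, recall and F-measure with the 0-for-empty rule."""
    tp = np.diag(cm.counts).astype(float)
    ti = cm.counts.sum(axis=0).astype(float)
    tt = cm.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_i = np.where(ti > 0, tp / np.where(ti > 0, ti, 1), 0.0)
        rec_i = np.where(tt > 0, tp / np.where(tt > 0, tt, 1), 0.0)
    precision = float(prec_i.mean())
    recall = float(rec_i.mean())
    if precision + recall == 0:
        return precision, recall, 0.0
    f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, float(f)


def leave_one_day_out(
    days: Sequence[DaySequence], trainer: Trainer
) -> list[FoldResult]:
    """One fold per day: train on all other days, score the held-out one.

    A class present only in the held-out day is still scored (it simply
    contributes zero recall) and triggers a warning.
    """
    if len(days) < 2:
        raise ValidationError("leave-one-day-out needs at least 2 days")
    results = []
    for d, (test_feat, test_labels) in enumerate(days):
        train_days = [p for k, p in enumerate(days) if k != d]
        train_classes = np.unique(
            np.concatenate([l.labels for _, l in train_days]))
        only_test = set(np.unique(test_labels.labels)) - set(train_classes)
        if only_test:
            names = [test_labels.class_names[c - 1] for c in sorted(only_test)]
            warnings.warn(
                f"fold {d}: classes {names} appear only in the test day"
            )
        predict_fn = trainer(train_days)
        cm = confusion(test_labels, predict_fn(test_feat))
        p, r, f = macro_metrics(cm)
        results.append(FoldResult(d, p, r, f, cm))
    return results


def summarize_folds(results: Sequence[FoldResult]) -> dict[str, float]:
    """Unweighted mean ± sd of the per-fold metrics."""
    f = np.array([r.fmeasure for r in results])
    p = np.array([r.precision for r in results])
    r_ = np.array([r.recall for r in results])
    return {
        "fmeasure_mean": float(f.mean()),
        "fmeasure_sd": float(f.std(ddof=1)) if f.size > 1 else 0.0,
        "precision_mean": float(p.mean()),
        "precision_sd": float(p.std(ddof=1)) if p.size > 1 else 0.0,
        "recall_mean": float(r_.mean()),
        "recall_sd": float(r_.std(ddof=1)) if r_.size > 1 else 0.0,
        "n_folds": float(len(results)),
    }


def _wilcoxon(diff: np.ndarray) -> tuple[float, float, bool]:
    """Signed-ranks statistic min(W+, W-) and two-sided p-value.

    Zero differences are dropped (the standard signed-ranks convention);
    the p-value uses the exact distribution for n <= 25 and the normal
    approximation beyond.  Returns (W, p, undefined_flag).
    """
    d = diff[diff != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    method = "exact" if d.size <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.wilcoxon(d, method=method).pvalue)
    return w, p, False


def paired_tests(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> PairedTestResult:
    """Compare two models' per-fold scores with matched pairs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ShapeError("paired score vectors must have equal length")
    if a.size < 2:
        raise ValidationError("paired tests need at least 2 folds")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(0.0, 1.0, 0.0, 1.0, all_equal=True)
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, np.abs(d).max()):
        # constant nonzero difference: t diverges, report a strong rejection
        w, wp, _ = _wilcoxon(d)
        sign = float(np.sign(d.mean()))
        return PairedTestResult(sign * np.inf, 0.0, w, wp, zero_variance=True)
    t_stat, t_p = stats.ttest_rel(a, b)
    w, wp, undefined = _wilcoxon(d)
    return PairedTestResult(float(t_stat), float(t_p), w,
                            1.0 if undefined else wp)
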