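"""Binary-classification metrics, ROC/AUC, cross-validation and model comparison.

Metrics follow the standard confusion-count definitions: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy, and Matthews' correlation
coefficient; AUC is the trapezoidal area under the ROC curve (equal to
the Mann-Whitney probability of ranking a random positive above a random
negative).  The balance statistic deltaS = |sensitivity - specificity|
quantifies how even a predictor is across classes; small is balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .io_core import LABEL_PIP, PeptideDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: Optional[float] = None

    @property
    def delta_s(self) -> float:
        return abs(self.sensitivity - self.specificity)

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "mcc": self.mcc,
            "auc": self.auc, "delta_s": self.delta_s,
        }


def count_confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally calls against labels (1 = PIP/positive)."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label/call length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> EvalReport:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    A zero MCC denominator (any marginal empty) yields MCC = 0; an empty
    positive or negative margin yields sensitivity/specificity 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated peptides")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return EvalReport(counts, sens, spec, acc, float(mcc))


def compute_auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the ROC curve; errors if only one class is present."""
    yt = np.asarray(y_true, dtype=int)
    if len(np.unique(yt)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(yt, np.asarray(scores, dtype=float)))


def roc_points(scores: Sequence[float], y_true: Sequence[int]) -> np.ndarray:
    """ROC curve as an (n, 2) array of (FPR, TPR) points."""
    fpr, tpr, _ = roc_curve(np.asarray(y_true, int), np.asarray(scores, float))
    return np.column_stack([fpr, tpr])


def evaluate_predictions(
    scores: Sequence[float], calls: Sequence[int], y_true: Sequence[int]
) -> EvalReport:
    """Full report (metrics + AUC when both classes present) from scores/calls."""
    report = compute_metrics(count_confusion(y_true, calls))
    auc = None
    if len(np.unique(np.asarray(y_true, int))) == 2:
        auc = compute_auc(scores, y_true)
    return EvalReport(report.counts, report.sensitivity, report.specificity,
                      report.accuracy, report.mcc, auc)


def labels_to_binary(ds: PeptideDataset) -> np.ndarray:
    return np.asarray([1 if p.label == LABEL_PIP else 0 for p in ds], dtype=int)


def cross_validate(
    ds: PeptideDataset,
    trainer: Callable[[PeptideDataset], Callable[[PeptideDataset], tuple[np.ndarray, np.ndarray]]],
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[EvalReport], EvalReport]:
    """Stratified k-fold cross-validation of an arbitrary trainer.

    ``trainer(train_ds)`` must return a predictor mapping a dataset to
    ``(scores, calls)`` arrays.  Returns per-fold reports plus a pooled
    report computed from summed confusion counts and pooled scores.
    """
    y = labels_to_binary(ds)
    if folds > min(np.bincount(y)):
        raise ValueError("more folds than members of the smallest class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ids = ds.ids()
    fold_reports: list[EvalReport] = []
    pooled_scores: list[float] = []
    pooled_calls: list[int] = []
    pooled_true: list[int] = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = ds.subset([ids[i] for i in train_idx], "cv-train")
        test = ds.subset([ids[i] for i in test_idx], "cv-test")
        predictor = trainer(train)
        scores, calls = predictor(test)
        yt = labels_to_binary(test)
        fold_reports.append(evaluate_predictions(scores, calls, yt))
        pooled_scores.extend(np.asarray(scores, float))
        pooled_calls.extend(np.asarray(calls, int))
        pooled_true.extend(yt)
    pooled = evaluate_predictions(pooled_scores, pooled_calls, pooled_true)
    return fold_reports, pooled


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    zero_variance: bool = False


def compare_models(
    metrics_a: Sequence[float], metrics_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided paired t-test over matched per-subset metric values.

    Identical lists give p = 1.  A nonzero constant difference has zero
    variance, for which the t statistic diverges; this is reported as
    p = 0 with the ``zero_variance`` flag set.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric lists must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = a - b
    if np.allclose(diff, 0.0):
        return ComparisonResult(0.0, 1.0)
    if np.isclose(np.std(diff, ddof=1), 0.0):
        return ComparisonResult(float(np.inf) * np.sign(diff.mean()), 0.0, True)
    t, p = _scipy_stats.ttest_rel(a, b)
    return ComparisonResult(float(t), float(p))


def report_to_tsv(reports: dict[str, EvalReport], path: str) -> None:
    keys = ("tp", "tn", "fp", "fn", "sensitivity", "specificity",
            "accuracy", "mcc", "auc", "delta_s")
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(keys) + "\n")
        for name, rep in reports.items():
            d = rep.as_dict()
            fh.write(name + "\t" + "\t".join(
                "" if d[k] is None else f"{d[k]:.6g}" for k in keys) + "\n")
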