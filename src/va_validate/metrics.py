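"""Individual- and population-level accuracy metrics for VA cause assignment.

Individual level: chance-corrected concordance (CCC).  For cause ``j`` out of
``N`` causes,

    CCC_j = (TP_j / (TP_j + FN_j) - 1/N) / (1 - 1/N)

i.e. one-vs-rest sensitivity rescaled so 0 equals random guessing among N
causes and 1 equals perfect detection; the minimum, at sensitivity 0, is
-1/(N-1).  Causes with no true cases in the evaluation set (TP+FN = 0) have
undefined CCC; they are flagged as NaN and excluded from the overall
mean/median.

Population level: cause-specific mortality fraction (CSMF) accuracy,

    1 - sum_j |CSMF_j^true - CSMF_j^pred| / (2 (1 - min_j CSMF_j^true)),

which lies in [0, 1], and its chance-corrected form

    CCCSMF = (CSMFAccuracy - (1 - e^-1)) / (1 - (1 - e^-1)),

where 1 - e^-1 ~= 0.632 is the CSMF accuracy achieved by random cause
allocation when true fractions are drawn from an uninformative Dirichlet;
CCCSMF is negative when a method does worse than that chance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import CauseList

__all__ = [
    "CHANCE_CSMF_ACCURACY",
    "ConfusionSummary",
    "MetricReport",
    "confusion_counts",
    "ccc_per_cause",
    "overall_ccc",
    "csmf_from_labels",
    "csmf_accuracy",
    "cccsmf_accuracy",
    "sensitivity_specificity",
    "compute_metric_report",
]

#: CSMF accuracy of random allocation under Dirichlet-distributed true
#: fractions: 1 - 1/e.
CHANCE_CSMF_ACCURACY: float = 1.0 - math.exp(-1.0)


@dataclass
class ConfusionSummary:
    """One-vs-rest counts per cause plus the full misclassification matrix."""

    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    matrix: np.ndarray  # matrix[true, predicted]
    n_records: int
    cause_list: CauseList

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        N = self.cause_list.N
        if not (self.tp.shape == self.fn.shape == self.fp.shape == self.tn.shape == (N,)):
            raise ValueError("per-cause count vectors must have length N")
        if self.matrix.shape != (N, N):
            raise ValueError("misclassification matrix must be N x N")
        if (self.matrix < 0).any():
            raise ValueError("misclassification counts must be non-negative")
        totals = self.tp + self.fn + self.fp + self.tn
        if not (totals == self.n_records).all():
            raise ValueError("TP+FN+FP+TN must equal n_records for every cause")
        if self.matrix.sum() != self.n_records:
            raise ValueError("misclassification matrix total must equal n_records")


def confusion_counts(true_causes: Sequence[str], predicted_causes: Sequence[str],
                     cause_list: CauseList) -> ConfusionSummary:
    """Tally one-vs-rest TP/FN/FP/TN per cause and the N x N matrix."""
    if len(true_causes) == 0:
        raise ValueError("empty label sequences")
    if len(true_causes) != len(predicted_causes):
        raise ValueError("true and predicted label sequences differ in length")
    t = cause_list.indices_of(list(true_causes))
    p = cause_list.indices_of(list(predicted_causes))
    N = cause_list.N
    matrix = np.zeros((N, N), dtype=np.int64)
    np.add.at(matrix, (t, p), 1)
    true_counts = matrix.sum(axis=1)
    pred_counts = matrix.sum(axis=0)
    tp = np.diag(matrix).copy()
    fn = true_counts - tp
    fp = pred_counts - tp
    n = len(t)
    tn = n - tp - fn - fp
    return ConfusionSummary(tp, fn, fp, tn, matrix, n, cause_list)


def ccc_per_cause(confusion: ConfusionSummary, N: int | None = None) -> np.ndarray:
    """Chance-corrected concordance per cause; NaN where TP+FN = 0."""
    if N is None:
        N = confusion.cause_list.N
    if N < 2:
        raise ValueError("CCC needs at least 2 causes")
    denom = confusion.tp + confusion.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = confusion.tp / denom
    ccc = (sens - 1.0 / N) / (1.0 - 1.0 / N)
    ccc = np.where(denom > 0, ccc, np.nan)
    defined = ccc[~np.isnan(ccc)]
    lo = -1.0 / (N - 1)
    if defined.size and ((defined < lo - 1e-12).any() or (defined > 1.0 + 1e-12).any()):
        raise AssertionError("CCC outside [-1/(N-1), 1]")
    return ccc


def overall_ccc(ccc_by_cause: Sequence[float], method: str = "mean") -> float:
    """Aggregate per-cause CCCs over defined (non-NaN) causes."""
    vals = np.asarray(ccc_by_cause, dtype=np.float64)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no cause has a defined CCC")
    if method == "mean":
        return float(vals.mean())
    if method == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregation method {method!r}")


def csmf_from_labels(labels: Sequence[str], cause_list: CauseList) -> np.ndarray:
    """Fraction of records per cause (sums to 1 exactly for integer counts)."""
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    idx = cause_list.indices_of(list(labels))
    counts = np.bincount(idx, minlength=cause_list.N)
    return counts / counts.sum()


def csmf_accuracy(csmf_true: Sequence[float], csmf_pred: Sequence[float]) -> float:
    t = np.asarray(csmf_true, dtype=np.float64)
    p = np.asarray(csmf_pred, dtype=np.float64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("CSMF vectors must be 1-D of equal length")
    for name, v in (("true", t), ("pred", p)):
        if (v < -1e-12).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"csmf_{name} must be non-negative and sum to 1 within 1e-9")
    denom = 2.0 * (1.0 - t.min())
    if denom == 0.0:
        raise ValueError("degenerate true CSMF (all mass on one cause): denominator is 0")
    acc = 1.0 - np.abs(t - p).sum() / denom
    return float(min(max(acc, 0.0), 1.0))


def cccsmf_accuracy(csmf_acc: float) -> float:
    """Chance-correct a CSMF accuracy; negative means worse than chance."""
    if not (0.0 <= csmf_acc <= 1.0):
        raise ValueError("csmf_acc must be in [0, 1]")
    return (csmf_acc - CHANCE_CSMF_ACCURACY) / (1.0 - CHANCE_CSMF_ACCURACY)


def sensitivity_specificity(confusion: ConfusionSummary):
    """Per-cause sensitivity/specificity and their medians over defined causes.

    Sensitivity is NaN for causes with no true cases and excluded from the
    median; specificity is NaN only if TN+FP = 0 (a single-cause test set).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = confusion.tp / (confusion.tp + confusion.fn)
        spec = confusion.tn / (confusion.tn + confusion.fp)
    sens = np.where(confusion.tp + confusion.fn > 0, sens, np.nan)
    spec = np.where(confusion.tn + confusion.fp > 0, spec, np.nan)
    sens_med = float(np.nanmedian(sens)) if not np.isnan(sens).all() else float("nan")
    spec_med = float(np.nanmedian(spec)) if not np.isnan(spec).all() else float("nan")
    return sens, spec, sens_med, spec_med


@dataclass
class MetricReport:
    """All accuracy metrics for one evaluation (e.g. one test-train split)."""

    confusion: ConfusionSummary
    ccc_by_cause: np.ndarray
    ccc_overall_mean: float
    ccc_overall_median: float
    csmf_true: np.ndarray
    csmf_pred: np.ndarray
    csmf_accuracy: float
    cccsmf_accuracy: float
    sensitivity_by_cause: np.ndarray
    specificity_by_cause: np.ndarray
    sensitivity_median: float
    specificity_median: float

    SCALAR_METRICS = (
        "ccc_overall_mean",
        "ccc_overall_median",
        "csmf_accuracy",
        "cccsmf_accuracy",
        "sensitivity_median",
        "specificity_median",
    )

    def scalars(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.SCALAR_METRICS}


def compute_metric_report(true_causes: Sequence[str], predicted_causes: Sequence[str],
                          cause_list: CauseList) -> MetricReport:
    """Score one set of predictions against gold causes.

    The true CSMF is the realised cause composition of ``true_causes`` (for a
    Dirichlet-resampled test set this is the realised, not the target,
    composition).
    """
    conf = confusion_counts(true_causes, predicted_causes, cause_list)
    ccc = ccc_per_cause(conf)
    csmf_t = csmf_from_labels(true_causes, cause_list)
    csmf_p = csmf_from_labels_allow_zero(predicted_causes, cause_list)
    acc = csmf_accuracy(csmf_t, csmf_p)
    sens, spec, sens_med, spec_med = sensitivity_specificity(conf)
    return MetricReport(
        confusion=conf,
        ccc_by_cause=ccc,
        ccc_overall_mean=overall_ccc(ccc, "mean"),
        ccc_overall_median=overall_ccc(ccc, "median"),
        csmf_true=csmf_t,
        csmf_pred=csmf_p,
        csmf_accuracy=acc,
        cccsmf_accuracy=cccsmf_accuracy(acc),
        sensitivity_by_cause=sens,
        specificity_by_cause=spec,
        sensitivity_median=sens_med,
        specificity_median=spec_med,
    )


def csmf_from_labels_allow_zero(labels: Sequence[str], cause_list: CauseList) -> np.ndarray:
    # identical to csmf_from_labels; kept as an alias to make the call sites
    # explicit that a predicted composition may legitimately miss causes
    return csmf_from_labels(labels, cause_list)
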