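"""Classification statistics, ROC curves and DeLong AUC standard errors.

Six statistics are reported as percentages from the confusion counts:

    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)
    F-measure   = 2 * Precision * Sensitivity / (Precision + Sensitivity)
    NPV         = TN / (TN + FN)

ROC curves are built with Fawcett's linear-scan algorithm: samples sorted by
decreasing score, one ROC point per distinct score value (ties grouped, which
yields diagonal segments), starting at (0, 0) for threshold +inf and ending
at (1, 1).  The trapezoidal AUC of this curve equals the Mann-Whitney
concordance probability.  The AUC standard error follows DeLong's placement
value construction, with a normal-approximation 95% confidence interval.

Metrics with a zero denominator are reported as ``nan`` (with a warning),
never silently as zero.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    pass


class UndefinedRocError(EvaluationError):
    """ROC requested with fewer than one positive or one negative."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise EvaluationError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six classification statistics, in percent (nan if undefined)."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    npv: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "npv": self.npv,
        }

    def rounded(self, ndigits: int = 1) -> dict:
        """Reporting-layer rounding; internals stay full precision."""
        return {
            k: (round(v, ndigits) if math.isfinite(v) else v)
            for k, v in self.as_dict().items()
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC points (fpr, tpr, threshold), AUC, DeLong SE and 95% CI."""

    points: tuple
    auc: float
    se: float
    ci95: tuple


def confusion(truth, predicted) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from +-1 truth and prediction vectors."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1 or truth.size == 0:
        raise EvaluationError("truth/prediction must be equal-length 1-D, n >= 1")
    if not (np.isin(truth, (-1, 1)).all() and np.isin(predicted, (-1, 1)).all()):
        raise EvaluationError("labels must be -1 or +1")
    pos = truth == 1
    pred_pos = predicted == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _ratio_pct(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return math.nan
    return 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The six classification statistics from confusion counts."""
    if c.total == 0:
        raise EvaluationError("empty confusion table")
    accuracy = _ratio_pct(c.tp + c.tn, c.total, "accuracy")
    sensitivity = _ratio_pct(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio_pct(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio_pct(c.tp, c.tp + c.fp, "precision")
    npv = _ratio_pct(c.tn, c.tn + c.fn, "npv")
    if (
        math.isfinite(precision)
        and math.isfinite(sensitivity)
        and precision + sensitivity > 0
    ):
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        warnings.warn("f_measure undefined", stacklevel=2)
        f_measure = math.nan
    return MetricsReport(
        accuracy, sensitivity, specificity, precision, f_measure, npv
    )


# ---------------------------------------------------------------------------
# ROC by threshold linear scan
# ---------------------------------------------------------------------------

def _check_roc_inputs(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise EvaluationError("scores/truth must be equal-length 1-D")
    if not np.isin(truth, (-1, 1)).all():
        raise EvaluationError("truth labels must be -1 or +1")
    m = int(np.sum(truth == 1))
    n = int(np.sum(truth == -1))
    if m == 0 or n == 0:
        raise UndefinedRocError("need at least one positive and one negative")
    return scores, truth, m, n


def roc_linear_scan(scores, truth) -> RocCurve:
    """ROC curve via a single pass over score-sorted samples.

    Emits one point per distinct score value (equal scores processed as a
    group), beginning at (0, 0) with threshold +inf and ending at (1, 1).
    AUC is the trapezoidal area, equal to the Mann-Whitney statistic with
    ties counted 1/2.
    """
    scores, truth, m, n = _check_roc_inputs(scores, truth)
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0, math.inf)]
    tp = fp = 0
    auc = 0.0
    i = 0
    while i < scores.size:
        thr = scores[order[i]]
        tp_prev, fp_prev = tp, fp
        while i < scores.size and scores[order[i]] == thr:
            if truth[order[i]] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        auc += (fp - fp_prev) / n * (tp + tp_prev) / (2 * m)  # trapezoid
        points.append((fp / n, tp / m, float(thr)))
    se, ci95 = auc_se_delong(scores, truth)
    return RocCurve(points=tuple(points), auc=auc, se=se, ci95=ci95)


def auc_se_delong(scores, truth) -> tuple[float, tuple]:
    """DeLong standard error of the AUC and a normal 95% CI.

    Placement values: V10[i] is the fraction of negatives each positive
    out-scores (ties 1/2), V01[j] the fraction of positives out-scoring
    each negative.  SE = sqrt(var(V10)/m + var(V01)/n) with sample
    variances; CI = AUC +- 1.96*SE, clipped to [0, 1].
    """
    scores, truth, m, n = _check_roc_inputs(scores, truth)
    pos = scores[truth == 1]
    neg = scores[truth == -1]
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    auc = float(cmp.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return se, (lo, hi)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_metrics_table(path, rows: dict, fmt: str = "tsv") -> None:
    """Write per-classifier metrics, ``{name: MetricsReport}``, as TSV/JSON."""
    table = {name: rep.rounded() for name, rep in rows.items()}
    if fmt == "tsv":
        df = pd.DataFrame.from_dict(table, orient="index")
        df.index.name = "classifier"
        df.to_csv(path, sep="\t")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(table, fh, indent=2)
            fh.write("\n")
    else:
        raise EvaluationError(f"unknown report format {fmt!r}")


def write_roc_points(path, curve: RocCurve) -> None:
    """Export ROC points as TSV (fpr, tpr, threshold) for plotting."""
    df = pd.DataFrame(curve.points, columns=["fpr", "tpr", "threshold"])
    df.to_csv(path, sep="\t", index=False)
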