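"""Confusion-matrix bookkeeping and classification performance metrics.

Implements the standard binary-classification summary statistics used to
grade diabetic-eye-disease classifiers: accuracy, sensitivity (recall),
specificity, precision, Matthews correlation coefficient, error rate and
F1-score, plus a one-vs-rest report for multiclass problems.

All metrics are computed on the fraction scale internally; percent
formatting is a presentation concern handled by :meth:`MetricSet.to_percent`
and the report writers.  Metrics whose denominator vanishes are reported as
``None`` (flagged missing), never silently as zero, so macro averages are
not quietly inflated.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "classification_metrics",
    "one_vs_rest_report",
    "write_report_json",
    "write_report_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a binary confusion matrix (tp, tn, fp, fn)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass
class MetricSet:
    """One row of a performance report.

    ``None`` marks a metric whose denominator was zero (undefined), e.g.
    precision when no positive prediction was made.  ``scale`` is either
    ``"fraction"`` or ``"percent"``.
    """

    acc: Optional[float]
    sen: Optional[float]
    spc: Optional[float]
    pre: Optional[float]
    mcc: Optional[float]
    err: Optional[float]
    f1: Optional[float]
    scale: str = "fraction"

    _FIELDS = ("acc", "sen", "spc", "pre", "mcc", "err", "f1")

    def to_percent(self) -> "MetricSet":
        """Return a copy on the percent scale (values x 100).

        MCC, ER and F1 are conventionally printed as fractions even in
        percent-scale tables; here *all* fields are scaled uniformly and the
        caller chooses which to format how.
        """
        if self.scale == "percent":
            return MetricSet(**self.as_dict(), scale="percent")
        vals = {k: (None if v is None else 100.0 * v) for k, v in self.as_dict().items()}
        return MetricSet(**vals, scale="percent")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive_label
) -> ConfusionCounts:
    """Tally the binary confusion matrix of two label sequences.

    Every pair is classified against ``positive_label``: a pair where both
    sides equal it is a true positive, and so on.  The four counts always
    partition the input, so ``tp + tn + fp + fn == len(y_true)``.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted labels"
        )
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    alphabet = set(y_true) | set(y_pred)
    if positive_label not in alphabet:
        raise ValueError(f"positive label {positive_label!r} absent from labels")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        truth_pos = t == positive_label
        pred_pos = p == positive_label
        if truth_pos and pred_pos:
            tp += 1
        elif not truth_pos and not pred_pos:
            tn += 1
        elif pred_pos:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def classification_metrics(
    counts: ConfusionCounts, er_mode: str = "complement_accuracy"
) -> MetricSet:
    """Compute the full metric set from confusion counts.

    Parameters
    ----------
    counts
        Binary confusion counts; the total must be at least 1.
    er_mode
        ``"complement_accuracy"`` gives ER = 1 - ACC (the convention that
        matches the reference result tables, e.g. ACC 0.986 -> ER 0.014);
        ``"balanced"`` gives ER = 1 - (SEN + SPC)/2, the balanced error
        rate.  In balanced mode ER is undefined whenever SEN or SPC is.
    """
    if er_mode not in ("complement_accuracy", "balanced"):
        raise ValueError(f"unknown er_mode {er_mode!r}")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total < 1:
        raise ValueError("at least one labeled pair required")

    acc = (tp + tn) / total
    sen = _safe_div(tp, tp + fn)
    spc = _safe_div(tn, tn + fp)
    pre = _safe_div(tp, tp + fp)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    if pre is None or sen is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2 * pre * sen / (pre + sen)
    if er_mode == "complement_accuracy":
        err: Optional[float] = 1.0 - acc
    else:
        err = None if (sen is None or spc is None) else 1.0 - 0.5 * (sen + spc)
    return MetricSet(acc=acc, sen=sen, spc=spc, pre=pre, mcc=mcc, err=err, f1=f1)


def one_vs_rest_report(
    y_true: Sequence, y_pred: Sequence, er_mode: str = "complement_accuracy"
) -> dict:
    """Per-class one-vs-rest metrics plus a macro-average row.

    Each class present in ``y_true`` is scored on the binarized problem
    (class vs rest).  The ``"macro"`` row averages each metric over the
    classes for which it is defined.
    """
    classes = sorted(set(y_true), key=lambda c: str(c))
    if len(classes) < 2:
        raise ValueError("one-vs-rest report needs at least two classes in y_true")
    report: dict = {}
    for c in classes:
        counts = confusion_counts(y_true, y_pred, positive_label=c)
        report[c] = classification_metrics(counts, er_mode=er_mode)

    macro_vals = {}
    for f in MetricSet._FIELDS:
        defined = [getattr(report[c], f) for c in classes if getattr(report[c], f) is not None]
        macro_vals[f] = sum(defined) / len(defined) if defined else None
    report["macro"] = MetricSet(**macro_vals)
    return report


def write_report_json(report: Mapping, path) -> None:
    """Serialize a class -> MetricSet map as nested JSON."""
    payload = {
        str(cls): {k: v for k, v in ms.as_dict().items()} for cls, ms in report.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_report_csv(report: Mapping, path) -> None:
    """Serialize a class -> MetricSet map as CSV, one row per class."""
    cols = ["class", "ACC", "SEN", "SPC", "PRE", "MCC", "ER", "F1"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for cls, ms in report.items():
            d = ms.as_dict()
            writer.writerow(
                [cls] + ["" if d[k] is None else f"{d[k]:.6g}"
                         for k in ("acc", "sen", "spc", "pre", "mcc", "err", "f1")]
            )
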