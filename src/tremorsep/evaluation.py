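"""Confusion-based metrics, rank AUC, per-action breakdown, repeat aggregation.

Positive = tremulous, negative = voluntary. Accuracy, sensitivity (recall
on tremor), specificity (recall on voluntary), precision and F1 follow the
usual confusion-count definitions; metrics with a zero denominator are
reported as missing (None) and flagged, never silently coerced to 0 —
silent zeros would corrupt mean +/- SD aggregation over the re-training
repeats. AUC-ROC is the midrank Mann-Whitney statistic, which equals
trapezoidal integration of the ROC curve and is tie-safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity",
                "f1", "auc_roc")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    auc_roc: float | None = None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "counts": {"TP": self.counts.tp, "TN": self.counts.tn,
                       "FP": self.counts.fp, "FN": self.counts.fn},
            **{m: getattr(self, m) for m in METRIC_NAMES},
            "undefined": sorted(self.undefined),
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Metrics from binary truth/prediction arrays.

    ``scores`` (optional) adds AUC-ROC when both classes are present.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.size == 0:
        raise EvaluationError("empty input")
    if y_true.shape != y_pred.shape:
        raise EvaluationError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    counts = ConfusionCounts(tp, tn, fp, fn)
    accuracy = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    if precision is not None and sensitivity is not None \
            and (precision + sensitivity) > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = None
    auc = None
    if scores is not None and np.unique(y_true).size == 2:
        auc = auc_roc(y_true, scores)
    undefined = frozenset(
        m for m, v in (("precision", precision), ("sensitivity", sensitivity),
                       ("specificity", specificity), ("f1", f1))
        if v is None)
    return MetricsReport(counts=counts, accuracy=accuracy,
                         precision=precision, sensitivity=sensitivity,
                         specificity=specificity, f1=f1, auc_roc=auc,
                         undefined=undefined)


def auc_roc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y_true = np.asarray(y_true, int)
    scores = np.asarray(scores, float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes in y_true")
    ranks = rankdata(scores, method="average")
    return float((ranks[y_true == 1].sum()
                  - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aggregate_repeats(reports: list[MetricsReport]
                      ) -> dict[str, dict[str, float | int | None]]:
    """Per-metric sample mean and SD (ddof=1) over re-training repeats.

    Undefined (missing) values are excluded; each entry records how many
    repeats contributed.
    """
    if len(reports) < 2:
        raise EvaluationError("need >= 2 reports to aggregate")
    out: dict[str, dict] = {}
    for m in METRIC_NAMES:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        if vals:
            arr = np.asarray(vals, float)
            out[m] = {"mean": float(arr.mean()),
                      "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                      "n": int(arr.size)}
        else:
            out[m] = {"mean": None, "sd": None, "n": 0}
    return out


def per_action_report(y_true, y_pred, action_tags,
                      scores=None,
                      known_actions: tuple[str, ...] | None = None,
                      ) -> dict[str, MetricsReport]:
    """Confusion metrics restricted to each activity's windows."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    tags = np.asarray(action_tags)
    if tags.shape != y_true.shape:
        raise EvaluationError("action tags must cover all windows")
    if known_actions is not None:
        unknown = set(tags) - set(known_actions)
        if unknown:
            raise EvaluationError(f"unknown action tags: {sorted(unknown)}")
    out = {}
    for action in sorted(set(tags.tolist())):
        mask = tags == action
        sc = None if scores is None else np.asarray(scores, float)[mask]
        try:
            out[action] = confusion_metrics(y_true[mask], y_pred[mask], sc)
        except EvaluationError:
            # AUC undefined for a single-class activity slice
            out[action] = confusion_metrics(y_true[mask], y_pred[mask], None)
    return out
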