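"""Classifier evaluation statistics.

Confusion counts, precision / recall / accuracy / F1, ROC with AUC,
cumulative gain, and outcome-stratified probability summaries. The active
class is the positive class throughout.

Definitions::

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Ratios with zero denominators are reported as undefined with a stated
reason rather than coerced to 0. AUC uses the rank (Mann-Whitney)
formulation with midranks for ties, so it equals the probability that a
randomly chosen active outscores a randomly chosen inactive, ties counted
one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .containers import ValidationError
from .models import PROBABILITY_CUTOFF, as_binary_labels


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Metric values; an unset metric is None with the reason in ``undefined``."""

    counts: ConfusionCounts
    precision: float | None
    recall: float | None
    accuracy: float
    f1: float | None
    auc: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "undefined": self.undefined,
        }


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = as_binary_labels(y_true)
    y_pred = as_binary_labels(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.n == 0:
        raise ValidationError("no evaluated compounds (all counts zero)")
    undefined: dict[str, str] = {}
    precision = recall = f1 = None
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        undefined["precision"] = "no predicted positives (TP + FP = 0)"
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        undefined["recall"] = "no true positives in reference (TP + FN = 0)"
    accuracy = (counts.tp + counts.tn) / counts.n
    if precision is not None and recall is not None:
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            undefined["f1"] = "precision + recall = 0"
    else:
        undefined["f1"] = "precision or recall undefined"
    return MetricsReport(
        counts=counts,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        undefined=undefined,
    )


def roc_auc(y_true, scores) -> tuple[float, pd.DataFrame]:
    """Midrank AUC plus trapezoidal ROC curve points for plotting.

    AUC = (sum of active midranks - n_act*(n_act+1)/2) / (n_act * n_inact).
    """
    y_true = as_binary_labels(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValidationError("labels and scores lengths differ")
    n_act = int((y_true == 1).sum())
    n_inact = int((y_true == 0).sum())
    if n_act == 0 or n_inact == 0:
        raise ValidationError("roc_auc requires both classes present")
    ranks = rankdata(scores, method="average")
    auc = (ranks[y_true == 1].sum() - n_act * (n_act + 1) / 2) / (n_act * n_inact)
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc), curve


def cumulative_gain(y_true, scores, depths) -> pd.DataFrame:
    """Fraction of all actives captured in the top score-ranked fraction.

    Compounds are sorted by score descending with a stable tie-break on
    input order; gain(d) = actives among the top ceil(d*n) / total actives.
    """
    y_true = as_binary_labels(y_true)
    scores = np.asarray(scores, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValidationError("depths must be non-empty")
    if (depths <= 0).any() or (depths > 1).any():
        raise ValidationError("depths must lie in (0, 1]")
    n_act = int((y_true == 1).sum())
    if n_act == 0 or n_act == len(y_true):
        raise ValidationError("cumulative gain requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = y_true[order]
    cum_actives = np.cumsum(sorted_labels)
    n = len(y_true)
    rows = []
    for d in depths:
        k = int(np.ceil(d * n))
        rows.append({"depth": float(d), "n_top": k, "gain": cum_actives[k - 1] / n_act})
    return pd.DataFrame(rows)


def probability_by_outcome(y_true, probabilities) -> dict[str, dict]:
    """Probability-score summaries per prediction outcome (TP/TN/FP/FN).

    Hard labels via p >= 0.5. Each group reports its size, mean, quartiles
    and raw values; empty groups are reported as empty.
    """
    y_true = as_binary_labels(y_true)
    p = np.asarray(probabilities, dtype=float)
    y_pred = (p >= PROBABILITY_CUTOFF).astype(int)
    groups = {
        "TP": p[(y_true == 1) & (y_pred == 1)],
        "TN": p[(y_true == 0) & (y_pred == 0)],
        "FP": p[(y_true == 0) & (y_pred == 1)],
        "FN": p[(y_true == 1) & (y_pred == 0)],
    }
    out: dict[str, dict] = {}
    for name, vals in groups.items():
        if vals.size == 0:
            out[name] = {"n": 0, "mean": None, "q1": None, "median": None,
                         "q3": None, "values": []}
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[name] = {
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "values": vals.tolist(),
            }
    return out


def evaluate_model(y_true, scores) -> MetricsReport:
    """Full report from probabilities: hard-label metrics plus AUC."""
    y_true_arr = as_binary_labels(y_true)
    scores = np.asarray(scores, dtype=float)
    counts = confusion_counts(y_true_arr, (scores >= PROBABILITY_CUTOFF).astype(int))
    report = metrics(counts)
    report.auc, _ = roc_auc(y_true_arr, scores)
    return report
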