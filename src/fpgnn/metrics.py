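"""Classification metrics for masked multi-task binary predictions.

All thresholded metrics derive from confusion counts at the 0.5
probability cut-off (a probability exactly at the threshold counts as a
positive call): F1 = 2TP/(2TP+FN+FP), MCC, balanced accuracy
BA = (SE+SP)/2 with sensitivity SE = TP/(TP+FN) and specificity
SP = TN/(TN+FP). AUC is threshold-free, computed as the Mann–Whitney
pair statistic with ties counted 1/2. Macro averages over tasks are
unweighted; a task failing a metric's precondition is reported as NaN
and excluded from that metric's average.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "MetricsReport",
    "confusion", "f1", "mcc", "balanced_accuracy", "sensitivity", "specificity",
    "auc", "evaluate_multitask",
]

METRIC_NAMES = ("AUC", "F1", "BA", "MCC", "SE", "SP")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred_prob: np.ndarray, label: np.ndarray, mask: np.ndarray | None = None,
              threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts over masked-in entries; call = 1 iff prob >= threshold."""
    pred_prob = np.asarray(pred_prob, dtype=float)
    label = np.asarray(label, dtype=float)
    mask = np.ones_like(label, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not (pred_prob.shape == label.shape == mask.shape):
        raise ValueError("pred_prob, label and mask must have equal shapes")
    if not mask.any():
        raise ValueError("no masked-in entries: confusion counts undefined")
    p, y = pred_prob[mask], label[mask]
    call = p >= threshold
    return ConfusionCounts(
        tp=int((call & (y == 1)).sum()),
        tn=int((~call & (y == 0)).sum()),
        fp=int((call & (y == 0)).sum()),
        fn=int((~call & (y == 1)).sum()),
    )


def f1(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return math.nan  # no positive labels and no positive calls
    return 2 * c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    denom = math.sqrt(float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp))
    if denom == 0.0:
        return 0.0  # standard convention for a degenerate margin
    return (c.tp * c.tn - c.fn * c.fp) / denom


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return math.nan
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        return math.nan
    return c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    se, sp = sensitivity(c), specificity(c)
    if math.isnan(se) or math.isnan(sp):
        return math.nan
    return (se + sp) / 2


def auc(pred_prob: np.ndarray, label: np.ndarray, mask: np.ndarray | None = None) -> float:
    """ROC AUC as the Mann–Whitney statistic (tied scores count 1/2)."""
    pred_prob = np.asarray(pred_prob, dtype=float)
    label = np.asarray(label, dtype=float)
    mask = np.ones_like(label, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    p, y = pred_prob[mask], label[mask]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"AUC undefined: no {missing} examples among masked-in entries")
    ranks = rankdata(p)  # midranks handle ties as 1/2 per pair
    rank_sum_pos = ranks[y == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class MetricsReport:
    """Per-task metrics, confusion counts, and unweighted macro averages."""

    task_names: list[str]
    per_task: dict[str, dict[str, float]]       # task -> metric -> value (NaN if undefined)
    confusions: dict[str, ConfusionCounts | None]
    averages: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = {t: self.per_task[t] for t in self.task_names}
        rows["average"] = self.averages
        return pd.DataFrame(rows).T[list(METRIC_NAMES)]

    def to_json(self, path=None) -> str:
        payload = {"per_task": self.per_task, "averages": self.averages}
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def __str__(self) -> str:
        return self.to_frame().to_string(float_format=lambda v: f"{v:.4f}")


def evaluate_multitask(preds: np.ndarray, labels: np.ndarray, mask: np.ndarray,
                       task_names: list[str] | None = None,
                       threshold: float = 0.5) -> MetricsReport:
    """Score an (n, T) prediction matrix per task and macro-average.

    Tasks violating a metric's precondition (e.g. a single-class task
    for AUC) get NaN for that metric and are excluded from its average,
    with a logged warning.
    """
    preds = np.atleast_2d(np.asarray(preds, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    if not (preds.shape == labels.shape == mask.shape):
        raise ValueError("preds, labels and mask must have equal shapes")
    n_tasks = preds.shape[1]
    if task_names is None:
        task_names = [f"task_{j}" for j in range(n_tasks)]

    per_task: dict[str, dict[str, float]] = {}
    confusions: dict[str, ConfusionCounts | None] = {}
    for j, name in enumerate(task_names):
        vals: dict[str, float] = {}
        try:
            c = confusion(preds[:, j], labels[:, j], mask[:, j], threshold)
        except ValueError:
            logger.warning("task %s has no masked-in entries; all metrics undefined", name)
            c = None
        confusions[name] = c
        if c is not None:
            vals["F1"] = f1(c)
            vals["MCC"] = mcc(c)
            vals["BA"] = balanced_accuracy(c)
            vals["SE"] = sensitivity(c)
            vals["SP"] = specificity(c)
        else:
            vals.update({m: math.nan for m in ("F1", "MCC", "BA", "SE", "SP")})
        try:
            vals["AUC"] = auc(preds[:, j], labels[:, j], mask[:, j])
        except ValueError as exc:
            logger.warning("task %s: %s", name, exc)
            vals["AUC"] = math.nan
        per_task[name] = vals

    averages = {}
    for m in METRIC_NAMES:
        vals = [per_task[t][m] for t in task_names if not math.isnan(per_task[t][m])]
        averages[m] = float(np.mean(vals)) if vals else math.nan
    return MetricsReport(list(task_names), per_task, confusions, averages)
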