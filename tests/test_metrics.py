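"""Metric definitions against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpgnn.metrics import (ConfusionCounts, auc, balanced_accuracy, confusion,
                           evaluate_multitask, f1, mcc, sensitivity, specificity)

# --- independent oracles (deliberately different code paths) -------------------


def oracle_f1(c):
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else None
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    if precision is None and recall is None:
        return math.nan
    if not precision and not recall:
        return 0.0 if c.tp + c.fn + c.fp else math.nan
    p = precision or 0.0
    r = recall or 0.0
    return 2 * p * r / (p + r) if (p + r) else 0.0


def oracle_mcc(c):
    num = c.tp * c.tn - c.fn * c.fp
    den = math.sqrt(c.tp + c.fn) * math.sqrt(c.tp + c.fp) \
        * math.sqrt(c.tn + c.fn) * math.sqrt(c.tn + c.fp)
    return num / den if den else 0.0


def oracle_auc(scores, labels):
    """Exhaustive positive-negative pair counting, ties at 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# --- worked examples -----------------------------------------------------------


def test_confusion_counts_and_tie_rule():
    c = confusion(np.array([0.9, 0.1]), np.array([1, 0]))
    assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)
    # a probability exactly at the threshold is a positive call
    c = confusion(np.array([0.5]), np.array([0]))
    assert c.fp == 1
    with pytest.raises(ValueError):
        confusion(np.array([0.5]), np.array([0]), np.array([False]))


def test_f1_worked_example():
    c = ConfusionCounts(tp=2, tn=0, fp=1, fn=1)
    assert f1(c) == pytest.approx(4 / 6)
    assert f1(ConfusionCounts(5, 5, 0, 0)) == 1.0
    assert f1(ConfusionCounts(0, 5, 2, 1)) == 0.0
    assert math.isnan(f1(ConfusionCounts(0, 5, 0, 0)))


def test_mcc_worked_examples():
    assert mcc(ConfusionCounts(5, 5, 0, 0)) == 1.0
    assert mcc(ConfusionCounts(0, 0, 5, 5)) == -1.0
    assert mcc(ConfusionCounts(1, 1, 1, 1)) == 0.0
    assert mcc(ConfusionCounts(0, 5, 0, 0)) == 0.0  # degenerate margin convention


def test_balanced_accuracy_worked_example():
    c = ConfusionCounts(tp=3, fn=1, tn=2, fp=2)
    assert sensitivity(c) == 0.75
    assert specificity(c) == 0.5
    assert balanced_accuracy(c) == pytest.approx(0.625)
    assert balanced_accuracy(ConfusionCounts(5, 5, 0, 0)) == 1.0


def test_auc_worked_examples():
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([0, 0, 1, 1])
    assert auc(scores, labels) == pytest.approx(0.75)
    assert auc(np.array([0.1, 0.9]), np.array([0, 1])) == 1.0
    assert auc(np.array([0.3, 0.3, 0.3]), np.array([0, 1, 0])) == 0.5
    with pytest.raises(ValueError, match="negative"):
        auc(np.array([0.2, 0.4]), np.array([1, 1]))


# --- oracle equivalence on random inputs ------------------------------------------


def test_threshold_metrics_match_oracles_on_random_tables(rng):
    for _ in range(1000):
        c = ConfusionCounts(*(int(v) for v in rng.integers(0, 50, size=4)))
        assert mcc(c) == pytest.approx(oracle_mcc(c), abs=1e-12)
        got, want = f1(c), oracle_f1(c)
        assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want, abs=1e-12)
        se, sp = sensitivity(c), specificity(c)
        if not (math.isnan(se) or math.isnan(sp)):
            assert balanced_accuracy(c) == pytest.approx((se + sp) / 2, abs=1e-12)


def test_auc_matches_bruteforce_pair_counting(rng):
    for _ in range(200):
        n = int(rng.integers(4, 60))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert auc(scores, labels) == pytest.approx(oracle_auc(scores, labels), abs=1e-12)


def test_auc_symmetries(rng):
    scores = rng.random(40)
    labels = (rng.random(40) < 0.4).astype(float)
    labels[:2] = [0, 1]
    a = auc(scores, labels)
    # swapping classes and reflecting scores leaves AUC unchanged
    assert auc(1.0 - scores, 1.0 - labels) == pytest.approx(a, abs=1e-12)
    # reflecting scores alone inverts the ranking
    assert auc(1.0 - scores, labels) == pytest.approx(1.0 - a, abs=1e-12)


def test_negating_predictions_negates_mcc(rng):
    for _ in range(50):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 30, size=4))
        c = ConfusionCounts(tp, tn, fp, fn)
        swapped = ConfusionCounts(fn, fp, tn, tp)  # all calls inverted
        assert mcc(swapped) == pytest.approx(-mcc(c), abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=2, max_size=40))
def test_auc_pair_statistic_property(pairs):
    scores = np.array([round(s, 2) for s, _ in pairs])
    labels = np.array([float(l) for _, l in pairs])
    if labels.min() == labels.max():
        return
    assert auc(scores, labels) == pytest.approx(oracle_auc(scores, labels), abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.tuples(*(st.integers(0, 60),) * 4))
def test_confusion_metric_identities_property(counts):
    c = ConfusionCounts(*counts)
    assert -1.0 <= mcc(c) <= 1.0
    v = f1(c)
    assert math.isnan(v) or 0.0 <= v <= 1.0
    se, sp = sensitivity(c), specificity(c)
    if not (math.isnan(se) or math.isnan(sp)):
        assert balanced_accuracy(c) == pytest.approx((se + sp) / 2, abs=1e-12)
    # total conservation: counts partition the evaluated pairs
    assert c.total == sum(counts)


# --- multi-task report ----------------------------------------------------------------


def test_evaluate_multitask_averages_and_ranges(rng):
    preds = rng.random((60, 3))
    labels = (rng.random((60, 3)) < 0.5).astype(float)
    mask = rng.random((60, 3)) < 0.9
    report = evaluate_multitask(preds, labels, mask)
    for t, vals in report.per_task.items():
        for m in ("AUC", "F1", "BA", "SE", "SP"):
            if not math.isnan(vals[m]):
                assert 0.0 <= vals[m] <= 1.0
        assert -1.0 <= vals["MCC"] <= 1.0
    for m, avg in report.averages.items():
        per = [report.per_task[t][m] for t in report.task_names
               if not math.isnan(report.per_task[t][m])]
        assert avg == pytest.approx(float(np.mean(per)), abs=1e-12)


def test_single_task_report_equals_task_metrics(rng):
    preds = rng.random(30)
    labels = (rng.random(30) < 0.5).astype(float)
    labels[:2] = [0, 1]
    report = evaluate_multitask(preds[:, None], labels[:, None], np.ones((30, 1), bool))
    assert report.averages["AUC"] == pytest.approx(auc(preds, labels))


def test_undefined_task_excluded_from_average():
    preds = np.array([[0.9, 0.9], [0.2, 0.8]])
    labels = np.array([[1.0, 1.0], [0.0, 1.0]])  # task 2 is single-class
    mask = np.ones((2, 2), bool)
    report = evaluate_multitask(preds, labels, mask)
    assert math.isnan(report.per_task["task_1"]["AUC"])
    assert report.averages["AUC"] == pytest.approx(report.per_task["task_0"]["AUC"])
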