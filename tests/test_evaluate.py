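"""Evaluation: confusion matrix, metrics, Fisher, ROC/AUC, bootstrap CI."""

import json
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from paindraw.classify import ClassificationRecord
from paindraw.evaluate import (ConfusionMatrix2x2, bootstrap_auc_ci,
                               confusion_matrix, metrics, roc_curve,
                               write_report)


def _records_from_counts(tp, fn, fp, tn, pos="EDS", neg="GBS"):
    recs = []
    def add(true, pred, n, score):
        for i in range(n):
            recs.append(ClassificationRecord(
                id=f"{true}{pred}{i}", true_label=true, sim_a=score,
                sim_b=1 - score, score_a=score, predicted_label=pred,
                cutoff_used=0.5))
    add(pos, pos, tp, 0.9)
    add(pos, neg, fn, 0.1)
    add(neg, pos, fp, 0.8)
    add(neg, neg, tn, 0.2)
    return recs


def _records_from_scores(pos_scores, neg_scores, pos="A", neg="B"):
    recs = []
    for i, s in enumerate(pos_scores):
        recs.append(ClassificationRecord(
            id=f"p{i}", true_label=pos, sim_a=s, sim_b=1 - s, score_a=s,
            predicted_label=pos if s >= 0.5 else neg, cutoff_used=0.5))
    for i, s in enumerate(neg_scores):
        recs.append(ClassificationRecord(
            id=f"n{i}", true_label=neg, sim_a=s, sim_b=1 - s, score_a=s,
            predicted_label=pos if s >= 0.5 else neg, cutoff_used=0.5))
    return recs


def fisher_two_sided_enumeration(tp, fn, fp, tn):
    """Exact oracle: sum hypergeometric probabilities of all tables at the
    observed margins that are no more probable than the observed table."""
    n = tp + fn + fp + tn
    row1 = tp + fp
    col1 = tp + fn
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(tp, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def auc_bruteforce(pos, neg):
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_printed_table_counts(self):
        recs = _records_from_counts(51, 8, 1, 28)
        cm = confusion_matrix(recs, "EDS")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (51, 8, 1, 28)
        assert cm.n == 88

    def test_perfect_separation_no_errors(self):
        cm = confusion_matrix(_records_from_counts(5, 0, 0, 4), "EDS")
        assert cm.fn == 0 and cm.fp == 0

    def test_swapping_positive_label_transposes(self):
        recs = _records_from_counts(51, 8, 1, 28)
        a = confusion_matrix(recs, "EDS")
        b = confusion_matrix(recs, "GBS")
        assert (a.tp, a.fn, a.fp, a.tn) == (b.tn, b.fp, b.fn, b.tp)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(_records_from_counts(2, 1, 1, 2), "XYZ")


class TestMetrics:
    def test_study_confusion_matrix_metrics(self):
        m = metrics(ConfusionMatrix2x2(51, 8, 1, 28, "EDS"))
        assert m.accuracy == pytest.approx(79 / 88)
        assert m.sensitivity == pytest.approx(51 / 59)
        assert m.specificity == pytest.approx(28 / 29)
        assert m.ppv == pytest.approx(51 / 52)
        assert m.npv == pytest.approx(28 / 36)
        assert m.misclassification_rate == pytest.approx(9 / 88)

    def test_study_fisher_p(self):
        m = metrics(ConfusionMatrix2x2(51, 8, 1, 28, "EDS"))
        oracle = fisher_two_sided_enumeration(51, 8, 1, 28)
        assert m.fisher_p == pytest.approx(oracle, rel=1e-9)

    def test_perfect_table(self):
        m = metrics(ConfusionMatrix2x2(10, 0, 0, 10, "A"))
        assert m.accuracy == 1.0 and m.fisher_p < 1.0

    def test_zero_denominator_reported_nan(self):
        m = metrics(ConfusionMatrix2x2(0, 0, 3, 5, "A"))
        assert math.isnan(m.sensitivity)
        assert m.specificity == pytest.approx(5 / 8)

    def test_agrees_with_bruteforce_counting(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            recs = _records_from_counts(*rng.integers(1, 30, size=4))
            cm = confusion_matrix(recs, "EDS")
            m = metrics(cm)
            n_correct = sum(r.true_label == r.predicted_label for r in recs)
            assert m.accuracy == pytest.approx(n_correct / len(recs))

    def test_fisher_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            tp, fn, fp, tn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + fn + fp + tn == 0:
                continue
            m = metrics(ConfusionMatrix2x2(tp, fn, fp, tn, "A"))
            oracle = fisher_two_sided_enumeration(tp, fn, fp, tn)
            assert m.fisher_p == pytest.approx(oracle, rel=1e-8, abs=1e-12)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        recs = _records_from_scores([0.9, 0.8], [0.3, 0.1])
        assert roc_curve(recs, "A").auc == 1.0

    def test_all_tied_auc_half(self):
        recs = _records_from_scores([0.5, 0.5], [0.5, 0.5])
        assert roc_curve(recs, "A").auc == 0.5

    def test_worked_example_eight_ninths(self):
        recs = _records_from_scores([0.9, 0.8, 0.4], [0.7, 0.3, 0.2])
        assert roc_curve(recs, "A").auc == pytest.approx(8 / 9)

    def test_points_monotone(self):
        recs = _records_from_scores([0.9, 0.6, 0.4, 0.4], [0.7, 0.5, 0.2])
        roc = roc_curve(recs, "A")
        fpr = [p[0] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_matches_bruteforce_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(40):
            pos = rng.random(rng.integers(2, 10))
            neg = rng.random(rng.integers(2, 10))
            recs = _records_from_scores(pos, neg)
            auc = roc_curve(recs, "A").auc
            assert auc == pytest.approx(auc_bruteforce(pos, neg))
            labels = [1] * len(pos) + [0] * len(neg)
            assert auc == pytest.approx(
                roc_auc_score(labels, np.concatenate([pos, neg])))

    def test_label_swap_flips_auc(self):
        recs = _records_from_scores([0.9, 0.8, 0.4], [0.7, 0.3, 0.2])
        assert roc_curve(recs, "A").auc == pytest.approx(
            1.0 - roc_curve(recs, "B").auc)

    def test_youden_cutoff_midpoint(self):
        recs = _records_from_scores([0.9, 0.8], [0.3, 0.1])
        roc = roc_curve(recs, "A")
        assert roc.best_cutoff == pytest.approx(0.55)  # between 0.3 and 0.8
        assert roc.best_sensitivity == 1.0 and roc.best_specificity == 1.0

    def test_one_class_rejected(self):
        recs = _records_from_scores([0.9, 0.8], [])
        with pytest.raises(ValueError):
            roc_curve(recs, "A")


class TestBootstrap:
    def test_perfect_separation_degenerate_interval(self):
        recs = _records_from_scores([0.9, 0.8, 0.7], [0.3, 0.2, 0.1])
        assert bootstrap_auc_ci(recs, "A", n_boot=200, seed=0) == (1.0, 1.0)

    def test_seeded_determinism(self):
        recs = _records_from_scores([0.9, 0.4, 0.7], [0.5, 0.2, 0.6])
        a = bootstrap_auc_ci(recs, "A", n_boot=300, seed=42)
        b = bootstrap_auc_ci(recs, "A", n_boot=300, seed=42)
        assert a == b

    def test_interval_brackets_point_auc(self):
        rng = np.random.default_rng(17)
        pos = rng.normal(0.7, 0.1, 20).clip(0, 1)
        neg = rng.normal(0.4, 0.1, 15).clip(0, 1)
        recs = _records_from_scores(pos, neg)
        low, high = bootstrap_auc_ci(recs, "A", n_boot=500, seed=3)
        auc = roc_curve(recs, "A").auc
        assert low <= auc <= high


class TestWriteReport:
    def test_report_round_trip(self, tmp_path):
        recs = _records_from_scores([0.9, 0.8, 0.7], [0.3, 0.2, 0.1])
        rep = metrics(confusion_matrix(recs, "A"))
        ci = bootstrap_auc_ci(recs, "A", n_boot=100, seed=0)
        roc = roc_curve(recs, "A", ci=ci)
        paths = write_report(rep, roc, tmp_path, cutoff_provenance="default 0.5")
        doc = json.loads(paths["json"].read_text())
        assert doc["metrics"]["accuracy"] == rep.accuracy
        assert doc["roc"]["auc"] == roc.auc
        assert doc["cutoff_provenance"] == "default 0.5"
        csv_rows = paths["roc_csv"].read_text().strip().splitlines()
        assert len(csv_rows) == len(roc.points) + 1
        assert paths["roc_png"].stat().st_size > 0
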