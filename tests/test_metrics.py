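"""Evaluation metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from phagegate import (ConfusionCounts, aggregate_folds, auc, aupr, confusion,
                       evaluate, threshold_metrics)


def pairwise_auc_oracle(labels, scores):
    """Exhaustive O(n^2) positive-vs-negative comparison, ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def sweep_aupr_oracle(labels, scores):
    """Brute-force precision/recall sweep over descending distinct scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        called = scores >= t
        tp = int((labels[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 1, 0)

    def test_enumerated_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_random_vectors_match_elementwise_oracle(self, rng):
        y = (rng.random(200) < 0.4).astype(int)
        yhat = (rng.random(200) < 0.5).astype(int)
        c = confusion(y, yhat)
        oracle = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for a, b in zip(y, yhat):
            key = ("t" if a == b else "f") + ("p" if b == 1 else "n")
            oracle[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            oracle["tp"], oracle["fp"], oracle["tn"], oracle["fn"])
        assert c.total == 200

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([0, 2], [0, 1])


class TestThresholdMetrics:
    def test_hand_arithmetic_example(self):
        m = threshold_metrics(ConfusionCounts(tp=8, fp=2, tn=5, fn=5))
        assert m["acc"] == pytest.approx(0.65)
        assert m["prec"] == pytest.approx(0.8)
        assert m["sens"] == pytest.approx(8 / 13)
        assert m["spec"] == pytest.approx(5 / 7)
        assert m["f1"] == pytest.approx(2 * 0.8 * (8 / 13) / (0.8 + 8 / 13))

    def test_zero_denominator_is_undefined_not_zero(self):
        m = threshold_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert m["prec"] is None
        assert m["spec"] == 1.0

    def test_perfect_predictor_all_ones(self):
        m = threshold_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(m[k] == 1.0 for k in ("acc", "prec", "sens", "spec", "f1"))

    def test_f1_equals_harmonic_mean_closed_form(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            m = threshold_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            hm = 2 / (1 / m["prec"] + 1 / m["sens"])
            assert m["f1"] == pytest.approx(hm)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(30):
            y = np.zeros(30, dtype=int)
            y[:rng.integers(1, 29)] = 1
            rng.shuffle(y)
            scores = np.round(rng.random(30), 2)  # induce ties
            assert auc(y, scores) == pytest.approx(pairwise_auc_oracle(y, scores))

    def test_cross_check_against_sklearn(self, rng):
        y = (rng.random(80) < 0.3).astype(int)
        scores = rng.random(80)
        assert auc(y, scores) == pytest.approx(roc_auc_score(y, scores))

    def test_invariant_under_monotone_transform(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        scores = rng.random(50)
        assert auc(y, scores) == pytest.approx(auc(y, np.exp(5 * scores)))

    def test_label_swap_symmetry(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        scores = rng.random(50)
        assert auc(y, scores) == pytest.approx(1.0 - auc(y, -scores))

    def test_single_class_undefined(self):
        assert auc([1, 1, 1], [0.1, 0.5, 0.9]) is None


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_matches_brute_force_sweep(self, rng):
        for _ in range(30):
            y = np.zeros(10, dtype=int)
            y[:rng.integers(1, 9)] = 1
            rng.shuffle(y)
            scores = np.round(rng.random(10), 1)
            assert aupr(y, scores) == pytest.approx(sweep_aupr_oracle(y, scores))

    def test_random_scores_concentrate_near_prevalence(self, rng):
        n, prevalence = 10_000, 0.2
        y = (rng.random(n) < prevalence).astype(int)
        assert aupr(y, rng.random(n)) == pytest.approx(prevalence, abs=0.03)

    def test_no_positives_undefined(self):
        assert aupr([0, 0, 0], [0.1, 0.5, 0.9]) is None


class TestEvaluateAndAggregate:
    def test_report_acc_consistent_with_counts(self, rng):
        y = (rng.random(60) < 0.4).astype(int)
        scores = rng.random(60)
        r = evaluate(y, scores)
        c = r.counts
        assert r.acc == pytest.approx((c.tp + c.tn) / c.total)
        assert c.total == 60 and r.n_pos + r.n_neg == 60

    def test_degenerate_fold_flags_na(self):
        r = evaluate([0, 0, 0, 0], [0.1, 0.2, 0.3, 0.4])
        assert r.auc is None and r.aupr is None and r.sens is None
        assert set(r.undefined) >= {"auc", "aupr", "sens"}

    def test_identical_folds_aggregate_to_value_sd_zero(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        scores = rng.random(40)
        reports = [evaluate(y, scores, fold=i) for i in range(3)]
        agg = aggregate_folds(reports)
        assert agg["acc"]["mean"] == reports[0].acc
        assert agg["acc"]["sd"] == 0.0

    def test_undefined_folds_counted_and_excluded_from_mean(self, rng):
        good = evaluate((rng.random(40) < 0.5).astype(int), rng.random(40), fold=0)
        degenerate = evaluate(np.zeros(10, dtype=int), rng.random(10), fold=1)
        agg = aggregate_folds([good, degenerate])
        assert agg["auc"]["n_undefined"] == 1
        assert agg["auc"]["mean"] == good.auc

    def test_aggregate_matches_arithmetic_oracle(self, rng):
        reports = [evaluate((rng.random(30) < 0.5).astype(int), rng.random(30),
                            fold=i) for i in range(4)]
        agg = aggregate_folds(reports)
        accs = [r.acc for r in reports]
        assert agg["acc"]["mean"] == pytest.approx(np.mean(accs))
        assert agg["acc"]["sd"] == pytest.approx(np.std(accs))
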