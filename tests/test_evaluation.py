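"""Evaluation metrics against independent oracles and hand arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finid.evaluation import (MatchResult, TopKWeights, average_precision,
                              box_iou, classification_metrics,
                              error_reduction_rate, match_detections,
                              mean_average_precision, precision_recall_f1,
                              top3_accuracies)


def exhaustive_match_counts(preds, truths, thr):
    """Oracle: enumerate every injective pred->truth assignment and pick
    the one maximizing (number of matches, total IoU)."""
    np_, nt = len(preds), len(truths)
    best = (0, 0.0)
    for k in range(min(np_, nt), -1, -1):
        for pred_subset in itertools.combinations(range(np_), k):
            for truth_perm in itertools.permutations(range(nt), k):
                ious = [box_iou(preds[i], truths[j])
                        for i, j in zip(pred_subset, truth_perm)]
                if all(v > thr for v in ious):
                    best = max(best, (k, sum(ious)))
        if best[0] == k:
            break
    tp = best[0]
    return tp, np_ - tp, nt - tp


def random_boxes(rng, n):
    out = []
    for _ in range(n):
        w, h = rng.uniform(0.1, 0.5, 2)
        cx = rng.uniform(w / 2, 1 - w / 2)
        cy = rng.uniform(h / 2, 1 - h / 2)
        out.append((cx, cy, w, h))
    return out


class TestMatchDetections:
    def test_two_preds_one_truth_best_iou_wins(self):
        truth = [(0.5, 0.5, 0.4, 0.4)]
        preds = [(0.5, 0.5, 0.4, 0.4), (0.52, 0.5, 0.4, 0.4)]
        m = match_detections(preds, truth)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        # the matched prediction is the higher-IoU one
        assert m.pairs[0][0] == 0

    def test_no_predictions(self):
        m = match_detections([], [(0.5, 0.5, 0.2, 0.2)])
        assert (m.tp, m.fp, m.fn) == (0, 0, 1)

    def test_crafted_scene_matches_oracle(self):
        truths = [(0.3, 0.3, 0.2, 0.2), (0.7, 0.7, 0.2, 0.2),
                  (0.5, 0.5, 0.3, 0.3)]
        preds = [(0.3, 0.3, 0.2, 0.2), (0.31, 0.3, 0.2, 0.2),
                 (0.7, 0.72, 0.2, 0.2), (0.1, 0.9, 0.1, 0.1)]
        m = match_detections(preds, truths)
        assert (m.tp, m.fp, m.fn) == exhaustive_match_counts(preds, truths,
                                                             0.5)

    def test_1000_random_scenes_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            preds = random_boxes(rng, int(rng.integers(0, 6)))
            truths = random_boxes(rng, int(rng.integers(0, 6)))
            m = match_detections(preds, truths)
            assert (m.tp, m.fp, m.fn) == exhaustive_match_counts(
                preds, truths, 0.5)
            assert m.tp + m.fn == len(truths)

    def test_each_truth_matched_at_most_once(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            preds = random_boxes(rng, 5)
            truths = random_boxes(rng, 3)
            m = match_detections(preds, truths)
            matched_truths = [j for _, j, _ in m.pairs]
            assert len(matched_truths) == len(set(matched_truths))


class TestPrecisionRecallF1:
    def test_arithmetic(self):
        p, r, f1 = precision_recall_f1(MatchResult(tp=9, fp=1, fn=1))
        assert (p, r, f1) == (0.9, 0.9, pytest.approx(0.9))

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            p, r, _ = precision_recall_f1(MatchResult(tp=0, fp=0, fn=5))
        assert p == 0.0 and r == 0.0

    def test_perfect(self):
        assert precision_recall_f1(MatchResult(tp=5)) == (1.0, 1.0, 1.0)


def ap_step_oracle(outcomes, n_truth):
    """Oracle: enumerate P-R points of a ranked TP/FP outcome list,
    monotonize precision from the right, integrate the step function."""
    points = []
    tp = fp = 0
    for o in outcomes:
        tp += o == "TP"
        fp += o == "FP"
        points.append((tp / n_truth, tp / (tp + fp)))
    env = []
    best = 0.0
    for r, p in reversed(points):
        best = max(best, p)
        env.append((r, best))
    env.reverse()
    ap = 0.0
    prev = 0.0
    for r, p in env:
        ap += (r - prev) * p
        prev = r
    return ap


class TestAveragePrecision:
    def box(self, cx):  # well-separated unit-grid boxes
        return (cx, 0.5, 0.08, 0.08)

    def test_perfect_detector(self):
        truths = [[self.box(0.2), self.box(0.6)]]
        preds = [[(*self.box(0.2), 0.9), (*self.box(0.6), 0.8)]]
        assert average_precision(preds, truths) == pytest.approx(1.0)

    def test_tp_fp_tp_matches_step_oracle(self):
        # ranked outcomes TP, FP, TP over 2 ground truths
        truths = [[self.box(0.2), self.box(0.6)]]
        preds = [[(*self.box(0.2), 0.9), (*self.box(0.9), 0.8),
                  (*self.box(0.6), 0.7)]]
        ap = average_precision(preds, truths)
        assert ap == pytest.approx(ap_step_oracle(["TP", "FP", "TP"], 2))
        assert ap == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_single_class_map_equals_ap(self):
        truths = [[self.box(0.2)], [self.box(0.5)]]
        preds = [[(*self.box(0.2), 0.9)], [(*self.box(0.9), 0.6)]]
        ap = average_precision(preds, truths)
        m = mean_average_precision({"fin": preds}, {"fin": truths})
        assert m == pytest.approx(ap)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        truths = [random_boxes(rng, 3) for _ in range(4)]
        preds = [[(*b, rng.random()) for b in random_boxes(rng, 4)]
                 for _ in range(4)]
        ap1 = average_precision(preds, truths)
        shuffled = [list(p) for p in preds]
        for p in shuffled:
            rng.shuffle(p)
        assert average_precision(shuffled, truths) == pytest.approx(ap1)

    def test_adding_false_positives_never_helps(self):
        truths = [[self.box(0.2), self.box(0.6)]]
        preds = [[(*self.box(0.2), 0.9), (*self.box(0.6), 0.85)]]
        ap1 = average_precision(preds, truths)
        worse = [preds[0] + [(*self.box(0.9), 0.95)]]
        assert average_precision(worse, truths) <= ap1


class TestClassificationMetrics:
    def test_confusion_arithmetic(self):
        true = ["pos"] * 100 + ["neg"] * 100
        pred = (["pos"] * 80 + ["neg"] * 20) + (["pos"] * 5 + ["neg"] * 95)
        acc, prec, rec, fpr, f1 = classification_metrics(pred, true, "pos")
        assert rec == pytest.approx(0.8)
        assert prec == pytest.approx(80 / 85, abs=1e-3)
        assert fpr == pytest.approx(0.05)
        assert acc == pytest.approx(0.875)

    def test_all_correct(self):
        acc, _, _, fpr, _ = classification_metrics(["a", "b"], ["a", "b"],
                                                   "a")
        assert acc == 1.0 and fpr == 0.0

    def test_relabeling_invariance(self):
        true = ["x", "y", "x", "y", "x"]
        pred = ["x", "x", "y", "y", "x"]
        ref = classification_metrics(pred, true, "x")
        mapped = {"x": "valid", "y": "invalid"}
        assert classification_metrics([mapped[p] for p in pred],
                                      [mapped[t] for t in true],
                                      "valid") == ref


class TestTop3:
    def test_all_rank1(self):
        ranked = [("a", "b", "c")] * 4
        assert top3_accuracies(ranked, ["a"] * 4) == (1.0, 1.0)

    def test_all_rank3(self):
        ranked = [("a", "b", "c")] * 4
        assert top3_accuracies(ranked, ["c"] * 4) == (0.25, 1.0)

    def test_mixed_ranks(self):
        ranked = [("t", "x", "y"), ("x", "t", "y"), ("x", "y", "z")]
        twa, tua = top3_accuracies(ranked, ["t", "t", "t"])
        assert twa == pytest.approx(0.5)
        assert tua == pytest.approx(2 / 3)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1,
                    max_size=30))
    def test_tua_bounds_twa(self, ranks):
        classes = [f"c{i}" for i in range(6)]
        ranked = []
        for r in ranks:
            order = classes[:]
            order.remove("t" if False else order[r - 1])
            ranked.append(tuple([*(classes[:r - 1]), "t",
                                 *classes[r - 1:]])[:6])
        twa, tua = top3_accuracies([r[:6] for r in ranked], ["t"] * len(ranks))
        assert 0.0 <= twa <= tua <= 1.0

    def test_weights_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            TopKWeights(1.0, 0.5, 0.6)


class TestErrorReductionRate:
    @pytest.mark.parametrize("before,after,expected", [
        (86.7, 92.5, 43.6),
        (94.3, 97.2, 50.9),
        (82.8, 84.5, 9.9),
        (91.7, 92.9, 14.5),
    ])
    def test_reported_pairs(self, before, after, expected):
        assert error_reduction_rate(before, after) == expected

    def test_no_change(self):
        assert error_reduction_rate(73.2, 73.2) == 0.0

    def test_error_form_identity(self):
        # computing from errors e = 100 - acc gives the same number
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = float(rng.uniform(0, 99))
            b = float(rng.uniform(0, 100))
            e0, e1 = 100 - a, 100 - b
            assert error_reduction_rate(a, b) == pytest.approx(
                round((e0 - e1) / e0 * 100, 1))

    def test_perfect_before_is_undefined(self):
        with pytest.raises(ValueError):
            error_reduction_rate(100.0, 100.0)
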