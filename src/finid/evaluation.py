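"""Detection and classification evaluation.

Covers the quantitative machinery of the pipeline: IoU-based matching of
box predictions to ground truth (TP/FP/FN; true negatives are undefined
for detection), precision/recall/F1, average precision with the
monotone precision envelope, binary classification metrics including the
false-positive rate, top-3 weighted/unweighted accuracy for the ranked
individual classifier, and the error-reduction-rate arithmetic used to
compare classifier generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult", "TopKWeights", "box_iou", "match_detections",
    "precision_recall_f1", "average_precision", "mean_average_precision",
    "classification_metrics", "top3_accuracies", "error_reduction_rate",
]


@dataclass
class MatchResult:
    """TP/FP/FN counts for one image plus the matched (pred, truth, IoU) pairs."""
    tp: int = 0
    fp: int = 0
    fn: int = 0
    pairs: list = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn, self.pairs + other.pairs)


@dataclass(frozen=True)
class TopKWeights:
    """Rank-dependent weights for top-3 weighted accuracy."""
    w1: float = 1.0
    w2: float = 0.5
    w3: float = 0.25

    def __post_init__(self):
        if not (self.w1 == 1.0 and self.w1 >= self.w2 >= self.w3):
            raise ValueError("weights must be non-increasing with w1 == 1")

    def as_tuple(self):
        return (self.w1, self.w2, self.w3)


def box_iou(a, b) -> float:
    """Intersection over union of two (cx, cy, w, h) boxes."""
    ax0, ay0 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax1, ay1 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx0, by0 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx1, by1 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return float(inter / union)


def iou_matrix(preds, truths) -> np.ndarray:
    m = np.zeros((len(preds), len(truths)))
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            m[i, j] = box_iou(p, t)
    return m


def match_detections(preds, truths, iou_threshold: float = 0.5) -> MatchResult:
    """Match predicted boxes to ground-truth boxes in one image.

    A prediction is a true positive when it is assigned to a ground
    truth with IoU above the threshold and it is the best such box for
    that truth; every other prediction is a false positive, every
    unmatched truth a false negative. The assignment maximises the
    number of matches first and total IoU second (the per-truth
    "highest IoU wins" rule, made globally consistent when a box
    overlaps several truths).

    ``preds``/``truths`` are sequences of (cx, cy, w, h) boxes; a
    prediction may also carry a trailing score which is ignored here.
    """
    preds = [p[:4] for p in preds]
    truths = [t[:4] for t in truths]
    if not preds or not truths:
        return MatchResult(tp=0, fp=len(preds), fn=len(truths))
    m = iou_matrix(preds, truths)
    eligible = m > iou_threshold
    # Lexicographic (match count, total IoU) objective: a large constant
    # per eligible pair dominates any sum of IoUs.
    big = 10.0 * (len(preds) + len(truths) + 1)
    weight = np.where(eligible, big + m, 0.0)
    rows, cols = linear_sum_assignment(weight, maximize=True)
    pairs = [(int(i), int(j), float(m[i, j]))
             for i, j in zip(rows, cols) if eligible[i, j]]
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp,
                       pairs=pairs)


def precision_recall_f1(match: MatchResult):
    """Pooled precision/recall/F1 from aggregated match counts."""
    if match.tp + match.fp > 0:
        precision = match.tp / (match.tp + match.fp)
    else:
        warnings.warn("precision undefined (no predictions); reporting 0")
        precision = 0.0
    if match.tp + match.fn > 0:
        recall = match.tp / (match.tp + match.fn)
    else:
        warnings.warn("recall undefined (no ground truths); reporting 0")
        recall = 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def average_precision(scored_preds, truths, iou_threshold: float = 0.5) -> float:
    """All-point average precision at one IoU threshold.

    ``scored_preds``: list over images of lists of (cx, cy, w, h, score).
    ``truths``: list over images of lists of (cx, cy, w, h).
    Predictions are pooled over images, sorted by score (ties broken by
    image/prediction index for determinism), and greedily matched to the
    best remaining ground truth of their image. The precision/recall
    curve is replaced by its running right-maximum before integrating.
    """
    n_truth = sum(len(t) for t in truths)
    if n_truth == 0:
        warnings.warn("no ground truths; AP undefined")
        return float("nan")
    flat = []
    for img, preds in enumerate(scored_preds):
        for k, p in enumerate(preds):
            flat.append((-float(p[4]), img, k, p[:4]))
    flat.sort(key=lambda r: (r[0], r[1], r[2]))
    used = [set() for _ in truths]
    tps = []
    for _, img, _, box in flat:
        cand = [(box_iou(box, t), j) for j, t in enumerate(truths[img])
                if j not in used[img]]
        cand = [(v, j) for v, j in cand if v > iou_threshold]
        if cand:
            v, j = max(cand)
            used[img].add(j)
            tps.append(1)
        else:
            tps.append(0)
    if not tps:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum([1 - t for t in tps])
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone envelope (running max from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(per_class_preds: dict, per_class_truths: dict,
                           iou_threshold: float = 0.5,
                           thresholds=None) -> float:
    """Mean of per-class APs (equal to AP for a single class).

    ``thresholds`` optionally sweeps several IoU thresholds and averages
    (e.g. ``np.arange(0.5, 1.0, 0.05)``); default is the single 0.5.
    """
    aps = []
    for cls, truths in per_class_truths.items():
        if sum(len(t) for t in truths) == 0:
            warnings.warn(f"class {cls!r} has no ground truths; skipped")
            continue
        preds = per_class_preds.get(cls, [[] for _ in truths])
        if thresholds is None:
            aps.append(average_precision(preds, truths, iou_threshold))
        else:
            aps.append(float(np.mean([average_precision(preds, truths, t)
                                      for t in thresholds])))
    if not aps:
        return float("nan")
    return float(np.mean(aps))


def classification_metrics(predicted, true, positive_class):
    """Binary accuracy, precision, recall, FPR and F1.

    Any label other than ``positive_class`` counts as negative, so the
    function also works on multi-class outputs in one-vs-rest fashion.
    """
    predicted = list(predicted)
    true = list(true)
    if len(predicted) != len(true):
        raise ValueError("length mismatch")
    tp = sum(1 for p, t in zip(predicted, true)
             if p == positive_class and t == positive_class)
    fp = sum(1 for p, t in zip(predicted, true)
             if p == positive_class and t != positive_class)
    fn = sum(1 for p, t in zip(predicted, true)
             if p != positive_class and t == positive_class)
    tn = len(true) - tp - fp - fn
    accuracy = (tp + tn) / len(true) if true else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return accuracy, precision, recall, fpr, f1


def top3_accuracies(ranked_predictions, true_labels,
                    weights: TopKWeights = TopKWeights()):
    """Top-3 weighted (TWA) and unweighted (TUA) accuracy.

    ``ranked_predictions``: per sample, labels sorted by descending
    probability (at least 3). TWA credits rank r in the top 3 with
    weight (1, 0.5, 0.25)[r-1]; TUA credits any top-3 hit with 1.
    """
    ranked_predictions = list(ranked_predictions)
    true_labels = list(true_labels)
    if len(ranked_predictions) != len(true_labels):
        raise ValueError("length mismatch")
    if not true_labels:
        return 0.0, 0.0
    w = weights.as_tuple()
    twa = 0.0
    tua = 0
    for ranked, target in zip(ranked_predictions, true_labels):
        if len(ranked) < 3:
            raise ValueError("need at least 3 ranked classes per sample")
        top3 = list(ranked[:3])
        if target in top3:
            twa += w[top3.index(target)]
            tua += 1
    n = len(true_labels)
    return twa / n, tua / n


def error_reduction_rate(acc_before: float, acc_after: float) -> float:
    """Relative shrinkage (percent) of the error 100-accuracy, 1 decimal."""
    if not (0.0 <= acc_before < 100.0):
        raise ValueError("acc_before must be in [0, 100)")
    if not (0.0 <= acc_after <= 100.0):
        raise ValueError("acc_after must be in [0, 100]")
    err_before = 100.0 - acc_before
    err_after = 100.0 - acc_after
    return round((err_before - err_after) / err_before * 100.0, 1)
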