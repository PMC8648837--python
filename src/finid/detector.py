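"""Single-stage, three-scale dorsal fin / saddle-patch detector.

A grid-based detector in the YOLOv3 mould: a convolutional backbone plus
a feature-pyramid head predicting, on grids of stride 32/16/8, b = 3
anchored boxes per cell with 4 box coordinates, an objectness score and
c = 2 class confidences — b*(5+c) = 21 channels per cell, so an input of
416 px yields 13x13x21, 26x26x21 and 52x52x21 output grids. The
``reduced`` backbone scale keeps the same head contract but shrinks the
backbone so toy instances train on a single CPU; ``full`` instantiates a
53-layer residual backbone.

Box convention throughout: (cx, cy, w, h), center-based, normalized to
[0, 1], matching the YOLO label-file dialect. Pixel boxes are half-open.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .evaluation import average_precision, box_iou

__all__ = [
    "DetectorConfig", "DetectionThresholds", "BoxHypothesis",
    "PreprocessTransform", "DEFAULT_ANCHORS", "preprocess_image",
    "FinDetector", "build_detector", "decode", "encode_targets",
    "non_max_suppression", "iou", "detector_loss", "train_detector",
    "detect", "self_training_expansion", "evaluate_detector",
    "save_detector", "load_detector", "kmeans_anchors",
]

# YOLOv3 anchor priors (w, h) in pixels at a 416-px input, finest->coarsest.
DEFAULT_ANCHORS = ((10, 13), (16, 30), (33, 23),
                   (30, 61), (62, 45), (59, 119),
                   (116, 90), (156, 198), (373, 326))


@dataclass
class DetectorConfig:
    input_size: int = 416
    boxes_per_cell: int = 3
    n_classes: int = 2
    backbone_scale: str = "reduced"       # "full" (53-layer) or "reduced"
    anchors: tuple = DEFAULT_ANCHORS      # at 416; rescaled to input_size
    nms_score: str = "combined"           # "combined" or "objectness"

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.backbone_scale not in ("full", "reduced"):
            raise ValueError("backbone_scale must be 'full' or 'reduced'")
        if len(self.anchors) != 3 * self.boxes_per_cell:
            raise ValueError("need boxes_per_cell anchors per scale")

    @property
    def per_cell_channels(self) -> int:
        return self.boxes_per_cell * (5 + self.n_classes)

    @property
    def grid_sizes(self) -> tuple:
        s = self.input_size
        return (s // 32, s // 16, s // 8)

    def scaled_anchors(self):
        """Anchor (w, h) in input pixels, grouped coarse->fine by area."""
        f = self.input_size / 416.0
        scaled = [(w * f, h * f) for w, h in self.anchors]
        ordered = sorted(scaled, key=lambda a: a[0] * a[1], reverse=True)
        b = self.boxes_per_cell
        return tuple(tuple(ordered[i * b:(i + 1) * b]) for i in range(3))


@dataclass(frozen=True)
class DetectionThresholds:
    objectness_train_val: float = 0.5
    objectness_test: float = 0.8
    iou: float = 0.5
    nms: float = 0.5

    def objectness(self, mode: str) -> float:
        if mode == "test":
            return self.objectness_test
        if mode == "train_val":
            return self.objectness_train_val
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class BoxHypothesis:
    box: tuple                       # normalized (cx, cy, w, h)
    objectness: float
    class_confidences: tuple

    def score(self, mode: str = "combined") -> float:
        if mode == "objectness":
            return self.objectness
        return self.objectness * max(self.class_confidences)

    def as_row(self):
        return (*self.box, self.objectness)


@dataclass(frozen=True)
class PreprocessTransform:
    """Affine mapping between original-image and model box frames."""
    orig_h: int
    orig_w: int
    pad_top: int
    pad_left: int
    side: int

    def box_to_model(self, box):
        cx, cy, w, h = box[:4]
        return ((cx * self.orig_w + self.pad_left) / self.side,
                (cy * self.orig_h + self.pad_top) / self.side,
                w * self.orig_w / self.side, h * self.orig_h / self.side)

    def box_from_model(self, box):
        cx, cy, w, h = box[:4]
        return ((cx * self.side - self.pad_left) / self.orig_w,
                (cy * self.side - self.pad_top) / self.orig_h,
                w * self.side / self.orig_w, h * self.side / self.orig_h)


def preprocess_image(image: np.ndarray, input_size: int):
    """Zero-pad a non-square image symmetrically, resize, scale to [0,1].

    Returns (float32 array of shape 3 x S x S, PreprocessTransform).
    """
    h, w = image.shape[:2]
    side = max(h, w)
    pad_top = (side - h) // 2
    pad_left = (side - w) // 2
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    canvas = np.zeros((side, side, 3), dtype=image.dtype)
    canvas[pad_top:pad_top + h, pad_left:pad_left + w] = image
    if side != input_size:
        canvas = np.asarray(Image.fromarray(canvas).resize(
            (input_size, input_size), Image.BILINEAR))
    arr = (canvas.astype(np.float32) / 255.0).transpose(2, 0, 1)
    return arr, PreprocessTransform(orig_h=h, orig_w=w, pad_top=pad_top,
                                    pad_left=pad_left, side=side)


class FinDetector(nn.Module):
    """Backbone + three-scale detection head."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = self.config.per_cell_channels
        if config.backbone_scale == "reduced":
            widths = (8, 16, 32, 64, 128)
        else:
            widths = (32, 64, 128, 256, 512)
        w0, w1, w2, w3, w4 = widths
        self.stem = nn.ConvBNAct(rng, 3, w0, 3, 2)
        n_blocks = (1, 2, 2) if config.backbone_scale == "reduced" \
            else (8, 8, 4)
        self.stage1 = nn.ConvBNAct(rng, w0, w1, 3, 2)
        self.stage2 = self._stage(rng, w1, w2, n_blocks[0])   # stride 8
        self.stage3 = self._stage(rng, w2, w3, n_blocks[1])   # stride 16
        self.stage4 = self._stage(rng, w3, w4, n_blocks[2])   # stride 32
        # feature pyramid: coarse head + lateral upsampling paths
        self.lat5 = nn.ConvBNAct(rng, w4, w3, 1)
        self.head32 = nn.Sequential(nn.ConvBNAct(rng, w3, w4, 3),
                                    nn.Conv2d(rng, w4, ch, 1, padding=0))
        self.red5 = nn.ConvBNAct(rng, w3, w2, 1)
        self.mix16 = nn.ConvBNAct(rng, w3 + w2, w3, 1)
        self.head16 = nn.Sequential(nn.ConvBNAct(rng, w3, w3, 3),
                                    nn.Conv2d(rng, w3, ch, 1, padding=0))
        self.red4 = nn.ConvBNAct(rng, w3, w1, 1)
        self.mix8 = nn.ConvBNAct(rng, w2 + w1, w2, 1)
        self.head8 = nn.Sequential(nn.ConvBNAct(rng, w2, w2, 3),
                                   nn.Conv2d(rng, w2, ch, 1, padding=0))

    @staticmethod
    def _stage(rng, cin, cout, n_blocks):
        mods = [nn.ConvBNAct(rng, cin, cout, 3, 2)]
        for _ in range(n_blocks):
            mods.append(nn.BasicBlock(rng, cout, cout))
        return nn.Sequential(*mods)

    def forward(self, x: nn.Tensor):
        """Raw grids for strides (32, 16, 8): (N, 21, S/32, S/32), ..."""
        c1 = self.stage1.forward(self.stem.forward(x))
        c2 = self.stage2.forward(c1)
        c3 = self.stage3.forward(c2)
        c4 = self.stage4.forward(c3)
        p5 = self.lat5.forward(c4)
        out32 = self.head32.forward(p5)
        up = nn.ops.upsample2x(self.red5.forward(p5))
        p4 = self.mix16.forward(nn.ops.concat_channels(c3, up))
        out16 = self.head16.forward(p4)
        up2 = nn.ops.upsample2x(self.red4.forward(p4))
        p3 = self.mix8.forward(nn.ops.concat_channels(c2, up2))
        out8 = self.head8.forward(p3)
        return [out32, out16, out8]

    def forward_raw(self, image_arr: np.ndarray):
        """Single-image inference: list of (G, G, b*(5+c)) numpy grids."""
        was_training = self.training
        self.eval()
        outs = self.forward(nn.Tensor(image_arr[None]))
        self.train(was_training)
        return [o.data[0].transpose(1, 2, 0) for o in outs]


def build_detector(config: DetectorConfig, seed: int = 0) -> FinDetector:
    return FinDetector(config, seed=seed)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def iou(a, b) -> float:
    """Intersection over union of two (cx, cy, w, h) boxes."""
    return box_iou(a, b)


def decode(raw_grids, config: DetectorConfig,
           thresholds: DetectionThresholds = DetectionThresholds(),
           mode: str = "train_val"):
    """Decode raw grids into box hypotheses above the mode's threshold.

    Cell offsets pass through a sigmoid, anchor scalings through an
    exponential; hypotheses with objectness <= the mode's threshold are
    removed.
    """
    thr = thresholds.objectness(mode)
    b, c = config.boxes_per_cell, config.n_classes
    s = config.input_size
    hyps = []
    for grid, anchors in zip(raw_grids, config.scaled_anchors()):
        g = grid.shape[0]
        t = grid.reshape(g, g, b, 5 + c)
        obj = _sigmoid(t[..., 4])
        keep = np.argwhere(obj > thr)
        for i, j, a in keep:
            tx, ty, tw, th = t[i, j, a, :4]
            cx = (_sigmoid(tx) + j) / g
            cy = (_sigmoid(ty) + i) / g
            w = anchors[a][0] * math.exp(min(tw, 10.0)) / s
            h = anchors[a][1] * math.exp(min(th, 10.0)) / s
            cls = _sigmoid(t[i, j, a, 5:])
            hyps.append(BoxHypothesis(box=(float(cx), float(cy), float(w),
                                           float(h)),
                                      objectness=float(obj[i, j, a]),
                                      class_confidences=tuple(cls)))
    return hyps


def _best_anchor(box, config: DetectorConfig):
    """Scale and anchor index with the best shape IoU for a box, plus
    the per-(scale, anchor) shape IoUs (used for the ignore band)."""
    s = config.input_size
    w, h = box[2] * s, box[3] * s
    ious = []
    for sc, anchors in enumerate(config.scaled_anchors()):
        for a, (aw, ah) in enumerate(anchors):
            inter = min(w, aw) * min(h, ah)
            union = w * h + aw * ah - inter
            ious.append((inter / union, sc, a))
    best = max(ious)
    return best[1], best[2], ious


def encode_targets(gt_boxes, config: DetectorConfig, class_id: int = 0,
                   ignore_iou: float = 0.5):
    """Encode ground-truth boxes into per-scale target/weight grids.

    Returns (targets, bce_w, mse_w): lists over scales of arrays shaped
    (3, G, G, 5+c). BCE weights cover tx/ty/objectness/classes, MSE
    weights cover tw/th; anchors whose shape-IoU with a ground truth
    exceeds ``ignore_iou`` without being the best match are excluded
    from the no-object loss.
    """
    b, c = config.boxes_per_cell, config.n_classes
    grids = config.grid_sizes
    targets = [np.zeros((b, g, g, 5 + c), np.float32) for g in grids]
    bce_w = [np.zeros((b, g, g, 5 + c), np.float32) for g in grids]
    mse_w = [np.zeros((b, g, g, 5 + c), np.float32) for g in grids]
    for scale_t, w_t in zip(targets, bce_w):
        w_t[..., 4] = 1.0            # every anchor participates as negative
    s = config.input_size
    anchors = config.scaled_anchors()
    eps = 1e-7
    for box in gt_boxes:
        cx, cy, w, h = box[:4]
        sc, a, ious = _best_anchor(box, config)
        g = grids[sc]
        j = min(int(cx * g), g - 1)
        i = min(int(cy * g), g - 1)
        ox = np.clip(cx * g - j, eps, 1 - eps)
        oy = np.clip(cy * g - i, eps, 1 - eps)
        aw, ah = anchors[sc][a]
        targets[sc][a, i, j, 0] = ox
        targets[sc][a, i, j, 1] = oy
        targets[sc][a, i, j, 2] = math.log(max(w * s / aw, eps))
        targets[sc][a, i, j, 3] = math.log(max(h * s / ah, eps))
        targets[sc][a, i, j, 4] = 1.0
        targets[sc][a, i, j, 5 + class_id] = 1.0
        for v, isc, ia in ious:
            if v > ignore_iou and not (isc == sc and ia == a):
                gg = grids[isc]
                jj = min(int(cx * gg), gg - 1)
                ii = min(int(cy * gg), gg - 1)
                bce_w[isc][ia, ii, jj, 4] = 0.0
        bce_w[sc][a, i, j, 0] = bce_w[sc][a, i, j, 1] = 1.0
        bce_w[sc][a, i, j, 4] = 1.0
        bce_w[sc][a, i, j, 5:] = 1.0
        mse_w[sc][a, i, j, 2] = mse_w[sc][a, i, j, 3] = 1.0
    return targets, bce_w, mse_w


def targets_to_raw(targets, config: DetectorConfig):
    """Turn encoded target grids back into raw logit grids.

    Inverse of the decode equations on the encoded cells (logit on the
    offsets, identity on the log scalings, +/-inf surrogates on the
    objectness), so ``decode(targets_to_raw(encode_targets(boxes)))``
    recovers the boxes — the round-trip identity the tests assert.
    """
    raw = []
    for sc, tgt in enumerate(targets):
        b, g = tgt.shape[0], tgt.shape[1]
        t = tgt.copy()
        pos = tgt[..., 4] == 1.0
        t[..., 0] = np.where(pos, np.log(tgt[..., 0] / (1 - tgt[..., 0]),
                                         where=pos, out=np.zeros_like(
                                             tgt[..., 0])), 0.0)
        t[..., 1] = np.where(pos, np.log(tgt[..., 1] / (1 - tgt[..., 1]),
                                         where=pos, out=np.zeros_like(
                                             tgt[..., 1])), 0.0)
        t[..., 4] = np.where(pos, 20.0, -20.0)
        t[..., 5:] = np.where(tgt[..., 5:] == 1.0, 20.0, -20.0)
        # (b, G, G, 5+c) -> (G, G, b*(5+c))
        raw.append(t.transpose(1, 2, 0, 3).reshape(g, g, -1))
    return raw


def non_max_suppression(hyps, nms_threshold: float = 0.5,
                        score_mode: str = "combined"):
    """Greedy NMS by descending score; class-agnostic.

    Any hypothesis with IoU > threshold against an already-kept one is
    removed; output is sorted by descending score.
    """
    ordered = sorted(hyps, key=lambda hh: -hh.score(score_mode))
    kept = []
    for h in ordered:
        if all(box_iou(h.box, k.box) <= nms_threshold for k in kept):
            kept.append(h)
    return kept


def detector_loss(model: FinDetector, batch_x: np.ndarray, batch_targets,
                  hyper: dict):
    """Composite single-stage loss for one batch.

    BCE on cell offsets (soft targets), objectness and class terms, MSE
    on log-scale extents; positives up-weighted by ``lambda_*`` factors
    to offset the foreground/background imbalance.
    """
    b, c = model.config.boxes_per_cell, model.config.n_classes
    outs = model.forward(nn.Tensor(batch_x))
    n = batch_x.shape[0]
    l_box = hyper.get("lambda_box", 5.0)
    l_obj = hyper.get("lambda_obj", 5.0)
    l_noobj = hyper.get("lambda_noobj", 1.0)
    l_cls = hyper.get("lambda_cls", 1.0)
    losses = []
    for sc, out in enumerate(outs):
        g = out.data.shape[2]
        tgt = np.stack([t[sc] for t in batch_targets[0]])
        wb = np.stack([t[sc] for t in batch_targets[1]])
        wm = np.stack([t[sc] for t in batch_targets[2]])
        # scale the generic weight grids by the loss-term lambdas
        wb = wb.copy()
        pos = tgt[..., 4] == 1.0
        wb[..., 0] *= l_box
        wb[..., 1] *= l_box
        wb[..., 4] = np.where(pos, wb[..., 4] * l_obj, wb[..., 4] * l_noobj)
        wb[..., 5:] *= l_cls
        wm = wm * l_box
        # (N, b, G, G, 5+c) -> (N, b*(5+c), G, G) to match the conv output
        tgt = tgt.transpose(0, 1, 4, 2, 3).reshape(n, -1, g, g)
        wb = wb.transpose(0, 1, 4, 2, 3).reshape(n, -1, g, g)
        wm = wm.transpose(0, 1, 4, 2, 3).reshape(n, -1, g, g)
        losses.append(nn.ops.bce_with_logits(out, tgt, wb))
        losses.append(nn.ops.mse(out, tgt, wm))
    return nn.ops.mul_scalar(nn.ops.sum_losses(losses), 1.0 / n)


DEFAULT_DETECT_HYPERPARAMS = {
    "lr": 3e-3, "batch_size": 8, "epochs": 20, "lambda_box": 5.0,
    "lambda_obj": 5.0, "lambda_noobj": 1.0, "lambda_cls": 1.0,
    "eval_every": 5,
}


def train_detector(train_scenes, val_scenes, config: DetectorConfig,
                   hyper: dict | None = None, seed: int = 0,
                   log_csv=None):
    """Train on (image, gt_boxes) pairs; select the best checkpoint by
    validation mAP.

    ``train_scenes``/``val_scenes``: sequences of (uint8 RGB image,
    list of normalized (cx, cy, w, h) ground-truth boxes). Returns
    (model, history) where history is a list of per-epoch dicts.
    Deterministic given ``seed``.
    """
    if not train_scenes:
        raise ValueError("empty training set")
    hyper = {**DEFAULT_DETECT_HYPERPARAMS, **(hyper or {})}
    rng = np.random.default_rng(seed)
    model = build_detector(config, seed=seed)
    opt = nn.Adam(model.parameters(), lr=hyper["lr"])

    cache = []
    for img, gts in train_scenes:
        arr, tr = preprocess_image(img, config.input_size)
        model_boxes = [tr.box_to_model(bx) for bx in gts]
        cache.append((arr, encode_targets(model_boxes, config)))

    history = []
    best = (-1.0, None)
    bs = int(hyper["batch_size"])
    for epoch in range(int(hyper["epochs"])):
        order = rng.permutation(len(cache))
        model.train()
        epoch_loss = 0.0
        for start in range(0, len(order), bs):
            idxs = order[start:start + bs]
            batch_x = np.stack([cache[i][0] for i in idxs])
            t = [[cache[i][1][0] for i in idxs],
                 [cache[i][1][1] for i in idxs],
                 [cache[i][1][2] for i in idxs]]
            loss = detector_loss(model, batch_x, t, hyper)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idxs)
        epoch_loss /= len(cache)
        row = {"epoch": epoch, "train_loss": epoch_loss, "val_map": ""}
        if val_scenes and ((epoch + 1) % int(hyper["eval_every"]) == 0
                           or epoch == int(hyper["epochs"]) - 1):
            val_map = evaluate_detector(model, val_scenes)["mAP"]
            row["val_map"] = val_map
            if val_map > best[0]:
                best = (val_map, copy.deepcopy(model.named_state()))
        history.append(row)
    if best[1] is not None:
        model.load_state(best[1])
    if log_csv is not None:
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss",
                                                    "val_map"])
            writer.writeheader()
            writer.writerows(history)
    return model, history


def detect(image: np.ndarray, model: FinDetector,
           thresholds: DetectionThresholds = DetectionThresholds(),
           mode: str = "test", out_txt=None):
    """Full detection pipeline on one image.

    preprocess -> forward -> decode -> NMS, then boxes are mapped back to
    original-image coordinates. Optionally writes one text line per
    surviving hypothesis: ``class_id cx cy w h objectness``.
    """
    config = model.config
    arr, tr = preprocess_image(image, config.input_size)
    raw = model.forward_raw(arr)
    hyps = decode(raw, config, thresholds, mode)
    hyps = non_max_suppression(hyps, thresholds.nms, config.nms_score)
    mapped = []
    for h in hyps:
        bx = tr.box_from_model(h.box)
        bx = tuple(float(np.clip(v, 0.0, 1.0)) for v in bx[:2]) + \
            (float(min(bx[2], 1.0)), float(min(bx[3], 1.0)))
        mapped.append(BoxHypothesis(box=bx, objectness=h.objectness,
                                    class_confidences=h.class_confidences))
    if out_txt is not None:
        with open(out_txt, "w") as fh:
            for h in mapped:
                fh.write("0 " + " ".join(f"{v:.6f}" for v in h.box)
                         + f" {h.objectness:.6f}\n")
    return mapped


def evaluate_detector(model: FinDetector, scenes,
                      thresholds: DetectionThresholds = DetectionThresholds(),
                      mode: str = "train_val") -> dict:
    """mAP / precision / recall of a model over (image, gt_boxes) pairs."""
    from .evaluation import MatchResult, match_detections, precision_recall_f1
    preds, truths = [], []
    total = MatchResult()
    for img, gts in scenes:
        hyps = detect(img, model, thresholds, mode)
        preds.append([(*h.box, h.score(model.config.nms_score))
                      for h in hyps])
        truths.append([tuple(b[:4]) for b in gts])
        total = total + match_detections(preds[-1], truths[-1],
                                         thresholds.iou)
    ap = average_precision(preds, truths, thresholds.iou)
    precision, recall, f1 = precision_recall_f1(total)
    return {"mAP": ap, "precision": precision, "recall": recall, "f1": f1,
            "tp": total.tp, "fp": total.fp, "fn": total.fn}


def self_training_expansion(records, model: FinDetector,
                            thresholds: DetectionThresholds = DetectionThresholds(),
                            mode: str = "test"):
    """Pseudo-label unannotated images, discarding unreliable ones.

    ``records``: sequence of (image, n_labels) where n_labels is the
    number of identity labels attached to the image. Images with zero
    predicted boxes, or with more boxes than labels, are discarded; the
    survivors are returned as (image, machine_boxes) pairs usable as
    pseudo-ground-truth for retraining.
    """
    kept = []
    for image, n_labels in records:
        hyps = detect(image, model, thresholds, mode)
        if len(hyps) == 0 or len(hyps) > n_labels:
            continue
        kept.append((image, [h.box for h in hyps]))
    return kept


def save_detector(model: FinDetector, path):
    meta = {"input_size": model.config.input_size,
            "boxes_per_cell": model.config.boxes_per_cell,
            "n_classes": model.config.n_classes,
            "backbone_scale": model.config.backbone_scale,
            "anchors": [list(a) for a in model.config.anchors],
            "nms_score": model.config.nms_score}
    nn.save_checkpoint(path, model, meta)


def load_detector(path) -> FinDetector:
    state, meta = nn.load_checkpoint(path)
    meta["anchors"] = tuple(tuple(a) for a in meta["anchors"])
    model = build_detector(DetectorConfig(**meta))
    model.load_state(state)
    return model


def kmeans_anchors(boxes, input_size: int, k: int = 9, n_iter: int = 50,
                   seed: int = 0):
    """IoU-distance k-means over training box shapes (optional anchors)."""
    wh = np.array([[b[2] * input_size, b[3] * input_size] for b in boxes])
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), size=k, replace=len(wh) < k)]
    for _ in range(n_iter):
        inter = (np.minimum(wh[:, None, 0], centers[None, :, 0])
                 * np.minimum(wh[:, None, 1], centers[None, :, 1]))
        union = (wh[:, 0] * wh[:, 1])[:, None] + \
            (centers[:, 0] * centers[:, 1])[None] - inter
        assign = np.argmax(inter / union, axis=1)
        for c in range(k):
            if np.any(assign == c):
                centers[c] = np.median(wh[assign == c], axis=0)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return tuple((float(w), float(h)) for w, h in centers[order])
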