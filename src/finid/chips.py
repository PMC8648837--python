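"""Chip classifiers: quality filtering and individual identification.

Both networks share one residual-network family (a 34-layer profile by
default, with the initial convolution widened from 7x7 to 9x9 to give
the first stage a larger receptive field on 512-px chips): a binary
valid/invalid quality filter and a multi-class individual classifier
(100 individuals + 1 rejection class at reference settings). The module
also owns the stochastic training-time augmentation pool and the
procedures built on the classifiers: the strict p_invalid > 0.85 validity
partition and the argmax-matching expansion that recovers training chips
from multi-animal images.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "ResNetSpec", "AugmentationPlan", "VVIThreshold", "ChipClassifier",
    "build_classifier", "AUGMENTATION_POOL", "augment_chip",
    "train_classifier", "classify_chips", "vvi_filter",
    "resolve_multilabel_expansion", "save_classifier", "load_classifier",
]


@dataclass
class ResNetSpec:
    """Architecture of a chip classifier.

    ``depth_profile`` gives residual-block counts per stage — (3, 4, 6, 3)
    is the 34-layer profile; tests use a reduced profile and narrower
    stages. ``initial_kernel`` defaults to 9 (widened from the usual 7).
    """
    n_classes: int = 2
    depth_profile: tuple = (3, 4, 6, 3)
    initial_kernel: int = 9
    input_size: int = 512
    base_channels: int = 64

    def __post_init__(self):
        if len(self.depth_profile) < 1 or any(b < 1
                                              for b in self.depth_profile):
            raise ValueError(f"invalid depth profile {self.depth_profile}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass
class VVIThreshold:
    """Strict cut on the invalid-class probability."""
    p_invalid_cut: float = 0.85

    def __post_init__(self):
        if not 0.0 < self.p_invalid_cut < 1.0:
            raise ValueError("cut must lie in (0, 1)")


class ChipClassifier(nn.Module):
    """Residual CNN mapping a 3 x S x S chip to a class ProbVector."""

    def __init__(self, spec: ResNetSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        self.stem_conv = nn.Conv2d(rng, 3, c, spec.initial_kernel, 2,
                                   bias=False)
        self.stem_bn = nn.BatchNorm2d(c)
        stages = []
        cin = c
        for s_idx, n_blocks in enumerate(spec.depth_profile):
            cout = c * (2 ** s_idx)
            for b_idx in range(n_blocks):
                stride = 2 if (s_idx > 0 and b_idx == 0) else 1
                stages.append(nn.BasicBlock(rng, cin, cout, stride))
                cin = cout
        self.stages = nn.Sequential(*stages)
        self.fc = nn.Linear(rng, cin, spec.n_classes)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.ops.relu(self.stem_bn.forward(self.stem_conv.forward(x)))
        h = nn.ops.max_pool2x2(h)
        h = self.stages.forward(h)
        return self.fc.forward(nn.ops.global_avg_pool(h))

    def probabilities(self, batch: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a (N, 3, S, S) batch (eval mode)."""
        was_training = self.training
        self.eval()
        logits = self.forward(nn.Tensor(batch)).data
        self.train(was_training)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)


def build_classifier(spec: ResNetSpec, seed: int = 0) -> ChipClassifier:
    return ChipClassifier(spec, seed=seed)


# --- augmentation pool -------------------------------------------------

def _aug_gaussian_noise(img, rng):
    sigma = rng.uniform(2.0, 12.0) / 255.0
    return img + rng.normal(0.0, sigma, img.shape).astype(np.float32)


def _aug_rotate(img, rng):
    angle = rng.uniform(-25.0, 25.0)
    return ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                          order=1, mode="nearest").astype(np.float32)


def _aug_gaussian_blur(img, rng):
    sigma = rng.uniform(0.5, 2.0)
    return ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0.0))


def _aug_mirror_y(img, rng):
    return img[:, ::-1].copy()


_EDGE_KERNEL = np.array([[-1, -1, -1], [-1, 10, -1], [-1, -1, -1]],
                        dtype=np.float32) / 2.0
_SHARPEN_KERNEL = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]],
                           dtype=np.float32)


def _conv3(img, kernel):
    out = np.stack([ndimage.convolve(img[:, :, c], kernel, mode="nearest")
                    for c in range(3)], axis=-1)
    return out.astype(np.float32)


def _aug_edge_enhance(img, rng):
    return _conv3(img, _EDGE_KERNEL)


def _aug_sharpen(img, rng):
    return _conv3(img, _SHARPEN_KERNEL)


def _aug_brightness(img, rng):
    return img * np.float32(rng.uniform(0.6, 1.4))


def _aug_channel_swap(img, rng):
    return img[:, :, rng.permutation(3)].copy()


AUGMENTATION_POOL = {
    "gaussian_noise": _aug_gaussian_noise,
    "rotate": _aug_rotate,
    "gaussian_blur": _aug_gaussian_blur,
    "mirror_y": _aug_mirror_y,
    "edge_enhance": _aug_edge_enhance,
    "sharpen": _aug_sharpen,
    "brightness": _aug_brightness,
    "channel_swap": _aug_channel_swap,
}


@dataclass
class AugmentationPlan:
    """k operations drawn without replacement from the 8-function pool,
    applied in random order; k is uniform on [1, a_max] per image."""
    a_max: int = 5
    pool: tuple = tuple(AUGMENTATION_POOL)

    def __post_init__(self):
        if not 1 <= self.a_max <= len(self.pool):
            raise ValueError(f"a_max must lie in [1, {len(self.pool)}]")

    def draw(self, rng: np.random.Generator):
        k = int(rng.integers(1, self.a_max + 1))
        idx = rng.choice(len(self.pool), size=k, replace=False)
        return [self.pool[i] for i in idx]


def augment_chip(chip: np.ndarray, plan: AugmentationPlan,
                 rng: np.random.Generator) -> np.ndarray:
    """Apply a random augmentation plan to a float [0,1] HxWx3 chip.

    Shape and value range are preserved; fully reproducible from the
    generator state.
    """
    out = chip.astype(np.float32)
    for name in plan.draw(rng):
        out = AUGMENTATION_POOL[name](out, rng)
    return np.clip(out, 0.0, 1.0)


# --- training / inference ---------------------------------------------

DEFAULT_CLS_HYPERPARAMS = {
    "lr": 2e-3, "batch_size": 16, "epochs": 15, "eval_every": 3,
    "augment": True, "a_max": 5,
}


def _to_batch(chips) -> np.ndarray:
    """HxWx3 uint8/float chips -> (N, 3, S, S) float32 in [0, 1]."""
    arrs = []
    for c in chips:
        a = np.asarray(c)
        if a.dtype == np.uint8:
            a = a.astype(np.float32) / 255.0
        arrs.append(a.astype(np.float32).transpose(2, 0, 1))
    return np.stack(arrs)


def train_classifier(train_chips, train_labels, val_chips, val_labels,
                     spec: ResNetSpec, hyper: dict | None = None,
                     seed: int = 0, log_csv=None,
                     augment_counter: list | None = None):
    """Train a chip classifier; checkpoint selection by validation accuracy.

    ``train_labels``/``val_labels`` are integer class ids in
    [0, spec.n_classes). Augmentation runs on the training stream only
    (``augment_counter``, if given, collects the number of augmentation
    events per stream for instrumentation). Raises if a class is absent
    from the training set. Deterministic given ``seed``.
    """
    hyper = {**DEFAULT_CLS_HYPERPARAMS, **(hyper or {})}
    train_labels = np.asarray(train_labels, dtype=np.int64)
    val_labels = np.asarray(val_labels, dtype=np.int64)
    present = set(train_labels.tolist())
    missing = sorted(set(range(spec.n_classes)) - present)
    if missing:
        raise ValueError(f"classes absent from training set: {missing}")
    rng = np.random.default_rng(seed)
    model = build_classifier(spec, seed=seed)
    opt = nn.Adam(model.parameters(), lr=hyper["lr"])
    plan = AugmentationPlan(a_max=int(hyper["a_max"]))
    train_imgs = [np.asarray(c).astype(np.float32) / 255.0
                  if np.asarray(c).dtype == np.uint8
                  else np.asarray(c, dtype=np.float32) for c in train_chips]
    val_batch = _to_batch(val_chips) if len(val_chips) else None

    bs = int(hyper["batch_size"])
    history = []
    best = (-1.0, None)
    for epoch in range(int(hyper["epochs"])):
        order = rng.permutation(len(train_imgs))
        model.train()
        epoch_loss = 0.0
        correct = 0
        for start in range(0, len(order), bs):
            idxs = order[start:start + bs]
            imgs = []
            for i in idxs:
                img = train_imgs[i]
                if hyper["augment"]:
                    img = augment_chip(img, plan, rng)
                    if augment_counter is not None:
                        augment_counter.append("train")
                imgs.append(img.transpose(2, 0, 1))
            batch = np.stack(imgs)
            labels = train_labels[idxs]
            logits = model.forward(nn.Tensor(batch))
            loss = nn.ops.softmax_cross_entropy(logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idxs)
            correct += int((logits.data.argmax(axis=1) == labels).sum())
        row = {"epoch": epoch, "train_loss": epoch_loss / len(train_imgs),
               "train_acc": correct / len(train_imgs), "val_acc": ""}
        if val_batch is not None and (
                (epoch + 1) % int(hyper["eval_every"]) == 0
                or epoch == int(hyper["epochs"]) - 1):
            probs = _batched_probs(model, val_batch)
            val_acc = float((probs.argmax(axis=1) == val_labels).mean())
            row["val_acc"] = val_acc
            if val_acc > best[0]:
                best = (val_acc, copy.deepcopy(model.named_state()))
        history.append(row)
    if best[1] is not None:
        model.load_state(best[1])
    if log_csv is not None:
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss",
                                                    "train_acc", "val_acc"])
            writer.writeheader()
            writer.writerows(history)
    return model, history


def _batched_probs(model, batch, bs: int = 32):
    return np.concatenate([model.probabilities(batch[i:i + bs])
                           for i in range(0, len(batch), bs)])


def classify_chips(chips, model: ChipClassifier, top_k: int = 3):
    """Class probabilities and ranked top-k class ids per chip.

    Batch order is preserved; inference is deterministic (no
    augmentation). Ties in the ranking break by class index.
    Returns (probs array (N, n_classes), ranked list of tuples).
    """
    batch = _to_batch(chips)
    if batch.shape[2] != model.spec.input_size:
        raise ValueError(f"chip size {batch.shape[2]} does not match spec "
                         f"input size {model.spec.input_size}")
    probs = _batched_probs(model, batch)
    ranked = []
    for p in probs:
        order = np.lexsort((np.arange(len(p)), -p))[:top_k]
        ranked.append(tuple(int(i) for i in order))
    return probs, ranked


def partition_by_invalid_prob(p_invalid,
                              threshold: VVIThreshold = VVIThreshold()):
    """Strict-inequality partition on the invalid-class probability.

    A chip is invalid iff p_invalid strictly exceeds the cut; a chip at
    exactly the cut stays valid. Order is preserved within each part.
    """
    valid = [i for i, p in enumerate(p_invalid)
             if not p > threshold.p_invalid_cut]
    invalid = [i for i, p in enumerate(p_invalid)
               if p > threshold.p_invalid_cut]
    return valid, invalid


def vvi_filter(chips, model: ChipClassifier,
               threshold: VVIThreshold = VVIThreshold(),
               invalid_class: int = 1):
    """Partition chips into (valid, invalid) with the quality filter.

    Returns (valid_indices, invalid_indices, probs); counts are
    conserved by construction of the strict-cut partition.
    """
    probs, _ = classify_chips(chips, model)
    valid, invalid = partition_by_invalid_prob(probs[:, invalid_class],
                                               threshold)
    return valid, invalid, probs


def resolve_multilabel_expansion(records, model: ChipClassifier,
                                 class_names: list):
    """Assign chips from multi-animal images to classes by argmax matching.

    ``records``: sequence of (label_set, chips) where label_set is the
    image's identity labels and chips the per-detection chips. A chip
    whose best classification hypothesis is one of the image's labels is
    assigned to that class; otherwise it is discarded. Returns a list of
    (chip, assigned_label) pairs — an extended training manifest.
    """
    assigned = []
    for label_set, chip_list in records:
        if not chip_list:
            continue
        _, ranked = classify_chips(chip_list, model)
        for chip, ranks in zip(chip_list, ranked):
            best = class_names[ranks[0]]
            if best in label_set:
                assigned.append((chip, best))
    return assigned


def save_classifier(model: ChipClassifier, path):
    meta = {"n_classes": model.spec.n_classes,
            "depth_profile": list(model.spec.depth_profile),
            "initial_kernel": model.spec.initial_kernel,
            "input_size": model.spec.input_size,
            "base_channels": model.spec.base_channels}
    nn.save_checkpoint(path, model, meta)


def load_classifier(path) -> ChipClassifier:
    state, meta = nn.load_checkpoint(path)
    meta["depth_profile"] = tuple(meta["depth_profile"])
    model = build_classifier(ResNetSpec(**meta))
    model.load_state(state)
    return model
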