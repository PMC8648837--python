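"""End-to-end orchestration of the four-stage pipeline.

Stage order is fixed: (1) fin/saddle-patch detection, (2) square chip
extraction, (3) valid/invalid quality filtering, (4) individual
classification. The report accounts for every input image: detections,
chips, valid/invalid partition (always conserving n_valid + n_invalid ==
n_chips) and a per-chip top-3 prediction table. Invalid chips are logged
with their invalid-class probability rather than deleted, and are
excluded from identification unless the run is asked to classify
everything (the rejection-class audit mode).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .catalog import CatalogRecord, IntervalRule, interval_filter
from .chips import ChipClassifier, VVIThreshold, classify_chips, vvi_filter
from .detector import DetectionThresholds, FinDetector, detect
from .extractor import extract_chip

__all__ = ["PipelineReport", "run_pipeline", "build_identification_dataset"]


@dataclass
class PipelineReport:
    n_images_in: int = 0
    n_detections: int = 0
    n_chips: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    stage_seconds: dict = field(default_factory=dict)

    def check_conservation(self):
        assert self.n_valid + self.n_invalid == self.n_chips

    def to_json(self, path=None):
        payload = {"n_images_in": self.n_images_in,
                   "n_detections": self.n_detections,
                   "n_chips": self.n_chips,
                   "n_valid": self.n_valid,
                   "n_invalid": self.n_invalid,
                   "stage_seconds": self.stage_seconds}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path):
        self.predictions.to_csv(path, index=False)


def _load_image(rec) -> np.ndarray:
    if isinstance(rec, np.ndarray):
        return rec
    if isinstance(rec, CatalogRecord):
        return np.asarray(Image.open(rec.image_path).convert("RGB"))
    return np.asarray(Image.open(rec).convert("RGB"))


def _resize_chip(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape[0] == size:
        return pixels
    resample = Image.BILINEAR if pixels.shape[0] < size else Image.BOX
    return np.asarray(Image.fromarray(pixels).resize((size, size), resample))


PRED_COLUMNS = ["image", "chip_index", "p_invalid", "is_valid",
                "top1", "p1", "top2", "p2", "top3", "p3"]


def run_pipeline(records, det_model: FinDetector, vvi_model: ChipClassifier,
                 id_model: ChipClassifier, class_names,
                 thresholds: DetectionThresholds = DetectionThresholds(),
                 vvi_threshold: VVIThreshold = VVIThreshold(),
                 mode: str = "test", classify_invalid: bool = False,
                 chip_size: int | None = None) -> PipelineReport:
    """Run detect -> extract -> filter -> classify over an image sequence.

    ``records`` may hold CatalogRecords, image paths, or arrays;
    ``class_names`` maps the identification model's class indices to
    identity labels (the last/rejection class included). With
    ``classify_invalid`` every chip is classified regardless of the
    validity verdict, which is how the rejection class is audited.
    """
    report = PipelineReport()
    timers = {"detect": 0.0, "extract": 0.0, "filter": 0.0, "classify": 0.0}
    rows = []
    chip_size = chip_size or id_model.spec.input_size
    for rec in records:
        image = _load_image(rec)
        name = str(rec.image_path) if isinstance(rec, CatalogRecord) else \
            (str(rec) if isinstance(rec, (str, Path)) else
             f"array_{report.n_images_in}")
        report.n_images_in += 1

        t0 = time.perf_counter()
        hyps = detect(image, det_model, thresholds, mode)
        timers["detect"] += time.perf_counter() - t0
        report.n_detections += len(hyps)

        t0 = time.perf_counter()
        chips = [extract_chip(image, h.box, chip_size, source_image=name)
                 for h in hyps]
        timers["extract"] += time.perf_counter() - t0
        report.n_chips += len(chips)
        if not chips:
            continue

        t0 = time.perf_counter()
        vvi_pixels = [_resize_chip(c.pixels, vvi_model.spec.input_size)
                      for c in chips]
        valid_idx, invalid_idx, vvi_probs = vvi_filter(
            vvi_pixels, vvi_model, vvi_threshold)
        timers["filter"] += time.perf_counter() - t0
        report.n_valid += len(valid_idx)
        report.n_invalid += len(invalid_idx)

        to_classify = (list(range(len(chips))) if classify_invalid
                       else valid_idx)
        id_results = {}
        if to_classify:
            t0 = time.perf_counter()
            id_pixels = [_resize_chip(chips[i].pixels,
                                      id_model.spec.input_size)
                         for i in to_classify]
            probs, ranked = classify_chips(id_pixels, id_model)
            timers["classify"] += time.perf_counter() - t0
            id_results = {i: (probs[k], ranked[k])
                          for k, i in enumerate(to_classify)}
        for i in range(len(chips)):
            row = {"image": name, "chip_index": i,
                   "p_invalid": float(vvi_probs[i, 1]),
                   "is_valid": i in valid_idx,
                   "top1": "", "p1": "", "top2": "", "p2": "",
                   "top3": "", "p3": ""}
            if i in id_results:
                probs, ranks = id_results[i]
                for r, cls in enumerate(ranks[:3], start=1):
                    row[f"top{r}"] = class_names[cls]
                    row[f"p{r}"] = float(probs[cls])
            rows.append(row)
    report.predictions = pd.DataFrame(rows, columns=PRED_COLUMNS)
    report.stage_seconds = {k: round(v, 4) for k, v in timers.items()}
    report.check_conservation()
    return report


def build_identification_dataset(records, det_model: FinDetector,
                                 vvi_model: ChipClassifier,
                                 thresholds: DetectionThresholds = DetectionThresholds(),
                                 vvi_threshold: VVIThreshold = VVIThreshold(),
                                 mode: str = "test",
                                 chip_size: int | None = None,
                                 apply_interval_rule: bool = False,
                                 rule: IntervalRule = IntervalRule(),
                                 invalid_admixture: float = 0.08,
                                 rejection_label: str = "INVALID",
                                 seed: int = 0):
    """Build a chip manifest for training the individual classifier.

    Only single-labeled images whose detection yields exactly one box
    are used; chips passing the validity filter are labeled with the
    image's identity. A small admixture of invalid chips (a configured
    fraction of the valid count, mirroring the reference proportion of
    roughly 3,000 rejected chips against ~36,000 valid ones) is labeled
    with the rejection class. Multi-labeled records are returned
    separately for the argmax-matching expansion. The burst-series
    interval rule is applied first when requested (validation/test
    manifests only — training material keeps its near-duplicates).

    Returns (manifest, multilabel_records) where manifest is a list of
    (chip, label) and multilabel_records a list of (label_set, chips).
    """
    if apply_interval_rule:
        records = interval_filter(records, rule)
    chip_size = chip_size or vvi_model.spec.input_size
    manifest = []
    invalid_pool = []
    multilabel = []
    for rec in records:
        image = _load_image(rec)
        hyps = detect(image, det_model, thresholds, mode)
        if not rec.single_labeled:
            if len(hyps) >= 1:
                chips = [extract_chip(image, h.box, chip_size,
                                      source_image=str(rec.image_path))
                         for h in hyps]
                multilabel.append((rec.label_set,
                                   [c.pixels for c in chips]))
            continue
        if len(hyps) != 1:
            continue
        chip = extract_chip(image, hyps[0].box, chip_size,
                            source_image=str(rec.image_path))
        pixels = _resize_chip(chip.pixels, vvi_model.spec.input_size)
        valid_idx, _, _ = vvi_filter([pixels], vvi_model, vvi_threshold)
        if valid_idx:
            manifest.append((chip.pixels, str(rec.labels[0])))
        else:
            invalid_pool.append(chip.pixels)
    rng = np.random.default_rng(seed)
    n_invalid = min(len(invalid_pool),
                    int(round(invalid_admixture * max(len(manifest), 1))))
    if n_invalid:
        for i in rng.choice(len(invalid_pool), size=n_invalid,
                            replace=False):
            manifest.append((invalid_pool[i], rejection_label))
    return manifest, multilabel
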