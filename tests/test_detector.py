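"""Detector: architecture contract, geometry, decode/NMS, toy training."""

import math

import numpy as np
import pytest

from finid.detector import (BoxHypothesis, DetectionThresholds,
                            DetectorConfig, build_detector, decode,
                            encode_targets, iou, non_max_suppression,
                            preprocess_image, save_detector, load_detector,
                            self_training_expansion, targets_to_raw,
                            train_detector, evaluate_detector, detect)
from finid.scene import sample_detection_scenes


class TestConfig:
    def test_reference_contract(self):
        cfg = DetectorConfig(input_size=416)
        assert cfg.per_cell_channels == 21
        assert cfg.grid_sizes == (13, 26, 52)

    def test_small_input_grids(self):
        assert DetectorConfig(input_size=160).grid_sizes == (5, 10, 20)

    def test_non_multiple_of_32_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=200)

    def test_anchor_areas_decrease_with_grid_resolution(self):
        groups = DetectorConfig(input_size=416).scaled_anchors()
        areas = [np.mean([w * h for w, h in g]) for g in groups]
        assert areas[0] > areas[1] > areas[2]


class TestPreprocess:
    def test_square_input_identity_transform(self):
        img = np.zeros((416, 416, 3), dtype=np.uint8)
        arr, tr = preprocess_image(img, 416)
        assert arr.shape == (3, 416, 416)
        box = (0.3, 0.6, 0.2, 0.1)
        assert tr.box_to_model(box) == pytest.approx(box)

    def test_nonsquare_round_trip(self):
        img = np.zeros((400, 600, 3), dtype=np.uint8)
        arr, tr = preprocess_image(img, 160)
        assert arr.shape == (3, 160, 160)
        assert tr.side == 600 and tr.pad_top == 100
        box = (0.25, 0.4, 0.2, 0.3)
        assert tr.box_from_model(tr.box_to_model(box)) == pytest.approx(box)

    def test_padding_is_zero(self):
        img = np.full((100, 200, 3), 255, dtype=np.uint8)
        arr, _ = preprocess_image(img, 96)
        assert arr[:, 0, :].max() == 0.0       # top padding rows
        assert arr[:, 48, :].max() == 1.0      # image center


class TestForward:
    def test_output_shapes_160(self):
        cfg = DetectorConfig(input_size=160)
        model = build_detector(cfg, seed=0)
        raw = model.forward_raw(np.zeros((3, 160, 160), np.float32))
        assert [r.shape for r in raw] == [(5, 5, 21), (10, 10, 21),
                                          (20, 20, 21)]


class TestDecode:
    def test_all_suppressed(self):
        cfg = DetectorConfig(input_size=160)
        raw = [np.full((g, g, 21), -30.0, np.float32)
               for g in cfg.grid_sizes]
        assert decode(raw, cfg) == []

    def test_single_cell_hand_computed(self):
        cfg = DetectorConfig(input_size=160)
        raw = [np.full((g, g, 21), -30.0, np.float32)
               for g in cfg.grid_sizes]
        # activate anchor 1 of the coarsest (5x5) grid at cell (2, 3)
        tx, ty, tw, th = 0.4, -0.6, 0.5, -0.25
        raw[0][2, 3, 7:14] = [tx, ty, tw, th, 2.0, 1.0, -1.0]
        hyps = decode(raw, cfg, mode="train_val")
        assert len(hyps) == 1
        h = hyps[0]
        sig = lambda v: 1 / (1 + math.exp(-v))
        aw, ah = cfg.scaled_anchors()[0][1]
        assert h.box[0] == pytest.approx((sig(tx) + 3) / 5)
        assert h.box[1] == pytest.approx((sig(ty) + 2) / 5)
        assert h.box[2] == pytest.approx(aw * math.exp(tw) / 160)
        assert h.box[3] == pytest.approx(ah * math.exp(th) / 160)
        assert h.objectness == pytest.approx(sig(2.0))

    def test_mode_thresholds(self):
        cfg = DetectorConfig(input_size=160)
        raw = [np.full((g, g, 21), -30.0, np.float32)
               for g in cfg.grid_sizes]
        raw[0][0, 0, 4] = 0.5            # objectness sigmoid ~ 0.62
        assert len(decode(raw, cfg, mode="train_val")) == 1
        assert len(decode(raw, cfg, mode="test")) == 0

    def test_encode_decode_round_trip(self):
        cfg = DetectorConfig(input_size=160)
        rng = np.random.default_rng(0)
        for _ in range(50):
            w, h = rng.uniform(0.05, 0.6, 2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            box = (float(cx), float(cy), float(w), float(h))
            targets, _, _ = encode_targets([box], cfg)
            hyps = decode(targets_to_raw(targets, cfg), cfg)
            assert len(hyps) == 1
            assert hyps[0].box == pytest.approx(box, abs=1e-5)


class TestIoU:
    def test_identical(self):
        assert iou((0.5, 0.5, 0.2, 0.2), (0.5, 0.5, 0.2, 0.2)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_disjoint(self):
        assert iou((0.2, 0.2, 0.1, 0.1), (0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_half_offset_unit_squares(self):
        # unit squares offset by half a side: overlap 0.5, union 1.5
        assert iou((0.0, 0.0, 1.0, 1.0), (0.5, 0.0, 1.0, 1.0)) == \
            pytest.approx(1 / 3)

    def test_rasterization_oracle_1000_pairs(self):
        """Boxes on a 1/128 lattice: rasterized IoU is exact, so the
        analytic implementation must agree to 1e-6."""
        rng = np.random.default_rng(8)
        res = 128
        for _ in range(1000):
            def snap_box():
                w, h = rng.integers(1, 64, 2)
                x0 = rng.integers(0, res - w)
                y0 = rng.integers(0, res - h)
                return x0, y0, w, h
            ax, ay, aw, ah = snap_box()
            bx, by, bw, bh = snap_box()
            a = ((ax + aw / 2) / res, (ay + ah / 2) / res, aw / res, ah / res)
            b = ((bx + bw / 2) / res, (by + bh / 2) / res, bw / res, bh / res)
            ga = np.zeros((res, res), bool)
            gb = np.zeros((res, res), bool)
            ga[ay:ay + ah, ax:ax + aw] = True
            gb[by:by + bh, bx:bx + bw] = True
            inter = (ga & gb).sum()
            union = (ga | gb).sum()
            assert iou(a, b) == pytest.approx(inter / union, abs=1e-6)
            assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)


def hyp(box, obj=0.9, cls=(0.9, 0.1)):
    return BoxHypothesis(box=box, objectness=obj, class_confidences=cls)


class TestNMS:
    def test_single_survives(self):
        h = hyp((0.5, 0.5, 0.2, 0.2))
        assert non_max_suppression([h]) == [h]

    def test_overlapping_pair_keeps_best(self):
        a = hyp((0.5, 0.5, 0.4, 0.4), obj=0.9)
        b = hyp((0.55, 0.5, 0.4, 0.4), obj=0.8)   # IoU ~ 0.68
        assert non_max_suppression([b, a], 0.5) == [a]

    def test_distant_pair_both_kept(self):
        a = hyp((0.3, 0.5, 0.25, 0.25), obj=0.9)
        b = hyp((0.5, 0.5, 0.25, 0.25), obj=0.8)  # IoU = 1/3
        assert non_max_suppression([b, a], 0.5) == [a, b]

    def test_output_is_antichain(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            hyps = []
            for _ in range(12):
                w, h = rng.uniform(0.1, 0.5, 2)
                hyps.append(hyp((rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                                 w, h), obj=float(rng.random())))
            kept = non_max_suppression(hyps, 0.5)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert iou(a.box, b.box) <= 0.5
            scores = [k.score("combined") for k in kept]
            assert scores == sorted(scores, reverse=True)


class TestSelfTraining:
    def test_discard_rules(self, monkeypatch):
        import finid.detector as det
        outcomes = {0: 0, 1: 3, 2: 2}   # image id -> number of boxes

        def fake_detect(image, model, thresholds=None, mode="test"):
            n = outcomes[int(image[0, 0, 0])]
            return [hyp((0.5, 0.5, 0.2, 0.2))] * n

        monkeypatch.setattr(det, "detect", fake_detect)
        images = [np.full((4, 4, 3), i, np.uint8) for i in range(3)]
        records = [(images[0], 1),   # 0 boxes -> discard
                   (images[1], 2),   # 3 boxes > 2 labels -> discard
                   (images[2], 2)]   # 2 boxes == 2 labels -> keep
        kept = self_training_expansion(records, model=None)
        assert len(kept) == 1
        assert len(kept[0][1]) == 2


@pytest.fixture(scope="module")
def toy_training():
    """One small training run shared by the training-behaviour tests."""
    scenes = sample_detection_scenes(10, n_identities=6, seed=21,
                                     image_size=(128, 160))
    cfg = DetectorConfig(input_size=96)
    hyper = {"epochs": 45, "eval_every": 45, "batch_size": 5}
    model, history = train_detector(scenes, [], cfg, hyper, seed=2)
    return scenes, cfg, hyper, model, history


class TestTraining:
    def test_loss_decreases(self, toy_training):
        _, _, _, _, history = toy_training
        losses = [h["train_loss"] for h in history]
        thirds = [np.mean(losses[:15]), np.mean(losses[15:30]),
                  np.mean(losses[30:])]
        assert thirds[0] > thirds[1] > thirds[2]
        assert losses[-1] < 0.5 * losses[0]

    def test_overfit_recall(self, toy_training):
        scenes, _, _, model, _ = toy_training
        res = evaluate_detector(model, scenes)
        assert res["recall"] >= 0.9

    def test_seeded_reruns_identical(self, toy_training):
        scenes, cfg, hyper, _, history = toy_training
        _, history2 = train_detector(scenes, [], cfg, hyper, seed=2)
        assert [h["train_loss"] for h in history2] == \
            [h["train_loss"] for h in history]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_detector([], [], DetectorConfig(input_size=96))

    def test_detect_writes_prediction_file(self, toy_training, tmp_path):
        scenes, _, _, model, _ = toy_training
        out = tmp_path / "pred.txt"
        hyps = detect(scenes[0][0], model, mode="train_val", out_txt=out)
        lines = [l for l in out.read_text().splitlines() if l]
        assert len(lines) == len(hyps)
        for line in lines:
            parts = line.split()
            assert parts[0] == "0" and len(parts) == 6

    def test_checkpoint_round_trip(self, toy_training, tmp_path):
        scenes, _, _, model, _ = toy_training
        save_detector(model, tmp_path / "det.npz")
        loaded = load_detector(tmp_path / "det.npz")
        img = scenes[0][0]
        h1 = detect(img, model, mode="train_val")
        h2 = detect(img, loaded, mode="train_val")
        assert [h.box for h in h1] == [h.box for h in h2]
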