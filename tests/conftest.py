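import numpy as np
import pytest

from finid.scene import (ArchiveConfig, SceneConfig, generate_archive,
                         label_for_index, render_scene, make_identity,
                         sample_detection_scenes, sample_identity_chips,
                         _water_background)


@pytest.fixture(scope="session")
def small_archive(tmp_path_factory):
    """A 60-image synthetic archive shared by catalog/pipeline tests."""
    root = tmp_path_factory.mktemp("archive")
    cfg = ArchiveConfig(n_identities=8, n_images=60, tail_exponent=1.0,
                        burst_probability=0.3, multi_label_fraction=0.2,
                        invalid_fraction=0.15, image_size=(128, 160), seed=5)
    generate_archive(cfg, root)
    return root


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def invalid_chip_pool(n_per_kind=6, seed=0, chip_size=48):
    """Invalid chips: unusable-scenario renders plus fin-free noise."""
    from finid.extractor import extract_chip
    chips = []
    for i, scenario in enumerate(("missing_saddle", "bad_angle", "blur",
                                  "overexposed", "occluded", "distant")):
        got, _ = sample_identity_chips(3, max(n_per_kind // 3, 1),
                                       seed=seed + 31 * i,
                                       chip_size=chip_size,
                                       scenario=scenario)
        chips.extend(got[:n_per_kind])
    local = np.random.default_rng(seed + 7)
    for _ in range(n_per_kind):
        water = (_water_background(96, 96, int(local.integers(0, 2 ** 31)))
                 * 255).astype(np.uint8)
        chips.append(extract_chip(water, (0.5, 0.5, 0.6, 0.6),
                                  chip_size).pixels)
    return chips


@pytest.fixture(scope="session")
def toy_models():
    """Small trained detector + VVI filter + 6-class identifier
    (5 identities and a rejection class), shared across pipeline tests."""
    from finid.chips import ResNetSpec, train_classifier
    from finid.detector import DetectorConfig, train_detector

    det_scenes = sample_detection_scenes(50, n_identities=5, seed=101,
                                         image_size=(128, 160))
    det_model, _ = train_detector(
        det_scenes, [], DetectorConfig(input_size=96),
        {"epochs": 35, "eval_every": 35, "batch_size": 8}, seed=4)

    chip_size = 48
    valid, _ = sample_identity_chips(5, 10, seed=55, chip_size=chip_size)
    invalid = invalid_chip_pool(seed=77, chip_size=chip_size)
    vvi_chips = valid + invalid
    vvi_labels = [0] * len(valid) + [1] * len(invalid)
    vvi_spec = ResNetSpec(n_classes=2, depth_profile=(1, 1),
                          input_size=chip_size, base_channels=8)
    vvi_model, _ = train_classifier(
        vvi_chips, vvi_labels, vvi_chips, vvi_labels, vvi_spec,
        {"epochs": 12, "eval_every": 4, "batch_size": 12}, seed=5)

    # The identifier trains on machine-annotated chips (detector + filter
    # output), exactly like the real pipeline builds its dataset — chips
    # from hand boxes would differ systematically from detected ones.
    import tempfile

    from finid.catalog import parse_archive
    from finid.pipeline import build_identification_dataset

    train_root = generate_archive(
        ArchiveConfig(n_identities=5, n_images=90, tail_exponent=0.6,
                      burst_probability=0.0, multi_label_fraction=0.0,
                      invalid_fraction=0.1, image_size=(128, 160), seed=303),
        tempfile.mkdtemp(prefix="finid_train_"))
    records = parse_archive(train_root).records
    manifest, _ = build_identification_dataset(
        records, det_model, vvi_model, mode="train_val",
        chip_size=chip_size, invalid_admixture=0.15)
    class_names = [label_for_index(i) for i in range(5)] + ["INVALID"]
    idx = {c: i for i, c in enumerate(class_names)}
    id_chips = [c for c, _ in manifest] + invalid[:8]
    id_labels = [idx[l] for _, l in manifest] + [5] * 8
    id_spec = ResNetSpec(n_classes=6, depth_profile=(1, 1),
                         input_size=chip_size, base_channels=16)
    id_model, _ = train_classifier(
        id_chips, id_labels, id_chips, id_labels, id_spec,
        {"epochs": 30, "eval_every": 10, "batch_size": 12, "lr": 3e-3,
         "a_max": 3},
        seed=6)

    return det_model, vvi_model, id_model, class_names
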