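"""Synthetic fin-scene generator.

Stands in for a field archive of killer whale identification photographs:
each rendered scene is a "water" background with one or more schematic
dorsal fins. An individual's biometric signature is exactly the pair of
attributes used by human matchers — the silhouette of the dorsal fin
(height/width ratio, curvature, trailing-edge notches) and the gray-level
pattern of the saddle patch — so identities are distinguishable by the
same cues the downstream classifier is supposed to learn.

Archives are written in the layout the catalog module parses: PNG images,
YOLO-dialect label text files, and a metadata CSV with identity labels,
photographer, date, time and optional GPS. Per-identity frequencies decay
Zipf-like (long-tailed), a configurable fraction of images belongs to
burst series shot less than five seconds apart, and a configurable
fraction shows one of the invalid-image scenarios (missing saddle, bad
angle, distant, blur, overexposure, occlusion, distractor shapes).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

__all__ = [
    "FinIdentity", "SceneConfig", "SceneTruth", "ArchiveConfig",
    "INVALID_SCENARIOS", "label_for_index", "make_identity",
    "render_fin_tile", "render_scene", "generate_archive",
]

INVALID_SCENARIOS = ("missing_saddle", "bad_angle", "distant", "blur",
                     "overexposed", "occluded", "noise_distractor")

WATER_RGB = np.array([0.58, 0.64, 0.70], dtype=np.float32)
BODY_RGB = np.array([0.07, 0.07, 0.09], dtype=np.float32)

_PHOTOGRAPHERS = ("AW", "BK", "CM", "DL", "EP")
_SUFFIXES = ("", "A", "B", "A2")


def label_for_index(i: int) -> str:
    """Deterministic T-grammar identity label for a non-negative index."""
    return f"T{i + 1:03d}{_SUFFIXES[i % len(_SUFFIXES)]}"


@dataclass(frozen=True)
class FinIdentity:
    """Biometric parameters of one synthetic individual.

    ``fin_shape`` = (height_ratio, curvature, notch positions x3 ascending
    along the trailing edge, notch depths x3); ``saddle_params`` =
    (x-offset, half-width, half-height, tilt, pattern fx, pattern fy,
    pattern phase, base gray).
    """
    identity_id: str
    fin_shape: tuple
    saddle_params: tuple
    side_asymmetry: float

    def param_vector(self) -> np.ndarray:
        return np.array(self.fin_shape + self.saddle_params
                        + (self.side_asymmetry,), dtype=np.float64)


@dataclass
class SceneConfig:
    image_size: tuple = (256, 320)          # (height, width)
    invalid_scenario: str = "none"
    background_seed: int = 0

    def __post_init__(self):
        if self.invalid_scenario not in ("none",) + INVALID_SCENARIOS:
            raise ValueError(f"unknown scenario {self.invalid_scenario!r}")
        if min(self.image_size) < 64:
            raise ValueError("image_size must be at least 64 px per side")


@dataclass
class SceneTruth:
    """Ground truth for one rendered scene.

    ``boxes`` are (cx, cy, w, h) normalized to [0, 1]; ``identities`` has
    one label per box (None for non-fin distractor shapes); ``validity``
    flags whether the box shows a usable fin + saddle patch.
    """
    boxes: list = field(default_factory=list)
    identities: list = field(default_factory=list)
    validity: list = field(default_factory=list)
    series_id: str = ""
    photographer: str = ""
    timestamp: str = ""          # "YYYY-MM-DD HH:MM:SS"

    def __post_init__(self):
        assert len(self.boxes) == len(self.identities) == len(self.validity)

    def fin_entries(self):
        return [(b, i, v) for b, i, v in
                zip(self.boxes, self.identities, self.validity)
                if i is not None]


@dataclass
class ArchiveConfig:
    """Synthetic-archive shape.

    ``n_images`` counts photographic *events*; a burst series spawned by
    an event adds its extra frames on top, so the written archive holds
    at least ``n_images`` images. Per-identity event counts decay as
    rank^(-tail_exponent).
    """
    n_identities: int = 20
    n_images: int = 200
    tail_exponent: float = 1.0
    burst_probability: float = 0.15
    multi_label_fraction: float = 0.2
    invalid_fraction: float = 0.1
    noise_image_fraction: float = 0.0
    image_size: tuple = (256, 320)
    seed: int = 0

    def __post_init__(self):
        if self.n_identities < 2:
            raise ValueError("need at least 2 identities")
        for name in ("burst_probability", "multi_label_fraction",
                     "invalid_fraction", "noise_image_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def make_identity(seed: int) -> FinIdentity:
    """Draw a deterministic biometric signature from a seed.

    Parameter ranges: height ratio 1.1-1.8, curvature -0.3..0.3, three
    trailing-edge notches at ascending positions in (0.15, 0.85) with
    depths 0.03-0.09 of tile width; saddle ellipse geometry, sinusoidal
    gray pattern (spatial frequencies 2-6 cycles/tile) and base gray.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed + 982451653)
    # Dominant cues follow low-discrepancy (golden-ratio) sequences in the
    # seed with random jitter, so consecutive catalog identities are
    # well-spread instead of occasionally near-identical.
    height_ratio = 1.1 + 0.7 * float((0.6180339887 * seed
                                      + 0.3 * rng.random()) % 1.0)
    curvature = float(rng.uniform(-0.3, 0.3))
    positions = tuple(sorted(float(p) for p in rng.uniform(0.15, 0.85, 3)))
    depths = tuple(float(d) for d in rng.uniform(0.03, 0.09, 3))
    saddle = (float(rng.uniform(-0.08, 0.12)),     # x-offset behind fin base
              float(rng.uniform(0.13, 0.20)),      # half-width
              float(rng.uniform(0.07, 0.11)),      # half-height
              float(rng.uniform(-0.4, 0.4)),       # tilt (radians)
              float(rng.uniform(2.0, 6.0)),        # pattern fx
              float(rng.uniform(2.0, 6.0)),        # pattern fy
              float(rng.uniform(0.0, 2 * math.pi)),  # pattern phase
              0.30 + 0.58 * float((0.3819660113 * seed
                                   + 0.25 * rng.random()) % 1.0))  # base gray
    asym = float(rng.uniform(0.0, 0.5))
    return FinIdentity(identity_id=label_for_index(seed),
                       fin_shape=(height_ratio, curvature) + positions + depths,
                       saddle_params=saddle, side_asymmetry=asym)


def _trailing_edge(identity: FinIdentity, n: int = 60) -> np.ndarray:
    """Trailing-edge polyline (tip -> base rear) in unit tile coords, y down."""
    hr, curv = identity.fin_shape[0], identity.fin_shape[1]
    positions = identity.fin_shape[2:5]
    depths = identity.fin_shape[5:8]
    tip = np.array([0.38 + 0.18 * curv, 0.78 - 0.72 * (hr - 1.1) / 0.7 - 0.13])
    rear = np.array([0.72, 0.78])
    mid = 0.5 * (tip + rear) + np.array([0.10 + 0.12 * curv, 0.0])
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = ((1 - t) ** 2 * tip + 2 * t * (1 - t) * mid + t ** 2 * rear)
    for pos, depth in zip(positions, depths):
        w = 0.06
        prof = np.clip(1.0 - np.abs(t[:, 0] - pos) / w, 0.0, None)
        pts[:, 0] -= depth * prof       # indent toward the fin interior
    return pts


def _fin_polygon(identity: FinIdentity) -> np.ndarray:
    """Closed fin silhouette polygon, unit tile coords (x, y), y down."""
    hr, curv = identity.fin_shape[0], identity.fin_shape[1]
    tip = np.array([0.38 + 0.18 * curv, 0.78 - 0.72 * (hr - 1.1) / 0.7 - 0.13])
    front = np.array([0.24, 0.78])
    mid = 0.5 * (front + tip) + np.array([-0.06 + 0.1 * curv, 0.0])
    t = np.linspace(0.0, 1.0, 40)[:, None]
    leading = ((1 - t) ** 2 * front + 2 * t * (1 - t) * mid + t ** 2 * tip)
    trailing = _trailing_edge(identity)
    return np.vstack([leading, trailing[1:]])


def render_fin_tile(identity: FinIdentity, side: str, size_px: int,
                    with_saddle: bool = True):
    """Rasterize one fin + body + saddle patch into a square tile.

    Deterministic in (identity, side, size_px, with_saddle): the same
    call always yields pixel-identical output. Returns (rgb float32
    array (size, size, 3), boolean object mask).
    """
    s = size_px
    rgb = np.zeros((s, s, 3), dtype=np.float32)
    mask = np.zeros((s, s), dtype=bool)

    poly = _fin_polygon(identity)
    if side == "left":
        poly = poly.copy()
        poly[:, 0] = 1.0 - poly[:, 0]
    rr, cc = draw_polygon(poly[:, 1] * (s - 1), poly[:, 0] * (s - 1),
                          shape=(s, s))
    mask[rr, cc] = True
    rgb[rr, cc] = BODY_RGB

    # back of the animal at the waterline
    rr, cc = draw_ellipse(int(0.99 * (s - 1)), int(0.5 * (s - 1)),
                          0.22 * s, 0.46 * s, shape=(s, s))
    mask[rr, cc] = True
    rgb[rr, cc] = BODY_RGB

    if with_saddle:
        (xoff, sw, sh, tilt, fx, fy, phase, gray) = identity.saddle_params
        if side == "right":
            phase = phase + identity.side_asymmetry * math.pi
            fx = fx + identity.side_asymmetry
            xoff = -xoff
        cx = (0.5 + xoff) * (s - 1)
        cy = 0.86 * (s - 1)
        rr, cc = draw_ellipse(cy, cx, sh * s, sw * s, rotation=tilt,
                              shape=(s, s))
        yy = rr / max(s - 1, 1)
        xx = cc / max(s - 1, 1)
        pattern = gray + 0.16 * np.sin(
            2 * math.pi * (fx * xx + fy * yy) + phase)
        vals = np.clip(pattern, 0.15, 0.95).astype(np.float32)
        rgb[rr, cc] = vals[:, None]
        mask[rr, cc] = True
    return rgb, mask


def _water_background(h: int, w: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    coarse = rng.normal(0.0, 1.0, (max(h // 24, 2), max(w // 24, 2)))
    noise = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]),
                         order=1)[:h, :w]
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = WATER_RGB
    img += 0.045 * noise[:, :, None].astype(np.float32)
    if rng.random() < 0.5:          # horizon band
        band = int(rng.uniform(0.05, 0.18) * h)
        img[:band] = np.clip(img[:band] + 0.12, 0.0, 1.0)
    return np.clip(img, 0.0, 1.0)


def _shear_tile(rgb, mask, shear: float, squash: float):
    """Affine 'bad viewing angle' distortion of a rendered tile."""
    s = mask.shape[0]
    # output(y, x) = input(y / squash - off, x - shear * (s - y))
    mat = np.array([[1.0 / squash, 0.0], [shear, 1.0]])
    offset = np.array([-(1.0 / squash - 1.0) * (s - 1), -shear * (s - 1)])
    out_rgb = np.stack([ndimage.affine_transform(rgb[:, :, c], mat, offset,
                                                 order=1, cval=0.0)
                        for c in range(3)], axis=-1)
    out_mask = ndimage.affine_transform(mask.astype(np.float32), mat, offset,
                                        order=0, cval=0.0) > 0.5
    return out_rgb.astype(np.float32), out_mask


def _mask_box(mask: np.ndarray):
    """Tight normalized (cx, cy, w, h) box around the True pixels."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    h, w = mask.shape
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return ((x0 + x1) / 2 / w, (y0 + y1) / 2 / h, (x1 - x0) / w, (y1 - y0) / h)


def render_scene(identities, config: SceneConfig, rng: np.random.Generator):
    """Render a scene with one fin per identity plus scenario effects.

    Returns (uint8 RGB image, SceneTruth). Fin placement, sizes and body
    sides are drawn from ``rng``; the water background from
    ``config.background_seed``.
    """
    if len(identities) < 1:
        raise ValueError("need at least one identity")
    h, w = config.image_size
    scenario = config.invalid_scenario
    img = _water_background(h, w, config.background_seed)

    boxes, labels, valid = [], [], []
    n = len(identities)
    slot_w = w / n
    for k, ident in enumerate(identities):
        if scenario == "distant":
            size = int(rng.uniform(0.10, 0.16) * min(h, w))
        else:
            size = int(rng.uniform(0.38, 0.62) * min(h, w))
        size = max(size, 18)
        side = "left" if rng.random() < 0.5 else "right"
        tile, mask = render_fin_tile(ident, side, size,
                                     with_saddle=scenario != "missing_saddle")
        if scenario == "bad_angle":
            tile, mask = _shear_tile(tile, mask,
                                     shear=float(rng.uniform(0.35, 0.6)),
                                     squash=float(rng.uniform(0.38, 0.52)))
        if scenario == "occluded":
            ys = np.nonzero(mask.any(axis=1))[0]
            top, bottom = int(ys.min()), int(ys.max())
            # water covers everything below a line through the fin itself
            cut = top + max(3, int((bottom - top) * rng.uniform(0.3, 0.55)))
            mask[cut:] = False
        x0 = int(k * slot_w + rng.uniform(0.02, 0.95) * max(slot_w - size, 1))
        y0 = int(rng.uniform(0.05, 0.9) * max(h - size, 1))
        x0 = min(x0, w - size) if size <= w else 0
        y0 = min(y0, h - size) if size <= h else 0
        sub = (slice(y0, y0 + mask.shape[0]), slice(x0, x0 + mask.shape[1]))
        m = mask[:img[sub].shape[0], :img[sub].shape[1]]
        t = tile[:img[sub].shape[0], :img[sub].shape[1]]
        region = img[sub]
        region[m] = t[m]
        full = np.zeros((h, w), dtype=bool)
        full[sub][m] = True
        box = _mask_box(full)
        if box is not None:
            boxes.append(box)
            labels.append(ident.identity_id)
            valid.append(scenario == "none")

    if scenario == "noise_distractor":
        tri = np.array([[rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.5)],
                        [0, 0], [0, 0]])
        tri[1] = tri[0] + [rng.uniform(-0.15, -0.05), rng.uniform(0.1, 0.25)]
        tri[2] = tri[0] + [rng.uniform(0.05, 0.15), rng.uniform(0.1, 0.25)]
        rr, cc = draw_polygon(tri[:, 1] * (h - 1), tri[:, 0] * (w - 1),
                              shape=(h, w))
        img[rr, cc] = float(rng.uniform(0.2, 0.4))
        full = np.zeros((h, w), dtype=bool)
        full[rr, cc] = True
        box = _mask_box(full)
        if box is not None:
            boxes.append(box)
            labels.append(None)
            valid.append(False)

    if scenario == "blur":
        img = ndimage.gaussian_filter(img, sigma=(3.0, 3.0, 0.0))
    elif scenario == "overexposed":
        img = np.clip(img * 0.3 + 0.68, 0.0, 1.0)

    out = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return out, SceneTruth(boxes=boxes, identities=labels, validity=valid)


def sample_detection_scenes(n_scenes: int, n_identities: int = 20,
                            seed: int = 0, image_size=(160, 200),
                            multi_fraction: float = 0.3):
    """Sample (image, gt_boxes) pairs for detector training/evaluation.

    Scenes show 1-2 fins (``multi_fraction`` controls the two-fin share)
    under the valid scenario; ground truth is the normalized box list.
    """
    rng = np.random.default_rng(seed + 32452843)
    identities = [make_identity(i) for i in range(n_identities)]
    scenes = []
    for _ in range(n_scenes):
        k = 2 if rng.random() < multi_fraction else 1
        idents = [identities[int(i)]
                  for i in rng.choice(n_identities, size=k, replace=False)]
        cfg = SceneConfig(image_size=image_size,
                          background_seed=int(rng.integers(0, 2 ** 31)))
        img, truth = render_scene(idents, cfg, rng)
        scenes.append((img, [tuple(b) for b in truth.boxes]))
    return scenes


def sample_identity_chips(n_classes: int = 5, per_class: int = 30,
                          seed: int = 0, chip_size: int = 64,
                          scenario: str = "none"):
    """Sample labeled identification chips for classifier experiments.

    Renders single-fin scenes and extracts the ground-truth chip from
    each. Returns (chips, labels): uint8 arrays (chip_size^2 x 3) and
    integer class ids 0..n_classes-1.
    """
    from .extractor import extract_chip
    rng = np.random.default_rng(seed + 49979687)
    identities = [make_identity(i) for i in range(n_classes)]
    chips, labels = [], []
    for k, ident in enumerate(identities):
        for _ in range(per_class):
            cfg = SceneConfig(image_size=(160, 200),
                              invalid_scenario=scenario,
                              background_seed=int(rng.integers(0, 2 ** 31)))
            img, truth = render_scene([ident], cfg, rng)
            if not truth.boxes:
                continue
            chips.append(extract_chip(img, truth.boxes[0], chip_size).pixels)
            labels.append(k)
    return chips, labels


def _allocate_counts(n_identities, n_images, tail_exponent):
    """Zipf-like per-identity image counts renormalized to a total."""
    weights = (np.arange(1, n_identities + 1, dtype=np.float64)
               ** (-tail_exponent))
    weights /= weights.sum()
    counts = np.floor(weights * n_images).astype(int)
    remainder = n_images - counts.sum()
    frac = weights * n_images - np.floor(weights * n_images)
    for i in np.argsort(-frac, kind="stable")[:remainder]:
        counts[i] += 1
    return counts


def generate_archive(config: ArchiveConfig, out_dir) -> Path:
    """Write a synthetic archive (images/, labels/, metadata.csv) to disk.

    Fully reproducible from ``config.seed``: the same configuration
    written twice yields byte-identical files.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 15485863)

    identities = [make_identity(i) for i in range(config.n_identities)]
    counts = _allocate_counts(config.n_identities, config.n_images,
                              config.tail_exponent)
    # expand to a per-image identity queue, then shuffle image order
    queue = [i for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(queue)

    n_noise = int(round(config.noise_image_fraction * len(queue)))
    rows = []
    img_idx = 0
    series_idx = 0
    pos = 0
    while pos < len(queue):
        primary = queue[pos]
        pos += 1
        members = [primary]
        if (rng.random() < config.multi_label_fraction
                and config.n_identities > 1):
            other = int(rng.integers(0, config.n_identities - 1))
            if other >= primary:
                other += 1
            members.append(other)
        scenario = "none"
        if rng.random() < config.invalid_fraction:
            scenario = INVALID_SCENARIOS[
                int(rng.integers(0, len(INVALID_SCENARIOS)))]
        burst_len = 1
        if rng.random() < config.burst_probability:
            burst_len = int(rng.integers(2, 5))
        photographer = _PHOTOGRAPHERS[
            int(rng.integers(0, len(_PHOTOGRAPHERS)))]
        day = int(rng.integers(0, 365))
        date = _date_from_day(2017, day)
        t0 = float(rng.uniform(6 * 3600, 20 * 3600))
        series_idx += 1
        series_id = f"S{series_idx:05d}"
        t = t0
        for frame in range(burst_len):
            if frame > 0:
                t += float(rng.uniform(0.2, 4.5))
            scfg = SceneConfig(image_size=config.image_size,
                               invalid_scenario=scenario,
                               background_seed=int(rng.integers(0, 2 ** 31)))
            idents = [identities[m] for m in members]
            img, truth = render_scene(idents, scfg, rng)
            truth.series_id = series_id
            truth.photographer = photographer
            truth.timestamp = f"{date} {_hms(t)}"
            img_idx += 1
            rows.append(_write_image(out, img_idx, img, truth, rng))
    for _ in range(n_noise):
        img_idx += 1
        h, w = config.image_size
        img = (_water_background(h, w, int(rng.integers(0, 2 ** 31)))
               * 255).round().astype(np.uint8)
        truth = SceneTruth(photographer=_PHOTOGRAPHERS[
            int(rng.integers(0, len(_PHOTOGRAPHERS)))],
            timestamp=f"{_date_from_day(2017, int(rng.integers(0, 365)))} "
                      f"{_hms(float(rng.uniform(6 * 3600, 20 * 3600)))}")
        rows.append(_write_image(out, img_idx, img, truth, rng))

    with open(out / "metadata.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "labels", "photographer", "date",
                         "time", "lat", "lon"])
        writer.writerows(rows)
    return out


def _date_from_day(year, day_of_year):
    import datetime
    d = datetime.date(year, 1, 1) + datetime.timedelta(days=day_of_year)
    return d.isoformat()


def _hms(seconds: float) -> str:
    s = int(seconds)
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def _write_image(out: Path, idx: int, img: np.ndarray, truth: SceneTruth,
                 rng) -> list:
    name = f"im_{idx:06d}"
    rel = f"images/{name}.png"
    Image.fromarray(img).save(out / rel)
    with open(out / "labels" / f"{name}.txt", "w") as fh:
        for box, ident, _ in truth.fin_entries():
            fh.write("0 " + " ".join(f"{v:.6f}" for v in box) + "\n")
    labels = ";".join(i for i in truth.identities if i is not None)
    date, time = ("", "")
    if truth.timestamp:
        date, time = truth.timestamp.split(" ")
    if rng.random() < 0.5:
        lat = f"{rng.uniform(48.0, 54.0):.5f}"
        lon = f"{rng.uniform(-133.0, -122.0):.5f}"
    else:
        lat, lon = "", ""
    return [rel, labels, truth.photographer, date, time, lat, lon]
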