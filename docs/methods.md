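# Methods

`finid` re-creates, at desk scale, a fully automated photo-identification
workflow for Bigg's (transient) killer whales: photographs are scanned
for dorsal fins with their saddle patches, each detection is cropped to a
square identification chip, chips of unusable quality are rejected by a
binary filter, and the surviving chips are assigned to individual whales
by a multi-class classifier. This note records the models, the synthetic
data they are exercised on, the numerical choices, and what the test
suite does and does not establish.

## The four stages

**1. Detection.** A single-stage, grid-based convolutional detector in
the YOLOv3 mould. The input image is zero-padded symmetrically to a
square, resized to the network input size S (reference 416 px, divisible
by 32), and processed by a backbone plus feature-pyramid head that
predicts on three grids of stride 32, 16 and 8 (13×13, 26×26, 52×52 at
416 px). Each cell predicts b = 3 anchored boxes with 4 coordinates, an
objectness score and c = 2 class confidences — b(5+c) = 21 channels per
cell. Decoding applies a sigmoid to the cell offsets and objectness and
an exponential to the anchor scalings; hypotheses at or below the
objectness threshold (0.5 during training/validation, 0.8 at test time)
are dropped, and greedy class-agnostic non-maximum suppression at IoU
0.5 keeps the best-scoring survivor of each overlap group. The NMS
ordering score is objectness × best class confidence by default
(objectness alone is available via configuration; the choice is not
fixed by the method description we follow). Anchors default to the nine
standard YOLOv3 priors rescaled to the input size; an IoU-distance
k-means estimator over training boxes is provided as an alternative.

The training loss is the standard single-stage composite: binary
cross-entropy on objectness (with an ignore band for non-best anchors
whose shape-IoU with a ground truth exceeds 0.5), binary cross-entropy
with soft targets on the cell offsets, squared error on the log-scale
extents, and binary cross-entropy on the class terms, with positives
up-weighted (λ_box = λ_obj = 5) to offset the extreme
foreground/background imbalance on small grids. Positive assignment is
best-shape-anchor per ground truth.

**2. Extraction.** Deterministic geometry, no learning. The normalized
box is denormalized by the original image shape, made square on its
larger side, clamped to the smaller image dimension when necessary, and
translated the minimal distance needed to lie fully inside the image.
The crop is then resampled to the chip size (512 px at reference scale)
— bilinear when up-sampling, area-averaging when down-sampling — so no
chip pixel is ever synthetic padding. When the method's description of
small source images is ambiguous we resample the *cropped square*, not
the whole photograph; resizing the photograph would break the box
geometry for every other detection in it.

**3. Validity filtering.** A residual CNN (34-layer block profile
(3, 4, 6, 3) at reference scale; reduced profiles for CPU tests) whose
initial convolution is widened from 7×7 to 9×9 to enlarge the first
receptive field on large chips. Output is a 2-class probability vector;
a chip is rejected iff its invalid-class probability strictly exceeds
0.85 (a chip at exactly the cut is kept). Training draws k ∈ [1, a_max]
(a_max = 5) distinct operations per image, in random order, from an
8-function augmentation pool: Gaussian noise (σ ∈ [2, 12] of the 8-bit
range), rotation up to ±25°, Gaussian blur (σ ∈ [0.5, 2]), horizontal
mirror, edge enhancement and sharpening (fixed 3×3 kernels), brightness
scaling (factor ∈ [0.6, 1.4]) and random RGB channel permutation. The
pool parameters left open by the method description are our choices, all
configurable. No augmentation is ever applied at validation or test
time. Operations are drawn without replacement within one plan.

**4. Identification.** The same residual architecture with an n-class
head (reference: 101 = 100 individuals + 1 rejection class). The
rejection class absorbs invalid chips that leak through stage 3; it is
trained with a small invalid-chip admixture (default 8% of the valid
count, mirroring the reference proportion of roughly 3,000 rejected
chips against ~36,000 valid ones) so class frequencies are not distorted.
Reported metrics include top-3 weighted accuracy (rank weights 1, 0.5,
0.25) and top-3 unweighted accuracy. Ranking ties break by class index.

A practical point the pipeline tests exposed: the identifier must be
trained on *machine-annotated* chips — detector output filtered by the
validity network, exactly how the deployment-time dataset is built.
Chips cropped from hand (ground-truth) boxes are systematically tighter
than detected ones, and a classifier trained on them transfers poorly to
the pipeline's own crops.

## Dataset curation

Identity labels follow the catalog grammar: one uppercase ecotype letter
('T' for this population), the documentation number, then zero or more
birth-order suffix characters (T109, T109A2). Malformed rows are routed
to a rejects report, never silently dropped.

Burst series — frames shot by the same photographer on the same date
less than δ = 5 s apart — would let near-duplicates inflate validation
and test scores, so only the first frame of each series is kept there.
Training sets are deliberately left unfiltered (augmentation
de-correlates near-duplicates). Chaining semantics: a frame joins the
current series if its gap to the *previous* frame is ≤ δ (transitive
chains); measuring from the series head instead is available behind a
flag. The chained reading matches the idea of a continuous shooting
burst and is the default.

Splits are stratified per identity (every identity with ≥ 3 images
contributes to train, validation and test), deterministic given a seed,
with default ratios (0.75, 0.13, 0.12).

The identification dataset applies three constraints: single-labeled
images with exactly one predicted box; validity filtering; and the
interval rule on validation/test only. Multi-animal images (the label
assignment problem: several labels, unknown box-to-label correspondence)
are recovered separately — each chip whose top-1 classification matches
one of the image's labels is assigned to that class, all others are
discarded.

Self-training expansion of the detection dataset pseudo-labels unseen
images with the current detector and discards images with zero predicted
boxes or with more boxes than identity labels.

## Evaluation

Detection follows the usual TP/FP/FN accounting (true negatives are
undefined for detection): a prediction is a TP when it exceeds the IoU
threshold (0.5) against the ground truth it is assigned to and is the
best such box; all other predictions are FPs; unmatched truths are FNs.
The per-truth "highest IoU wins" rule is made globally consistent when
one box overlaps several truths by computing the assignment that
maximises match count first and total IoU second (an optimal bipartite
matching); the tests verify equivalence against an exhaustive-assignment
oracle on random scenes. Average precision sorts pooled predictions by
score, replaces the precision/recall curve with its monotone (running
right-maximum) envelope, and integrates; mAP averages per-class APs and
equals AP in the single-class case. AP is computed at the single IoU
threshold 0.5 by default; an optional sweep (mean over 0.5:0.95:0.05) is
provided. Aggregation is micro (pooled counts) across images.

The error-reduction rate between two accuracies a₀ < a₁ (in percent) is
ERR = ((100−a₀) − (100−a₁)) / (100−a₀) × 100, reported to one decimal.

## Synthetic scenes

The generator is first-class code, not a fixture: it emulates the
statistical structure of a field archive so every stage is trainable and
testable without the (non-public) photographs.

A synthetic individual is a parameter vector covering exactly the two
biometric attributes the field method uses: the dorsal fin silhouette
(height/width ratio 1.1–1.8, leading/trailing-edge curvature, three
trailing-edge notches at ascending positions with depths 3–9% of the
tile) and the saddle patch (ellipse geometry, sinusoidal gray-level
pattern with 2–6 cycles per tile, base gray 0.30–0.88). Left and right
body sides are mirrored silhouettes with a side-asymmetry parameter
perturbing the saddle pattern; sides are not separate classes. The two
dominant cues (height ratio, base gray) follow low-discrepancy
golden-ratio sequences in the seed with random jitter, so consecutive
catalog identities are guaranteed well spread — with pure uniform draws,
small catalogs occasionally contained near-twins, which says something
true about real catalogs but makes tiny-scale tests uninformative.
Rendering is deterministic: the same identity, side, size and scenario
always produce pixel-identical output.

Scenes place 1–N fins on a low-frequency noise "water" field (optional
horizon band) and emit ground truth as the tight bounding box of each
fin's rendered pixels. Invalid-image scenarios mirror the unusable
categories of field data: missing saddle patch, bad viewing angle
(affine shear + vertical squash), too distant, motion/optical blur,
overexposure, partial occlusion by water, and non-fin distractor shapes
(triangles; boxed in the scene truth with no identity, excluded from
detector label files). Archives draw per-identity counts from a
Zipf-like decay with configurable exponent renormalized to a configured
total, spawn burst series (length 2–4, gaps uniform on [0.2 s, 4.5 s],
shared photographer and date) with a configured probability, and write
PNG images, YOLO-dialect label files and a metadata CSV (labels,
photographer, ISO date, time, optional GPS). Archive generation is
byte-identical given the configuration.

The generator does **not** emulate photographic texture, lighting
physics, water dynamics, scar acquisition over years, or the
low-contrast ambiguity of real fins. A green end-to-end test therefore
establishes that the pipeline machinery (target encoding, losses,
decoding, geometry, filtering rules, orchestration) is correct and
trainable — not that the reference networks' field accuracies are
reproduced. The field-scale headline numbers require the original
archive and GPU-class training, both out of scope here. What anchors the
generator's adequacy is the renderability invariant: five identities ×
30 chips must be > 80% separable by a nearest-centroid classifier on
down-sampled chips, which guarantees classifier tests are meaningful.

## Numerical choices

* All networks run on a small numpy reverse-mode autodiff engine
  (`finid.nn`) written for this package: convolution as per-tap einsum
  contractions, batch normalisation with running statistics, 2×2 max
  pooling with deterministic tie-breaking, Adam. Everything is float32
  and bit-for-bit reproducible given the seed on one CPU — which is what
  the determinism tests assert. No GPU framework is assumed present.
* He initialisation everywhere; the reference backbone's ImageNet
  pretraining is out of scope at desk scale.
* Checkpoint selection: best validation mAP (detector) or accuracy
  (classifiers); the best state is restored at the end of training.
* Default training hyperparameters (Adam, lr 2–3e-3, batch 8–16) are
  engineering choices exposed through YAML/dicts; the reference values
  were not available.
* Interpolation kernels are fixed (bilinear up, area/box down) for
  reproducibility; pixel boxes are half-open, normalized boxes are
  center-based (cx, cy, w, h).
* Degenerate inputs: zero-area boxes and boxes fully outside the image
  raise; empty detection lists, empty archives and empty metric inputs
  are valid and return empty/zero results (with warnings where a metric
  is undefined).
* Scale reductions for CPU tests: detector input 96–160 px with an
  8–128-channel backbone; classifier chips 32–64 px with block profile
  (1, 1) and 4–16 base channels. The architecture contract (21 channels
  per cell, grids S/32, S/16, S/8; 9×9 initial classifier kernel) is
  preserved at every scale and asserted at the 416-px reference setting.

## Known limitations

* The synthetic world is far easier than field photography; measured
  accuracies on it say nothing quantitative about real archives.
* The full-scale (53-layer, 416 px) backbone is instantiable and runs
  forward, but training it on CPU is impractical and untested.
* The numpy engine trains small networks in minutes but is orders of
  magnitude slower than a GPU framework; it is a correctness vehicle,
  not a performance one.
* Multi-fin scenes place fins in horizontal slots, so extreme occlusion
  between animals is not exercised.
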