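# Methods

This note documents the models, conventions, and numerical choices behind
`sonotriage`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and mask conventions

All modules share one convention: 0-based coordinates, x = column,
y = row, origin at the top-left; polygon vertices live in continuous
pixel-corner coordinates, and the centre of pixel (r, c) is
(c + 0.5, r + 0.5). Label masks are one-channel integer images with
background = 0 and one class per pixel (defaults: vein = 1, artery = 2,
nerve = 3, shrapnel = 4). When regions overlap during rasterization the
numerically higher label wins, so shrapnel has the highest priority; the
single-label mask format forces *some* tie rule and this one is stated so
every test can be exact. Mask resizing is always nearest-neighbour (each
output pixel takes the input pixel containing its centre): label maps are
categorical, and any interpolating scheme would invent classes.

## Synthetic phantom model

The generator emulates the *geometry and first-order appearance* of a
gelatin tissue phantom used for foreign-body imaging: a speckled tissue
background, a neurovascular bundle of three roughly circular channels
(vein, artery, nerve — mildly elliptical, radii 6–12 px, grouped within a
28 px bundle spread), and a thin bright rod of shrapnel. Default rod
dimensions follow a 2 mm-diameter rod cut to five lengths between 0.2 and
1.0 cm at a nominal 1 px = 1 mm scale: width 2 px, lengths
{2, 4, 6, 8, 10} px on a 256 × 256 frame. No pixel-to-mm calibration is
asserted anywhere downstream; all distances are reported in pixels with the
resolution recorded in output metadata.

Scene placement is rejection sampling (cap: 1000 attempts, after which the
spec is reported infeasible): vessels must not overlap each other, and the
rod pose is re-drawn until its continuous boundary distance to the nearest
feature falls inside a configured range (default 1–30 px). The continuous
rod–ellipse boundary distance is computed as the exact point-to-rectangle
distance minimised over a dense (8192-point) sampling of the ellipse
boundary; the residual error of that minimisation is below 0.01 px, far
under the discretization bound used in any comparison. Each sample carries
this continuous geometry, so mask-level measurements always have an
analytic reference.

Rendering is deliberately not an acoustic simulation: per-class mean
intensities modulated by multiplicative unit-mean gamma speckle whose
coefficient of variation is the `speckle_strength` parameter (default
0.12). Unit mean keeps class intensities identifiable, which the
Monte-Carlo rendering test exploits. Shadowing, reverberation, beam-width
effects, anisotropic speckle, and labeling subjectivity are all absent —
so green tests here show correctness of the *measurement chain*, not
segmentation performance on real ultrasound.

`perturb_mask` produces "simulated predictions" by controlled corruption:
`dilate` grows every non-background class by a Euclidean disk (growth
claims background pixels only, contested pixels go to the higher class),
emulating an over-segmenting model; `erode` shrinks symmetrically,
emulating tight masks; `flip` reassigns a fraction of boundary-adjacent
pixels to a random differing neighbour's label. Dilation never decreases
and erosion never increases any class's pixel count, which is what makes
the recall/precision bias directions provable end to end.

## Annotations

COCO-dialect JSON (polygon segmentation only — RLE, crowd, and
multi-polygon records are rejected with a structured error), YOLO
segmentation text (one object per line: class index then vertices
normalized to [0, 1], 6 decimals ⇒ round-trip error ≤ 5·10⁻⁴ px at
512 × 512), and single-channel PNG masks.

Mask → polygon conversion traces the *cracks* (pixel-corner edges) around
each 4-connected region; polygon → mask rasterization uses the
pixel-centre-inside rule under even-odd parity with a half-open edge rule.
These two are exact inverses for simply connected regions, which is what
makes the COCO ↔ mask round trip pixel-exact rather than approximately
right. At pinch vertices the tracer prefers the right turn (towards the
region), keeping every emitted loop simple; a region hole traced as a
separate loop re-rasterizes harmlessly because only a higher-priority class
can carve a hole and it repaints that area afterwards.

## Segmentation model

A depth-4 U-Net-style encoder–decoder: two 3×3 convolutions per stage,
each followed by batch normalization and ReLU; one 2×2 max-pool per
encoder stage; channel width doubles per stage (desk-scale default base 16,
i.e. 16/32/64/128 with a 256-channel bottleneck); nearest-neighbour
upsampling with skip concatenation in the decoder; final 1×1 projection to
per-pixel class scores decoded by arg-max (ties to the lower index). The
network, its gradients, and Adam are implemented in numpy/float32, so
training is bit-deterministic for a fixed seed; an end-to-end
finite-difference test validates the gradients.

The training contract is per-pixel softmax cross-entropy. Optimizer,
learning rate, batch size, and class weighting are exposed in `TrainConfig`
(defaults: Adam, lr 1e-3, batch 8, unweighted) because they are protocol
choices, not facts about the method. Shrapnel occupies ~0.2 % of pixels, so
the desk-scale experiments use inverse-frequency-style class weights
(1/5/5/5/20) and lr 1e-2 for the 50-epoch overfit check at 64 × 64 — at
those settings the network memorises 8 samples to shrapnel Dice ≈ 0.96.
Data are split 80:20 into train/validation by seeded shuffle
(train size = round(n·ratio)).

## Evaluation metrics

One-vs-rest TP/FP/TN/FN per class (background included as its own row),
then accuracy, precision, recall, IOU, and Dice. Zero-denominator cases
(class absent from both masks, empty prediction) produce an explicit NaN
marker that aggregation skips and counts — silent zeros would bias sparse
classes. Aggregation is macro (unweighted over classes), reported both with
and without the background class. Multi-image evaluation pools counts
within a class across images (micro over pixels) *and* reports per-image
metrics, since either convention is defensible and they differ on sparse
classes.

## Triage distance

Boundaries are class pixels with a 4-connected neighbour outside the class
(image border = outside); disconnected instances are pooled. The closest
pair between two boundaries is found by exact integer squared-distance
minimisation over all cross pairs (chunked for memory), so the result
equals brute force *exactly*, with ties broken to the lexicographically
lowest (row, col) on the shrapnel side, then the feature side. The triage
score is the minimum defined per-feature distance. Absent shrapnel or
features yield explicit undefined markers, never exceptions. Per-image
error versus ground truth is reported as the absolute difference (the
signed value is stored too) and percent error, undefined when the truth
score is 0.

Discretization: on ≥ 100 random scenes the mask-level score stays within
2·√2 px of the continuous geometric distance (each closest point can move
by at most ~√2 px when snapped through a 2 px-wide rasterized primitive to
a boundary pixel centre).

## Outlier exclusion

Constant-model ROUT recipe: centre = median; scale = RSDR, the 68.27th
percentile of absolute residuals (the percentile that estimates one
standard deviation under normality) with an n/(n−1) one-parameter
small-sample correction; two-tailed p-values from t = |r|/RSDR with n−1
degrees of freedom; Benjamini–Hochberg step-up at Q (default 1 %). The
reference implementation in commercial statistics software is unpublished,
so this documented recipe is the package's own; its calibration is
verified empirically (sensitivity ≥ 0.9 on 10σ contaminants at 5 % of
n = 200; clean-data flag rate ≤ 2Q), but flagged counts on any particular
dataset may differ from other ROUT implementations. Below `min_n = 10`
samples detection is skipped with a warning rather than flagging from an
unstable scale estimate. Flags are invariant under shifting and positive
rescaling of the data.

## Pipeline

Experiments are a single YAML file (validated with explicit error
messages): phantom spec, predictor branch (`simulate` with a perturbation
mode/magnitude, or `train` with network/training settings), test-set size,
seed, output directory. All per-sample randomness derives from
`default_rng([seed, stage, index])` streams, so the simulate branch is
bit-reproducible; the run log records config, seed, and package version and
contains no timestamps for that reason. Every artifact is plain CSV, JSON,
or PNG, and each is re-readable by the module that defines its format.

## Problem sizes used in the shipped experiments

Tests and the acceptance script run the study at reduced scale, chosen as
the smallest sizes at which each property is meaningfully exercised:
96–128 px frames (256 px where the geometric bound is checked), 8–46 images
per run, 50 training epochs at 64 × 64 with base width 16, 100 replicate
seeds for calibration statistics. All are configurable upward.

## Known limitations

- The phantom emulates geometry, not acoustics; results do not transfer to
  real B-mode imagery without retraining and re-validation.
- Multi-polygon COCO records with holes are out of scope for annotation
  input (the tracer can *emit* hole loops; the reader does not accept
  them as one annotation).
- The YOLO text dialect is the plain normalized-polygon form; other
  dialects (bounding-box, RLE) are not parsed.
- The outlier recipe approximates an unpublished algorithm; only its
  stated calibration properties are guaranteed.
- Distances are pixel-valued; no physical calibration is implied.
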