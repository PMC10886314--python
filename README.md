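# sonotriage

Tools for studying AI-assisted **foreign-body triage from ultrasound
images**: multi-class semantic segmentation of tissue-phantom frames (vein,
artery, nerve, shrapnel) and an objective **triage-distance score** — the
minimum boundary-to-boundary distance from an embedded shrapnel fragment to
the nearest neurovascular feature.

The package is aimed at researchers evaluating segmentation models for
emergency-medicine triage who need (a) fully controlled synthetic data with
exactly known geometric ground truth, and (b) a tested implementation of the
evaluation chain: pixel metrics, boundary closest-point distances, and
robust outlier exclusion of distance errors.

## What it computes

For a prediction mask *P* and ground-truth mask *T*, each class is scored
one-vs-rest from pixel tallies TP/FP/TN/FN:

    accuracy  = (TP + TN) / (TP + FN + TN + FP)
    precision = TP / (FP + TP)
    recall    = TP / (FN + TP)
    IOU       = TP / (TP + FP + FN)
    Dice      = 2·TP / (2·TP + FP + FN)  =  2·IOU / (1 + IOU)

The **triage score** of a mask is

    d* = min over features f of  min { ‖x − y‖ : x ∈ ∂S, y ∈ ∂f }

where ∂S and ∂f are the pixel boundaries (4-connectivity, border counts as
outside) of the shrapnel region and feature *f*. Prediction quality for
triage is summarized by the absolute difference |d*_pred − d*_truth| and the
percent error 100·|d*_pred − d*_truth| / d*_truth per image, with
ROUT-style robust outlier exclusion (median / RSDR / t p-values /
Benjamini–Hochberg at Q = 1 %) applied to the error distribution.

Because real phantom image sets are rarely shareable, the `phantom` module
generates speckle-textured frames with a parametric neurovascular bundle
and a thin bright rod, carrying the *continuous* scene geometry alongside
every rasterized mask — so the mask-level triage measurement can always be
checked against an analytic distance.

## Worked example

```python
import numpy as np
import sonotriage as st

spec = st.PhantomSpec(image_size=96, vessel_radius_range=(5.0, 9.0),
                      bundle_spread=16.0, shrapnel_distance_range=(1.0, 25.0))
rng = np.random.default_rng(0)
scene = st.generate_scene(spec, rng)
mask = st.rasterize_mask(scene, spec)

result = st.triage_distance(mask, shrapnel_class=4, feature_classes=[1, 2, 3])
print(round(result.triage_score, 2), result.nearest_feature)
print(round(scene.true_triage_score, 2))
```

prints

```
9.22 2
8.51
```

— the shrapnel's nearest structure is the artery (class 2) at 9.22 px
measured on the mask, versus 8.51 px for the exact continuous geometry; the
0.71 px gap is rasterization error, bounded by 2·√2 px.

A full experiment (generate → simulated or trained predictions → metrics →
triage → outlier summary) runs from a YAML config:

```
sonotriage run --config experiment.yaml --seed 7 --out results/
```

with `predictor: {simulate: {mode: dilate, magnitude: 2}}` emulating an
over-segmenting model (recall ≫ precision) or `mode: erode` a tight one
(precision ≫ recall); `predictor: {train: {...}}` trains the encoder–decoder
instead. Outputs are plain CSV/JSON/PNG, bit-reproducible for a fixed seed
on the simulate branch.

## Layout

- `sonotriage.phantom` — synthetic phantom scenes, masks, rendering, mask
  perturbation, dataset generation
- `sonotriage.annotations` — COCO polygon JSON, label-mask PNG, YOLO
  segmentation text I/O, mask resizing
- `sonotriage.polygons` — pixel-exact crack tracing ↔ centre-inside
  rasterization
- `sonotriage.model` — depth-4 encoder–decoder, train/validation split,
  training loop, prediction; `sonotriage.nn` — the numpy layers
- `sonotriage.metrics` — confusion tallies, the five metrics, macro
  aggregation with/without background
- `sonotriage.triage` — boundary extraction, exact closest pairs, triage
  score, error statistics, overlays
- `sonotriage.outliers` — ROUT-style robust outlier flagging at 1 % FDR
- `sonotriage.pipeline` / `sonotriage.cli` — YAML-configured experiments and
  the `sonotriage` command

See `docs/methods.md` for the modelling choices and their rationale.
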