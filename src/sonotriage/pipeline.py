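"""End-to-end experiment orchestration.

Reproduces the shape of a phantom segmentation study on synthetic data:
generate phantom frames with ground truth -> produce prediction masks
(either by training the encoder–decoder or by controlled perturbation of
the truth, which emulates a model's over-/under-segmentation bias) ->
pixel-metric evaluation -> boundary triage distances -> FDR-based outlier
exclusion of the distance errors.  All outputs are plain CSV/JSON/PNG and
the simulate branch is bit-reproducible for a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import write_coco, write_mask_png
from .metrics import aggregate, compute_metrics, confusion_counts
from .model import TrainConfig, UNetConfig, build_model, predict_mask, split_dataset, train
from .outliers import RoutConfig, rout_constant
from .phantom import PhantomSpec, generate_dataset, perturb_mask
from .triage import triage_distance, triage_error

__all__ = ["ExperimentConfig", "load_config", "run_experiment", "StageError"]

_SIM_MODES = ("dilate", "erode", "flip")


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage and offending sample."""

    def __init__(self, stage: str, sample_id: str | None, cause: Exception):
        msg = f"stage {stage!r} failed" + (f" on sample {sample_id!r}" if sample_id else "")
        super().__init__(f"{msg}: {cause}")
        self.stage, self.sample_id = stage, sample_id


@dataclass
class ExperimentConfig:
    phantom: PhantomSpec
    predictor: dict  # {"simulate": {...}} or {"train": {...}}
    n_train: int
    n_test: int
    output_dir: Path
    seed: int

    @property
    def simulate(self) -> bool:
        return "simulate" in self.predictor


def _validate_config(raw: dict) -> None:
    required = {"predictor", "n_test", "output_dir"}
    missing = required - set(raw)
    if missing:
        raise ValueError(f"config missing required keys: {sorted(missing)}")
    pred = raw["predictor"]
    if not isinstance(pred, dict) or len(set(pred) & {"simulate", "train"}) != 1:
        raise ValueError("predictor must contain exactly one of 'simulate' or 'train'")
    if "simulate" in pred:
        sim = pred["simulate"]
        if sim.get("mode") not in _SIM_MODES:
            raise ValueError(f"simulate.mode must be one of {_SIM_MODES}")
        if not isinstance(sim.get("magnitude"), (int, float)) or sim["magnitude"] < 0:
            raise ValueError("simulate.magnitude must be a non-negative number")
    if int(raw["n_test"]) < 1:
        raise ValueError("n_test must be >= 1")


def load_config(path: str | Path, seed: int | None = None, output_dir: str | None = None) -> ExperimentConfig:
    """Load and validate a YAML experiment config; CLI flags may override."""
    raw = yaml.safe_load(Path(path).read_text())
    if output_dir is not None:
        raw["output_dir"] = output_dir
    if seed is not None:
        raw["seed"] = seed
    raw.setdefault("seed", 0)
    raw.setdefault("n_train", 0)
    _validate_config(raw)
    phantom_kwargs = dict(raw.get("phantom") or {})
    for key in ("vessel_radius_range", "shrapnel_distance_range", "shrapnel_length_set"):
        if key in phantom_kwargs:
            phantom_kwargs[key] = tuple(phantom_kwargs[key])
    return ExperimentConfig(
        phantom=PhantomSpec(**phantom_kwargs),
        predictor=raw["predictor"],
        n_train=int(raw["n_train"]),
        n_test=int(raw["n_test"]),
        output_dir=Path(raw["output_dir"]),
        seed=int(raw["seed"]),
    )


def _simulate_predictions(config: ExperimentConfig, samples) -> list[np.ndarray]:
    sim = config.predictor["simulate"]
    preds = []
    for i, sample in enumerate(samples):
        rng = np.random.default_rng([config.seed, 70000 + i])
        try:
            preds.append(
                perturb_mask(sample.mask, sim["mode"], sim["magnitude"], rng=rng)
            )
        except Exception as exc:
            raise StageError("simulate", sample.sample_id, exc) from exc
    return preds


def _train_predictions(config: ExperimentConfig, spec: PhantomSpec, samples) -> list[np.ndarray]:
    tr = dict(config.predictor["train"])
    n_classes = max(spec.class_table.values()) + 1
    unet_cfg = UNetConfig(
        depth=int(tr.pop("depth", 4)),
        base_channels=int(tr.pop("base_channels", 16)),
        n_classes=n_classes,
        batch_norm=bool(tr.pop("batch_norm", True)),
        input_size=spec.image_size,
    )
    train_cfg = TrainConfig(seed=config.seed, **tr)
    if config.n_train < 2:
        raise StageError("train", None, ValueError("n_train must be >= 2"))
    train_samples, _ = generate_dataset(spec, config.n_train, seed=config.seed + 1)
    tr_set, val_set = split_dataset(train_samples, train_cfg.split_ratio, train_cfg.seed)
    model = build_model(unet_cfg, seed=train_cfg.seed)
    model, _history = train(
        model,
        [s.image for s in tr_set],
        [s.mask for s in tr_set],
        train_cfg,
        val_images=[s.image for s in val_set],
        val_masks=[s.mask for s in val_set],
    )
    return [predict_mask(model, s.image) for s in samples]


def run_experiment(config: ExperimentConfig) -> dict:
    """Run generate -> predict -> evaluate -> triage -> outlier summary.

    Writes the dataset manifest, per-class metric tables (pooled and
    per-image), macro summaries with and without the background class, the
    per-image triage CSV, the outlier report, and a run log, all under
    ``config.output_dir``.  Returns the report bundle as a dict.
    """
    out = Path(config.output_dir)
    spec = config.phantom
    for sub in ("images", "masks", "predictions"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    try:
        samples, annset = generate_dataset(spec, config.n_test, seed=config.seed)
    except Exception as exc:
        raise StageError("generate", None, exc) from exc

    if config.simulate:
        preds = _simulate_predictions(config, samples)
    else:
        preds = _train_predictions(config, spec, samples)

    manifest = {
        "seed": config.seed,
        "n_test": config.n_test,
        "spec": spec.to_dict(),
        "samples": [],
    }
    for sample, pred in zip(samples, preds):
        write_mask_png(sample.image, out / "images" / f"{sample.sample_id}.png")
        write_mask_png(sample.mask, out / "masks" / f"{sample.sample_id}.png")
        write_mask_png(pred, out / "predictions" / f"{sample.sample_id}.png")
        manifest["samples"].append(
            {
                "sample_id": sample.sample_id,
                "image": f"images/{sample.sample_id}.png",
                "mask": f"masks/{sample.sample_id}.png",
                "prediction": f"predictions/{sample.sample_id}.png",
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    write_coco(annset, out / "annotations.json")

    # --- pixel metrics: pooled over images (micro within class) + per image
    try:
        pooled = None
        per_image_rows = []
        for sample, pred in zip(samples, preds):
            counts = confusion_counts(pred, sample.mask, spec.class_table)
            pooled = counts if pooled is None else pooled + counts
            rep = compute_metrics(counts)
            for cls, row in rep.per_class.items():
                per_image_rows.append({"sample_id": sample.sample_id, "class": cls, **row})
        pooled_report = compute_metrics(pooled)
    except Exception as exc:
        raise StageError("evaluate", None, exc) from exc

    pooled_frame = pooled_report.to_frame()
    pooled_frame.to_csv(out / "metrics_per_class.csv", index_label="class")
    (out / "metrics_per_class.json").write_text(
        json.dumps(pooled_report.per_class, indent=1)
    )
    pd.DataFrame(per_image_rows).to_csv(out / "metrics_per_image.csv", index=False)
    summary = {
        "feature_average": aggregate(pooled_report, include_background=False),
        "all_class_average": aggregate(pooled_report, include_background=True),
    }
    pd.DataFrame(summary).T.to_csv(out / "metrics_summary.csv", index_label="scope")

    # --- triage distances on truth and prediction masks
    shrapnel_label = spec.class_table["shrapnel"]
    feature_labels = [spec.class_table[n] for n in spec.feature_classes]
    label_names = {v: k for k, v in spec.class_table.items()}
    triage_rows = []
    errors = []
    for sample, pred in zip(samples, preds):
        try:
            t_truth = triage_distance(sample.mask, shrapnel_label, feature_labels)
            t_pred = triage_distance(pred, shrapnel_label, feature_labels)
        except Exception as exc:
            raise StageError("triage", sample.sample_id, exc) from exc
        err = triage_error(t_pred, t_truth)
        row = {
            "sample_id": sample.sample_id,
            "truth_score": t_truth.triage_score,
            "pred_score": t_pred.triage_score,
            "truth_nearest": label_names.get(t_truth.nearest_feature),
            "pred_nearest": label_names.get(t_pred.nearest_feature),
            "difference": err.difference,
            "signed_difference": err.signed_difference,
            "percent_error": err.percent_error,
        }
        for lbl in feature_labels:
            fd = t_truth.per_feature[lbl]
            row[f"truth_dist_{label_names[lbl]}"] = fd.distance
            fd = t_pred.per_feature[lbl]
            row[f"pred_dist_{label_names[lbl]}"] = fd.distance
        triage_rows.append(row)
        if err.defined and err.percent_error is not None:
            errors.append(err.percent_error)
    triage_frame = pd.DataFrame(triage_rows)
    triage_frame.to_csv(out / "triage.csv", index=False)

    # --- ROUT outlier exclusion on the percent errors
    outlier_summary: dict = {"applied": False}
    if len(errors) >= 2:
        try:
            report = rout_constant(np.asarray(errors), RoutConfig())
        except Exception as exc:
            raise StageError("outliers", None, exc) from exc
        outlier_summary = {"applied": True, **report.summary()}
        pd.DataFrame(
            {
                "percent_error": report.values,
                "p_value": report.p_values,
                "flagged": report.flags,
            }
        ).to_csv(out / "outliers.csv", index=False)
    (out / "outliers.json").write_text(json.dumps(outlier_summary, indent=1))

    (out / "run_log.txt").write_text(
        "\n".join(
            [
                f"sonotriage version: {__version__}",
                f"seed: {config.seed}",
                f"predictor: {json.dumps(config.predictor, sort_keys=True)}",
                f"n_test: {config.n_test}",
                f"n_train: {config.n_train}",
                f"phantom: {json.dumps(spec.to_dict(), sort_keys=True)}",
            ]
        )
        + "\n"
    )

    return {
        "manifest": manifest,
        "metrics": pooled_report,
        "summary": summary,
        "triage": triage_frame,
        "outliers": outlier_summary,
    }
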