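"""Depth-4 encoder–decoder pixel classifier and its training loop.

A U-Net-style network: each encoder stage applies two 3x3 convolutions
(each followed by batch normalization and ReLU when enabled) and then
downsamples once by 2x2 max pooling; channel width doubles per stage.  The
decoder mirrors the encoder with nearest-neighbour upsampling and a skip
concatenation from the matching encoder stage, and a final 1x1 convolution
projects to per-pixel class scores (the pixel classification layer).  Loss
is per-pixel softmax cross-entropy, optionally class-weighted; the
optimizer is Adam.  Pure numpy: training is bit-deterministic for a fixed
seed and runs at desk scale (small inputs, narrow widths) on one CPU.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, BatchNorm2d, Conv2d, MaxPool2, ReLU, UpsampleNearest2, softmax_cross_entropy

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "TrainHistory",
    "UNet",
    "build_model",
    "split_dataset",
    "train",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 16
    n_classes: int = 5
    batch_norm: bool = True
    input_size: int = 256

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    split_ratio: float = 0.8
    seed: int = 0
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")


@dataclass
class TrainHistory:
    """Per-batch training curves and per-epoch validation curves."""

    batch_loss: list[float] = field(default_factory=list)
    batch_accuracy: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)
    epoch_val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"batch": range(1, len(self.batch_loss) + 1),
             "loss": self.batch_loss,
             "accuracy": self.batch_accuracy}
        )

    def epoch_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": range(1, len(self.epoch_val_loss) + 1),
             "val_loss": self.epoch_val_loss,
             "val_accuracy": self.epoch_val_accuracy}
        )


class _DoubleConv:
    def __init__(self, cin: int, cout: int, batch_norm: bool, rng: np.random.Generator):
        self.layers = [Conv2d(cin, cout, 3, rng)]
        if batch_norm:
            self.layers.append(BatchNorm2d(cout))
        self.layers.append(ReLU())
        self.layers.append(Conv2d(cout, cout, 3, rng))
        if batch_norm:
            self.layers.append(BatchNorm2d(cout))
        self.layers.append(ReLU())

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """Encoder–decoder with skip connections; see module docstring."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        widths = [config.base_channels * 2**i for i in range(config.depth)]
        self.encoders = []
        cin = 1
        for wdt in widths:
            self.encoders.append(_DoubleConv(cin, wdt, config.batch_norm, rng))
            cin = wdt
        self.pools = [MaxPool2() for _ in widths]
        self.bottleneck = _DoubleConv(widths[-1], widths[-1] * 2, config.batch_norm, rng)
        self.ups = [UpsampleNearest2() for _ in widths]
        self.decoders = []
        cprev = widths[-1] * 2
        for wdt in reversed(widths):
            self.decoders.append(_DoubleConv(cprev + wdt, wdt, config.batch_norm, rng))
            cprev = wdt
        self.head = Conv2d(widths[0], config.n_classes, 1, rng)
        self._skip_channels: list[int] = []

    @property
    def encoder_widths(self) -> list[int]:
        return [self.config.base_channels * 2**i for i in range(self.config.depth)]

    def params(self):
        out = []
        for enc in self.encoders:
            out.extend(enc.params())
        out.extend(self.bottleneck.params())
        for dec in self.decoders:
            out.extend(dec.params())
        out.extend(self.head.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.decoders), self._skip_channels
        ):
            dcat = dec.backward(dy)
            dskips.append(dcat[:, :c_skip])
            dy = up.backward(dcat[:, c_skip:])
        dy = self.bottleneck.backward(dy)
        # dskips accumulate shallow-to-deep; encoders unwind deep-to-shallow
        for enc, pool, dskip in zip(
            reversed(self.encoders), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dskip)


def build_model(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a network with seeded (reproducible) initial parameters."""
    return UNet(config, seed=seed)


def split_dataset(items: list, split_ratio: float, seed: int) -> tuple[list, list]:
    """Shuffle and partition into train/validation at ``split_ratio``.

    Train size is round(n * ratio); the partition is disjoint, exhaustive,
    and deterministic for a fixed seed.  A ratio emptying either side is an
    error.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_train = round(n * split_ratio)
    if n_train == 0 or n_train == n:
        raise ValueError(f"split_ratio {split_ratio} leaves an empty side for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    train_items = [items[i] for i in perm[:n_train]]
    val_items = [items[i] for i in perm[n_train:]]
    return train_items, val_items


def _prep_images(images: list[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float32) / 255.0 for im in images])
    return arr[:, None, :, :]


def _check_samples(model: UNet, images, masks) -> None:
    size = model.config.input_size
    k = model.config.n_classes
    for im, mk in zip(images, masks):
        if im.shape != (size, size) or mk.shape != (size, size):
            raise ValueError(
                f"sample shape {im.shape}/{mk.shape} does not match input_size {size}"
            )
        if mk.max() >= k:
            raise ValueError(f"mask label {int(mk.max())} outside n_classes={k}")


def train(
    model: UNet,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    config: TrainConfig,
    val_images: list[np.ndarray] | None = None,
    val_masks: list[np.ndarray] | None = None,
) -> tuple[UNet, TrainHistory]:
    """Minimize per-pixel cross-entropy with Adam; record curves per batch.

    Zero epochs leaves the model untouched with an empty history.  Training
    order is shuffled each epoch from ``config.seed``, so runs are exactly
    reproducible.
    """
    _check_samples(model, images, masks)
    history = TrainHistory()
    if config.epochs == 0:
        return model, history
    x = _prep_images(images)
    y = np.stack([np.asarray(m, dtype=np.int64) for m in masks])
    weights = (
        np.asarray(config.class_weights, dtype=np.float32)
        if config.class_weights is not None
        else None
    )
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(images)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx], weights)
            model.backward(dlogits)
            opt.step()
            pred = logits.argmax(axis=1)
            history.batch_loss.append(loss)
            history.batch_accuracy.append(float((pred == y[idx]).mean()))
        if val_images:
            vx = _prep_images(val_images)
            vy = np.stack([np.asarray(m, dtype=np.int64) for m in val_masks])
            vlogits = model.forward(vx, train=False)
            vloss, _ = softmax_cross_entropy(vlogits, vy, weights)
            history.epoch_val_loss.append(vloss)
            history.epoch_val_accuracy.append(
                float((vlogits.argmax(axis=1) == vy).mean())
            )
    return model, history


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Arg-max decode of the per-pixel class scores (ties -> lower index)."""
    size = model.config.input_size
    if image.shape != (size, size):
        raise ValueError(f"image shape {image.shape} != input size {size}")
    logits = model.forward(_prep_images([image]), train=False)
    return logits[0].argmax(axis=0).astype(np.uint8)


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Save parameters as .npz with a JSON sidecar holding the config."""
    path = Path(path)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    bn_state = {}
    i = 0
    for enc in model.encoders + [model.bottleneck] + model.decoders:
        for layer in enc.layers:
            if isinstance(layer, BatchNorm2d):
                bn_state[f"rm{i}"] = layer.running_mean
                bn_state[f"rv{i}"] = layer.running_var
                i += 1
    np.savez(path, **arrays, **bn_state)
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), indent=1))


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    config = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = UNet(config, seed=0)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, (p, _) in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    i = 0
    for enc in model.encoders + [model.bottleneck] + model.decoders:
        for layer in enc.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = data[f"rm{i}"]
                layer.running_var = data[f"rv{i}"]
                i += 1
    return model
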