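"""Stage-regression CNN for brightfield embryo images.

A small AlexNet-lineage network that maps a single embryo image to a scalar
developmental stage in hpf: an x-only centre crop, a rescaling layer,
``n`` repeating units of (3x3 convolution, ReLU, 2x2 max pooling), then
flatten -> dense -> dropout -> dense(1).  Training minimises mean squared
error in hpf^2 with the Adam optimiser.

The network, its backpropagation and the Adam optimiser are implemented
directly on NumPy arrays.  Owning the backward pass keeps the model light
enough to train on a CPU at reduced scale and lets the saliency code apply
the DeconvNet rule exactly: on the backward pass, ReLU units transmit only
the positive part of the upstream signal, regardless of the sign of their
forward activation.

Data augmentation (training only) follows the six-transform recipe used for
plate time-lapse data: randomly applied histogram equalisation, randomly
applied saturation scaling, additive Gaussian noise, random horizontal and
vertical flips, random x-translation (max 20% of width) and random zoom
(max 30%).  Translation is restricted to x because the centre-crop layer
crops only in x, so edge artefacts introduced by an x-shift are largely
removed by the crop while y-shift artefacts would survive.  Empty regions
from shifts and zoom-out are filled by edge replication to avoid dark
borders that a saliency map would latch onto.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import map_coordinates

from . import plateio

__all__ = [
    "StageModelConfig",
    "AugmentationConfig",
    "TransferSpec",
    "StageNet",
    "build_model",
    "scaled_config",
    "center_crop_x",
    "augment",
    "train",
    "predict",
    "transfer_learn",
    "saliency_map",
    "load_model",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageModelConfig:
    """Architecture and optimisation hyperparameters.

    The defaults are the full-scale network (224x320 input cropped to
    224x224, five conv units); :func:`scaled_config` gives the reduced
    desk-scale variant used throughout the test-suite.
    """

    input_height: int = 224
    input_width: int = 320
    crop_width: Optional[int] = None  # None -> square crop to input_height
    n_conv_units: int = 5
    filters_per_unit: tuple[int, ...] = (16, 32, 64, 128, 256)
    dense_width: int = 512
    dropout_rate: float = 0.5
    learning_rate: float = 5e-4
    epochs: int = 500
    batch_size: int = 32
    rescale_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters_per_unit) != self.n_conv_units:
            raise ValueError(
                f"filters_per_unit has {len(self.filters_per_unit)} entries "
                f"for {self.n_conv_units} conv units"
            )
        if any(f < 1 for f in self.filters_per_unit):
            raise ValueError("all filter counts must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        cw = self.effective_crop_width
        if cw > self.input_width:
            raise ValueError(
                f"crop width {cw} exceeds input width {self.input_width}"
            )
        h, w = self.input_height, cw
        for _ in range(self.n_conv_units):
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError(
                f"{self.n_conv_units} pooling halvings collapse the "
                f"{self.input_height}x{cw} input to zero size"
            )

    @property
    def effective_crop_width(self) -> int:
        return self.input_height if self.crop_width is None else self.crop_width


def scaled_config(**overrides) -> StageModelConfig:
    """Desk-scale config: 64x96 input, three conv units (8, 16, 32)."""
    base = dict(
        input_height=64,
        input_width=96,
        n_conv_units=3,
        filters_per_unit=(8, 16, 32),
        dense_width=64,
        dropout_rate=0.2,
        learning_rate=2e-3,
        epochs=30,
        batch_size=32,
    )
    base.update(overrides)
    return StageModelConfig(**base)


@dataclass(frozen=True)
class AugmentationConfig:
    """Probabilities and magnitudes of the six training-time transforms.

    Only the translation (20% of width) and zoom (30%) bounds are fixed by
    the acquisition geometry; the application probabilities are
    conventional choices.
    """

    p_hist_equalise: float = 0.5
    p_saturation: float = 0.5
    saturation_range: tuple[float, float] = (0.6, 1.4)
    noise_sigma: float = 0.02
    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    max_x_translation: float = 0.20  # fraction of image width
    max_zoom: float = 0.30           # fraction; zoom factor in [1-z, 1+z]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hist_equalise", "p_saturation", "p_flip_h", "p_flip_v"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.max_x_translation < 0 or self.max_zoom < 0:
            raise ValueError("translation/zoom bounds must be nonnegative")


@dataclass(frozen=True)
class TransferSpec:
    """Fine-tuning control: fraction of parameters retrained, from the output end.

    The learning rate default is one fifth of the initial-training rate, to
    keep the fine-tune from collapsing into a nearby local minimum.
    """

    target_retrained_fraction: float
    learning_rate: float = 1e-4
    epochs: int = 1200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_retrained_fraction <= 1.0:
            raise ValueError(
                "target_retrained_fraction must be in (0, 1], got "
                f"{self.target_retrained_fraction}"
            )


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Layer:
    """Base layer: forward caches what backward needs; no parameters."""

    trainable = True  # meaningful only for layers with parameters
    name = "layer"

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, deconv: bool = False) -> np.ndarray:
        raise NotImplementedError


class CenterCropX(Layer):
    """Crop equal margins from left/right only (odd margin: extra px on right)."""

    name = "crop_x"

    def __init__(self, target_width: int):
        self.target_width = target_width

    def forward(self, x, training=False):
        w = x.shape[2]
        if w < self.target_width:
            raise ValueError(f"cannot crop width {w} to {self.target_width}")
        left = (w - self.target_width) // 2
        self._in_width, self._left = w, left
        return x[:, :, left : left + self.target_width, :]

    def backward(self, grad, deconv=False):
        out = np.zeros(grad.shape[:2] + (self._in_width,) + grad.shape[3:], grad.dtype)
        out[:, :, self._left : self._left + self.target_width, :] = grad
        return out


class Rescaling(Layer):
    name = "rescale"

    def __init__(self, scale: float = 1.0, offset: float = 0.0):
        self.scale, self.offset = scale, offset

    def forward(self, x, training=False):
        return x * self.scale + self.offset

    def backward(self, grad, deconv=False):
        return grad * self.scale


class Conv2D(Layer):
    """3x3 convolution, stride 1, 'same' zero padding."""

    name = "conv"

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel: int = 3):
        k = kernel
        fan_in = k * k * in_channels
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.kernel = k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, training=False):
        k = self.kernel
        pad = k // 2
        n, h, w, cin = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # (n, h, w, cin, k, k) -> (n, h, w, k, k, cin)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * cin
        )
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.w.reshape(-1, self.w.shape[-1]) + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, grad, deconv=False):
        k = self.kernel
        pad = k // 2
        n, h, w, cin = self._in_shape
        cout = self.w.shape[-1]
        g = grad.reshape(-1, cout)
        if not deconv:
            self.dw = (self._cols.T @ g).reshape(self.w.shape)
            self.db = g.sum(axis=0)
        dcols = (g @ self.w.reshape(-1, cout).T).reshape(n, h, w, k, k, cin)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, cin), dtype=grad.dtype)
        for ky in range(k):
            for kx in range(k):
                dxp[:, ky : ky + h, kx : kx + w, :] += dcols[:, :, :, ky, kx, :]
        return dxp[:, pad : pad + h, pad : pad + w, :]


class ReLU(Layer):
    name = "relu"

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad, deconv=False):
        if deconv:
            # DeconvNet rule: rectify the backward signal itself
            return np.where(grad > 0, grad, 0.0)
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    name = "maxpool"

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad, deconv=False):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        scat = np.zeros((n, h2, w2, c, 4), dtype=grad.dtype)
        np.put_along_axis(scat, self._argmax[..., None], grad[..., None], axis=-1)
        scat = scat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        out = np.zeros((n, h, w, c), dtype=grad.dtype)
        out[:, : 2 * h2, : 2 * w2, :] = scat.reshape(n, 2 * h2, 2 * w2, c)
        return out


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, deconv=False):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    name = "dense"

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / max(in_features, 1))
        self.w = rng.normal(0.0, std, (in_features, out_features))
        self.b = np.zeros(out_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad, deconv=False):
        if not deconv:
            self.dw = self._x.T @ grad
            self.db = grad.sum(axis=0)
        return grad @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad, deconv=False):
        if deconv or self._mask is None:
            return grad
        return grad * self._mask


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class StageNet:
    """Sequential stage-regression network built from the layers above."""

    def __init__(self, layers: Sequence[Layer], config: Optional[StageModelConfig] = None):
        self.layers = list(layers)
        self.config = config

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray, deconv: bool = False) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad, deconv=deconv)
        return grad

    def predict_batch(self, images: np.ndarray) -> np.ndarray:
        """Scalar hpf prediction per image; inference mode, no clipping."""
        return self.forward(images, training=False)[:, 0]

    # -- parameter bookkeeping ------------------------------------------------
    def parametric_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.n_params() > 0]

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def param_report(self) -> pd.DataFrame:
        rows = [
            {"layer": f"{i}:{l.name}", "n_params": l.n_params(),
             "trainable": bool(l.trainable and l.n_params() > 0)}
            for i, l in enumerate(self.layers)
        ]
        return pd.DataFrame(rows)

    def trainable_fraction(self) -> float:
        total = self.n_params()
        if total == 0:
            return 0.0
        t = sum(l.n_params() for l in self.parametric_layers() if l.trainable)
        return t / total

    def set_retrained_fraction(self, target: float) -> float:
        """Unfreeze whole layers from the output end until >= target fraction.

        Returns the achieved fraction (the smallest whole-layer fraction at
        or above the target).
        """
        if not 0.0 < target <= 1.0:
            raise ValueError(f"target fraction must be in (0, 1], got {target}")
        layers = self.parametric_layers()
        total = self.n_params()
        for l in layers:
            l.trainable = False
        acc = 0
        for l in reversed(layers):
            l.trainable = True
            acc += l.n_params()
            if acc / total >= target:
                break
        return acc / total

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights as .npz plus a sidecar JSON of the config."""
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for pname, p in layer.params().items():
                arrays[f"layer{i}_{pname}"] = p
        np.savez(path.with_suffix(".npz"), **arrays)
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["filters_per_unit"] = list(cfg["filters_per_unit"])
            path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_model(path: str | Path) -> StageNet:
    """Rebuild a model from the .npz/.json pair written by :meth:`StageNet.save`."""
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["filters_per_unit"] = tuple(cfg["filters_per_unit"])
    model = build_model(StageModelConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as data:
        for i, layer in enumerate(model.layers):
            for pname in layer.params():
                setattr(layer, pname, data[f"layer{i}_{pname}"].copy())
    return model


def build_model(config: StageModelConfig) -> StageNet:
    """Assemble the network for ``config`` with seeded weight initialisation."""
    rng = np.random.default_rng(config.seed)
    layers: list[Layer] = [
        CenterCropX(config.effective_crop_width),
        Rescaling(config.rescale_factor),
    ]
    h, w, c = config.input_height, config.effective_crop_width, 3
    for filters in config.filters_per_unit:
        layers += [Conv2D(c, filters, rng), ReLU(), MaxPool2D()]
        h, w, c = h // 2, w // 2, filters
    layers.append(Flatten())
    layers.append(Dense(h * w * c, config.dense_width, rng))
    layers.append(ReLU())
    layers.append(Dropout(config.dropout_rate, rng))
    layers.append(Dense(config.dense_width, 1, rng))
    return StageNet(layers, config)


def center_crop_x(images: np.ndarray, target_width: int) -> np.ndarray:
    """Crop an (N, H, W, C) batch to ``target_width`` in x only.

    Margins split floor/ceil: an odd total margin removes one more column
    from the right than from the left.  Content pixels are untouched.
    """
    return CenterCropX(target_width).forward(images)


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def _equalize(img: np.ndarray) -> np.ndarray:
    import warnings

    from skimage import exposure

    with warnings.catch_warnings():
        # equalising over all channels jointly is intended: channels are
        # replicated grayscale, so a per-channel split would be identical
        warnings.simplefilter("ignore", UserWarning)
        return exposure.equalize_hist(img).astype(img.dtype)


def _zoom(img: np.ndarray, factor: float) -> np.ndarray:
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.array([cy + (yy - cy) / factor, cx + (xx - cx) / factor])
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = map_coordinates(
            img[:, :, c], coords, order=1, mode="nearest"
        )
    return out


def _translate_x(img: np.ndarray, shift: int) -> np.ndarray:
    w = img.shape[1]
    src = np.clip(np.arange(w) - shift, 0, w - 1)
    return img[:, src, :]


def augment(
    batch: np.ndarray,
    config: AugmentationConfig,
    training: bool,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply the six training-time transforms independently per image.

    At inference (``training=False``) the batch is returned unchanged —
    bit-identical, augmentation is active for training only.  Output is
    clipped to [0, 1].  Deterministic given the generator state.
    """
    if not training:
        return batch
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = batch.astype(np.float32).copy()
    n, h, w, _ = out.shape
    for i in range(n):
        img = out[i]
        if rng.random() < config.p_hist_equalise:
            img = _equalize(img)
        if rng.random() < config.p_saturation:
            lo, hi = config.saturation_range
            f = lo + rng.random() * (hi - lo)
            gray = img.mean(axis=2, keepdims=True)
            img = gray + f * (img - gray)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, img.shape).astype(np.float32)
        if rng.random() < config.p_flip_h:
            img = img[:, ::-1, :]
        if rng.random() < config.p_flip_v:
            img = img[::-1, :, :]
        if config.max_x_translation > 0:
            max_px = int(round(config.max_x_translation * w))
            shift = int(rng.integers(-max_px, max_px + 1))
            img = _translate_x(img, shift)
        if config.max_zoom > 0:
            factor = 1.0 + (2 * rng.random() - 1.0) * config.max_zoom
            img = _zoom(img, factor)
        out[i] = img
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# optimisation
# --------------------------------------------------------------------------

class Adam:
    """Adam on the trainable layers of a model."""

    def __init__(self, model: StageNet, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.model.layers):
            if not layer.trainable or layer.n_params() == 0:
                continue
            grads = layer.grads()
            for pname, p in layer.params().items():
                g = grads[pname]
                key = (i, pname)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m += (1 - self.b1) * (g - m)
                v += (1 - self.b2) * (g * g - v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _check_disjoint_wells(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    overlap = set(a["well"]) & set(b["well"])
    if overlap:
        raise ValueError(f"wells present in both {what}: {sorted(overlap)}")


def _epoch_loss(model: StageNet, images: np.ndarray, labels: np.ndarray,
                batch_size: int) -> float:
    se = 0.0
    for s in range(0, len(images), batch_size):
        pred = model.forward(images[s : s + batch_size], training=False)[:, 0]
        se += float(np.sum((pred - labels[s : s + batch_size]) ** 2))
    return se / len(images)


def _fit(
    model: StageNet,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    aug: Optional[AugmentationConfig],
    val: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> pd.DataFrame:
    opt = Adam(model, lr=lr)
    history = []
    n = len(images)
    for epoch in range(epochs):
        order = rng.permutation(n)
        se = 0.0
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            xb, yb = images[idx], labels[idx]
            if aug is not None:
                xb = augment(xb, aug, training=True, rng=rng)
            pred = model.forward(xb, training=True)[:, 0]
            err = pred - yb
            se += float(np.sum(err**2))
            model.backward((2.0 * err / len(idx))[:, None])
            opt.step()
        row = {"epoch": epoch, "train_loss": se / n}
        if val is not None:
            row["val_loss"] = _epoch_loss(model, val[0], val[1], batch_size)
        history.append(row)
    return pd.DataFrame(history)


def train(
    model: StageNet,
    train_manifest: pd.DataFrame,
    val_manifest: Optional[pd.DataFrame],
    config: StageModelConfig,
    augmentation: Optional[AugmentationConfig] = None,
    checkpoint: Optional[str | Path] = None,
) -> tuple[StageNet, pd.DataFrame]:
    """Train by MSE/Adam; returns the model and per-epoch loss history.

    Train and validation manifests must use disjoint well sets (all frames
    of one embryo stay on one side).  The history has one row per epoch with
    ``train_loss`` (mean over the epoch's minibatches, in hpf^2) and
    ``val_loss`` when a validation manifest is given.  If ``checkpoint`` is
    set, the trained weights, config sidecar and history CSV are written
    there.
    """
    if len(train_manifest) == 0:
        raise ValueError("empty training manifest")
    if val_manifest is not None and len(val_manifest) > 0:
        _check_disjoint_wells(train_manifest, val_manifest, "train and validation sets")
    if augmentation is None:
        augmentation = AugmentationConfig(seed=config.seed)

    images, labels = plateio.load_batch(
        train_manifest, config.input_height, config.input_width
    )
    val = None
    if val_manifest is not None and len(val_manifest) > 0:
        val = plateio.load_batch(val_manifest, config.input_height, config.input_width)

    rng = np.random.default_rng(config.seed + 1)
    history = _fit(
        model, images, labels,
        epochs=config.epochs, batch_size=config.batch_size,
        lr=config.learning_rate, rng=rng, aug=augmentation, val=val,
    )
    if checkpoint is not None:
        checkpoint = Path(checkpoint)
        checkpoint.parent.mkdir(parents=True, exist_ok=True)
        model.save(checkpoint)
        history.to_csv(checkpoint.with_suffix(".history.csv"), index=False)
    return model, history


def predict(
    model: StageNet, manifest: pd.DataFrame, batch_size: int = 64
) -> pd.DataFrame:
    """Predict hpf for every manifest record, order preserved.

    Returns the manifest columns plus ``predicted_hpf`` and a ``true_hpf``
    column equal to wall-clock hours post fertilisation (``time_h``) — the
    x-axis against which predicted stage is regressed when comparing
    populations at different temperatures.  Predictions are raw network
    outputs; no clipping to nonnegative values.
    """
    cfg = model.config
    if cfg is None:
        raise ValueError("model has no config; cannot determine input size")
    images, _ = plateio.load_batch(manifest, cfg.input_height, cfg.input_width)
    preds = np.concatenate(
        [
            model.predict_batch(images[s : s + batch_size])
            for s in range(0, len(images), batch_size)
        ]
    )
    out = manifest.copy()
    out["true_hpf"] = out["time_h"]
    out["predicted_hpf"] = preds
    return out


def transfer_learn(
    model: StageNet,
    new_train_manifest: pd.DataFrame,
    spec: TransferSpec,
    augmentation: Optional[AugmentationConfig] = None,
) -> tuple[StageNet, dict]:
    """Fine-tune on new data with only a tail fraction of parameters trainable.

    Whole layers are unfrozen from the output end until the retrained
    parameter fraction reaches ``spec.target_retrained_fraction``; frozen
    parameters are bit-identical before and after.  Returns the model and a
    report with the achieved fraction and per-layer trainability.
    """
    if len(new_train_manifest) == 0:
        raise ValueError("empty fine-tuning manifest")
    cfg = model.config
    if cfg is None:
        raise ValueError("model has no config; cannot determine input size")
    achieved = model.set_retrained_fraction(spec.target_retrained_fraction)
    images, labels = plateio.load_batch(
        new_train_manifest, cfg.input_height, cfg.input_width
    )
    rng = np.random.default_rng(spec.seed + 17)
    history = _fit(
        model, images, labels,
        epochs=spec.epochs, batch_size=spec.batch_size,
        lr=spec.learning_rate, rng=rng, aug=augmentation,
    )
    report = {
        "target_retrained_fraction": spec.target_retrained_fraction,
        "actual_retrained_fraction": achieved,
        "n_params_total": model.n_params(),
        "layers": model.param_report().to_dict("records"),
        "final_train_loss": float(history["train_loss"].iloc[-1]),
    }
    return model, report


# --------------------------------------------------------------------------
# saliency
# --------------------------------------------------------------------------

def saliency_map(model: StageNet, image: np.ndarray) -> np.ndarray:
    """DeconvNet-style pixel attribution for one image.

    Runs a forward pass, then propagates the scalar output backwards with
    the DeconvNet ReLU rule: each ReLU transmits only the positive part of
    the signal arriving from above, regardless of its forward activation.
    Max-pool layers route through the forward switch locations; dense and
    convolution layers apply their transposed weights.  The per-channel
    signal is reduced by the maximum of absolute values, so the returned
    map is nonnegative with the spatial shape of the (cropped) input.
    """
    if image.ndim == 3:
        batch = image[None]
    elif image.ndim == 4 and image.shape[0] == 1:
        batch = image
    else:
        raise ValueError(f"expected one (H, W, C) image, got shape {image.shape}")
    out = model.forward(batch, training=False)
    signal = np.ones_like(out)
    # stop before the crop layer: attribution is for the cropped field of view
    layers = model.layers
    start = 1 if isinstance(layers[0], CenterCropX) else 0
    for layer in reversed(layers[start:]):
        signal = layer.backward(signal, deconv=True)
    return np.max(np.abs(signal[0]), axis=-1)
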