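"""Small VGG-style convolutional classifiers for waveform-plot images.

Three variants are provided, all ending in a single sigmoid unit for binary
P300 / non-P300 classification of 150 x 150 plots:

``vgg16``
    Five 3x3 conv blocks (output depths 32, 64, 128, 128, 256), each conv
    stride 1 with same padding followed by a 2x2 stride-2 max-pool
    (ceil mode), giving the spatial trace 150, 75, 38, 19, 10, 5; dropout
    0.5; flatten 5*5*256 = 6400; dense 1024, 512, 256, 1.
``sv16``
    A shallower version: conv depths 32, 64, 128, trace 150, 75, 38, 19,
    flatten 19*19*128 = 46208, dense 512, 256, 1, with early stopping.
``msv16``
    SV16 with an 8-deep input layer so all channel plots of one segment are
    classified together as a single multichannel image.

Layers, mean-squared-error loss and the Adam optimizer are implemented on
NumPy arrays; convolution runs as nine shifted matrix products (one per
kernel tap) and its input gradient as the transposed convolution with the
spatially flipped kernels.  Images enter the network scaled to [0, 1]
(pixel / 255).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .recording import ValidationError

VARIANTS = ("vgg16", "sv16", "msv16")

_PRESETS = {
    "vgg16": dict(conv_depths=(32, 64, 128, 128, 256), dense_sizes=(1024, 512, 256), input_depth=1),
    "sv16": dict(conv_depths=(32, 64, 128), dense_sizes=(512, 256), input_depth=1),
    "msv16": dict(conv_depths=(32, 64, 128), dense_sizes=(512, 256), input_depth=8),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan of one classifier variant."""

    variant: str
    conv_depths: tuple[int, ...]
    dense_sizes: tuple[int, ...]  # hidden dense widths; a final 1-unit sigmoid is implied
    input_depth: int = 1
    input_size: int = 150
    dropout_rate: float = 0.5

    @classmethod
    def preset(cls, variant: str, width_factor: float = 1.0) -> "ArchitectureSpec":
        """A named variant, optionally narrowed.

        ``width_factor`` < 1 scales conv depths and hidden dense widths down
        (minimum 1) for desk-scale runs; the layer count, input depth and
        spatial trace are unchanged.
        """
        key = variant.lower()
        if key not in _PRESETS:
            raise ValidationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        p = _PRESETS[key]
        scale = lambda n: max(1, int(round(n * width_factor)))
        return cls(
            variant=key,
            conv_depths=tuple(scale(d) for d in p["conv_depths"]),
            dense_sizes=tuple(scale(d) for d in p["dense_sizes"]),
            input_depth=p["input_depth"],
        )

    @property
    def spatial_trace(self) -> tuple[int, ...]:
        """Spatial side length at the input and after each 2x2 ceil-mode pool."""
        trace = [self.input_size]
        for _ in self.conv_depths:
            trace.append(math.ceil(trace[-1] / 2))
        return tuple(trace)

    @property
    def flatten_size(self) -> int:
        side = self.spatial_trace[-1]
        return side * side * self.conv_depths[-1]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults follow the per-variant prescriptions."""

    learning_rate: float = 5e-4
    batch_size: int = 20
    max_epochs: int = 30
    early_stopping_epochs: int | None = None  # patience in epochs, None = off
    seed: int = 0

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "TrainingConfig":
        key = variant.lower()
        if key not in _PRESETS:
            raise ValidationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        base = dict(learning_rate=5e-4, batch_size=20, early_stopping_epochs=None)
        if key == "sv16":
            base["early_stopping_epochs"] = 7
        elif key == "msv16":
            base.update(learning_rate=3e-3, batch_size=6, early_stopping_epochs=7)
        base.update(overrides)
        cfg = cls(**base)
        if cfg.learning_rate <= 0 or cfg.batch_size <= 0 or cfg.max_epochs < 0:
            raise ValidationError("learning rate and batch size must be positive")
        return cfg


# --------------------------------------------------------------------------
# layers


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(_Layer):
    """3x3 convolution, stride 1, same padding (He-initialized).

    Computed as nine shifted matrix products (one per kernel tap) on views
    of the padded input — no im2col buffer, which keeps small batches fast.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = math.sqrt(2.0 / (9 * c_in))
        self.w = (rng.standard_normal((3, 3, c_in, c_out)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        x = x.astype(np.float32)
        B, H, W, _ = x.shape
        self._xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.broadcast_to(self.b, (B, H, W, self.b.size)).copy()
        for di in range(3):
            for dj in range(3):
                out += self._xp[:, di : di + H, dj : dj + W, :] @ self.w[di, dj]
        return out

    def backward(self, g):
        g = g.astype(np.float32)
        B, H, W, _ = g.shape
        dxp = np.zeros_like(self._xp)
        for di in range(3):
            for dj in range(3):
                x_slice = self._xp[:, di : di + H, dj : dj + W, :]
                self.grads[0][di, dj] = np.tensordot(x_slice, g, ([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + H, dj : dj + W, :] += g @ self.w[di, dj].T
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        del self._xp
        return dxp[:, 1 : H + 1, 1 : W + 1, :]


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(_Layer):
    """2x2 max-pool, stride 2, ceil mode (odd sides padded with -inf)."""

    def forward(self, x, train, rng):
        B, H, W, C = x.shape
        H2, W2 = math.ceil(H / 2), math.ceil(W / 2)
        self._in_shape = x.shape
        xp = np.full((B, H2 * 2, W2 * 2, C), -np.inf, dtype=x.dtype)
        xp[:, :H, :W] = x
        patches = xp.reshape(B, H2, 2, W2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        patches = patches.reshape(B, H2, W2, 4, C)
        self._argmax = patches.argmax(axis=3)
        return np.take_along_axis(patches, self._argmax[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, g):
        B, H, W, C = self._in_shape
        H2, W2 = math.ceil(H / 2), math.ceil(W / 2)
        gp = np.zeros((B, H2, W2, 4, C), dtype=g.dtype)
        np.put_along_axis(gp, self._argmax[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gp = gp.reshape(B, H2, W2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        return gp.reshape(B, H2 * 2, W2 * 2, C)[:, :H, :W]


class Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = math.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * std).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x.astype(np.float32)
        return self._x @ self.w + self.b

    def backward(self, g):
        g = g.astype(np.float32)
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class Sigmoid(_Layer):
    def forward(self, x, train, rng):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


# --------------------------------------------------------------------------
# model


class Model:
    """A feed-forward stack of layers with a scalar sigmoid output."""

    def __init__(self, spec: ArchitectureSpec, layers: list[_Layer], seed: int) -> None:
        self.spec = spec
        self.layers = layers
        self._rng = np.random.default_rng(seed)  # dropout masks

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != (
            self.spec.input_size,
            self.spec.input_size,
            self.spec.input_depth,
        ):
            raise ValidationError(
                f"{self.spec.variant} expects input (B, {self.spec.input_size}, "
                f"{self.spec.input_size}, {self.spec.input_depth}), got {x.shape}"
            )
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, self._rng)
        return out[:, 0]

    def backward(self, g: np.ndarray) -> None:
        grad = g[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValidationError("weight list does not match model")
        for p, w in zip(flat, weights):
            p[...] = w

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)


def build_model(spec: ArchitectureSpec | str, seed: int = 0) -> Model:
    """Instantiate a variant (conv/pool blocks, dropout, dense head, sigmoid)."""
    if isinstance(spec, str):
        spec = ArchitectureSpec.preset(spec)
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    c_in = spec.input_depth
    for depth in spec.conv_depths:
        layers += [Conv3x3(c_in, depth, rng), ReLU(), MaxPool2()]
        c_in = depth
    layers += [Dropout(spec.dropout_rate), Flatten()]
    n_in = spec.flatten_size
    for width in spec.dense_sizes:
        layers += [Dense(n_in, width, rng), ReLU()]
        n_in = width
    layers += [Dense(n_in, 1, rng), Sigmoid()]
    return Model(spec, layers, seed=rng.integers(2**31))


# --------------------------------------------------------------------------
# training


class Adam:
    def __init__(self, model: Model, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.model.parameters()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mh = self.m[i] / (1 - self.beta1**self.t)
            vh = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def balance_batches(
    labels: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index batches with equal class counts, for one pass over the data.

    The minority class is shuffled and consumed without replacement; the
    majority class is subsampled to match; whatever does not fill a complete
    balanced batch is discarded for this pass.
    """
    labels = np.asarray(labels)
    if batch_size < 2 or batch_size % 2:
        raise ValidationError("batch size must be an even number >= 2")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be non-empty to balance batches")
    half = batch_size // 2
    n_batches = min(pos.size, neg.size) // half
    pos = rng.permutation(pos)[: n_batches * half]
    neg = rng.permutation(neg)[: n_batches * half]
    batches = []
    for k in range(n_batches):
        idx = np.concatenate([pos[k * half : (k + 1) * half], neg[k * half : (k + 1) * half]])
        batches.append(rng.permutation(idx))
    return batches


def _mse(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - y
    return float(np.mean(diff**2)), 2.0 * diff / y.size


def _forward_in_chunks(model: Model, x: np.ndarray, chunk: int = 16) -> np.ndarray:
    """Inference in chunks; pixel values are scaled to [0, 1] per chunk."""
    return np.concatenate(
        [
            model.forward(x[i : i + chunk].astype(np.float32) / 255.0)
            for i in range(0, len(x), chunk)
        ]
    )


def train_classifier(
    model: Model,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, list[float]]:
    """Optimize MSE between the sigmoid output and {0,1} labels with Adam.

    ``images`` are raw plots in [0, 255], shape (N, size, size, depth); they
    are divided by 255 at the model input.  Batches are class-balanced each
    epoch.  With ``validation`` given and an early-stopping patience set, the
    run halts after that many epochs without validation-loss improvement and
    the best weights are restored.  Returns the per-epoch history.
    """
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=np.float32)
    if images.ndim != 4 or len(images) != len(labels):
        raise ValidationError("images must be (N, size, size, depth) matching labels")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValidationError("labels must be binary {0, 1}")
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if validation is not None:
        xv = np.asarray(validation[0])
        yv = np.asarray(validation[1], dtype=np.float32)
        history["val_loss"] = []
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, config.learning_rate)
    best_loss, best_weights, stale = np.inf, None, 0
    for _epoch in range(config.max_epochs):
        losses, hits, seen = [], 0, 0
        for idx in balance_batches(labels, config.batch_size, rng):
            pred = model.forward(images[idx].astype(np.float32) / 255.0, train=True)
            loss, g = _mse(pred, labels[idx])
            model.backward(g)
            opt.step()
            losses.append(loss)
            hits += int(((pred >= 0.5) == (labels[idx] >= 0.5)).sum())
            seen += idx.size
        if not losses:
            break  # minority class cannot fill even one balanced batch
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(hits / max(seen, 1))
        if validation is not None:
            val_pred = _forward_in_chunks(model, xv)
            val_loss, _ = _mse(val_pred, yv)
            history["val_loss"].append(val_loss)
            if config.early_stopping_epochs is not None:
                if val_loss < best_loss - 1e-9:
                    best_loss, best_weights, stale = val_loss, model.get_weights(), 0
                else:
                    stale += 1
                    if stale >= config.early_stopping_epochs:
                        break
    if best_weights is not None:
        model.set_weights(best_weights)
    return history


def predict_scores(model: Model, images: np.ndarray) -> np.ndarray:
    """Sigmoid score in (0, 1) per image, order-preserving and deterministic."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[..., None]
    return _forward_in_chunks(model, images)
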