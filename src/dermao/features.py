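"""Image preprocessing, augmentation, and a compact trainable convnet
used as the deep-feature extractor.

The network is a small, self-contained implementation (im2col
convolutions, max-pooling, optional batch normalization, ReLU, global
average pooling, a dense penultimate layer whose activations are the
extracted features, and a 2-way softmax head) trained with cross-entropy
via Adam or momentum SGD.  It is deliberately desk-scale: a few conv
blocks and a configurable feature width (default 1024) stand in for the
large pretrained backbones used in production dermoscopy systems, while
exposing the same extract-penultimate-features interface.  Everything is
driven by an explicit seed, and inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate, rescale as _sk_rescale

__all__ = [
    "PreprocessConfig",
    "CNNSpec",
    "TrainConfig",
    "SmallCNN",
    "preprocess",
    "augment",
    "train_cnn",
    "extract_features",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: tuple[int, int] = (224, 224)
    normalization: str = "unit"  # "unit" -> [0,1]; "standard" -> per-channel z-score
    rotation_max_degrees: float = 20.0
    horizontal_flip: bool = True
    vertical_flip: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        h, w = self.target_size
        if h < 1 or w < 1:
            raise ValueError("target_size must be positive")
        if self.normalization not in ("unit", "standard"):
            raise ValueError("normalization must be 'unit' or 'standard'")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise ValueError("scale_range must be positive and ordered")


def preprocess(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Resize an 8-bit RGB image to the target size and normalize.

    'unit' maps values to [0, 1] (exactly pixel/255 when no resize is
    needed); 'standard' additionally z-scores each channel within the
    image.
    """
    image = np.asarray(image)
    if image.size == 0 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    x = image.astype(np.float32) / 255.0
    if image.shape[:2] != tuple(config.target_size):
        x = _sk_resize(
            x, config.target_size, order=1, mode="edge", anti_aliasing=True
        ).astype(np.float32)
    if config.normalization == "standard":
        mean = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        x = (x - mean) / np.where(std > 0, std, 1.0)
    return x


def augment(image: np.ndarray, config: PreprocessConfig, rng: np.random.Generator) -> np.ndarray:
    """One random label-preserving augmentation chain: rotation, scale
    jitter (center-cropped/edge-padded back to size), and flips.

    Identity parameters (0 degrees, scale 1, flips off) return the input
    unchanged; output dtype always matches the 8-bit input.
    """
    image = np.asarray(image)
    out = image
    angle = rng.uniform(-config.rotation_max_degrees, config.rotation_max_degrees)
    if angle != 0.0:
        rot = _sk_rotate(out.astype(np.float32) / 255.0, angle, mode="edge")
        out = np.clip(np.round(rot * 255.0), 0, 255).astype(np.uint8)
    lo, hi = config.scale_range
    factor = rng.uniform(lo, hi)
    if factor != 1.0:
        h, w = out.shape[:2]
        scaled = _sk_rescale(
            out.astype(np.float32) / 255.0, factor, channel_axis=2, mode="edge"
        )
        sh, sw = scaled.shape[:2]
        if sh >= h and sw >= w:  # zoom in: center crop
            y0, x0 = (sh - h) // 2, (sw - w) // 2
            scaled = scaled[y0 : y0 + h, x0 : x0 + w]
        else:  # zoom out: edge-pad back
            py, px = h - sh, w - sw
            scaled = np.pad(
                scaled,
                ((py // 2, py - py // 2), (px // 2, px - px // 2), (0, 0)),
                mode="edge",
            )
        out = np.clip(np.round(scaled * 255.0), 0, 255).astype(np.uint8)
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.vertical_flip and rng.random() < 0.5:
        out = out[::-1]
    return np.ascontiguousarray(out)


@dataclass(frozen=True)
class CNNSpec:
    """Architecture: conv blocks (filters, kernel, stride), each followed
    by 2x2 max-pooling, then global average pooling, a dense feature
    layer of width ``feature_dim`` (the extracted representation), and a
    2-class softmax head."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 3, 1), (32, 3, 1), (64, 3, 1))
    batch_norm: bool = True
    feature_dim: int = 1024

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("need at least one conv block")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        for f, k, s in self.conv_blocks:
            if f < 1 or k < 1 or k % 2 == 0 or s < 1:
                raise ValueError("conv blocks need positive filters, odd kernel, stride >= 1")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # or "sgd" (momentum)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    momentum: float = 0.9
    epochs: int = 10
    batch_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


# ---------------------------------------------------------------------------
# layers (NHWC, float32)

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    n, h, w, c = x.shape
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * c
    )


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, stride: int, rng) -> None:
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = rng.normal(0.0, scale, size=(k * k * cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout

    def forward(self, x, train):
        self._x = x
        n, h, w, _ = x.shape
        y = (_im2col(x, self.k) @ self.W + self.b).reshape(n, h, w, self.cout)
        if self.stride > 1:
            y = y[:, :: self.stride, :: self.stride]
        return y

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        if self.stride > 1:
            full = np.zeros((n, h, w, self.cout), dtype=np.float32)
            full[:, :: self.stride, :: self.stride] = dy
            dy = full
        dyf = dy.reshape(-1, self.cout)
        cols = _im2col(x, self.k)
        self.dW = cols.T @ dyf
        self.db = dyf.sum(axis=0)
        # dx = correlation of dy with the spatially flipped, channel-swapped kernel
        wt = (
            self.W.reshape(self.k, self.k, c, self.cout)[::-1, ::-1]
            .transpose(0, 1, 3, 2)
            .reshape(self.k * self.k * self.cout, c)
        )
        return (_im2col(dy, self.k) @ wt).reshape(n, h, w, c)

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm:
    def __init__(self, c: int) -> None:
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = 0.9, 1e-5

    def forward(self, x, train):
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = (0, 1, 2)
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) * self._istd

    def params(self):
        return [("gamma", self), ("beta", self)]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = (h // 2) * 2, (w // 2) * 2
        self._in_shape = x.shape
        xc = x[:, :h2, :w2]
        xr = xc.reshape(n, h2 // 2, 2, w2 // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dy):
        n, h, w, c = self._in_shape
        h2, w2 = (h // 2) * 2, (w // 2) * 2
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = self._mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :h2, :w2] = g.reshape(n, h2, w2, c)
        return dx

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(
            np.float32
        )

    def params(self):
        return []


class _Dense:
    def __init__(self, nin: int, nout: int, rng) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class SmallCNN:
    """Compact convnet; ``features`` returns the penultimate activations."""

    def __init__(self, spec: CNNSpec, input_channels: int = 3, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        layers: list = []
        cin = input_channels
        for f, k, s in spec.conv_blocks:
            layers.append(_Conv(cin, f, k, s, rng))
            if spec.batch_norm:
                layers.append(_BatchNorm(f))
            layers.append(_ReLU())
            layers.append(_MaxPool2())
            cin = f
        layers.append(_GlobalAvgPool())
        layers.append(_Dense(cin, spec.feature_dim, rng))
        layers.append(_ReLU())
        self.backbone = layers
        self.head = _Dense(spec.feature_dim, 2, rng)

    # -- forward / backward -------------------------------------------------
    def features(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic penultimate-layer features, rows in input order."""
        images = np.asarray(images, dtype=np.float32)
        out = []
        for i in range(0, len(images), batch_size):
            x = images[i : i + batch_size]
            for layer in self.backbone:
                x = layer.forward(x, train=False)
            out.append(x)
        return np.concatenate(out, axis=0)

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        for layer in self.backbone:
            x = layer.forward(x, train)
        return self.head.forward(x, train)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            out.append(_softmax(self.logits(images[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def _backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        for layer in reversed(self.backbone):
            dx = layer.backward(dx)

    def _param_slots(self):
        for layer in [*self.backbone, self.head]:
            for name, owner in layer.params():
                yield name, owner


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = _softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class _Adam:
    def __init__(self, slots, lr, beta1, beta2):
        self.slots = list(slots)
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = [np.zeros_like(getattr(o, n)) for n, o in self.slots]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in self.slots]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, owner) in enumerate(self.slots):
            g = getattr(owner, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(owner, name)
            setattr(owner, name, (p - self.lr * mhat / (np.sqrt(vhat) + 1e-8)).astype(np.float32))


class _MomentumSGD:
    def __init__(self, slots, lr, momentum):
        self.slots = list(slots)
        self.lr, self.mom = lr, momentum
        self.v = [np.zeros_like(getattr(o, n)) for n, o in self.slots]

    def step(self):
        for i, (name, owner) in enumerate(self.slots):
            g = getattr(owner, "d" + name)
            self.v[i] = self.mom * self.v[i] - self.lr * g
            p = getattr(owner, name)
            setattr(owner, name, (p + self.v[i]).astype(np.float32))


def train_cnn(
    images: np.ndarray,
    labels: np.ndarray,
    spec: CNNSpec,
    train: TrainConfig,
) -> tuple[SmallCNN, dict[str, list[float]]]:
    """Train the convnet with cross-entropy; returns (model, loss traces).

    ``images`` must be preprocessed float arrays (N, H, W, 3).  A
    stratified ``val_fraction`` split is held out and scored in eval
    mode after each epoch; the history dict carries per-epoch
    ``train_loss`` and ``val_loss``.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two classes")

    rng = np.random.default_rng(train.seed)
    model = SmallCNN(spec, input_channels=images.shape[-1], seed=train.seed)

    # stratified holdout
    val_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_val = max(1, int(round(train.val_fraction * len(idx)))) if train.val_fraction > 0 else 0
        val_idx.extend(rng.permutation(idx)[:n_val].tolist())
    val_mask = np.zeros(len(labels), dtype=bool)
    val_mask[val_idx] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)

    slots = list(model._param_slots())
    if train.optimizer == "adam":
        opt = _Adam(slots, train.learning_rate, train.beta1, train.beta2)
    else:
        opt = _MomentumSGD(slots, train.learning_rate, train.momentum)

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for _epoch in range(train.epochs):
        order = rng.permutation(tr_idx)
        loss_sum = 0.0
        for i in range(0, len(order), train.batch_size):
            batch = order[i : i + train.batch_size]
            logits = model.logits(images[batch], train=True)
            loss, dlogits = _cross_entropy(logits, labels[batch])
            model._backward(dlogits)
            opt.step()
            loss_sum += loss * len(batch)
        history["train_loss"].append(loss_sum / len(order))
        if len(va_idx):
            vloss, _ = _cross_entropy(model.logits(images[va_idx], train=False), labels[va_idx])
            history["val_loss"].append(vloss)
    return model, history


def extract_features(model: SmallCNN, images: np.ndarray) -> np.ndarray:
    """Penultimate-layer feature matrix (n_images x feature_dim), rows in
    input order; deterministic given fixed weights."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError("expected a batch of preprocessed images (N, H, W, C)")
    return model.features(images)
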