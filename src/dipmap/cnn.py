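"""Isolated CNN family for activation-image classification.

The classifier is a compact convolutional network assembled from a fixed
layer vocabulary — input, convolution, ReLU, cross-channel (local
response) normalisation, max-pooling, dropout, fully connected, softmax
and classification-output — at one of four depths (16, 19, 22 or 25
declared layers).  A depth-D network has ``k = (D - 7) / 3`` convolution
blocks: the first two are ``conv → relu → norm → pool`` and the rest
``conv → relu → pool``, followed by dropout, a two-way fully connected
layer, softmax and the output layer.  Filter counts double per block from
a configurable base, capped at a maximum.

Everything — forward pass, backpropagation and stochastic gradient
descent with momentum on the cross-entropy loss — is implemented here on
top of numpy, so training is deterministic for a fixed seed on a single
thread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .tmap import ImageDataset

__all__ = [
    "SUPPORTED_DEPTHS",
    "LayerSpec",
    "CnnArchitecture",
    "TrainConfig",
    "TrainHistory",
    "CnnClassifier",
    "build_architecture",
    "split_dataset",
    "train",
    "predict",
]

SUPPORTED_DEPTHS = (16, 19, 22, 25)


# ---------------------------------------------------------------------------
# architecture description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One declared layer: a type from the fixed vocabulary plus options."""

    type: str
    options: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CnnArchitecture:
    """Ordered layer schedule of one depth variant."""

    depth: int
    layers: tuple[LayerSpec, ...]
    n_classes: int = 2
    input_size: int = 227

    def __post_init__(self) -> None:
        if len(self.layers) != self.depth:
            raise ValueError("layer list length must equal the declared depth")
        if self.layers[0].type != "input" or self.layers[-1].type != "classification-output":
            raise ValueError("architecture must start with input and end with classification-output")

    @property
    def n_conv_blocks(self) -> int:
        return sum(1 for l in self.layers if l.type == "convolution")

    def shape_trace(self) -> list[tuple[int, int, int]]:
        """(H, W, C) after every layer; raises if the map collapses below 1 px."""
        h = w = self.input_size
        c = 3
        trace = []
        for spec in self.layers:
            if spec.type == "convolution":
                k = spec.options["kernel"]
                s = spec.options["stride"]
                p = spec.options["pad"]
                h = (h + 2 * p - k) // s + 1
                w = (w + 2 * p - k) // s + 1
                c = spec.options["filters"]
            elif spec.type == "maxpool":
                k = spec.options["kernel"]
                s = spec.options["stride"]
                h = (h - k) // s + 1
                w = (w - k) // s + 1
            elif spec.type == "fully-connected":
                h = w = 1
                c = spec.options["units"]
            if h < 1 or w < 1:
                raise ValueError(
                    f"spatial map collapses below 1 px at layer {spec.type} "
                    f"for input size {self.input_size}"
                )
            trace.append((h, w, c))
        return trace

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "n_classes": self.n_classes,
            "input_size": self.input_size,
            "layers": [asdict(l) for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CnnArchitecture":
        return cls(
            depth=d["depth"], n_classes=d["n_classes"], input_size=d["input_size"],
            layers=tuple(LayerSpec(l["type"], l["options"]) for l in d["layers"]),
        )


def build_architecture(
    depth: int,
    n_classes: int = 2,
    input_size: int = 227,
    base_filters: int = 8,
    max_filters: int = 128,
    first_kernel: int = 7,
    first_stride: int = 2,
    kernel: int = 3,
    pool: int = 2,
    lrn_window: int = 5,
    dropout: float = 0.5,
) -> CnnArchitecture:
    """Layer schedule for one of the four supported depths.

    ``depth`` counts every declared layer, including input, softmax and
    the classification output, so the supported depths correspond to 3,
    4, 5 and 6 convolution blocks.
    """
    if depth not in SUPPORTED_DEPTHS:
        raise ValueError(f"unsupported depth {depth}; supported depths are {SUPPORTED_DEPTHS}")
    k_blocks = (depth - 7) // 3
    layers: list[LayerSpec] = [LayerSpec("input", {"size": input_size, "channels": 3})]
    for b in range(k_blocks):
        filters = min(base_filters * 2**b, max_filters)
        if b == 0:
            conv = {"kernel": first_kernel, "stride": first_stride, "pad": 0, "filters": filters}
        else:
            conv = {"kernel": kernel, "stride": 1, "pad": kernel // 2, "filters": filters}
        layers.append(LayerSpec("convolution", conv))
        layers.append(LayerSpec("relu", {}))
        if b < 2:
            layers.append(LayerSpec("cross-channel-normalization", {"window": lrn_window}))
        layers.append(LayerSpec("maxpool", {"kernel": pool, "stride": pool}))
    layers.append(LayerSpec("dropout", {"rate": dropout}))
    layers.append(LayerSpec("fully-connected", {"units": n_classes}))
    layers.append(LayerSpec("softmax", {}))
    layers.append(LayerSpec("classification-output", {}))
    arch = CnnArchitecture(
        depth=depth, layers=tuple(layers), n_classes=n_classes, input_size=input_size
    )
    arch.shape_trace()  # fail fast if the input is too small for this depth
    return arch


# ---------------------------------------------------------------------------
# executable layers (float32, NCHW)
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv(_Layer):
    def __init__(self, in_ch, out_ch, kernel, stride, pad, rng):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]), "b": np.zeros_like(self.params["b"])}
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def _im2col(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = x.shape
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        return np.ascontiguousarray(cols), (n, c, h, w, oh, ow)

    def forward(self, x, train, rng):
        self._x_shape = x.shape
        cols, (n, c, h, w, oh, ow) = self._im2col(x)
        self._cols, self._dims = cols, (n, c, h, w, oh, ow)
        wmat = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ wmat.T + self.params["b"]
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w, oh, ow = self._dims
        out_ch = self.params["W"].shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, out_ch)
        self.grads["W"][...] = (dmat.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"][...] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"].reshape(out_ch, -1)
        dcols = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h, w), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[:, :, ki, kj]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        # crop to the true input in case stride left a remainder
        nh, nw = self._x_shape[2], self._x_shape[3]
        return dxp[:, :, :nh, :nw]


class _ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _window_sum(a: np.ndarray, n: int) -> np.ndarray:
    """Sliding sum of length-n symmetric windows along axis 1 (channels)."""
    half = n // 2
    c = a.shape[1]
    cs = np.cumsum(np.concatenate([np.zeros_like(a[:, :1]), a], axis=1), axis=1)
    lo = np.maximum(np.arange(c) - half, 0)
    hi = np.minimum(np.arange(c) + half + 1, c)
    return cs[:, hi] - cs[:, lo]


class _LRN(_Layer):
    """Cross-channel local response normalisation (window 5 by default)."""

    def __init__(self, window=5, alpha=1e-4, beta=0.75, k=2.0):
        super().__init__()
        self.window, self.alpha, self.beta, self.k = window, alpha, beta, k

    def forward(self, x, train, rng):
        sq = _window_sum(x.astype(np.float32) ** 2, self.window)
        d = self.k + (self.alpha / self.window) * sq
        self._x, self._d = x, d
        self._dpow = d ** (-self.beta)
        return (x * self._dpow).astype(np.float32)

    def backward(self, dout):
        x, d = self._x, self._d
        t = dout * x * d ** (-self.beta - 1.0)
        u = _window_sum(t, self.window)
        coef = 2.0 * self.alpha * self.beta / self.window
        return (dout * self._dpow - coef * x * u).astype(np.float32)


class _MaxPool(_Layer):
    def __init__(self, kernel=2, stride=2):
        super().__init__()
        if kernel != stride:
            raise ValueError("only non-overlapping pooling is supported")
        self.k = kernel

    def forward(self, x, train, rng):
        k = self.k
        n, c, h, w = x.shape
        oh, ow = h // k, w // k
        self._in_shape = x.shape
        xc = x[:, :, : oh * k, : ow * k]
        win = xc.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
        self._arg = win.argmax(axis=-1)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        k = self.k
        n, c, h, w = self._in_shape
        oh, ow = h // k, w // k
        dwin = np.zeros((n, c, oh, ow, k * k), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : oh * k, : ow * k] = (
            dwin.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh * k, ow * k)
        )
        return dx


class _Dropout(_Layer):
    def __init__(self, rate=0.5):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Dense(_Layer):
    def __init__(self, in_dim, out_dim, rng):
        super().__init__()
        w = rng.normal(0.0, math.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_dim, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]), "b": np.zeros_like(self.params["b"])}

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        self._xf = x.reshape(x.shape[0], -1)
        return self._xf @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._xf.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return (dout @ self.params["W"].T).reshape(self._in_shape)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe: SGD with momentum on cross-entropy."""

    epochs: int = 100
    learn_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    split: float = 0.7
    seed: int = 0
    solver: str = "sgdm"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.solver.lower() != "sgdm":
            raise ValueError("only the SGDM solver is implemented")


@dataclass
class TrainHistory:
    """Per-epoch curves recorded during fitting."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        d = {"epoch": np.arange(1, len(self.loss) + 1), "loss": self.loss, "accuracy": self.accuracy}
        if self.val_accuracy:
            d["val_accuracy"] = self.val_accuracy
        return pd.DataFrame(d)


class CnnClassifier:
    """Executable network for one architecture; fit/predict interface.

    Weights are drawn once at construction from the given seed, so two
    classifiers built with the same architecture and seed are identical.
    """

    def __init__(self, arch: CnnArchitecture, seed: int = 0):
        self.arch = arch
        self.seed = seed
        self.classes_: list[str] | None = None
        self.history: TrainHistory | None = None
        # zero-centre normalisation of the input layer; set from the
        # training data at fit time (per-channel means)
        self.input_mean_ = np.zeros(3, dtype=np.float32)
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(rng.integers(2**31))
        trace = arch.shape_trace()
        self.layers: list[_Layer] = []
        h = w = arch.input_size
        c = 3
        for spec, (nh, nw, nc) in zip(arch.layers, trace):
            t = spec.type
            if t == "convolution":
                o = spec.options
                self.layers.append(_Conv(c, o["filters"], o["kernel"], o["stride"], o["pad"], rng))
            elif t == "relu":
                self.layers.append(_ReLU())
            elif t == "cross-channel-normalization":
                self.layers.append(_LRN(window=spec.options["window"]))
            elif t == "maxpool":
                self.layers.append(_MaxPool(spec.options["kernel"], spec.options["stride"]))
            elif t == "dropout":
                self.layers.append(_Dropout(spec.options["rate"]))
            elif t == "fully-connected":
                self.layers.append(_Dense(h * w * c, spec.options["units"], rng))
            # input / softmax / classification-output carry no computation here
            h, w, c = nh, nw, nc
        self._velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in self.layers
        ]

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _to_nchw(images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        return np.ascontiguousarray(images.transpose(0, 3, 1, 2))

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self._rng)
        return x

    def _backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def _encode(self, labels: np.ndarray) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lookup[l] for l in labels], dtype=np.int64)

    # -- public api ---------------------------------------------------------

    def fit(
        self,
        train_set: ImageDataset,
        config: TrainConfig | None = None,
        val_set: ImageDataset | None = None,
    ) -> TrainHistory:
        """Minibatch SGDM on cross-entropy; records per-epoch curves."""
        config = config or TrainConfig()
        if len(train_set) == 0:
            raise ValueError("training set is empty")
        self.classes_ = sorted(set(train_set.labels.tolist()))
        if len(self.classes_) != self.arch.n_classes:
            raise ValueError(
                f"architecture expects {self.arch.n_classes} classes, "
                f"training labels have {len(self.classes_)}"
            )
        x_all = self._to_nchw(train_set.images)
        self.input_mean_ = x_all.mean(axis=(0, 2, 3)).astype(np.float32)
        x_all = x_all - self.input_mean_[None, :, None, None]
        y_all = self._encode(train_set.labels)
        rng = np.random.default_rng(config.seed)
        self.history = TrainHistory()
        n = len(y_all)
        for _epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_hits = 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                xb, yb = x_all[idx], y_all[idx]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {_epoch + 1}; "
                        "reduce the learning rate or inspect the inputs"
                    )
                epoch_loss += loss * len(yb)
                epoch_hits += int((probs.argmax(axis=1) == yb).sum())
                dlogits = probs
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self._backward(dlogits.astype(np.float32))
                for layer, vel in zip(self.layers, self._velocity):
                    for key, param in layer.params.items():
                        v = vel[key]
                        v *= config.momentum
                        v -= config.learn_rate * layer.grads[key]
                        param += v
            self.history.loss.append(float(epoch_loss / n))
            self.history.accuracy.append(float(epoch_hits / n))
            if val_set is not None and len(val_set):
                preds = self.predict(val_set.images)
                self.history.val_accuracy.append(float(np.mean(preds == val_set.labels)))
        return self.history

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class scores, rows summing to 1."""
        x = self._to_nchw(images)
        if x.shape[2] != self.arch.input_size or x.shape[3] != self.arch.input_size:
            raise ValueError(
                f"images must be {self.arch.input_size}px square, got {x.shape[2]}x{x.shape[3]}"
            )
        x = x - self.input_mean_[None, :, None, None]
        out = []
        for start in range(0, len(x), batch_size):
            logits = self._forward(x[start : start + batch_size], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predicted class labels (argmax of the softmax scores)."""
        classes = self.classes_ or [str(i) for i in range(self.arch.n_classes)]
        scores = self.predict_proba(images)
        return np.array([classes[i] for i in scores.argmax(axis=1)])

    def score(self, dataset: ImageDataset) -> float:
        return float(np.mean(self.predict(dataset.images) == dataset.labels))


# ---------------------------------------------------------------------------
# functional wrappers and the data split
# ---------------------------------------------------------------------------

def split_dataset(
    ds: ImageDataset,
    ratio: float = 0.7,
    seed: int = 0,
    group_by_subject: bool = False,
) -> tuple[ImageDataset, ImageDataset]:
    """Stratified random train/validation split.

    Per class, ``round(ratio * n_class)`` images go to training (528
    images at 70% give 370 train / 158 validation).  Trials are pooled
    before splitting, so images of one subject can appear on both sides;
    ``group_by_subject=True`` switches to a leakage-safe split that keeps
    every subject's images on one side only.
    """
    labels = ds.labels
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2 and ratio < 1.0:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    if group_by_subject:
        subjects = np.asarray(ds.meta["subject"])
        uniq = np.unique(subjects)
        perm = rng.permutation(uniq)
        n_train_subj = int(round(ratio * len(uniq)))
        train_subj = set(perm[:n_train_subj].tolist())
        for i, s in enumerate(subjects):
            (train_idx if s in train_subj else val_idx).append(i)
    else:
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            if len(idx) < 2 and ratio < 1.0:
                raise ValueError(f"class {cls!r} has fewer than 2 images")
            perm = rng.permutation(idx)
            n_train = int(round(ratio * len(idx)))
            train_idx.extend(perm[:n_train].tolist())
            val_idx.extend(perm[n_train:].tolist())
    train_arr = np.sort(np.asarray(train_idx, dtype=np.int64))
    val_arr = np.sort(np.asarray(val_idx, dtype=np.int64))
    return ds.subset(train_arr), ds.subset(val_arr)


def train(
    arch: CnnArchitecture,
    train_set: ImageDataset,
    config: TrainConfig | None = None,
    val_set: ImageDataset | None = None,
) -> tuple[CnnClassifier, TrainHistory]:
    """Build a classifier for ``arch`` and fit it; returns (model, curves)."""
    config = config or TrainConfig()
    model = CnnClassifier(arch, seed=config.seed)
    if config.epochs == 0:
        model.classes_ = sorted(set(train_set.labels.tolist()))
        model.history = TrainHistory()
        return model, model.history
    history = model.fit(train_set, config, val_set=val_set)
    return model, history


def predict(model: CnnClassifier, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and softmax scores for a batch of images."""
    scores = model.predict_proba(images)
    classes = model.classes_ or [str(i) for i in range(model.arch.n_classes)]
    labels = np.array([classes[i] for i in scores.argmax(axis=1)])
    return labels, scores
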