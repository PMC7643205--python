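"""In-house deep convolutional network for per-target activity classification.

The architecture is five convolution + max-pooling blocks followed by one
fully connected layer and a two-unit softmax output.  Convolutions use no
padding and stride 1, so a layer fed an N x N input with an f x f filter
produces an (N - f + 1) x (N - f + 1) activation map; ReLU follows each
convolution and the fully connected layer; dropout regularizes the fully
connected layer during training only.  Training minimizes the mini-batch
binary cross-entropy with the Adam optimizer, and every stochastic choice
(weight init, shuffling, dropout masks) is driven by one seed, so runs are
exactly reproducible.

The implementation is pure NumPy: convolutions are evaluated as a single
matrix product over im2col patch matrices, and their input gradients are
accumulated with one GEMM per filter offset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .evaluation import mcc_from_labels

__all__ = [
    "LayerSpec",
    "HyperParams",
    "TrainedModel",
    "conv_output_size",
    "build_network",
    "train",
    "predict_proba",
    "grid_search",
    "save_model",
    "load_model",
]


def conv_output_size(n: int, f: int, stride: int = 1, pool: bool = False) -> int:
    """Side length of a layer output: (n - f)/stride + 1, floored for pooling.

    With stride 1 and no padding this is the n - f + 1 rule for convolutions;
    pooling windows that do not fit are dropped (floor semantics).
    """
    if f > n:
        raise ValueError(f"filter size {f} exceeds input side {n}")
    return (n - f) // stride + 1


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one network stage."""

    kind: str  # conv | maxpool | flatten | fullyconnected | output
    input_side: int = 0
    in_channels: int = 0
    filter_size: int = 0
    filter_count: int = 0
    stride: int = 1
    activation: str | None = None  # relu | softmax | None

    @property
    def output_side(self) -> int:
        if self.kind in ("conv", "maxpool"):
            return conv_output_size(
                self.input_side, self.filter_size, self.stride, pool=self.kind == "maxpool"
            )
        return 0

    @property
    def n_parameters(self) -> int:
        if self.kind == "conv":
            return self.filter_count * (self.in_channels * self.filter_size**2 + 1)
        if self.kind in ("fullyconnected", "output"):
            # in_channels doubles as input width for dense stages
            return self.filter_count * (self.in_channels + 1)
        return 0


@dataclass(frozen=True)
class HyperParams:
    """Tunable training configuration for one model."""

    learning_rate: float = 1e-3
    dropout_keep: float = 0.5
    filter_counts: tuple[int, ...] = (8, 16, 32, 32, 32)
    filter_size: int = 5
    fc_width: int = 128
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dropout_keep <= 1:
            raise ValueError("dropout keep probability must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if len(self.filter_counts) != 5:
            raise ValueError("exactly five convolution blocks are supported")


#: default hyper-parameter grid searched per target when none is supplied
DEFAULT_GRID: tuple[HyperParams, ...] = tuple(
    HyperParams(learning_rate=lr, dropout_keep=dk, fc_width=fw)
    for lr in (1e-3, 1e-4)
    for dk in (0.5, 0.8)
    for fw in (128, 256)
)


@dataclass
class TrainedModel:
    """Architecture, parameters and training manifest of one classifier."""

    layers: list[LayerSpec]
    params: dict[str, np.ndarray]
    hyperparams: HyperParams
    image_size: int
    manifest: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return sum(spec.n_parameters for spec in self.layers)


def _normalize_labels(labels: Sequence) -> np.ndarray:
    """Map labels to {0, 1} with 1 = active; reject anything else."""
    mapping = {"active": 1, "inactive": 0, 1: 1, 0: 0, True: 1, False: 0}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        key = lab.item() if isinstance(lab, np.generic) else lab
        if key not in mapping:
            raise ValueError(f"label {lab!r} is not in {{active, inactive}}")
        out[i] = mapping[key]
    return out


def build_network(image_size: int, hyperparams: HyperParams | None = None) -> TrainedModel:
    """Construct the 13-stage network (untrained) for a given image size.

    Layer list: five (conv -> ReLU -> maxpool) blocks, flatten, a fully
    connected ReLU layer with dropout, and a two-unit softmax output.  Filter
    sizes are clamped to the current side length so the five-block stack
    remains feasible down to small inputs.
    """
    hp = hyperparams or HyperParams()
    if image_size < 32:
        raise ValueError(f"architecture infeasible for image size {image_size}")
    layers: list[LayerSpec] = []
    side, channels = image_size, 1
    for nfilt in hp.filter_counts:
        f = min(hp.filter_size, side)
        conv = LayerSpec("conv", side, channels, f, nfilt, 1, "relu")
        side, channels = conv.output_side, nfilt
        layers.append(conv)
        p = min(2, side)
        pool = LayerSpec("maxpool", side, channels, p, 0, p)
        side = pool.output_side
        layers.append(pool)
    flat = side * side * channels
    layers.append(LayerSpec("flatten", side, channels))
    layers.append(LayerSpec("fullyconnected", 0, flat, 0, hp.fc_width, 1, "relu"))
    layers.append(LayerSpec("output", 0, hp.fc_width, 0, 2, 1, "softmax"))

    rng = np.random.default_rng(hp.seed)
    params: dict[str, np.ndarray] = {}
    for i, spec in enumerate(layers):
        if spec.kind == "conv":
            fan_in = spec.in_channels * spec.filter_size**2
            params[f"W{i}"] = (
                rng.standard_normal((spec.filter_count, spec.in_channels, spec.filter_size, spec.filter_size))
                * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            params[f"b{i}"] = np.zeros(spec.filter_count, dtype=np.float32)
        elif spec.kind in ("fullyconnected", "output"):
            fan_in = spec.in_channels
            params[f"W{i}"] = (
                rng.standard_normal((fan_in, spec.filter_count)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            params[f"b{i}"] = np.zeros(spec.filter_count, dtype=np.float32)
    return TrainedModel(layers, params, hp, image_size, manifest={"seed": hp.seed, "trained_epochs": 0})


# ---------------------------------------------------------------------------
# forward / backward engine


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    nfilt, cin, f, _ = W.shape
    B = x.shape[0]
    windows = sliding_window_view(x, (f, f), axis=(2, 3))  # B, C, Ho, Wo, f, f
    ho, wo = windows.shape[2], windows.shape[3]
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * ho * wo, cin * f * f
    )
    out = cols @ W.reshape(nfilt, -1).T + b
    out = out.reshape(B, ho, wo, nfilt).transpose(0, 3, 1, 2)
    return out, cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, x_shape, W: np.ndarray):
    nfilt, cin, f, _ = W.shape
    B, _, H, Wd = x_shape
    ho, wo = dout.shape[2], dout.shape[3]
    dmat = dout.transpose(0, 2, 3, 1).reshape(-1, nfilt)  # B*ho*wo, nfilt
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0)
    dx = np.zeros((B, cin, H, Wd), dtype=np.float32)
    dgrid = dmat.reshape(B, ho, wo, nfilt)
    for a in range(f):
        for c in range(f):
            # one GEMM per filter offset: (B*ho*wo, nfilt) x (nfilt, cin)
            contrib = dgrid @ W[:, :, a, c]
            dx[:, :, a : a + ho, c : c + wo] += contrib.transpose(0, 3, 1, 2)
    return dx, dW, db


def _pool_forward(x: np.ndarray, p: int):
    if p == 1:
        return x, None
    B, C, H, W = x.shape
    ho, wo = H // p, W // p
    blocks = x[:, :, : ho * p, : wo * p].reshape(B, C, ho, p, wo, p)
    out = blocks.max(axis=(3, 5))
    mask = blocks == out[:, :, :, None, :, None]
    ties = mask.sum(axis=(3, 5), keepdims=True)
    return out, (mask, ties, x.shape, p)


def _pool_backward(dout: np.ndarray, cache):
    if cache is None:
        return dout
    mask, ties, x_shape, p = cache
    B, C, H, W = x_shape
    ho, wo = H // p, W // p
    dx = np.zeros(x_shape, dtype=np.float32)
    grad = mask * (dout[:, :, :, None, :, None] / ties)
    dx[:, :, : ho * p, : wo * p] = grad.reshape(B, C, ho * p, wo * p)
    return dx


def _forward(model: TrainedModel, x: np.ndarray, train_rng: np.random.Generator | None):
    """Full forward pass; returns class probabilities and per-stage caches."""
    caches = []
    h = x
    for i, spec in enumerate(model.layers):
        if spec.kind == "conv":
            out, cols = _conv_forward(h, model.params[f"W{i}"], model.params[f"b{i}"])
            relu_mask = out > 0
            out *= relu_mask
            caches.append(("conv", cols, h.shape, relu_mask))
            h = out
        elif spec.kind == "maxpool":
            h, cache = _pool_forward(h, spec.filter_size)
            caches.append(("pool", cache))
        elif spec.kind == "flatten":
            caches.append(("flatten", h.shape))
            h = h.reshape(h.shape[0], -1)
        elif spec.kind == "fullyconnected":
            z = h @ model.params[f"W{i}"] + model.params[f"b{i}"]
            relu_mask = z > 0
            z *= relu_mask
            if train_rng is not None and model.hyperparams.dropout_keep < 1.0:
                keep = model.hyperparams.dropout_keep
                drop = (train_rng.random(z.shape) < keep).astype(np.float32) / keep
                z *= drop
            else:
                drop = None
            caches.append(("fc", h, relu_mask, drop))
            h = z
        elif spec.kind == "output":
            logits = h @ model.params[f"W{i}"] + model.params[f"b{i}"]
            logits -= logits.max(axis=1, keepdims=True)
            ez = np.exp(logits)
            probs = ez / ez.sum(axis=1, keepdims=True)
            caches.append(("out", h))
            h = probs
    return h, caches


def predict_proba(model: TrainedModel, images: Sequence, batch_size: int = 64) -> np.ndarray:
    """Active-class probability for each compound image; dropout disabled."""
    x = _stack_images(model, images)
    if x.shape[0] == 0:
        return np.zeros(0)
    out = []
    for start in range(0, x.shape[0], batch_size):
        probs, _ = _forward(model, x[start : start + batch_size], train_rng=None)
        out.append(probs[:, 1])
    return np.concatenate(out).astype(np.float64)


def _stack_images(model: TrainedModel, images: Sequence) -> np.ndarray:
    arrs = []
    for img in images:
        pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img)
        if pixels.shape != (model.image_size, model.image_size):
            raise ValueError(
                f"image size {pixels.shape} does not match model size {model.image_size}"
            )
        arrs.append(pixels.astype(np.float32))
    if not arrs:
        return np.zeros((0, 1, model.image_size, model.image_size), dtype=np.float32)
    return np.stack(arrs)[:, None, :, :]


def train(
    model: TrainedModel,
    images: Sequence,
    labels: Sequence,
    hyperparams: HyperParams | None = None,
) -> TrainedModel:
    """Fit by mini-batch Adam on the binary cross-entropy; fully seeded.

    Returns a new :class:`TrainedModel`; the input model is not modified.
    The per-epoch loss trace is stored in the training manifest.
    """
    hp = hyperparams or model.hyperparams
    y = _normalize_labels(labels)
    x = _stack_images(model, images)
    if x.shape[0] != y.shape[0]:
        raise ValueError("images and labels differ in length")

    params = {k: v.copy() for k, v in model.params.items()}
    fitted = TrainedModel(model.layers, params, hp, model.image_size, dict(model.manifest))
    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 0xC0FFEE]))

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses: list[float] = []
    n = x.shape[0]
    for _epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = x[idx], y[idx]
            probs, caches = _forward(fitted, xb, train_rng=rng)
            p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            epoch_loss += float(-np.log(p_true).sum())
            grads = _backward(fitted, caches, probs, yb)
            step += 1
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                mhat = m[key] / (1 - beta1**step)
                vhat = v[key] / (1 - beta2**step)
                params[key] -= (hp.learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(
                    np.float32
                )
        losses.append(epoch_loss / n)

    fitted.manifest.update(
        {
            "seed": hp.seed,
            "trained_epochs": hp.epochs,
            "loss_trace": losses,
            "data_hash": hashlib.sha256(x.tobytes() + y.tobytes()).hexdigest()[:16],
            "hyperparams": asdict(hp),
        }
    )
    return fitted


def _backward(model: TrainedModel, caches, probs: np.ndarray, y: np.ndarray):
    B = probs.shape[0]
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), y] = 1.0
    delta = ((probs - onehot) / B).astype(np.float32)
    grads: dict[str, np.ndarray] = {}
    for i in range(len(model.layers) - 1, -1, -1):
        spec = model.layers[i]
        cache = caches[i]
        if spec.kind == "output":
            h = cache[1]
            grads[f"W{i}"] = h.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            delta = delta @ model.params[f"W{i}"].T
        elif spec.kind == "fullyconnected":
            _, h, relu_mask, drop = cache
            if drop is not None:
                delta = delta * drop
            delta = delta * relu_mask
            grads[f"W{i}"] = h.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            delta = delta @ model.params[f"W{i}"].T
        elif spec.kind == "flatten":
            delta = delta.reshape(cache[1])
        elif spec.kind == "maxpool":
            delta = _pool_backward(delta, cache[1])
        elif spec.kind == "conv":
            _, cols, x_shape, relu_mask = cache
            delta = delta * relu_mask
            delta, dW, db = _conv_backward(delta, cols, x_shape, model.params[f"W{i}"])
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
    return grads


# ---------------------------------------------------------------------------
# hyper-parameter grid search


@dataclass
class GridSearchResult:
    best_model: TrainedModel
    best_params: HyperParams
    #: (hyperparams, validation MCC, parameter count) per grid point
    leaderboard: list[tuple[HyperParams, float, int]]
    #: index -> partition tag over the input dataset
    split: dict[int, str]


def split_dataset(
    n: int, labels: Sequence, test_fraction: float = 0.2, val_fraction: float = 0.2, seed: int = 0
) -> dict[int, str]:
    """Stratified train/validation/test tags: 80/20 outer, then 80/20 inner."""
    y = _normalize_labels(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B11]))
    tags = {}
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(len(idx) * test_fraction))
        test, rest = idx[:n_test], idx[n_test:]
        n_val = int(round(len(rest) * val_fraction))
        val, trainset = rest[:n_val], rest[n_val:]
        for i in test:
            tags[int(i)] = "test"
        for i in val:
            tags[int(i)] = "validation"
        for i in trainset:
            tags[int(i)] = "train"
    return tags


def grid_search(
    images: Sequence,
    labels: Sequence,
    grid: Sequence[HyperParams] | None = None,
    image_size: int = 200,
    seed: int = 0,
) -> GridSearchResult:
    """Train one model per grid point; select the best validation MCC.

    Ties prefer the model with fewer parameters, then the lower grid index.
    The test partition is tagged but never read here: it stays untouched for
    the final, independent evaluation.
    """
    grid = list(DEFAULT_GRID if grid is None else grid)
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    tags = split_dataset(len(images), labels, seed=seed)
    train_idx = [i for i, t in tags.items() if t == "train"]
    val_idx = [i for i, t in tags.items() if t == "validation"]
    y = _normalize_labels(labels)

    leaderboard: list[tuple[HyperParams, float, int]] = []
    best = None
    for gi, hp in enumerate(grid):
        hp_seeded = replace(hp, seed=seed + gi if hp.seed == 0 else hp.seed)
        net = build_network(image_size, hp_seeded)
        fitted = train(net, [images[i] for i in train_idx], y[train_idx], hp_seeded)
        val_scores = predict_proba(fitted, [images[i] for i in val_idx])
        val_pred = (val_scores >= 0.5).astype(int)
        val_mcc = mcc_from_labels(y[val_idx], val_pred)
        leaderboard.append((hp_seeded, val_mcc, fitted.n_parameters))
        key = (-val_mcc, fitted.n_parameters, gi)
        if best is None or key < best[0]:
            best = (key, fitted, hp_seeded)
    assert best is not None
    return GridSearchResult(best[1], best[2], leaderboard, tags)


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a single-file checkpoint (manifest JSON + parameter arrays)."""
    meta = {
        "image_size": model.image_size,
        "hyperparams": asdict(model.hyperparams),
        "manifest": model.manifest,
    }
    np.savez_compressed(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    hp = HyperParams(**{**meta["hyperparams"], "filter_counts": tuple(meta["hyperparams"]["filter_counts"])})
    model = build_network(meta["image_size"], hp)
    model.params.update({k: v.astype(np.float32) for k, v in params.items()})
    model.manifest = meta["manifest"]
    return model
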