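"""The binary convolutional network: two conv/BN/ReLU/pool blocks, then
a 60-unit and a 2-unit fully connected layer under a softmax head.

For the canonical 32 x 91 x 1 spectral-image input the stack produces the
activation shapes 28x87x50 -> 14x43x50 -> 4x33x60 -> 2x16x60 and a
1920-long flattened feature vector, for 480,082 trainable parameters in
total. :func:`propagate_shapes` reproduces this arithmetic with no learning
backend, and is also the feasibility check: a kernel larger than its input
extent raises :class:`ArchitectureError`. Narrow inputs (e.g. the 32 x 15
images of a 6-channel montage, where the second 11x11 convolution does not
fit) are supported by clamping kernels and pool windows per dimension to the
available extent when ``adapt_narrow_input=True``; the adaptation is
reported through ``warnings``.

Training follows the published recipe: SGD with momentum, learning rate
0.01, 50 epochs, a stratified 70/30 train/validation split, and a 25%
input dropout whose default "exact-count" semantics zero exactly
floor(0.25 * N) pixels of each image.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn

__all__ = ["ArchitectureError", "BinaryCNN", "CNNSpec", "LayerInfo", "propagate_shapes", "stratified_split"]


class ArchitectureError(ValueError):
    """A layer's kernel or pool window exceeds its input extent."""


@dataclasses.dataclass(frozen=True)
class CNNSpec:
    """Architecture description; defaults are the published layer stack."""

    input_shape: tuple[int, int, int] = (32, 91, 1)
    dropout_rate: float = 0.25
    conv1_filters: int = 50
    conv1_kernel: tuple[int, int] = (5, 5)
    conv2_filters: int = 60
    conv2_kernel: tuple[int, int] = (11, 11)
    pool: tuple[int, int] = (2, 2)
    fc1_units: int = 60
    n_classes: int = 2
    adapt_narrow_input: bool = False


@dataclasses.dataclass(frozen=True)
class LayerInfo:
    name: str
    kind: str
    output_shape: tuple[int, ...]
    learnables: int


def _clamp(kernel: tuple[int, int], extent: tuple[int, int], name: str, adapt: bool) -> tuple[int, int]:
    kh, kw = kernel
    h, w = extent
    if kh <= h and kw <= w:
        return kernel
    if not adapt:
        raise ArchitectureError(
            f"architecture infeasible at {name}: kernel {kh}x{kw} exceeds input extent {h}x{w} "
            "(set adapt_narrow_input=True to clamp kernels to the available extent)"
        )
    clamped = (min(kh, h), min(kw, w))
    warnings.warn(
        f"{name}: kernel {kh}x{kw} clamped to {clamped[0]}x{clamped[1]} for input extent {h}x{w}",
        stacklevel=3,
    )
    return clamped


def propagate_shapes(spec: CNNSpec | None = None) -> list[LayerInfo]:
    """Pure shape/parameter arithmetic through the layer stack.

    Conv learnables = kh*kw*c_in*c_out + c_out; batch-norm = 2*channels;
    fully connected = in*out + out.
    """
    spec = spec or CNNSpec()
    h, w, c = spec.input_shape
    rows = [
        LayerInfo("input", "Image input", (h, w, c), 0),
        LayerInfo("dropout", "Dropout", (h, w, c), 0),
    ]

    def conv(name, extent, ch_in, ch_out, kernel):
        kh, kw = _clamp(kernel, extent, name, spec.adapt_narrow_input)
        oh, ow = extent[0] - kh + 1, extent[1] - kw + 1
        return (oh, ow), kh * kw * ch_in * ch_out + ch_out, (kh, kw)

    def pool(name, extent):
        ph, pw = _clamp(spec.pool, extent, name, spec.adapt_narrow_input)
        oh, ow = extent[0] // ph, extent[1] // pw
        if oh < 1 or ow < 1:
            raise ArchitectureError(f"architecture infeasible at {name}: empty output")
        return (oh, ow), (ph, pw)

    (h, w), n, _ = conv("conv_1", (h, w), c, spec.conv1_filters, spec.conv1_kernel)
    rows.append(LayerInfo("conv_1", "Convolution", (h, w, spec.conv1_filters), n))
    rows.append(LayerInfo("BN_1", "BatchNormalization", (h, w, spec.conv1_filters), 2 * spec.conv1_filters))
    rows.append(LayerInfo("relu_1", "ReLU", (h, w, spec.conv1_filters), 0))
    (h, w), _ = pool("pool_1", (h, w))
    rows.append(LayerInfo("pool_1", "Max Pooling", (h, w, spec.conv1_filters), 0))

    (h, w), n, _ = conv("conv_2", (h, w), spec.conv1_filters, spec.conv2_filters, spec.conv2_kernel)
    rows.append(LayerInfo("conv_2", "Convolution", (h, w, spec.conv2_filters), n))
    rows.append(LayerInfo("BN_2", "BatchNormalization", (h, w, spec.conv2_filters), 2 * spec.conv2_filters))
    rows.append(LayerInfo("relu_2", "ReLU", (h, w, spec.conv2_filters), 0))
    (h, w), _ = pool("pool_2", (h, w))
    rows.append(LayerInfo("pool_2", "Max Pooling", (h, w, spec.conv2_filters), 0))
    rows.append(LayerInfo("BN_3", "BatchNormalization", (h, w, spec.conv2_filters), 2 * spec.conv2_filters))

    flat = h * w * spec.conv2_filters
    rows.append(LayerInfo("fc1", "FullyConnected", (spec.fc1_units,), flat * spec.fc1_units + spec.fc1_units))
    rows.append(
        LayerInfo("fc2", "FullyConnected", (spec.n_classes,), spec.fc1_units * spec.n_classes + spec.n_classes)
    )
    rows.append(LayerInfo("softmax", "Softmax", (spec.n_classes,), 0))
    rows.append(LayerInfo("output", "ClassificationOutput", (spec.n_classes,), 0))
    return rows


def total_learnables(spec: CNNSpec | None = None) -> int:
    return sum(r.learnables for r in propagate_shapes(spec))


def _build_network(spec: CNNSpec, dropout_mode: str, rng: np.random.Generator) -> tuple[_nn.Network, list[str]]:
    info = propagate_shapes(spec)
    by_name = {r.name: r for r in info}
    conv1_k = _clamp(spec.conv1_kernel, spec.input_shape[:2], "conv_1", spec.adapt_narrow_input)
    c1_out = by_name["conv_1"].output_shape[:2]
    pool1_k = _clamp(spec.pool, c1_out, "pool_1", spec.adapt_narrow_input)
    p1_out = by_name["pool_1"].output_shape[:2]
    conv2_k = _clamp(spec.conv2_kernel, p1_out, "conv_2", spec.adapt_narrow_input)
    c2_out = by_name["conv_2"].output_shape[:2]
    pool2_k = _clamp(spec.pool, c2_out, "pool_2", spec.adapt_narrow_input)
    flat = int(np.prod(by_name["BN_3"].output_shape))

    layers: list[_nn.Layer] = [
        _nn.Dropout(spec.dropout_rate, rng, mode=dropout_mode),
        _nn.Conv2D(spec.input_shape[2], spec.conv1_filters, conv1_k, rng, input_grad=False),
        _nn.BatchNorm(spec.conv1_filters),
        _nn.ReLU(),
        _nn.MaxPool2D(pool1_k),
        _nn.Conv2D(spec.conv1_filters, spec.conv2_filters, conv2_k, rng),
        _nn.BatchNorm(spec.conv2_filters),
        _nn.ReLU(),
        _nn.MaxPool2D(pool2_k),
        _nn.BatchNorm(spec.conv2_filters),
        _nn.Flatten(),
        _nn.Dense(flat, spec.fc1_units, rng),
        _nn.Dense(spec.fc1_units, spec.n_classes, rng),
    ]
    names = [
        "dropout", "conv_1", "BN_1", "relu_1", "pool_1",
        "conv_2", "BN_2", "relu_2", "pool_2", "BN_3",
        "flatten", "fc1", "fc2",
    ]
    for layer, name in zip(layers, names):
        layer.name = name
    return _nn.Network(layers), names


def stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split with floor-based train sizes."""
    y = np.asarray(y)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = int(train_fraction * len(idx))
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


class BinaryCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style binary classifier around the conv stack.

    Parameters mirror the published training recipe; ``train_fraction < 1``
    makes ``fit`` hold out a stratified validation share whose per-epoch
    accuracy is recorded in ``history_``. Set ``train_fraction=1.0`` when an
    outer protocol manages the split.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int] | None = None,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        epochs: int = 50,
        batch_size: int = 128,
        train_fraction: float = 0.70,
        dropout_rate: float = 0.25,
        dropout_mode: str = "exact",
        adapt_narrow_input: bool = False,
        random_state: int = 0,
    ) -> None:
        self.input_shape = input_shape
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.train_fraction = train_fraction
        self.dropout_rate = dropout_rate
        self.dropout_mode = dropout_mode
        self.adapt_narrow_input = adapt_narrow_input
        self.random_state = random_state

    def _as_tensor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4:
            raise ValueError(f"X must be (n, height, width[, 1]), got shape {X.shape}")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinaryCNN":
        X = self._as_tensor(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"BinaryCNN needs exactly 2 classes, got {list(self.classes_)}")
        targets = np.searchsorted(self.classes_, y)

        shape = self.input_shape or X.shape[1:]
        if tuple(X.shape[1:]) != tuple(shape):
            raise ValueError(f"images of shape {X.shape[1:]} do not match input_shape {shape}")
        self.spec_ = CNNSpec(
            input_shape=tuple(shape),
            dropout_rate=self.dropout_rate,
            adapt_narrow_input=self.adapt_narrow_input,
        )

        ss = np.random.SeedSequence(self.random_state)
        rng_init, rng_split, rng_shuffle = (np.random.default_rng(s) for s in ss.spawn(3))
        self.network_, self.layer_names_ = _build_network(self.spec_, self.dropout_mode, rng_init)
        optimizer = _nn.SGDMomentum(self.network_, self.learning_rate, self.momentum)

        if self.train_fraction < 1.0:
            tr, va = stratified_split(targets, self.train_fraction, rng_split)
        else:
            tr, va = np.arange(len(X)), np.array([], dtype=int)
        Xtr, ttr = X[tr], targets[tr]
        Xva, tva = X[va], targets[va]

        history = []
        for epoch in range(self.epochs):
            order = rng_shuffle.permutation(len(Xtr))
            losses = []
            correct = 0
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                logits = self.network_.forward(Xtr[idx], train=True)
                loss, grad = _nn.softmax_cross_entropy(logits, ttr[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {s // self.batch_size} "
                        f"(lr={self.learning_rate}); training aborted"
                    )
                self.network_.backward(grad)
                optimizer.step()
                losses.append(loss)
                correct += int((logits.argmax(axis=1) == ttr[idx]).sum())
            row = {
                "epoch": epoch,
                "loss": float(np.mean(losses)) if losses else np.nan,
                "train_accuracy": correct / max(len(Xtr), 1),
            }
            if len(Xva):
                row["val_accuracy"] = float((self._predict_targets(Xva) == tva).mean())
            history.append(row)
        self._finalize_batchnorm(Xtr)
        if len(Xva):
            final_val = float((self._predict_targets(Xva) == tva).mean())
            if history:
                history[-1]["val_accuracy"] = final_val
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = int(np.prod(shape))
        return self

    def _finalize_batchnorm(self, Xtr: np.ndarray) -> None:
        """Replace running BN statistics with population statistics.

        A momentum-averaged running estimate is far from the population
        statistics after few updates; a dedicated pass over the training
        images (dropout inactive, batch statistics propagated) fixes the
        inference-time normalization, as reference CNN trainers do.
        """
        from ._nn import BatchNorm

        bns = [l for l in self.network_.layers if isinstance(l, BatchNorm)]
        if not bns or not len(Xtr):
            return
        for bn in bns:
            bn.start_collect()
        for s in range(0, len(Xtr), self.batch_size):
            self.network_.forward(Xtr[s : s + self.batch_size], train=False)
        for bn in bns:
            bn.finish_collect()

    def _predict_targets(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._as_tensor(X)
        out = np.empty((len(X), 2), dtype=np.float32)
        step = max(self.batch_size, 1)
        for s in range(0, len(X), step):
            logits = self.network_.forward(X[s : s + step], train=False)
            out[s : s + step] = _nn.softmax(logits)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self._predict_targets(X)]

    def activation(self, X: np.ndarray, layer: str) -> np.ndarray:
        """Forward pass up to and including the named layer (inference mode)."""
        if layer not in self.layer_names_:
            raise ValueError(f"unknown layer {layer!r}; available: {self.layer_names_}")
        upto = self.layer_names_.index(layer) + 1
        return self.network_.forward(self._as_tensor(X), train=False, upto=upto)

    def n_parameters(self) -> int:
        return self.network_.n_parameters()
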