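"""Minimal NumPy CNN engine: layers, backprop, and SGD with momentum.

Just enough machinery for the small two-block convolutional classifier this
package trains: conv / batch-norm / ReLU / max-pool / dropout / dense layers
on NHWC float32 tensors, exact manual gradients, and a momentum optimizer.
Convolutions use im2col matrix multiplication, chunked over the batch to
bound memory; the input gradient is computed as a full correlation of the
padded output gradient with the spatially flipped kernels (so no
scatter-add is needed).

All randomness flows through explicitly passed ``numpy.random.Generator``
instances; given the same generator state the engine is bit-deterministic
in a single-threaded run.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_CHUNK = 16  # batch sub-chunk for im2col buffers


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` with paired arrays."""

    name = "layer"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, H, W, C) -> (B, OH, OW, kh*kw*C) patch matrix."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (B, OH, OW, C, kh, kw)
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (B, OH, OW, kh, kw, C)
    B, OH, OW = v.shape[:3]
    return np.ascontiguousarray(v).reshape(B, OH, OW, kh * kw * x.shape[3])


class Conv2D(Layer):
    """Valid-mode 2-D convolution (cross-correlation), stride 1, no padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        input_grad: bool = True,
    ):
        super().__init__()
        self.input_grad = input_grad  # False for the first conv: nothing below needs dx
        self.kh, self.kw = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = self.kh * self.kw * in_channels
        fan_out = self.kh * self.kw * out_channels
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(fan_in, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, Wd, C = x.shape
        if H < self.kh or Wd < self.kw:
            raise ValueError(
                f"kernel {self.kh}x{self.kw} exceeds input extent {H}x{Wd} in layer {self.name}"
            )
        self._x = x
        OH, OW = H - self.kh + 1, Wd - self.kw + 1
        out = np.empty((B, OH, OW, self.out_channels), dtype=np.result_type(x, self.W))
        for s in range(0, B, _CHUNK):
            cols = _im2col(x[s : s + _CHUNK], self.kh, self.kw)
            out[s : s + _CHUNK] = cols @ self.W + self.b
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, H, Wd, C = x.shape
        dW = np.zeros_like(self.W)
        db = dout.sum(axis=(0, 1, 2))
        # flipped-kernel weights for the input gradient: (kh*kw*F, C)
        Wk = self.W.reshape(self.kh, self.kw, self.in_channels, self.out_channels)
        dx = np.zeros_like(x) if self.input_grad else None
        OH, OW = H - self.kh + 1, Wd - self.kw + 1
        for s in range(0, B, _CHUNK):
            xb = x[s : s + _CHUNK]
            db_out = dout[s : s + _CHUNK]
            cols = _im2col(xb, self.kh, self.kw)
            n = cols.shape[0] * cols.shape[1] * cols.shape[2]
            dW += cols.reshape(n, -1).T @ db_out.reshape(n, -1)
            if self.input_grad:
                # accumulate dx per kernel offset: kh*kw slice-adds, same
                # flop count as the forward pass, no padded-im2col blowup
                dcols = (db_out.reshape(-1, self.out_channels) @ self.W.T).reshape(
                    db_out.shape[0], OH, OW, self.kh, self.kw, self.in_channels
                )
                for di in range(self.kh):
                    for dj in range(self.kw):
                        dx[s : s + _CHUNK, di : di + OH, dj : dj + OW, :] += dcols[:, :, :, di, dj, :]
        self.grads[0][...] = dW
        self.grads[1][...] = db
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._collecting = False

    def start_collect(self) -> None:
        """Begin population-statistics finalization (post-training pass)."""
        self._collecting = True
        self._sum = np.zeros_like(self.running_mean, dtype=np.float64)
        self._sumsq = np.zeros_like(self.running_mean, dtype=np.float64)
        self._count = 0

    def finish_collect(self) -> None:
        mean = self._sum / max(self._count, 1)
        self.running_mean[...] = mean
        self.running_var[...] = self._sumsq / max(self._count, 1) - mean**2
        self._collecting = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        elif self._collecting:
            # population pass: normalize with batch stats (so downstream
            # layers see training-like activations) while accumulating
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = int(np.prod([x.shape[a] for a in axes]))
            self._sum += mean * n
            self._sumsq += (var + mean**2) * n
            self._count += n
        else:
            mean, var = self.running_mean, self.running_var
        self._train = train
        self._std = np.sqrt(var + self.eps).astype(x.dtype, copy=False)
        self._xhat = ((x - mean) / self._std).astype(x.dtype, copy=False)
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        xhat = self._xhat
        self.grads[0][...] = (dout * xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        if not self._train:
            return dout * (self.gamma / self._std)
        m = float(np.prod([dout.shape[a] for a in axes]))
        dxhat = dout * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) / self._std


class ReLU(Layer):
    """f(x) = x for x >= 0, else 0."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/columns are cropped."""

    def __init__(self, pool: tuple[int, int]):
        super().__init__()
        self.ph, self.pw = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W, C = x.shape
        OH, OW = H // self.ph, W // self.pw
        if OH < 1 or OW < 1:
            raise ValueError(f"pool {self.ph}x{self.pw} exceeds input extent {H}x{W} in layer {self.name}")
        self._in_shape = x.shape
        xc = x[:, : OH * self.ph, : OW * self.pw, :]
        win = xc.reshape(B, OH, self.ph, OW, self.pw, C).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(B, OH, OW, self.ph * self.pw, C)
        self._argmax = win.argmax(axis=3)
        out = np.take_along_axis(win, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._in_shape
        OH, OW = H // self.ph, W // self.pw
        dwin = np.zeros((B, OH, OW, self.ph * self.pw, C), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : OH * self.ph, : OW * self.pw, :] = (
            dwin.reshape(B, OH, OW, self.ph, self.pw, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, OH * self.ph, OW * self.pw, C)
        )
        return dx


class Dropout(Layer):
    """Input masking: ``exact`` mode zeroes exactly floor(rate*N) elements
    per sample (no activation rescaling — the following batch-norm absorbs
    the scale); ``bernoulli`` mode is standard inverted dropout."""

    def __init__(self, rate: float, rng: np.random.Generator, mode: str = "exact"):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        if mode not in {"exact", "bernoulli"}:
            raise ValueError(f"unknown dropout mode {mode!r}")
        self.rate = rate
        self.rng = rng
        self.mode = mode

    def make_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        """Per-sample mask over all non-batch dimensions."""
        B = shape[0]
        n = int(np.prod(shape[1:]))
        if self.mode == "exact":
            k = int(self.rate * n)
            mask = np.ones((B, n), dtype=np.float32)
            for i in range(B):
                idx = self.rng.choice(n, size=k, replace=False)
                mask[i, idx] = 0.0
        else:
            mask = (self.rng.random((B, n)) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return mask.reshape(shape)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = self.make_mask(x.shape)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if dout is None or self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.W = rng.uniform(-limit, limit, size=(in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits.

    ``targets`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class Network:
    """A plain sequential stack with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(
        self, x: np.ndarray, train: bool = False, upto: int | None = None, start: int = 0
    ) -> np.ndarray:
        out = x
        for layer in self.layers[start : upto if upto is not None else len(self.layers)]:
            out = layer.forward(out, train)
        return out

    def backward(self, dout: np.ndarray, downto: int = 0) -> np.ndarray:
        for layer in reversed(self.layers[downto:]):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)


class SGDMomentum:
    """Classical momentum: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, network: Network, learning_rate: float = 0.01, momentum: float = 0.9):
        self.network = network
        self.lr = learning_rate
        self.mu = momentum
        self.velocity = [np.zeros_like(p) for layer in network.layers for p in layer.params]

    def step(self) -> None:
        k = 0
        for p, g in self.network.parameters():
            v = self.velocity[k]
            v *= self.mu
            v -= self.lr * g
            p += v
            k += 1
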