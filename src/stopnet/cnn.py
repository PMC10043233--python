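"""The convolutional network shared by both cascade stages.

Architecture (input = band x channel rows stacked on one spatial axis of
4 x 27 = 108 rows, 300 time samples at 500 Hz):

    conv 64x2 (6 filters) - BN - ReLU - maxpool 1x2
    conv 1x11 (12)        - BN - ReLU - maxpool 1x2
    conv 1x10 (12)        - BN - ReLU - maxpool 1x2
    dropout - FC 60 - ReLU - FC 2 - softmax

Convolutions are unpadded ("valid") and pooling uses floor semantics, so
every layer's output shape is exactly computable.  Training is plain SGD
with momentum, an L2 penalty on conv/FC weights and a staircase learning
rate.  Everything is implemented on numpy (float32, im2col + BLAS matmul);
given a seed and a fixed BLAS, training is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_CHUNK = 16  # samples per im2col chunk; bounds transient memory


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "vel", "decay")

    def __init__(self, value: np.ndarray, decay: bool):
        self.value = value
        self.grad = np.zeros_like(value)
        self.vel = np.zeros_like(value)
        self.decay = decay  # subject to L2


def _im2col_tm(xs: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Time-major im2col: xs (b, W, H, C) contiguous -> (b*Wo*Ho, kw*kh*C).

    The (kh, C) tail of each patch is contiguous in memory, which keeps the
    gather fast (the channel-major layout makes this copy ~10x slower).
    """
    win = sliding_window_view(xs, (kw, kh), axis=(1, 2))  # (b,Wo,Ho,C,kw,kh)
    b, Wo, Ho, C = win.shape[:4]
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(b * Wo * Ho, kw * kh * C)


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation: x (B,C,H,W) * w (F,C,kh,kw) -> (B,F,H',W')."""
    B, C, H, W = x.shape
    F, _, kh, kw = w.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    wm = w.transpose(0, 3, 2, 1).reshape(F, kw * kh * C).T.astype(x.dtype)
    out = np.empty((B, F, Ho, Wo), dtype=x.dtype)
    for i in range(0, B, _CHUNK):
        xs = np.ascontiguousarray(x[i : i + _CHUNK].transpose(0, 3, 2, 1))
        y = _im2col_tm(xs, kh, kw) @ wm  # (b*Wo*Ho, F)
        out[i : i + _CHUNK] = y.reshape(xs.shape[0], Wo, Ho, F).transpose(0, 3, 2, 1)
    return out


def _conv_grad_w(x: np.ndarray, dy: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Gradient of _conv_valid w.r.t. the kernel."""
    B, C, H, W = x.shape
    F = dy.shape[1]
    dw = np.zeros((F, kw * kh * C), dtype=np.float32)
    for i in range(0, B, _CHUNK):
        xs = np.ascontiguousarray(x[i : i + _CHUNK].transpose(0, 3, 2, 1))
        cols = _im2col_tm(xs, kh, kw)
        dys = dy[i : i + _CHUNK].transpose(0, 3, 2, 1).reshape(-1, F)
        dw += dys.T @ cols
    return dw.reshape(F, kw, kh, C).transpose(0, 3, 2, 1)


def _conv_tall_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Single-input-channel conv with a tall kernel as a Toeplitz GEMM.

    The kernel height (64) is comparable to the input height (108), so the
    banded H -> Ho map is nearly dense and a plain matmul beats im2col.
    """
    B, _, H, W = x.shape
    F, _, kh, kw = w.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    X = x[:, 0]
    acc = np.zeros((F, Ho, B, Wo), dtype=x.dtype)
    idx = np.arange(Ho)
    for v in range(kw):
        T = np.zeros((F, Ho, H), dtype=x.dtype)
        for u in range(kh):
            T[:, idx, idx + u] = w[:, 0, u, v][:, None]
        Xs = np.ascontiguousarray(
            X[:, :, v : v + Wo].transpose(1, 0, 2)).reshape(H, B * Wo)
        acc += (T.reshape(F * Ho, H) @ Xs).reshape(F, Ho, B, Wo)
    return np.ascontiguousarray(acc.transpose(2, 0, 1, 3))


def _conv_tall_grad_w(x: np.ndarray, dy: np.ndarray, kh: int, kw: int) -> np.ndarray:
    B, _, H, W = x.shape
    _, F, Ho, Wo = dy.shape
    X = x[:, 0]
    dyr = np.ascontiguousarray(dy.transpose(1, 2, 0, 3)).reshape(F * Ho, B * Wo)
    dw = np.zeros((F, 1, kh, kw), dtype=np.float32)
    idx = np.arange(Ho)
    for v in range(kw):
        xr = np.ascontiguousarray(
            X[:, :, v : v + Wo].transpose(1, 0, 2)).reshape(H, B * Wo)
        C3 = (dyr @ xr.T).reshape(F, Ho, H)
        diag = sliding_window_view(C3, kh, axis=2)[:, idx, idx, :]  # (F,Ho,kh)
        dw[:, 0, :, v] = diag.sum(axis=1)
    return dw


def _conv_flat_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """1 x kw convolution via kw shifted channel-mixing GEMMs (no gathers)."""
    B, C, H, W = x.shape
    F, _, _, kw = w.shape
    Wo = W - kw + 1
    acc = np.zeros((F, B, H, Wo), dtype=x.dtype)
    for v in range(kw):
        acc += np.tensordot(w[:, :, 0, v], x[:, :, :, v : v + Wo], axes=([1], [1]))
    return np.ascontiguousarray(acc.transpose(1, 0, 2, 3))


def _conv_flat_grad_w(x: np.ndarray, dy: np.ndarray, kw: int) -> np.ndarray:
    B, C, H, W = x.shape
    _, F, _, Wo = dy.shape
    dyr = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(F, -1)
    dw = np.zeros((F, C, 1, kw), dtype=np.float32)
    for v in range(kw):
        xr = np.ascontiguousarray(
            x[:, :, :, v : v + Wo].transpose(1, 0, 2, 3)).reshape(C, -1)
        dw[:, :, 0, v] = dyr @ xr.T
    return dw


def _conv_flat_grad_x(dy: np.ndarray, w: np.ndarray, W_in: int) -> np.ndarray:
    B, F, H, Wo = dy.shape
    _, C, _, kw = w.shape
    dx = np.zeros((B, C, H, W_in), dtype=dy.dtype)
    for v in range(kw):
        g = np.tensordot(w[:, :, 0, v], dy, axes=([0], [1]))  # (C,B,H,Wo)
        dx[:, :, :, v : v + Wo] += g.transpose(1, 0, 2, 3)
    return dx


class Conv2D:
    def __init__(self, in_ch: int, filters: int, kh: int, kw: int,
                 rng: np.random.Generator, first: bool = False):
        fan_in = in_ch * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, in_ch, kh, kw))
        self.w = Param(w.astype(np.float32), decay=True)
        self.b = Param(np.zeros(filters, dtype=np.float32), decay=False)
        self.kh, self.kw = kh, kw
        self.in_ch = in_ch
        self.first = first  # first layer: input gradient not needed
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        if self.kh == 1:
            y = _conv_flat_forward(x, self.w.value)
        elif self.in_ch == 1 and self.kh >= 8:
            y = _conv_tall_forward(x, self.w.value)
        else:
            y = _conv_valid(x, self.w.value)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        x = self._x
        if self.kh == 1:
            dw = _conv_flat_grad_w(x, dy, self.kw)
        elif self.in_ch == 1 and self.kh >= 8:
            dw = _conv_tall_grad_w(x, dy, self.kh, self.kw)
        else:
            dw = _conv_grad_w(x, dy, self.kh, self.kw)
        self.w.grad[...] = dw / dy.shape[0]
        self.b.grad[...] = dy.sum(axis=(0, 2, 3)) / dy.shape[0]
        self._x = None
        if self.first:
            return None
        if self.kh == 1:
            return _conv_flat_grad_x(dy, self.w.value, x.shape[3])
        # generic fallback: full correlation with the flipped kernel
        wf = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        pad = ((0, 0), (0, 0), (self.kh - 1, self.kh - 1), (self.kw - 1, self.kw - 1))
        return _conv_valid(np.pad(dy, pad), wf)


class BatchNorm:
    """Per-feature-map batch normalization (reduce over batch x H x W)."""

    def __init__(self, n_feat: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_feat, dtype=np.float32), decay=False)
        self.beta = Param(np.zeros(n_feat, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(n_feat, dtype=np.float32)
        self.running_var = np.ones(n_feat, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        # fold normalization + affine into one scale/shift pass
        scale = (self.gamma.value * inv_std).astype(x.dtype)
        shift = (self.beta.value - mean * scale).astype(x.dtype)
        if train:
            self._cache = (x, mean.astype(x.dtype), inv_std)
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    def backward(self, dy):
        x, mean, inv_std = self._cache
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        sum_dy = dy.sum(axis=(0, 2, 3))
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3))
        self.gamma.grad[...] = sum_dy_xhat / dy.shape[0]
        self.beta.grad[...] = sum_dy / dy.shape[0]
        g = self.gamma.value * inv_std
        dx = (g[None, :, None, None] / m) * (
            m * dy
            - sum_dy[None, :, None, None]
            - xhat * sum_dy_xhat[None, :, None, None]
        )
        return dx.astype(dy.dtype)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1x2:
    """1x2 max-pool with stride 2 along time; floor semantics (odd tail dropped)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x, train):
        W2 = x.shape[3] // 2
        x0 = x[:, :, :, 0 : 2 * W2 : 2]
        x1 = x[:, :, :, 1 : 2 * W2 : 2]
        right = x1 > x0  # ties take the first (left) sample
        if train:
            self._cache = (right, x.shape)
        return np.where(right, x1, x0)

    def backward(self, dy):
        right, shape = self._cache
        self._cache = None
        W2 = dy.shape[3]
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, :, :, 0 : 2 * W2 : 2] = np.where(right, 0, dy)
        dx[:, :, :, 1 : 2 * W2 : 2] = np.where(right, dy, 0)
        return dx


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None
        self.rng: np.random.Generator | None = None

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Param(w.astype(np.float32), decay=True)
        self.b = Param(np.zeros(n_out, dtype=np.float32), decay=False)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad[...] = self._x.T @ dy / dy.shape[0]
        self.b.grad[...] = dy.sum(axis=0) / dy.shape[0]
        dx = dy @ self.w.value.T
        self._x = None
        return dx


class ReLU1D(ReLU):
    pass


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class NetSpec:
    """Architecture parameters; defaults are the cascade network's."""

    n_bands: int = 4
    n_channels: int = 27
    temporal: int = 300
    conv1_kernel: tuple[int, int] = (64, 2)
    conv1_filters: int = 6
    conv2_kernel: tuple[int, int] = (1, 11)
    conv2_filters: int = 12
    conv3_kernel: tuple[int, int] = (1, 10)
    conv3_filters: int = 12
    fc1_units: int = 60
    n_classes: int = 2
    dropout_rate: float = 0.5

    @property
    def spatial(self) -> int:
        return self.n_bands * self.n_channels


@dataclass
class TrainSpec:
    """SGD-with-momentum training parameters (staircase lr schedule)."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    l2: float = 1e-4
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    max_epochs: int = 500
    batch_size: int = 100
    seed: int = 0
    early_stop_patience: int | None = None  # off by default (paper fidelity)

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.lr_drop_factor ** (epoch // self.lr_drop_period)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class ConvNet:
    def __init__(self, spec: NetSpec, rng: np.random.Generator):
        s = spec
        if s.spatial < s.conv1_kernel[0]:
            raise ValueError(
                f"spatial input dimension {s.spatial} is smaller than the first "
                f"kernel height {s.conv1_kernel[0]}; the architecture needs "
                f"bands x channels >= {s.conv1_kernel[0]} rows"
            )
        shapes = self._shape_chain(s)
        flat = int(np.prod(shapes["pool3"]))
        self.spec = s
        self.dropout = Dropout(s.dropout_rate)
        self.layers = [
            Conv2D(1, s.conv1_filters, *s.conv1_kernel, rng=rng, first=True),
            BatchNorm(s.conv1_filters), ReLU(), MaxPool1x2(),
            Conv2D(s.conv1_filters, s.conv2_filters, *s.conv2_kernel, rng=rng),
            BatchNorm(s.conv2_filters), ReLU(), MaxPool1x2(),
            Conv2D(s.conv2_filters, s.conv3_filters, *s.conv3_kernel, rng=rng),
            BatchNorm(s.conv3_filters), ReLU(), MaxPool1x2(),
            self.dropout, Flatten(),
            Dense(flat, s.fc1_units, rng), ReLU1D(),
            Dense(s.fc1_units, s.n_classes, rng),
        ]

    @staticmethod
    def _shape_chain(s: NetSpec) -> dict[str, tuple[int, ...]]:
        """Analytic layer output shapes (channels, H, W) for a valid/floor net."""
        h, w = s.spatial, s.temporal
        out: dict[str, tuple[int, ...]] = {"input": (1, h, w)}
        for i, (k, f) in enumerate(
            [(s.conv1_kernel, s.conv1_filters),
             (s.conv2_kernel, s.conv2_filters),
             (s.conv3_kernel, s.conv3_filters)], start=1
        ):
            h, w = h - k[0] + 1, w - k[1] + 1
            out[f"conv{i}"] = (f, h, w)
            w = w // 2
            out[f"pool{i}"] = (f, h, w)
        out["fc1"] = (s.fc1_units,)
        out["fc2"] = (s.n_classes,)
        return out

    def output_shapes(self) -> dict[str, tuple[int, ...]]:
        """Shapes observed by pushing a dummy tensor through the built net."""
        x = np.zeros((1, 1, self.spec.spatial, self.spec.temporal), dtype=np.float32)
        names = iter(["conv1", "pool1", "conv2", "pool2", "conv3", "pool3"])
        out: dict[str, tuple[int, ...]] = {"input": x.shape[1:]}
        for layer in self.layers:
            x = layer.forward(x, train=False)
            if isinstance(layer, (Conv2D, MaxPool1x2)):
                out[next(names)] = x.shape[1:]
        out["fc2"] = x.shape[1:]
        return out

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break

    def predict_proba(self, x: np.ndarray, batch: int = 128) -> np.ndarray:
        out = np.empty((x.shape[0], self.spec.n_classes), dtype=np.float64)
        for i in range(0, x.shape[0], batch):
            out[i : i + batch] = softmax(self.forward(x[i : i + batch], train=False))
        return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained network plus its provenance; classes are 1 (walk) / 2 (stop)."""

    net: ConvNet
    train_spec: TrainSpec
    provenance: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._prep(x))

    def predict_classes(self, x: np.ndarray) -> np.ndarray:
        """Argmax class with ties resolved to walk (the conservative output)."""
        p = self.predict_proba(x)
        return np.where(p[:, 1] > p[:, 0], 2, 1)

    def _prep(self, x: np.ndarray) -> np.ndarray:
        """Accept (n, bands, channels, T) epoch tensors or flat (n, 1, S, T)."""
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != 1:
            x = x.reshape(x.shape[0], 1, -1, x.shape[-1])
        expected = (1, self.net.spec.spatial, self.net.spec.temporal)
        if x.shape[1:] != expected:
            raise ValueError(f"epoch tensor shape {x.shape[1:]} != expected {expected}")
        return np.ascontiguousarray(x, dtype=np.float32)

    def save(self, path) -> None:
        arrays = {}
        for i, p in enumerate(self.net.params()):
            arrays[f"p{i}"] = p.value
        bi = 0
        for layer in self.net.layers:
            if isinstance(layer, BatchNorm):
                arrays[f"rm{bi}"] = layer.running_mean
                arrays[f"rv{bi}"] = layer.running_var
                bi += 1
        meta = {
            "netspec": asdict(self.net.spec),
            "trainspec": asdict(self.train_spec),
            "provenance": self.provenance,
        }
        np.savez_compressed(path, meta=np.frombuffer(
            json.dumps(meta, default=str).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            spec = NetSpec(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["netspec"].items()})
            ts = TrainSpec(**{k: v for k, v in meta["trainspec"].items()})
            net = ConvNet(spec, np.random.default_rng(0))
            for i, p in enumerate(net.params()):
                p.value[...] = z[f"p{i}"]
            bi = 0
            for layer in net.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = z[f"rm{bi}"]
                    layer.running_var[...] = z[f"rv{bi}"]
                    bi += 1
            return cls(net, ts, meta["provenance"])


def build_network(spec: NetSpec | None = None, seed: int = 0) -> ConvNet:
    """Construct the untrained network with seeded He-normal initialization."""
    return ConvNet(spec or NetSpec(), np.random.default_rng(seed))


def train(net: ConvNet, x: np.ndarray, y: np.ndarray,
          spec: TrainSpec | None = None, provenance: dict | None = None) -> TrainedModel:
    """Train on labeled epoch tensors (labels in {1, 2}); deterministic per seed.

    Minimizes softmax cross-entropy with an L2 penalty on conv/FC weights,
    SGD momentum, and the staircase learning-rate schedule
    ``lr(epoch) = lr0 * factor^(epoch // period)``.
    """
    spec = spec or TrainSpec()
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError(f"training set contains a single class: {classes}")
    y01 = (y == 2).astype(np.int64) if set(classes) <= {1, 2} else y.astype(np.int64)
    if x.ndim == 4 and x.shape[1] != 1:
        x = x.reshape(x.shape[0], 1, -1, x.shape[-1])
    x = np.ascontiguousarray(x, dtype=np.float32)

    rng = np.random.default_rng(spec.seed)
    net.dropout.rng = rng
    n = x.shape[0]
    params = net.params()
    history: list[float] = []
    best, wait = np.inf, 0
    for epoch in range(spec.max_epochs):
        lr = spec.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            xb, yb = x[idx], y01[idx]
            logits = net.forward(xb, train=True)
            p = softmax(logits.astype(np.float64))
            loss = -np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at training epoch {epoch} (lr={lr:g}); "
                    "inputs may be unscaled or the learning rate too high"
                )
            epoch_loss += loss * len(yb)
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            net.backward(dlogits.astype(np.float32))
            for prm in params:
                g = prm.grad
                if prm.decay and spec.l2:
                    g = g + spec.l2 * prm.value
                prm.vel *= spec.momentum
                prm.vel -= lr * g
                prm.value += prm.vel
        history.append(epoch_loss / n)
        if spec.early_stop_patience is not None:
            if history[-1] < best - 1e-5:
                best, wait = history[-1], 0
            else:
                wait += 1
                if wait >= spec.early_stop_patience:
                    break

    model = TrainedModel(net, spec, dict(provenance or {}))
    pred = model.predict_classes(x.reshape(n, 1, net.spec.spatial, net.spec.temporal))
    truth = np.where(y01 == 1, 2, 1)
    model.provenance.update(
        final_loss=float(history[-1]) if history else None,
        train_accuracy=float(np.mean(pred == truth)),
        n_train=int(n),
        class_counts={int(c): int((y == c).sum()) for c in classes},
    )
    return model
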