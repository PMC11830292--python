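"""The customized 1D convolutional network for heart-sound classification.

Architecture: a stack of ``n_blocks`` identical blocks —

    conv1d(F_l, kernel K, same padding) -> batch-norm -> ReLU
        -> max-pool(P) -> dropout

— followed by flatten, a 128-unit dense layer with ReLU and dropout, and
a probabilistic head (2-way softmax by default; a single-sigmoid head is
selectable).  Same-padding convolutions leave the time axis untouched,
so pooling alone controls length: after block ``l`` the time dimension
is exactly ``input_len / P**l``, which is why ``input_len`` must be
divisible by ``P**n_blocks``.

The default filter schedule (64, 128, 128, 64, 32, 16) widens then
tapers: early wide layers learn the S1/S2 transient shapes, later narrow
layers summarise; six pool-2 stages reduce a 4-s window at 2000 Hz from
8000 samples to 125 time steps before the dense layer.

Everything — forward, backward, initialisation — is plain numpy in
float32, with im2col + BLAS matmuls carrying the convolution arithmetic.
Inference is deterministic (dropout inactive, batch-norm uses running
statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .segment_augment import Segment

DEFAULT_CONV_FILTERS = (64, 128, 128, 64, 32, 16)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network; see the module docstring."""

    input_len: int = 8000
    conv_filters: Tuple[int, ...] = DEFAULT_CONV_FILTERS
    kernel_size: int = 3
    pool_size: int = 2
    conv_dropout: float = 0.25
    dense_units: int = 128
    dense_dropout: float = 0.5
    head: str = "softmax2"
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.conv_filters)

    @property
    def final_time_steps(self) -> int:
        return self.input_len // self.pool_size**self.n_blocks

    @property
    def flatten_len(self) -> int:
        return self.final_time_steps * self.conv_filters[-1]

    def validate(self) -> None:
        if self.kernel_size < 1:
            raise ValidationError(f"kernel_size must be >= 1, got {self.kernel_size}")
        if self.pool_size < 1:
            raise ValidationError(f"pool_size must be >= 1, got {self.pool_size}")
        if not self.conv_filters:
            raise ValidationError("conv_filters must be non-empty")
        for r, name in ((self.conv_dropout, "conv_dropout"), (self.dense_dropout, "dense_dropout")):
            if not (0.0 <= r < 1.0):
                raise ValidationError(f"{name} must lie in [0, 1), got {r}")
        if self.head not in ("softmax2", "sigmoid1"):
            raise ValidationError(f"head must be 'softmax2' or 'sigmoid1', got {self.head!r}")
        divisor = self.pool_size**self.n_blocks
        if self.input_len % divisor != 0:
            raise ValidationError(
                f"input_len={self.input_len} is not divisible by "
                f"pool_size**n_blocks = {self.pool_size}**{self.n_blocks} = {divisor} "
                f"({self.input_len} % {divisor} = {self.input_len % divisor})"
            )


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax in the numerically stable shifted form."""
    logits = np.asarray(logits, dtype=np.float64)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# layers (channels-last layout: (batch, time, channels))


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class _Layer:
    """Base class: parameter dicts plus a persistent scratch-buffer cache.

    Activations at 2000 Hz are tens of megabytes per layer, so freshly
    allocating them every mini-batch costs more in page faults than the
    arithmetic does.  Buffers are keyed by (name, shape, dtype) and
    reused across batches; each layer owns its buffers, so the backward
    chain never aliases another layer's scratch space.
    """

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}
        self._bufs: dict = {}

    def _buf(self, name: str, shape, dtype=np.float32) -> np.ndarray:
        key = (name, tuple(shape), np.dtype(dtype))
        arr = self._bufs.get(key)
        if arr is None:
            arr = np.empty(shape, dtype=dtype)
            self._bufs[key] = arr
        return arr


class _Conv1D(_Layer):
    """Same-padding convolution as K shifted BLAS matmuls.

    The weight tensor is stored flat as (K * c_in, c_out); tap i uses the
    rows [i*c_in, (i+1)*c_in).  One full-length matmul per tap, added at
    its shift, touches far less memory than an explicit im2col column
    matrix.  A 1-channel input falls back to a broadcast multiply, where
    BLAS degenerates to a slow outer product.
    """

    def __init__(self, rng, c_in: int, c_out: int, kernel: int):
        super().__init__()
        self.k = kernel
        self.c_in = c_in
        self.params = {
            "W": _he_uniform(rng, kernel * c_in, (kernel * c_in, c_out)),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {
            "W": np.zeros((kernel * c_in, c_out), dtype=np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self._xp = None

    def _tap(self, i: int) -> np.ndarray:
        return self.params["W"][i * self.c_in : (i + 1) * self.c_in]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, _ = x.shape
        pl = (self.k - 1) // 2
        xp = self._buf("xp", (n, length + self.k - 1, self.c_in))
        xp[:, :pl, :] = 0.0
        xp[:, pl : pl + length, :] = x
        xp[:, pl + length :, :] = 0.0
        self._xp = xp if train else None
        f = self.params["W"].shape[1]
        out = self._buf("out", (n, length, f))
        z = self._buf("z", (n, length + self.k - 1, f))
        for i in range(self.k):
            if self.c_in == 1:
                np.multiply(xp, self._tap(i)[0], out=z)
            else:
                np.matmul(xp, self._tap(i), out=z)
            if i == 0:
                np.copyto(out, z[:, 0:length, :])
            else:
                out += z[:, i : i + length, :]
        out += self.params["b"]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, f = dy.shape
        xp = self._xp
        dy2 = dy.reshape(n * length, f)
        span = self._buf("span", (n, length, self.c_in))
        for i in range(self.k):
            np.copyto(span, xp[:, i : i + length, :])
            np.matmul(
                span.reshape(n * length, self.c_in).T,
                dy2,
                out=self.grads["W"][i * self.c_in : (i + 1) * self.c_in],
            )
        dy2.sum(axis=0, out=self.grads["b"])
        dxp = self._buf("dxp", (n, length + self.k - 1, self.c_in))
        dxp[:] = 0.0
        buf = self._buf("dxbuf", (n, length, self.c_in))
        for i in range(self.k):
            np.matmul(dy, np.ascontiguousarray(self._tap(i).T), out=buf)
            dxp[:, i : i + length, :] += buf
        pl = (self.k - 1) // 2
        self._xp = None
        return dxp[:, pl : pl + length, :]


class _BatchNorm(_Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._x = self._mean = self._ivar = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
            ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            # keep a reference to x (no copy); xhat is recomputed in backward
            self._x, self._mean, self._ivar = x, mean.astype(np.float32), ivar
        else:
            mean = self.running_mean
            ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        # fused affine: out = x * (gamma*ivar) + (beta - mean*gamma*ivar)
        scale = (self.params["gamma"] * ivar).astype(np.float32)
        shift = (self.params["beta"] - mean * scale).astype(np.float32)
        out = self._buf("out", x.shape)
        np.multiply(x, scale, out=out)
        out += shift
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m = dy.shape[0] * dy.shape[1]
        xhat = self._buf("xhat", dy.shape)
        np.subtract(self._x, self._mean, out=xhat)
        xhat *= self._ivar
        tmp = self._buf("tmp", dy.shape)
        np.multiply(dy, xhat, out=tmp)
        self.grads["gamma"] = tmp.sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g_over_m = (self.params["gamma"] * self._ivar / m).astype(np.float32)
        # dx = gamma*ivar/m * (m*dy - sum(dy) - xhat*sum(dy*xhat))
        dx = self._buf("dx", dy.shape)
        np.multiply(xhat, -self.grads["gamma"], out=dx)
        np.multiply(dy, np.float32(m), out=tmp)
        dx += tmp
        dx -= self.grads["beta"]
        dx *= g_over_m
        self._x = self._mean = self._ivar = None
        return dx


class _ReLU(_Layer):
    def forward(self, x, train):
        # in place: the producing layer never rereads its output buffer
        np.maximum(x, 0.0, out=x)
        self._out = x if train else None
        return x

    def backward(self, dy):
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, self._out > 0, out=dx)
        self._out = None
        return dx


class _MaxPool(_Layer):
    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        n, length, c = x.shape
        xr = x.reshape(n, length // self.pool, self.pool, c)
        if self.pool == 2:
            a, b = xr[:, :, 0, :], xr[:, :, 1, :]
            out = self._buf("out", a.shape)
            np.maximum(a, b, out=out)
            if train:
                mask = self._buf("mask", a.shape, dtype=bool)
                np.greater(b, a, out=mask)  # tie goes to the first element
                self._mask = mask
            return out
        if train:
            self._arg = xr.argmax(axis=2).astype(np.int8)
        return xr.max(axis=2)

    def backward(self, dy):
        n, lo, c = dy.shape
        dxr = self._buf("dxr", (n, lo, self.pool, c))
        if self.pool == 2:
            np.multiply(dy, self._mask, out=dxr[:, :, 1, :])
            np.subtract(dy, dxr[:, :, 1, :], out=dxr[:, :, 0, :])
            self._mask = None
        else:
            dxr[:] = 0.0
            ii, jj, cc = np.ogrid[:n, :lo, :c]
            dxr[ii, jj, self._arg, cc] = dy
            self._arg = None
        return dxr.reshape(n, lo * self.pool, c)


class _Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        u = self._buf("u", x.shape)
        self.rng.random(out=u, dtype=np.float32)
        mask = self._buf("mask", x.shape)
        np.less(u, keep, out=u)  # 0.0 / 1.0 in place
        np.divide(u, keep, out=mask)  # inverted-dropout scaling
        self._mask = mask
        x *= mask  # in place: pooling handed us a fresh buffer
        return x

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, self._mask, out=dx)
        self._mask = None
        return dx


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, rng, d_in: int, d_out: int):
        super().__init__()
        self.params = {
            "W": _he_uniform(rng, d_in, (d_in, d_out)),
            "b": np.zeros(d_out, dtype=np.float32),
        }

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class CNN1D:
    """The network itself: layer stack, forward pass, backprop."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.layers: List = []
        c_in = 1
        for f in config.conv_filters:
            self.layers += [
                _Conv1D(rng, c_in, f, config.kernel_size),
                _BatchNorm(f),
                _ReLU(),
                _MaxPool(config.pool_size),
                _Dropout(config.conv_dropout, self._dropout_rng),
            ]
            c_in = f
        self.layers.append(_Flatten())
        self.layers.append(_Dense(rng, config.flatten_len, config.dense_units))
        self.layers.append(_ReLU())
        self.layers.append(_Dropout(config.dense_dropout, self._dropout_rng))
        n_out = 2 if config.head == "softmax2" else 1
        self.layers.append(_Dense(rng, config.dense_units, n_out))

    # -- passes ------------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x[:, :, None].astype(np.float32) if x.ndim == 2 else x.astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities; shape (n, 2) for softmax2, (n, 1) for sigmoid1."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i : i + batch_size], train=False)
            outs.append(
                softmax(logits) if self.config.head == "softmax2" else sigmoid(logits)
            )
        return np.concatenate(outs, axis=0)

    # -- parameter access ---------------------------------------------------
    def parameters(self):
        """Yield (layer_index, name, array) for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    def state_arrays(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                state[f"layer{i}.{name}"] = arr
            if isinstance(layer, _BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"layer{i}.{name}"].astype(np.float32)
            if isinstance(layer, _BatchNorm):
                layer.running_mean = state[f"layer{i}.running_mean"].astype(np.float32)
                layer.running_var = state[f"layer{i}.running_var"].astype(np.float32)


@dataclass
class TrainedModel:
    """A network plus its per-epoch training history."""

    config: ModelConfig
    net: CNN1D
    training_history: List[dict] = field(default_factory=list)


def build_model(config: ModelConfig) -> TrainedModel:
    """Instantiate the network with seeded initial weights (untrained)."""
    return TrainedModel(config=config, net=CNN1D(config), training_history=[])


def forward(model: TrainedModel, batch: Sequence[Segment]) -> np.ndarray:
    """Class probabilities for a batch of segments.

    softmax2 head: an (n, 2) array of [P(normal), P(abnormal)] rows
    summing to 1.  sigmoid1 head: an (n, 1) array of P(abnormal).
    """
    if not batch:
        raise ValidationError("empty batch")
    want = model.config.input_len
    for s in batch:
        if s.samples.size != want:
            raise ValidationError(
                f"segment length mismatch: model expects {want} samples, "
                f"got {s.samples.size} (source {s.source_id!r})"
            )
    x = np.stack([s.samples for s in batch]).astype(np.float32)
    return model.net.predict_proba(x)


# ---------------------------------------------------------------------------
# checkpointing

CHECKPOINT_VERSION = 1


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-archive checkpoint: config + weights + history, versioned."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "history": model.training_history,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.net.state_arrays(),
    )


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(f"unsupported checkpoint version: {meta.get('version')}")
        cfg_d = meta["config"]
        cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
        config = ModelConfig(**cfg_d)
        model = build_model(config)
        model.net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        model.training_history = meta["history"]
    return model
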