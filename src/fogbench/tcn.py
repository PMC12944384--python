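"""Dilated causal temporal convolutional network (TCN), in numpy.

The classifier is a stack of temporal blocks — each block two causal dilated
1-D convolutions with batch normalization, ReLU and dropout, wrapped in a
residual skip (1x1 projection when channel counts differ) — followed by
global average pooling over time and a linear head producing two logits.
Exponentially increasing dilations (1, 2, 4, 8 by default) widen the
receptive field geometrically while keeping the parameter count flat.

The network is implemented directly on numpy arrays with hand-derived
gradients (forward caches + explicit backward passes) and an Adam optimizer.
The test suite validates every layer's gradient against central finite
differences, and the architecture introspection helpers
(:func:`receptive_field`, :func:`count_parameters`) against empirical
impulse-response support and the summed parameter sizes of a built model.

Causality: every convolution left-pads by ``(kernel_size - 1) * dilation``
so an output at time ``t`` depends only on inputs at times ``<= t``. Note
that train-mode batch normalization couples time steps through the batch
statistics; the causality guarantee applies in inference mode, where the
frozen running statistics are used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "TCNSpec",
    "TCN",
    "build_model",
    "receptive_field",
    "count_parameters",
    "Adam",
    "softmax",
    "focal_loss_batch",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class TCNSpec:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: four blocks with dilations
    1, 2, 4 and 8, kernel size 3, two convolutions per block, 64 hidden
    channels, 30% dropout, two output classes.
    """

    in_channels: int = 6
    n_blocks: int = 4
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    kernel_size: int = 3
    hidden_channels: int = 64
    convs_per_block: int = 2
    dropout: float = 0.3
    n_classes: int = 2
    pooling: str = "global_average"

    def __post_init__(self) -> None:
        for name in ("in_channels", "n_blocks", "kernel_size", "hidden_channels",
                     "convs_per_block", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if len(self.dilations) != self.n_blocks:
            raise ValueError(
                f"dilations has {len(self.dilations)} entries but n_blocks is "
                f"{self.n_blocks}"
            )
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be positive integers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pooling != "global_average":
            raise ValueError(f"unsupported pooling {self.pooling!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TCNSpec":
        d = json.loads(text)
        d["dilations"] = tuple(d["dilations"])
        return cls(**d)


def receptive_field(spec: TCNSpec) -> int:
    """Receptive field in samples: ``1 + sum (kernel-1) * dilation`` over all convs."""
    return 1 + sum(
        (spec.kernel_size - 1) * d
        for d in spec.dilations
        for _ in range(spec.convs_per_block)
    )


def count_parameters(spec: TCNSpec) -> int:
    """Closed-form trainable-parameter total (convs + batchnorm affine + head)."""
    h, k = spec.hidden_channels, spec.kernel_size
    total = 0
    cin = spec.in_channels
    for _ in range(spec.n_blocks):
        c = cin
        for _ in range(spec.convs_per_block):
            total += c * h * k + h  # conv weight + bias
            total += 2 * h  # batchnorm gamma + beta
            c = h
        if cin != h:
            total += cin * h + h  # 1x1 residual projection
        cin = h
    total += h * spec.n_classes + spec.n_classes  # linear head
    return total


# ---------------------------------------------------------------------------
# layers


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class CausalConv1d:
    """1-D dilated convolution with left ("causal") zero padding.

    Activations flow through the network as (channels, batch, time) arrays
    so every convolution collapses to a single (cout, cin*k) x (cin*k, B*T)
    matrix product.
    """

    def __init__(self, cin: int, cout: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (cin * kernel_size))
        self.w = Param((rng.normal(0.0, scale, (cout, cin * kernel_size))).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout
        self.k, self.d = kernel_size, dilation
        self._cols: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        cin, B, T = x.shape
        pad = (self.k - 1) * self.d
        xp = np.pad(x, ((0, 0), (0, 0), (pad, 0)))
        cols = np.empty((cin, self.k, B, T), dtype=x.dtype)
        for j in range(self.k):
            cols[:, j] = xp[:, :, j * self.d : j * self.d + T]
        return cols.reshape(cin * self.k, B * T)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cin, B, T = x.shape
        cols = self._im2col(x)
        self._cols = cols if train else None
        self._in_shape = x.shape
        y = self.w.value @ cols + self.b.value[:, None]
        return y.reshape(self.cout, B, T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cin, B, T = self._in_shape
        dy_flat = dy.reshape(self.cout, B * T)
        self.w.grad += dy_flat @ self._cols.T
        self.b.grad += dy_flat.sum(axis=1)
        dcols = (self.w.value.T @ dy_flat).reshape(cin, self.k, B, T)
        pad = (self.k - 1) * self.d
        dxp = np.zeros((cin, B, T + pad), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, :, j * self.d : j * self.d + T] += dcols[:, j]
        self._cols = None
        return dxp[:, :, pad:]

    def params(self):
        return [self.w, self.b]


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, channels: int, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean = (
                (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv, x.shape[1] * x.shape[2])
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.value[:, None, None]
        s1 = dxhat.sum(axis=(1, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        dx = (inv[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx

    def params(self):
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape, dtype=np.float32) >= self.p
        self._mask = keep.astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class TemporalBlock:
    """[conv -> bn -> relu -> dropout] x convs_per_block, plus residual skip."""

    def __init__(self, cin: int, cout: int, spec: TCNSpec, dilation: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.layers = []
        c = cin
        for _ in range(spec.convs_per_block):
            self.layers.append(CausalConv1d(c, cout, spec.kernel_size, dilation, rng, dtype))
            self.layers.append(BatchNorm1d(cout, dtype))
            self.layers.append(ReLU())
            self.layers.append(Dropout(spec.dropout, rng))
            c = cout
        self.proj = (
            CausalConv1d(cin, cout, 1, 1, rng, dtype) if cin != cout else None
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        res = self.proj.forward(x, train) if self.proj is not None else x
        return out + res

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dres = self.proj.backward(dy) if self.proj is not None else dy
        dx = dy
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        return dx + dres

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        if self.proj is not None:
            out.extend(self.proj.params())
        return out


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(1.0 / cin)
        self.w = Param(rng.normal(0.0, scale, (cin, cout)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        self._train = train
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]


class TCN:
    """The assembled network; accepts windows shaped (batch, time, channels)."""

    def __init__(self, spec: TCNSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.blocks = []
        cin = spec.in_channels
        for d in spec.dilations:
            self.blocks.append(TemporalBlock(cin, spec.hidden_channels, spec, d, rng, dtype))
            cin = spec.hidden_channels
        self.head = Linear(spec.hidden_channels, spec.n_classes, rng, dtype)
        self._T = None

    # -- forward / backward -------------------------------------------------

    def _features_cbt(self, x: np.ndarray, train: bool) -> np.ndarray:
        # (batch, time, channels) -> internal (channels, batch, time)
        x = np.ascontiguousarray(np.transpose(x, (2, 0, 1)), dtype=self.dtype)
        for block in self.blocks:
            x = block.forward(x, train)
        return x

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-pool activations, shaped (batch, hidden, time)."""
        return np.transpose(self._features_cbt(x, train), (1, 0, 2))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (batch, n_classes)."""
        feats = self._features_cbt(x, train)
        self._T = feats.shape[2]
        pooled = feats.mean(axis=2).T
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.head.backward(dlogits)  # (batch, hidden)
        dx = np.repeat(dpooled.T[:, :, None] / self._T, self._T, axis=2)
        for block in reversed(self.blocks):
            dx = block.backward(dx)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities in inference mode, computed in minibatches."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out)

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out = []
        for block in self.blocks:
            out.extend(block.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def state_dict(self) -> dict:
        state = {"params": [p.value.copy() for p in self.params()], "bn": []}
        for block in self.blocks:
            for layer in block.layers:
                if isinstance(layer, BatchNorm1d):
                    state["bn"].append(
                        (layer.running_mean.copy(), layer.running_var.copy())
                    )
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"], strict=True):
            p.value[...] = v
        bns = iter(state["bn"])
        for block in self.blocks:
            for layer in block.layers:
                if isinstance(layer, BatchNorm1d):
                    m, v = next(bns)
                    layer.running_mean[...] = m
                    layer.running_var[...] = v


def build_model(spec: TCNSpec, seed: int = 0, dtype=np.float32) -> TCN:
    """Instantiate a trainable TCN from an architecture spec."""
    return TCN(spec, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss_batch(
    logits: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    gamma: float,
    eps: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    Per window: ``-alpha[y] * (1 - p_y)**gamma * log(p_y)`` with ``p`` the
    softmax probability of the true class, clamped to ``[eps, 1]``.
    """
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    py = np.clip(p[np.arange(B), y], eps, 1.0)
    a = np.asarray(alpha, dtype=np.float64)[y]
    one_minus = 1.0 - py
    loss = float(np.mean(-a * one_minus**gamma * np.log(py)))
    # dL/dp_y, guarding the gamma=0 and p=1 corners.
    if gamma == 0.0:
        dldp = -a / py
    else:
        dldp = a * (
            gamma * np.where(one_minus > 0, one_minus ** (gamma - 1.0), 0.0) * np.log(py)
            - one_minus**gamma / py
        )
    onehot = np.zeros_like(p)
    onehot[np.arange(B), y] = 1.0
    dlogits = (dldp * py)[:, None] * (onehot - p) / B
    return loss, dlogits.astype(logits.dtype)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.wd:
                g = g + self.wd * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )
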