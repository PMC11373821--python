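"""Neural-network building blocks on top of the autodiff core.

Layout convention throughout: a batch of sequences is a ``(batch, length,
channels)`` tensor.  Convolutions are 1D over the length axis with
same-padding (length is changed only by pooling), pooling uses floor
division, and the GRU consumes positions as timesteps.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Layer", "Dense", "Conv1d", "BatchNorm1d", "Dropout",
    "BiGRU", "avg_pool1d", "max_pool1d",
    "global_max_pool", "global_avg_pool", "log_softmax", "Adam",
]


class Layer:
    """Base class: tracks parameters and train/eval mode recursively."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Layer):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Layer):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        item.set_training(mode)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    # variance-preserving init for ReLU layers
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Layer):
    """Same-padded 1D convolution on (batch, length, channels) tensors.

    Implemented as window extraction (k shifted slices of the zero-padded
    input concatenated along the channel axis) followed by one matmul, so
    the heavy lifting is a single BLAS call per layer.
    """

    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel size must be >= 1")
        self.kernel = kernel
        self.n_in = n_in
        self.n_out = n_out
        fan_in = n_in * kernel
        self.w = Tensor(_he(rng, fan_in, (fan_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        k = self.kernel
        if k == 1:
            return x @ self.w + self.b
        left = (k - 1) // 2
        right = k - 1 - left
        zl = Tensor(np.zeros((B, left, C)))
        zr = Tensor(np.zeros((B, right, C)))
        xp = concat([zl, x, zr], axis=1)
        windows = concat([xp[:, i : i + L, :] for i in range(k)], axis=2)
        return windows @ self.w + self.b


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, 1, -1))
            var = Tensor(self.running_var.reshape(1, 1, -1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Layer):
    """Inverted dropout; `rate` is the drop probability. Identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


def avg_pool1d(x: Tensor, size: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping average pooling over the length axis (floor division)."""
    stride = stride or size
    if stride != size:
        raise NotImplementedError("only non-overlapping pooling is supported")
    B, L, C = x.shape
    n = L // size
    if n < 1:
        raise ValueError(f"length {L} too short for pool size {size}")
    xt = x[:, : n * size, :].reshape(B, n, size, C)
    return xt.mean(axis=2)


def max_pool1d(x: Tensor, size: int = 2, stride: int | None = None) -> Tensor:
    stride = stride or size
    if stride != size:
        raise NotImplementedError("only non-overlapping pooling is supported")
    B, L, C = x.shape
    n = L // size
    if n < 1:
        raise ValueError(f"length {L} too short for pool size {size}")
    xt = x[:, : n * size, :].reshape(B, n, size, C)
    return xt.max(axis=2)


def global_max_pool(x: Tensor) -> Tensor:
    """(B, L, C) -> (B, C) max over positions."""
    return x.max(axis=1)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, L, C) -> (B, C) mean over positions."""
    return x.mean(axis=1)


def log_softmax(logits: Tensor) -> Tensor:
    """Numerically stable log-softmax over the last axis."""
    m = logits.max(axis=logits.ndim - 1, keepdims=True)
    shifted = logits - Tensor(m.data)  # constant shift; gradient flows via `logits`
    lse = shifted.exp().sum(axis=logits.ndim - 1, keepdims=True).log()
    return shifted - lse


class GRUCellParams(Layer):
    """Weights of one GRU direction: gates ordered (update z, reset r, candidate n)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Tensor(
            _glorot(rng, n_in, 3 * hidden, (n_in, 3 * hidden)), requires_grad=True
        )
        self.wh = Tensor(
            _glorot(rng, hidden, 3 * hidden, (hidden, 3 * hidden)), requires_grad=True
        )
        self.b = Tensor(np.zeros(3 * hidden), requires_grad=True)

    def run(self, x: Tensor) -> Tensor:
        """Run over (B, L, C); returns the full output sequence (B, L, hidden)."""
        B, L, _ = x.shape
        H = self.hidden
        xw = x @ self.wx + self.b  # (B, L, 3H), precomputed once
        h = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(L):
            xt = xw[:, t, :]
            hw = h @ self.wh
            z = (xt[:, :H] + hw[:, :H]).sigmoid()
            r = (xt[:, H : 2 * H] + hw[:, H : 2 * H]).sigmoid()
            n = (xt[:, 2 * H :] + r * hw[:, 2 * H :]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h.reshape(B, 1, H))
        return concat(outs, axis=1)


class BiGRU(Layer):
    """Bidirectional GRU returning the concatenated full output sequence."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = GRUCellParams(n_in, hidden, rng)
        self.bwd = GRUCellParams(n_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        out_f = self.fwd.run(x)
        out_b = self.bwd.run(x.flip(axis=1)).flip(axis=1)
        return concat([out_f, out_b], axis=2)


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 0.003,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
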