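"""Minimal NumPy neural-network layers with manual reverse-mode gradients.

Supports the 1-D convolutional residual autoencoder and dense discriminator
used for the latent-space models: Conv1d (same padding, im2col), BatchNorm,
ReLU/Sigmoid, Dropout, MaxPool/nearest Upsample, Dense, residual blocks and
an Adam optimizer.  Arrays are ``(batch, channels, length)`` for convolutional
layers and ``(batch, features)`` for dense layers.
"""

from __future__ import annotations

import numpy as np

#: global compute dtype; float32 for training speed, float64 in gradient tests
DTYPE = np.float32


class Param:
    """A learnable array with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: str = "relu"):
        scale = np.sqrt(2.0 / n_in) if gain == "relu" else np.sqrt(1.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv1d(Layer):
    """Same-padded 1-D convolution on (B, C, L) via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 gain: str = "relu"):
        fan_in = c_in * kernel
        scale = np.sqrt(2.0 / fan_in) if gain == "relu" else np.sqrt(1.0 / fan_in)
        self.W = Param(rng.normal(0.0, scale, size=(c_in * kernel, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.c_in = c_in
        self.pad = kernel // 2

    def params(self):
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, L: int) -> np.ndarray:
        # xp: (B, C, L + 2*pad) -> contiguous (B*L, C*kernel)
        s0, s1, s2 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(xp.shape[0], L, self.c_in, self.kernel), strides=(s0, s2, s1, s2)
        )
        return cols.reshape(xp.shape[0] * L, self.c_in * self.kernel)

    def forward(self, x, train):
        B, C, L = x.shape
        xp = np.pad(np.asarray(x, dtype=DTYPE), ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = self._im2col(xp, L)
        self._cols, self._shape = cols, (B, C, L)
        y = cols @ self.W.value + self.b.value  # (B*L, c_out)
        return y.reshape(B, L, -1).transpose(0, 2, 1)

    def backward(self, dy):
        B, C, L = self._shape
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, -1)
        self.W.grad += self._cols.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.value.T).reshape(B, L, C, self.kernel)
        dxp = np.zeros((B, C, L + 2 * self.pad), dtype=DTYPE)
        dct = dcols.transpose(0, 2, 1, 3)
        # scatter-add each kernel tap back onto the padded input
        for k in range(self.kernel):
            dxp[:, :, k : k + L] += dct[:, :, :, k]
        return dxp[:, :, self.pad : self.pad + L]


class BatchNorm(Layer):
    """Batch normalization; per feature on (B, D), per channel on (B, C, L)."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _expand(self, v, ndim):
        return v if ndim == 2 else v[:, None]

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        e = lambda v: self._expand(v, x.ndim)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - e(mean)) * e(self._istd)
        self._train = train
        self._n = x.shape[0] if x.ndim == 2 else x.shape[0] * x.shape[2]
        return e(self.gamma.value) * self._xhat + e(self.beta.value)

    def backward(self, dy):
        axes = self._axes(dy)
        e = lambda v: self._expand(v, dy.ndim)
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * e(self.gamma.value)
        if not self._train:
            return dxhat * e(self._istd)
        n = self._n
        return (
            e(self._istd)
            / n
            * (
                n * dxhat
                - e(dxhat.sum(axis=axes))
                - self._xhat * e((dxhat * self._xhat).sum(axis=axes))
            )
        )


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(DTYPE)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling with kernel 2 on (B, C, L); L must be even."""

    def forward(self, x, train):
        B, C, L = x.shape
        xr = x.reshape(B, C, L // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        dx = np.zeros((B, C, L // 2, 2), dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        return dx.reshape(B, C, L)


class Upsample1d(Layer):
    """Nearest-neighbour upsampling by 2 on (B, C, L)."""

    def forward(self, x, train):
        return np.repeat(x, 2, axis=2)

    def backward(self, dy):
        B, C, L2 = dy.shape
        return dy.reshape(B, C, L2 // 2, 2).sum(axis=3)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, channels: int, length: int):
        self.c, self.l = channels, length

    def forward(self, x, train):
        return x.reshape(x.shape[0], self.c, self.l)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResBlock1d(Layer):
    """Two same-padded convolutions with batch norm, ReLU and an additive skip.

    The skip path is the identity when input and output channel counts match;
    otherwise a 1x1 convolution (with batch norm) projects the input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dropout: float = 0.1):
        self.body = Sequential(
            Conv1d(c_in, c_out, kernel, rng),
            BatchNorm(c_out),
            ReLU(),
            Dropout(dropout, rng),
            Conv1d(c_out, c_out, kernel, rng),
            BatchNorm(c_out),
        )
        if c_in != c_out:
            self.skip = Sequential(Conv1d(c_in, c_out, 1, rng, gain="linear"), BatchNorm(c_out))
        else:
            self.skip = None
        self.out_relu = ReLU()

    def params(self):
        ps = self.body.params()
        if self.skip is not None:
            ps = ps + self.skip.params()
        return ps

    def forward(self, x, train):
        y = self.body.forward(x, train)
        s = x if self.skip is None else self.skip.forward(x, train)
        return self.out_relu.forward(y + s, train)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        dx = self.body.backward(dy)
        dx_skip = dy if self.skip is None else self.skip.backward(dy)
        return dx + dx_skip


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1.0 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    logits = logits.ravel()
    targets = targets.ravel()
    # log(1 + exp(-|x|)) formulation avoids overflow
    loss = np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits))))
    probs = 1.0 / (1.0 + np.exp(-logits))
    grad = (probs - targets)[:, None] / logits.size
    return float(loss), grad


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dloss/dpred)."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def get_state(layer: Layer) -> list[np.ndarray]:
    """Snapshot of all learnable parameters and batch-norm running statistics."""
    state = [p.value.copy() for p in layer.params()]
    for bn in _iter_batchnorms(layer):
        state.append(bn.running_mean.copy())
        state.append(bn.running_var.copy())
    return state


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    ps = layer.params()
    for p, v in zip(ps, state):
        p.value[...] = v
    rest = state[len(ps):]
    for i, bn in enumerate(_iter_batchnorms(layer)):
        bn.running_mean[...] = rest[2 * i]
        bn.running_var[...] = rest[2 * i + 1]


def _iter_batchnorms(layer: Layer):
    if isinstance(layer, BatchNorm):
        yield layer
    for attr in ("layers",):
        for sub in getattr(layer, attr, []):
            yield from _iter_batchnorms(sub)
    for attr in ("body", "skip", "out_relu"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, Layer):
            yield from _iter_batchnorms(sub)
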