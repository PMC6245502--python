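"""A compact numpy engine for 1-D convolutional networks.

Implements exactly the layer set the barcode classifier needs — 1-D
convolution (im2col/GEMM), ReLU, max pooling, batch normalisation,
dropout, additive Gaussian noise, an inception-style parallel branch
block, global average pooling and a dense softmax head — together with
an Adam optimiser and categorical cross-entropy.  Data layout is
``(batch, length, channels)`` in float32 throughout.

Forward passes cache what the backward pass needs; ``training=False``
disables noise and dropout and uses batch-norm running statistics, as in
any standard deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "ReLU", "MaxPool1D", "SamePool1D", "BatchNorm1D", "Dropout",
    "GaussianNoise",
    "Inception1D", "GlobalAvgPool1D", "Dense", "Sequential", "Adam",
    "softmax", "cross_entropy",
]


class Layer:
    """Base layer: parameter-free by default."""

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """Non-trainable arrays that must survive save/load (e.g. BN stats)."""
        return []

    def out_channels(self, in_channels: int) -> int:
        return in_channels

    def out_length(self, in_length: int) -> int:
        return in_length


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L, k*C) with 'same' zero padding."""
    B, L, C = x.shape
    p_left = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (p_left, k - 1 - p_left), (0, 0)))
    s = xp.strides
    col = np.lib.stride_tricks.as_strided(
        xp, shape=(B, L, k, C), strides=(s[0], s[1], s[1], s[2]))
    return col.reshape(B, L, k * C)


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1, He-initialised, via GEMM."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, activation: str = "relu"):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = kernel * in_ch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        self._col = _im2col(x, self.k)
        B, L, _ = x.shape
        out = self._col.reshape(B * L, -1) @ self.W + self.b
        self._in_shape = x.shape
        return out.reshape(B, L, self.out_ch)

    def backward(self, grad):
        B, L, C = self._in_shape
        g = grad.reshape(B * L, self.out_ch)
        self.dW[...] = self._col.reshape(B * L, -1).T @ g
        self.db[...] = g.sum(axis=0)
        dcol = (g @ self.W.T).reshape(B, L, self.k, C)
        p_left = (self.k - 1) // 2
        dxp = np.zeros((B, L + self.k - 1, C), dtype=np.float32)
        for i in range(self.k):
            dxp[:, i:i + L, :] += dcol[:, :, i, :]
        return dxp[:, p_left:p_left + L, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_channels(self, in_channels):
        return self.out_ch


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training, rng):
        B, L, C = x.shape
        if L % self.pool:
            raise ValueError(f"length {L} not divisible by pool {self.pool}")
        self._in_shape = x.shape
        if self.pool == 2:  # fast path: elementwise compare of the halves
            a, b = x[:, 0::2, :], x[:, 1::2, :]
            self._mask2 = a >= b
            return np.where(self._mask2, a, b)
        xr = x.reshape(B, L // self.pool, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        Lp = L // self.pool
        if self.pool == 2:
            dx = np.zeros((B, L, C), dtype=np.float32)
            dx[:, 0::2, :] = np.where(self._mask2, grad, 0)
            dx[:, 1::2, :] = np.where(self._mask2, 0, grad)
            return dx
        dxr = np.zeros((B, Lp, self.pool, C), dtype=np.float32)
        b, l, c = np.ogrid[:B, :Lp, :C]
        dxr[b, l, self._argmax, c] = grad
        return dxr.reshape(B, L, C)

    def out_length(self, in_length):
        return in_length // self.pool


class SamePool1D(Layer):
    """Max pooling with stride 1 and 'same' padding (length preserved);
    used inside the inception pooled path."""

    def __init__(self, window: int = 3):
        self.w = window

    def forward(self, x, training, rng):
        B, L, C = x.shape
        p_left = (self.w - 1) // 2
        xp = np.pad(x, ((0, 0), (p_left, self.w - 1 - p_left), (0, 0)),
                    constant_values=-np.inf)
        s = xp.strides
        col = np.lib.stride_tricks.as_strided(
            xp, shape=(B, L, self.w, C), strides=(s[0], s[1], s[1], s[2]))
        self._argmax = col.argmax(axis=2)
        self._in_shape = x.shape
        return col.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        p_left = (self.w - 1) // 2
        dxp = np.zeros((B, L + self.w - 1, C), dtype=np.float32)
        b, l, c = np.ogrid[:B, :L, :C]
        # argmax index w maps to padded position l + w
        np.add.at(dxp, (b, l + self._argmax, c), grad)
        return dxp[:, p_left:p_left + L, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_sd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = ((x - mean) * self._inv_sd).astype(np.float32)
        self._n = x.shape[0] * x.shape[1]
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.dgamma[...] = (grad * self._xhat).sum(axis=(0, 1))
        self.dbeta[...] = grad.sum(axis=(0, 1))
        n = self._n
        gxh = grad * self.gamma
        return (self._inv_sd / n) * (
            n * gxh - gxh.sum(axis=(0, 1))
            - self._xhat * (gxh * self._xhat).sum(axis=(0, 1))
        ).astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return [self.running_mean, self.running_var]


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GaussianNoise(Layer):
    """Additive input noise, active only during training — the network's
    stand-in for amplitude distortion of the signal."""

    def __init__(self, sd: float):
        self.sd = sd

    def forward(self, x, training, rng):
        if not training or self.sd == 0:
            return x
        return x + np.float32(self.sd) * rng.standard_normal(x.shape, dtype=np.float32)

    def backward(self, grad):
        return grad


class GlobalAvgPool1D(Layer):
    """Collapse each filter's trace to its mean: (B, L, C) -> (B, C)."""

    def forward(self, x, training, rng):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return (np.repeat(grad[:, None, :], self._L, axis=1) / self._L).astype(np.float32)

    def out_length(self, in_length):
        return 1


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                            size=(in_dim, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Inception1D(Layer):
    """Parallel branches concatenated along the channel axis.

    Each branch is a list of layers applied in sequence; branch outputs
    must share (batch, length) and are concatenated on channels.
    """

    def __init__(self, branches: list[list[Layer]]):
        self.branches = branches

    def forward(self, x, training, rng):
        outs = []
        self._splits = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, training, rng)
            outs.append(h)
            self._splits.append(h.shape[-1])
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        dx = None
        offset = 0
        for branch, width in zip(self.branches, self._splits):
            g = grad[..., offset:offset + width]
            offset += width
            for layer in reversed(branch):
                g = layer.backward(g)
            dx = g if dx is None else dx + g
        return dx

    def params(self):
        return [p for br in self.branches for l in br for p in l.params()]

    def grads(self):
        return [g for br in self.branches for l in br for g in l.grads()]

    def state(self):
        return [s for br in self.branches for l in br for s in l.state()]

    def out_channels(self, in_channels):
        return sum(br[-1].out_channels(
            _chain_channels(br[:-1], in_channels)) for br in self.branches)


def _chain_channels(layers: list[Layer], in_channels: int) -> int:
    for l in layers:
        in_channels = l.out_channels(in_channels)
    return in_channels


class Sequential:
    """An ordered layer stack with a softmax classification head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng()
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def state(self) -> list[np.ndarray]:
        return [s for l in self.layers for s in l.state()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, inference mode, batched."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy; y is integer labels."""
    p = np.clip(probs[np.arange(y.size), y], 1e-12, None)
    return float(-np.log(p).mean())


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
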