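"""Minimal NumPy neural-network primitives with manual backpropagation.

Float64 throughout; every layer caches its forward activations and is
used exactly once per forward pass, so ``backward`` must be called in
reverse forward order.  Gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "LayerNorm",
    "Dropout",
    "Embedding",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Adam",
]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = math.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, (d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._xf = x.reshape(-1, x.shape[-1])
        y = self._xf @ self.W + self.b
        return y.reshape(*x.shape[:-1], self.W.shape[1])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads[0] += self._xf.T @ dyf
        self.grads[1] += dyf.sum(axis=0)
        return (dyf @ self.W.T).reshape(self._shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LayerNorm(Layer):
    def __init__(self, d: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = xc * self._inv
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        lead = tuple(range(dy.ndim - 1))
        self.grads[0] += (dy * xhat).sum(axis=lead)
        self.grads[1] += dy.sum(axis=lead)
        dxhat = dy * self.gamma
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        else:
            self._mask = 1.0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Embedding(Layer):
    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.table = rng.normal(0.0, 0.02, (n_tokens, d))
        self.params = [self.table]
        self.grads = [np.zeros_like(self.table)]

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        return self.table[idx]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.grads[0], self._idx, dy)


class MultiHeadSelfAttention(Layer):
    def __init__(
        self, d: int, heads: int, dropout: float, rng: np.random.Generator
    ) -> None:
        super().__init__()
        if d % heads != 0:
            raise ValueError("embed dim must be divisible by heads")
        self.heads = heads
        self.dh = d // heads
        self.q = Dense(d, d, rng)
        self.k = Dense(d, d, rng)
        self.v = Dense(d, d, rng)
        self.o = Dense(d, d, rng)
        self.drop = Dropout(dropout, rng)
        for layer in (self.q, self.k, self.v, self.o):
            self.params += layer.params
            self.grads += layer.grads

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, l, _ = x.shape
        return x.reshape(b, l, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, l, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        q = self._split(self.q.forward(x))
        k = self._split(self.k.forward(x))
        v = self._split(self.v.forward(x))
        scores = q @ k.swapaxes(-1, -2) / math.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        attn_d = self.drop.forward(attn, train)
        out = attn_d @ v
        self._q, self._k, self._v = q, k, v
        self._attn, self._attn_d = attn, attn_d
        return self.o.forward(self._merge(out))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d_out = self._split(self.o.backward(dy))
        d_attn_d = d_out @ self._v.swapaxes(-1, -2)
        dv = self._attn_d.swapaxes(-1, -2) @ d_out
        d_attn = self.drop.backward(d_attn_d)
        a = self._attn
        d_scores = a * (d_attn - (d_attn * a).sum(axis=-1, keepdims=True))
        d_scores /= math.sqrt(self.dh)
        dq = d_scores @ self._k
        dk = d_scores.swapaxes(-1, -2) @ self._q
        dx = self.q.backward(self._merge(dq))
        dx += self.k.backward(self._merge(dk))
        dx += self.v.backward(self._merge(dv))
        return dx


class TransformerBlock(Layer):
    """Post-norm block: MHA + residual + LN, then FFN + residual + LN."""

    def __init__(
        self,
        d: int,
        heads: int,
        dropout: float,
        rng: np.random.Generator,
        ff_mult: int = 4,
    ) -> None:
        super().__init__()
        self.attn = MultiHeadSelfAttention(d, heads, dropout, rng)
        self.drop1 = Dropout(dropout, rng)
        self.ln1 = LayerNorm(d)
        self.ff1 = Dense(d, ff_mult * d, rng)
        self.relu = ReLU()
        self.ff2 = Dense(ff_mult * d, d, rng)
        self.drop2 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(d)
        for layer in (self.attn, self.ln1, self.ff1, self.ff2, self.ln2):
            self.params += layer.params
            self.grads += layer.grads

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = self.drop1.forward(self.attn.forward(x, train), train)
        x1 = self.ln1.forward(x + a)
        f = self.ff2.forward(self.relu.forward(self.ff1.forward(x1)))
        f = self.drop2.forward(f, train)
        return self.ln2.forward(x1 + f)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.ln2.backward(dy)
        dx1 = d + self.ff1.backward(
            self.relu.backward(self.ff2.backward(self.drop2.backward(d)))
        )
        d1 = self.ln1.backward(dx1)
        return d1 + self.attn.backward(self.drop1.backward(d1))


class Adam:
    def __init__(
        self,
        params: Sequence[np.ndarray],
        grads: Sequence[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.grads = list(grads)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0
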