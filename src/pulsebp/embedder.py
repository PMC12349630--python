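"""Tabular transformer feature embedder.

Categorical columns are mapped to learned token embeddings and passed
through a stack of multi-head self-attention transformer blocks; the
attended embeddings are flattened, concatenated with the (already
scaled) continuous features and fed to a two-hidden-layer ReLU
perceptron with widths (4*d, 2*d) over the combined width d, trained to
regress (SBP, DBP) jointly under squared-error loss with Adam.  The
penultimate-layer activations (dimension 2*d) are the embedding exposed
to the stacking meta-learner via :meth:`transform`.

Training is fully deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn import Adam, Dense, Dropout, Embedding, ReLU, TransformerBlock

__all__ = ["EmbedderConfig", "TabTransformerEmbedder"]


@dataclass(frozen=True)
class EmbedderConfig:
    embed_dim: int = 64
    depth: int = 6
    heads: int = 8
    dropout: float = 0.2
    mlp_hidden_mults: tuple[int, int] = (4, 2)
    epochs: int = 100
    batch: int = 64
    learn_rate: float = 1e-3
    patience: int = 10
    val_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        if self.depth < 1 or self.heads < 1:
            raise ValueError("depth and heads must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class _Net:
    """Transformer over categorical tokens + MLP head over [tokens, cont]."""

    def __init__(
        self,
        cardinalities: Sequence[int],
        n_cont: int,
        config: EmbedderConfig,
        rng: np.random.Generator,
    ) -> None:
        cfg = config
        self.n_cat = len(cardinalities)
        self.offsets = np.cumsum([0] + list(cardinalities[:-1]))
        self.layers: list = []
        if self.n_cat:
            self.embedding = Embedding(int(sum(cardinalities)), cfg.embed_dim, rng)
            self.blocks = [
                TransformerBlock(cfg.embed_dim, cfg.heads, cfg.dropout, rng)
                for _ in range(cfg.depth)
            ]
            self.layers += [self.embedding] + self.blocks
        self.d = self.n_cat * cfg.embed_dim + n_cont
        m1, m2 = cfg.mlp_hidden_mults
        self.h1 = Dense(self.d, m1 * self.d, rng)
        self.a1 = ReLU()
        self.do1 = Dropout(cfg.dropout, rng)
        self.h2 = Dense(m1 * self.d, m2 * self.d, rng)
        self.a2 = ReLU()
        self.do2 = Dropout(cfg.dropout, rng)
        self.out = Dense(m2 * self.d, 2, rng)
        self.layers += [self.h1, self.h2, self.out]
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def forward(
        self, x_cat: np.ndarray, x_cont: np.ndarray, train: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        parts = []
        if self.n_cat:
            tokens = self.embedding.forward(x_cat + self.offsets)
            for block in self.blocks:
                tokens = block.forward(tokens, train)
            parts.append(tokens.reshape(tokens.shape[0], -1))
        parts.append(x_cont)
        z = np.concatenate(parts, axis=1)
        self._split_at = z.shape[1] - x_cont.shape[1]
        h1 = self.do1.forward(self.a1.forward(self.h1.forward(z)), train)
        penult = self.do2.forward(self.a2.forward(self.h2.forward(h1)), train)
        return self.out.forward(penult), penult

    def backward(self, d_pred: np.ndarray) -> None:
        d = self.out.backward(d_pred)
        d = self.h2.backward(self.a2.backward(self.do2.backward(d)))
        dz = self.h1.backward(self.a1.backward(self.do1.backward(d)))
        if self.n_cat:
            d_tokens = dz[:, : self._split_at].reshape(
                dz.shape[0], self.n_cat, -1
            )
            for block in reversed(self.blocks):
                d_tokens = block.backward(d_tokens)
            self.embedding.backward(d_tokens)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class TabTransformerEmbedder:
    """Fit/transform wrapper around the numeric network."""

    def __init__(self, config: EmbedderConfig | None = None) -> None:
        self.config = config or EmbedderConfig()
        self._net: _Net | None = None

    @property
    def embedding_dim(self) -> int:
        if self._net is None:
            raise RuntimeError("embedder not fitted")
        return self.config.mlp_hidden_mults[1] * self._net.d

    def fit(
        self,
        x_cat: np.ndarray,
        cardinalities: Sequence[int],
        x_cont: np.ndarray,
        y: np.ndarray,
    ) -> "TabTransformerEmbedder":
        """Train jointly on (SBP, DBP) with early stopping on a held-out split."""
        cfg = self.config
        x_cat = np.asarray(x_cat, dtype=int).reshape(len(x_cont), -1)
        x_cont = np.asarray(x_cont, dtype=float)
        y = np.asarray(y, dtype=float).reshape(len(x_cont), 2)
        if x_cat.shape[1] == 0:
            warnings.warn(
                "no categorical channel; continuous-only perceptron", stacklevel=2
            )
        rng = np.random.default_rng(cfg.seed)
        net = _Net(cardinalities, x_cont.shape[1], cfg, rng)

        self._y_mean = y.mean(axis=0)
        self._y_sd = np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
        yz = (y - self._y_mean) / self._y_sd

        n = len(x_cont)
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_frac * n))) if n >= 10 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            train_idx, val_idx = perm, perm[:0]

        opt = Adam(net.params, net.grads, lr=cfg.learn_rate)
        best_loss = np.inf
        best_state = [p.copy() for p in net.params]
        stale = 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(train_idx.size)
            for start in range(0, train_idx.size, cfg.batch):
                idx = train_idx[order[start : start + cfg.batch]]
                pred, _ = net.forward(x_cat[idx], x_cont[idx], train=True)
                err = pred - yz[idx]
                net.zero_grad()
                net.backward(2.0 * err / err.size)
                opt.step()
            monitor = val_idx if val_idx.size else train_idx
            pred, _ = net.forward(x_cat[monitor], x_cont[monitor], train=False)
            loss = float(np.mean((pred - yz[monitor]) ** 2))
            if loss < best_loss - 1e-9:
                best_loss = loss
                best_state = [p.copy() for p in net.params]
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        for p, b in zip(net.params, best_state):
            p[...] = b
        self._net = net
        self._cardinalities = list(cardinalities)
        return self

    def transform(self, x_cat: np.ndarray, x_cont: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (n, 2*d) in eval mode."""
        if self._net is None:
            raise RuntimeError("embedder not fitted")
        x_cat = np.asarray(x_cat, dtype=int).reshape(len(x_cont), -1)
        _, penult = self._net.forward(
            x_cat, np.asarray(x_cont, dtype=float), train=False
        )
        return penult

    def predict(self, x_cat: np.ndarray, x_cont: np.ndarray) -> np.ndarray:
        """(SBP, DBP) prediction on the original mmHg scale."""
        if self._net is None:
            raise RuntimeError("embedder not fitted")
        x_cat = np.asarray(x_cat, dtype=int).reshape(len(x_cont), -1)
        pred, _ = self._net.forward(
            x_cat, np.asarray(x_cont, dtype=float), train=False
        )
        return pred * self._y_sd + self._y_mean
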