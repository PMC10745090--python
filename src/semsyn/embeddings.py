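"""Token-level embedding construction.

Two families of embeddings feed the encoding models:

* **lexical** (context-insensitive): GloVe-style vectors trained here from
  a co-occurrence matrix, looked up token by token;
* **contextual**: any causal provider satisfying :class:`ContextualProvider`
  — one vector per position, depending only on the current and preceding
  tokens.  A transformer is one such provider; :class:`ToyContextualProvider`
  is a desk-scale one (exponentially decaying average of per-symbol base
  vectors) used to exercise the extraction protocols and the context
  manipulations end to end.

Extraction protocols mirror the two ways a causal model is probed over a
long stimulus: a sliding window of fixed length with stride one, reading
the next-to-last position, and fixed-context batches of length k+5 where
only the current token's vector is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import scipy.sparse as sp

from .corpus import FeatureStream

__all__ = [
    "CooccurrenceMatrix", "EmbeddingMatrix", "ContextualProvider",
    "ToyContextualProvider", "GloveModel", "DivergenceError",
    "build_cooccurrence", "train_glove", "lookup_embeddings",
    "sliding_window_extract", "fixed_context_extract",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite; try a smaller learning rate."""


class LookupError_(KeyError):
    """A stream symbol is missing from the vector table."""


@dataclass
class CooccurrenceMatrix:
    """Symmetric weighted co-occurrence counts over a vocabulary."""

    counts: sp.csr_matrix
    symbols: list[str]
    window: int
    weighting: str

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}


@dataclass
class EmbeddingMatrix:
    """One d-dimensional vector per stimulus-stream token (w × d)."""

    X: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (tokens × dims)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def n_tokens(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@runtime_checkable
class ContextualProvider(Protocol):
    """Causal sequence embedder: one vector per position, past-only."""

    d: int

    def embed(self, symbols: list[str]) -> np.ndarray:  # (len, d)
        ...


class ToyContextualProvider:
    """Exponentially decaying average of per-symbol base vectors.

    Position ``p`` gets ``sum_{j<=p} decay^(p-j) base[sym_j]`` divided by the
    corresponding weight sum, so the output is a weighted mean (linear in the
    base vectors, causal by construction).  As ``decay -> 0`` this reduces to
    a plain lookup of the current token's base vector.

    ``decay`` may be a scalar or a per-dimension vector: with a vector the
    provider integrates different embedding channels over different
    timescales, the way a real contextual model mixes fast (lexical) and
    slow (discourse) information.
    """

    def __init__(self, base: dict[str, np.ndarray], decay):
        decay = np.asarray(decay, dtype=float)
        if np.any(decay <= 0.0) or np.any(decay >= 1.0):
            raise ValueError("decay must lie strictly between 0 and 1")
        self.base = {k: np.asarray(v, dtype=float) for k, v in base.items()}
        self.decay = decay
        dims = {v.shape[0] for v in self.base.values()}
        if len(dims) != 1:
            raise ValueError("all base vectors must share one dimensionality")
        self.d = dims.pop()
        if decay.ndim == 1 and decay.shape[0] != self.d:
            raise ValueError("per-dimension decay must match dimensionality")

    def embed(self, symbols: list[str]) -> np.ndarray:
        n = len(symbols)
        out = np.empty((n, self.d))
        acc = np.zeros(self.d)
        wsum = np.zeros(self.d) if self.decay.ndim else 0.0
        for p, sym in enumerate(symbols):
            acc = self.decay * acc + self.base[sym]
            wsum = self.decay * wsum + 1.0
            out[p] = acc / wsum
        return out


def build_cooccurrence(stream: FeatureStream, window: int,
                       weighting: str = "uniform") -> CooccurrenceMatrix:
    """Accumulate symmetric co-occurrence counts within a token window.

    ``uniform`` adds 1 per co-occurring pair; ``inverse-distance`` adds
    ``1/d`` for a pair at distance ``d`` (the GloVe convention).  Both
    directions are accumulated, so the matrix is symmetric.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if weighting not in ("uniform", "inverse-distance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    symbols = sorted(set(stream.symbols))
    index = {s: i for i, s in enumerate(symbols)}
    v = len(symbols)
    ids = np.array([index[s] for s in stream.symbols], dtype=int)
    rows, cols, vals = [], [], []
    n = len(ids)
    for d in range(1, window + 1):
        if d >= n:
            break
        w = 1.0 if weighting == "uniform" else 1.0 / d
        left, right = ids[:-d], ids[d:]
        rows.append(left); cols.append(right)
        rows.append(right); cols.append(left)
        vals.append(np.full(n - d, w)); vals.append(np.full(n - d, w))
    if rows:
        counts = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(v, v)).tocsr()
    else:
        counts = sp.csr_matrix((v, v))
    return CooccurrenceMatrix(counts=counts, symbols=symbols,
                              window=window, weighting=weighting)


def glove_weight(x, x_max: float = 100.0, alpha: float = 0.75):
    """Clipped weighting f(x) = min((x/x_max)^alpha, 1) on co-occurrence counts."""
    return np.minimum((np.asarray(x, dtype=float) / x_max) ** alpha, 1.0)


@dataclass
class GloveModel:
    """Fixed per-symbol vectors (center + context sums) with training losses."""

    symbols: list[str]
    vectors: np.ndarray  # (vocab, d): W + W̃
    losses: list[float]
    params: dict = field(default_factory=dict)  # raw W, Wc, b, bc

    def as_table(self) -> dict[str, np.ndarray]:
        return {s: self.vectors[i] for i, s in enumerate(self.symbols)}


def train_glove(cooc: CooccurrenceMatrix, d: int, epochs: int = 20,
                x_max: float = 100.0, alpha: float = 0.75,
                lr: float = 0.05, seed: int = 0) -> GloveModel:
    """Weighted least squares on log co-occurrence counts (full-batch AdaGrad).

    Minimises ``J = sum_ij f(X_ij) (w_i·w̃_j + b_i + b̃_j − log X_ij)^2`` over
    the nonzero entries; the reported loss is J divided by the number of
    nonzero pairs.  The per-symbol embedding is ``w + w̃``.
    """
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    coo = cooc.counts.tocoo()
    i_idx, j_idx, x = coo.row, coo.col, coo.data
    v = len(cooc.symbols)
    rng = np.random.default_rng(seed)
    W = (rng.random((v, d)) - 0.5) / d
    Wc = (rng.random((v, d)) - 0.5) / d
    b = (rng.random(v) - 0.5) / d
    bc = (rng.random(v) - 0.5) / d
    gW = np.ones_like(W); gWc = np.ones_like(Wc)
    gb = np.ones_like(b); gbc = np.ones_like(bc)

    if len(x) == 0:
        return GloveModel(symbols=cooc.symbols, vectors=W + Wc, losses=[],
                          params={"W": W, "Wc": Wc, "b": b, "bc": bc})

    logx = np.log(x)
    f = glove_weight(x, x_max=x_max, alpha=alpha)
    losses: list[float] = []
    for _ in range(epochs):
        diff = (np.einsum("nd,nd->n", W[i_idx], Wc[j_idx])
                + b[i_idx] + bc[j_idx] - logx)
        loss = float(np.sum(f * diff * diff) / len(x))
        if not np.isfinite(loss):
            raise DivergenceError(
                "GloVe training loss diverged; try a smaller learning rate")
        losses.append(loss)
        fd = f * diff  # d J / d diff, up to factor 2 folded into lr
        grad_wi = fd[:, None] * Wc[j_idx]
        grad_wj = fd[:, None] * W[i_idx]
        dW = np.zeros_like(W); dWc = np.zeros_like(Wc)
        np.add.at(dW, i_idx, grad_wi)
        np.add.at(dWc, j_idx, grad_wj)
        db = np.zeros_like(b); dbc = np.zeros_like(bc)
        np.add.at(db, i_idx, fd)
        np.add.at(dbc, j_idx, fd)
        # AdaGrad: accumulate squared gradients, scale the step
        gW += dW * dW; gWc += dWc * dWc; gb += db * db; gbc += dbc * dbc
        W -= lr * dW / np.sqrt(gW)
        Wc -= lr * dWc / np.sqrt(gWc)
        b -= lr * db / np.sqrt(gb)
        bc -= lr * dbc / np.sqrt(gbc)
    return GloveModel(symbols=cooc.symbols, vectors=W + Wc, losses=losses,
                      params={"W": W, "Wc": Wc, "b": b, "bc": bc})


def glove_loss(cooc: CooccurrenceMatrix, W, Wc, b, bc,
               x_max: float = 100.0, alpha: float = 0.75) -> float:
    """Evaluate the mean weighted GloVe loss for given parameters (oracle aid)."""
    coo = cooc.counts.tocoo()
    diff = (np.einsum("nd,nd->n", W[coo.row], Wc[coo.col])
            + b[coo.row] + bc[coo.col] - np.log(coo.data))
    f = glove_weight(coo.data, x_max=x_max, alpha=alpha)
    return float(np.sum(f * diff * diff) / len(coo.data))


def lookup_embeddings(stream: FeatureStream, vectors: dict[str, np.ndarray],
                      oov: str = "error") -> EmbeddingMatrix:
    """w × d matrix of fixed per-symbol vectors in stream order."""
    dims = {np.asarray(v).shape[0] for v in vectors.values()}
    if len(dims) != 1:
        raise ValueError("vector table must have a single dimensionality")
    d = dims.pop()
    X = np.zeros((len(stream), d))
    for i, sym in enumerate(stream.symbols):
        vec = vectors.get(sym)
        if vec is None:
            if oov == "zero":
                continue
            raise LookupError_(f"symbol {sym!r} not in vector table")
        X[i] = vec
    return EmbeddingMatrix(X=X, provenance={"provider": "lookup", "mode": "lexical",
                                            "oov": oov})


def sliding_window_extract(provider: ContextualProvider, stream: FeatureStream,
                           N: int) -> EmbeddingMatrix:
    """Sliding window of size N, stride 1, reading the next-to-last position.

    Token t's vector comes from the window ending one token *after* t, at
    the next-to-last position (which is t itself).  Early tokens use the
    longest available prefix window; the final token (no successor) is read
    from the last position of the final window.
    """
    if N < 3:
        raise ValueError("window size N must be >= 3")
    syms = stream.symbols
    w = len(syms)
    if w == 0:
        return EmbeddingMatrix(X=np.zeros((0, provider.d)),
                               provenance={"provider": "contextual",
                                           "mode": "sliding", "N": N})
    X = np.empty((w, provider.d))
    for t in range(w):
        end = min(t + 2, w)              # window ends one token after t
        start = max(0, end - N)
        window = syms[start:end]
        X[t] = provider.embed(window)[t - start]
    return EmbeddingMatrix(X=X, provenance={"provider": "contextual",
                                            "mode": "sliding", "N": N})


def fixed_context_extract(provider: ContextualProvider, stream: FeatureStream,
                          k: int) -> EmbeddingMatrix:
    """Bounded-context extraction: sequences of length k+5, current token kept.

    Token t's vector is computed from the sequence of its ``min(t, k+4)``
    predecessors plus token t itself, so nothing more than k+4 positions in
    the past can influence it.
    """
    if k < 1:
        raise ValueError("context bound k must be >= 1")
    syms = stream.symbols
    w = len(syms)
    X = np.empty((w, provider.d))
    span = k + 5
    for t in range(w):
        start = max(0, t + 1 - span)
        X[t] = provider.embed(syms[start:t + 1])[-1]
    return EmbeddingMatrix(X=X, provenance={"provider": "contextual",
                                            "mode": "fixed-context", "k": k})
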