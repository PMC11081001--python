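"""Self-attention feature head.

The head computes the classic scaled-free attention map: correlation scores
P = X Y^T between query-side and key-side matrices, a row-wise softmax
turning scores into probabilities, and the attended output AM = softmax(P) V.
A flattened input vector is projected into X (T x T), Y (T x T) and
V (T x J) by three weight matrices; the attended map is flattened back to a
fixed-length feature vector (2,048 by default, matching the deep-feature
contract of the extraction stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AttentionInputs:
    """Query-side X, key-side Y (both T x T) and value V (T x J)."""

    X: np.ndarray
    Y: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.X.shape[1]:
            raise ValueError("X must be square")
        if self.Y.shape != self.X.shape:
            raise ValueError("Y must match X's shape")
        if self.V.ndim != 2 or self.V.shape[0] != self.X.shape[0]:
            raise ValueError("V row count must equal T")
        for m in (self.X, self.Y, self.V):
            if not np.all(np.isfinite(m)):
                raise ValueError("attention inputs must be finite")


@dataclass
class AttentionMap:
    """Raw scores P, row-stochastic softmax SMP, attended output AM."""

    P: np.ndarray
    SMP: np.ndarray
    AM: np.ndarray


@dataclass
class AttentionHeadConfig:
    """Projection wiring for the head.

    ``seq_len`` (T) is the side of the square score matrix obtained by
    projecting the flattened input; ``feature_dim`` must be divisible by it
    so the attended T x J map flattens to the advertised output length.
    Weights may be supplied or drawn once from a seeded RNG.
    """

    input_dim: int
    feature_dim: int = 2048
    seq_len: int = 32
    Wq: np.ndarray | None = None
    Wk: np.ndarray | None = None
    Wv: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if self.feature_dim % self.seq_len != 0:
            raise ValueError("feature_dim must be divisible by seq_len")
        t, j = self.seq_len, self.feature_dim // self.seq_len
        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(self.input_dim)
        if self.Wq is None:
            self.Wq = rng.normal(0.0, scale, size=(t * t, self.input_dim))
        if self.Wk is None:
            self.Wk = rng.normal(0.0, scale, size=(t * t, self.input_dim))
        if self.Wv is None:
            self.Wv = rng.normal(0.0, scale, size=(t * j, self.input_dim))
        if self.Wq.shape != (t * t, self.input_dim) or self.Wk.shape != (t * t, self.input_dim):
            raise ValueError("Wq/Wk must map input_dim -> T*T")
        if self.Wv.shape != (t * j, self.input_dim):
            raise ValueError("Wv must map input_dim -> T*J")

    @property
    def value_dim(self) -> int:
        return self.feature_dim // self.seq_len


def row_softmax(P: np.ndarray) -> np.ndarray:
    """Row-wise softmax with per-row max subtraction for overflow safety."""
    P = np.asarray(P, dtype=float)
    if P.size == 0:
        raise ValueError("empty matrix")
    if not np.all(np.isfinite(P)):
        raise ValueError("entries must be finite")
    shifted = P - P.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def self_attention(inp: AttentionInputs) -> AttentionMap:
    """P = X Y^T, SMP = row_softmax(P), AM = SMP V."""
    P = inp.X @ inp.Y.T
    SMP = row_softmax(P)
    return AttentionMap(P=P, SMP=SMP, AM=SMP @ inp.V)


def attention_head(features: np.ndarray, cfg: AttentionHeadConfig) -> np.ndarray:
    """Project a flat feature vector through the head; returns feature_dim values."""
    features = np.asarray(features, dtype=float).ravel()
    if features.size != cfg.input_dim:
        raise ValueError(f"expected input of length {cfg.input_dim}, got {features.size}")
    t, j = cfg.seq_len, cfg.value_dim
    X = (cfg.Wq @ features).reshape(t, t)
    Y = (cfg.Wk @ features).reshape(t, t)
    V = (cfg.Wv @ features).reshape(t, j)
    am = self_attention(AttentionInputs(X=X, Y=Y, V=V)).AM
    return am.reshape(cfg.feature_dim)
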