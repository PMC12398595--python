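"""Single-head scaled dot-product self-attention over feature batches.

A minibatch of feature vectors is treated as n tokens of dimension d:
Q = XW_Q, K = XW_K, V = XW_V, and the output is
softmax(QKᵀ/√d_k)·V.  Both GAN networks prepend this block (as a
residual, out = X + attention(X), with d_k = d) so that global
dependencies among features are modelled before the MLP; zeroing the
three weight matrices reduces the block to the identity, which is how
the self-attention ablation is realised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, constant

__all__ = ["AttentionWeights", "softmax", "self_attention", "self_attention_t"]


@dataclass(frozen=True)
class AttentionWeights:
    """Learned projections W_Q, W_K, W_V, each d × d_k."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray

    def __post_init__(self):
        for name in ("W_Q", "W_K", "W_V"):
            W = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, W)
            if W.ndim != 2:
                raise ValueError(f"{name} must be a matrix")
            if not np.isfinite(W).all():
                raise ValueError(f"{name} contains non-finite entries")
            if W.shape != self.W_Q.shape:
                raise ValueError("W_Q, W_K, W_V must share one d × d_k shape")

    @property
    def d(self) -> int:
        return self.W_Q.shape[0]

    @property
    def d_k(self) -> int:
        return self.W_Q.shape[1]

    @classmethod
    def zeros(cls, d: int, d_k: int | None = None) -> "AttentionWeights":
        d_k = d if d_k is None else d_k
        z = np.zeros((d, d_k))
        return cls(z, z.copy(), z.copy())


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis.

    Shift-invariant: softmax(z + c) == softmax(z).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.isfinite(z).all():
        raise ValueError("softmax input must be finite")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def self_attention_t(X: Tensor, W_Q: Tensor, W_K: Tensor, W_V: Tensor) -> Tensor:
    """Differentiable attention used inside the networks."""
    d_k = W_Q.shape[1]
    Q = X @ W_Q
    K = X @ W_K
    V = X @ W_V
    logits = (Q @ K.T) / float(np.sqrt(d_k))
    return logits.softmax_rows() @ V


def self_attention(X: np.ndarray, w: AttentionWeights) -> np.ndarray:
    """Attention output softmax(QKᵀ/√d_k)·V for a batch X (n × d)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if X.shape[1] != w.d:
        raise ValueError(
            f"shape mismatch: X has {X.shape[1]} columns but weights expect {w.d}"
        )
    out = self_attention_t(
        constant(X), constant(w.W_Q), constant(w.W_K), constant(w.W_V)
    )
    return out.value
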