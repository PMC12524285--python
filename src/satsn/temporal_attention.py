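"""Temporal attention: per-frame reweighting of fast-pathway features.

A feature map X ∈ R^{T×C×H×W} is compressed into two length-T descriptors by
average and max pooling over (C, H, W). Each descriptor passes through a
shared bottleneck (W_n reduces T → T/r, ReLU, W_m expands T/r → T, no
biases), the two branch outputs are summed, and a sigmoid squashes the result
into per-frame weights M ∈ (0,1)^T that rescale the corresponding frames:

    M = sigmoid( W_m ReLU(W_n avg) + W_m ReLU(W_n max) ),   X'_t = M_t X_t.

With all weights zero the logits vanish and every frame is scaled by
sigmoid(0) = 1/2 exactly — the closed-form anchor used by the unit tests.
The reduction ratio r (default 2) must divide T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor
from .nn import Module, parameter, xavier


@dataclass
class TemporalAttentionParams:
    """Shared-bottleneck weights: W_n maps T -> T/r, W_m maps T/r -> T."""

    W_n: np.ndarray  # (T/r, T)
    W_m: np.ndarray  # (T, T/r)
    r: int

    def __post_init__(self) -> None:
        self.W_n = np.asarray(self.W_n, dtype=float)
        self.W_m = np.asarray(self.W_m, dtype=float)
        if self.r < 1:
            raise ValueError("r must be >= 1")
        tr, T = self.W_n.shape
        if self.W_m.shape != (T, tr) or tr * self.r != T:
            raise ValueError(
                f"inconsistent shapes: W_n {self.W_n.shape}, W_m {self.W_m.shape}, r={self.r}"
            )


def make_ta_params(T: int, r: int = 2, rng: np.random.Generator | None = None
                   ) -> TemporalAttentionParams:
    """Construct parameters for sequence length T; r must divide T."""
    if r < 1 or T % r:
        raise ValueError(f"reduction ratio r={r} must divide T={T}")
    tr = T // r
    if rng is None:
        W_n = np.zeros((tr, T))
        W_m = np.zeros((T, tr))
    else:
        W_n = xavier(rng, T, tr, (tr, T))
        W_m = xavier(rng, tr, T, (T, tr))
    return TemporalAttentionParams(W_n=W_n, W_m=W_m, r=r)


def temporal_descriptor(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average- and max-pool each frame's (C, H, W) block to a scalar."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 4 or X.size == 0:
        raise ValueError(f"expected nonempty (T,C,H,W) features, got shape {X.shape}")
    T = X.shape[0]
    flat = X.reshape(T, -1)
    return flat.mean(axis=1), flat.max(axis=1)


def ta_forward(X: np.ndarray, params: TemporalAttentionParams) -> np.ndarray:
    """Temporal weights M ∈ (0,1)^T for a feature stack X (T,C,H,W)."""
    avg, mx = temporal_descriptor(X)
    T = avg.shape[0]
    if params.W_n.shape[1] != T:
        raise ValueError(f"params built for T={params.W_n.shape[1]}, features have T={T}")
    logits = params.W_m @ np.maximum(params.W_n @ avg, 0.0) \
        + params.W_m @ np.maximum(params.W_n @ mx, 0.0)
    return 1.0 / (1.0 + np.exp(-logits))


def apply_ta(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Rescale frame t by M_t (broadcast over C, H, W); shape preserved."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 1 or M.shape[0] != X.shape[0]:
        raise ValueError(f"len(M)={M.shape} does not match T={X.shape[0]}")
    return X * M.reshape(-1, *([1] * (X.ndim - 1)))


class TemporalAttention(Module):
    """Batched differentiable TA block for (B, T, C, H, W) feature tensors."""

    def __init__(self, T: int, r: int = 2, rng: np.random.Generator | None = None):
        if r < 1 or T % r:
            raise ValueError(f"reduction ratio r={r} must divide T={T}")
        p = make_ta_params(T, r, rng)
        self.W_n = parameter(p.W_n)
        self.W_m = parameter(p.W_m)
        self.T = T
        self.r = r

    def weights(self, x: Tensor) -> Tensor:
        """(B, T) temporal weights from a (B, T, C, H, W) tensor."""
        B, T = x.shape[0], x.shape[1]
        flat = x.reshape(B, T, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        logits = (avg @ self.W_n.transpose(1, 0)).relu() @ self.W_m.transpose(1, 0) \
            + (mx @ self.W_n.transpose(1, 0)).relu() @ self.W_m.transpose(1, 0)
        return logits.sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        M = self.weights(x)
        B, T = x.shape[0], x.shape[1]
        return x * M.reshape(B, T, 1, 1, 1)
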