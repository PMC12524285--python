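"""Neural-network layers on top of the autodiff engine.

Contains exactly the blocks the two-stream architecture needs: linear layers,
layer norm, multi-head joint space-time self-attention, pre-norm transformer
blocks, 3D convolutions, a cross-entropy loss, and SGD with momentum.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, conv3d


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Minimal container: collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj) -> None:
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = parameter(xavier(rng, n_in, n_out, (n_in, n_out)))
        self.bias = parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Joint space-time attention: every token attends to all tokens."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def attention_weights(self, x: Tensor) -> Tensor:
        """(B, heads, N, N) softmax attention matrix (diagnostic path)."""
        B, N, D = x.shape
        qkv = self.qkv(x).reshape(B, N, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, h, N, dh)
        q = qkv.index_select(0, [0]).reshape(B, self.n_heads, N, self.head_dim)
        k = qkv.index_select(0, [1]).reshape(B, self.n_heads, N, self.head_dim)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        return scores.softmax(axis=-1)

    def __call__(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        qkv = self.qkv(x).reshape(B, N, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)
        q = qkv.index_select(0, [0]).reshape(B, self.n_heads, N, self.head_dim)
        k = qkv.index_select(0, [1]).reshape(B, self.n_heads, N, self.head_dim)
        v = qkv.index_select(0, [2]).reshape(B, self.n_heads, N, self.head_dim)
        attn = ((q @ k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 2.0):
        hidden = int(dim * mlp_ratio)
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, stride: tuple[int, int, int] = (1, 1, 1),
                 bias: bool = True):
        kt, kh, kw = kernel
        fan_in = c_in * kt * kh * kw
        self.weight = parameter(xavier(rng, fan_in, c_out, (c_out, c_in, kt, kh, kw)))
        self.bias = parameter(np.zeros(c_out)) if bias else None
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class ids (B,)."""
    B, K = logits.shape
    z = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    logsumexp = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - logsumexp
    onehot = np.zeros((B, K))
    onehot[np.arange(B), np.asarray(labels, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / B)


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``clip_norm`` rescales the global gradient norm when it exceeds the
    threshold, which keeps early large-batch spikes from derailing momentum.
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params
                     if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * scale * p.grad
            p.data = p.data + v
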