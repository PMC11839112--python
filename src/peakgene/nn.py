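"""Neural-network building blocks on top of :mod:`peakgene.autograd`.

Layers follow the standard pre-LayerNorm transformer recipe: each block
computes ``x + MHA(LN(x))`` then ``x + FFN(LN(x))``.  No positional
encoding exists anywhere in this stack — the input is a *set* of peak
tokens, and permutation invariance of the pooled [CLS] state is a tested
contract of the model, not an accident.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter, Tensor, gather_rows

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "FeedForward",
    "MultiHeadAttention",
    "TransformerBlock",
    "Adam",
]


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_rows, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        idx = np.asarray(idx)
        if idx.size and (idx.min() < 0 or idx.max() >= self.weight.data.shape[0]):
            raise IndexError(
                f"index out of range for embedding table of size {self.weight.data.shape[0]}"
            )
        return gather_rows(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class FeedForward(Module):
    """Two-layer GELU MLP, hidden width ``mult * dim``."""

    def __init__(self, dim: int, rng: np.random.Generator, mult: int = 4):
        self.fc1 = Linear(dim, mult * dim, rng)
        self.fc2 = Linear(mult * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiHeadAttention(Module):
    """Standard scaled-dot-product attention with key padding mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        bias = np.where(mask[:, None, None, :], 0.0, -1e9)
        attn = (scores + bias).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-LN block; dropout applies to the two residual branches and is
    active only when a training rng is supplied (inverted scaling)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 4, dropout: float = 0.0):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff = FeedForward(dim, rng, ff_mult)
        self.dropout = dropout

    def _drop(self, t: Tensor, train_rng) -> Tensor:
        if train_rng is None or self.dropout <= 0:
            return t
        keep = (train_rng.random(t.shape) >= self.dropout) / (1.0 - self.dropout)
        return t * keep

    def __call__(self, x: Tensor, mask: np.ndarray, train_rng=None) -> Tensor:
        x = x + self._drop(self.attn(self.ln1(x), mask), train_rng)
        return x + self._drop(self.ff(self.ln2(x)), train_rng)


class Adam:
    """Adam optimizer with optional per-step learning-rate schedule."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data


def warmup_cosine(step: int, total_steps: int, base_lr: float, warmup_frac: float = 0.1) -> float:
    """Linear warmup to ``base_lr`` then cosine decay to 10% of it."""
    warmup = max(1, int(total_steps * warmup_frac))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    frac = (step - warmup) / max(1, total_steps - warmup)
    return base_lr * (0.1 + 0.9 * 0.5 * (1 + math.cos(math.pi * frac)))
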