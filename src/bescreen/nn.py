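"""Minimal reverse-mode autodiff engine and Transformer building blocks.

The attention models in this package run on plain numpy. This module
provides the small tensor/op set they need — broadcasting-aware add/mul,
batched matmul, softmax (with additive masks), layer normalization,
embedding lookup, dropout, and fused stable losses — together with the
standard layers (Linear, LayerNorm, multi-head attention, position-wise
feed-forward) and an Adam optimizer. Gradients are checked against finite
differences in the test suite.

All arrays are float64; integer index arrays and masks are passed as plain
ndarrays (constants from the graph's point of view).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = Tensor(a.data + b.data, (a, b))
        out._backward = lambda g: (
            a._accum(_unbroadcast(g, a.shape)),
            b._accum(_unbroadcast(g, b.shape)),
        )
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = Tensor(a.data * b.data, (a, b))
        out._backward = lambda g: (
            a._accum(_unbroadcast(g * b.data, a.shape)),
            b._accum(_unbroadcast(g * a.data, b.shape)),
        )
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = Tensor(np.matmul(a.data, b.data), (a, b))

        def back(g: np.ndarray) -> None:
            a._accum(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.shape))
            b._accum(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape))

        out._backward = back
        return out

    def scale(self, c: float) -> "Tensor":
        out = Tensor(self.data * c, (self,))
        out._backward = lambda g: self._accum(g * c)
        return out

    def add_const(self, c: np.ndarray) -> "Tensor":
        out = Tensor(self.data + c, (self,))
        out._backward = lambda g: self._accum(_unbroadcast(g, self.shape))
        return out

    def mul_const(self, c: np.ndarray) -> "Tensor":
        out = Tensor(self.data * c, (self,))
        out._backward = lambda g: self._accum(_unbroadcast(g * c, self.shape))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out


def softmax(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, with an optional additive mask (e.g. -1e9)."""
    z = x.data + mask if mask is not None else x.data
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, (x,))
    out._backward = lambda g: x._accum((g - (g * y).sum(axis=-1, keepdims=True)) * y)
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, (x, gamma, beta))

    def back(g: np.ndarray) -> None:
        axes = tuple(range(g.ndim - 1))
        gamma._accum((g * xhat).sum(axis=axes))
        beta._accum(g.sum(axis=axes))
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        x._accum(inv * (dxhat - m1 - xhat * m2))

    out._backward = back
    return out


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``table[idx]`` with scatter-add gradient."""
    out = Tensor(table.data[idx], (table,))

    def back(g: np.ndarray) -> None:
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, idx, g)

    out._backward = back
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x.mul_const(keep)


def bce_with_logits(z: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean masked binary cross-entropy on logits (numerically stable)."""
    n = mask.sum()
    if n == 0:
        raise ValueError("bce_with_logits: empty mask")
    per = np.maximum(z.data, 0) - z.data * y + np.log1p(np.exp(-np.abs(z.data)))
    out = Tensor((per * mask).sum() / n, (z,))
    sig = 1.0 / (1.0 + np.exp(-z.data))
    out._backward = lambda g: z._accum(g * (sig - y) * mask / n)
    return out


def weighted_softmax_xent(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray, weights: np.ndarray
) -> Tensor:
    """Weighted masked cross-entropy over the last axis of *logits*.

    ``targets`` holds class indices, ``mask`` zeroes out unused slots, and
    ``weights`` (broadcastable to mask's shape) weights rows; the loss is
    normalized by the total effective weight.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    w = np.broadcast_to(np.asarray(weights, dtype=float), mask.shape) * mask
    norm = w.sum()
    if norm <= 0:
        raise ValueError("weighted_softmax_xent: zero total weight")
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    out = Tensor(-(w * picked).sum() / norm, (logits,))
    soft = np.exp(logp)
    onehot = np.zeros_like(soft)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
    out._backward = lambda g: logits._accum(g * (soft - onehot) * (w / norm)[..., None])
    return out


# --------------------------------------------------------------------------
# layers


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_xavier(rng, d_in, d_out))
        self.b = Tensor(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W) + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d))
        self.beta = Tensor(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class MultiHeadAttention:
    """Scaled dot-product attention with multi-head support.

    Used for encoder self-attention (q_in is kv_in), decoder masked
    self-attention (causal additive mask) and decoder cross-attention
    (kv_in = encoder output).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(
        self, q_in: Tensor, kv_in: Tensor, mask: np.ndarray | None = None
    ) -> tuple[Tensor, np.ndarray]:
        B, Lq, D = q_in.shape
        Lk = kv_in.shape[1]

        def split(t: Tensor, L: int) -> Tensor:
            return t.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

        q = split(self.wq(q_in), Lq)
        k = split(self.wk(kv_in), Lk)
        v = split(self.wv(kv_in), Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)).scale(1.0 / np.sqrt(self.dh))
        attn = softmax(scores, mask)  # (B, H, Lq, Lk)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.wo(ctx), attn.data.mean(axis=1)  # head-averaged map for inspection

    @property
    def params(self) -> list[Tensor]:
        return [*self.wq.params, *self.wk.params, *self.wv.params, *self.wo.params]


class FeedForward:
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.l1 = Linear(d_model, d_ff, rng)
        self.l2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())

    @property
    def params(self) -> list[Tensor]:
        return [*self.l1.params, *self.l2.params]


class EncoderLayer:
    """Self-attention -> add & norm -> feed-forward -> add & norm."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.mha = MultiHeadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln2 = LayerNorm(d_model)

    def __call__(
        self,
        x: Tensor,
        rng: np.random.Generator,
        p_drop: float = 0.0,
        training: bool = False,
    ) -> tuple[Tensor, np.ndarray]:
        a, attn_map = self.mha(x, x)
        x = self.ln1(x + dropout(a, p_drop, rng, training))
        f = self.ff(x)
        x = self.ln2(x + dropout(f, p_drop, rng, training))
        return x, attn_map

    @property
    def params(self) -> list[Tensor]:
        return [*self.mha.params, *self.ln1.params, *self.ff.params, *self.ln2.params]


class DecoderLayer:
    """Masked self-attention -> cross-attention -> feed-forward, each add & norm."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.self_mha = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_mha = MultiHeadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln3 = LayerNorm(d_model)

    def __call__(
        self,
        x: Tensor,
        enc: Tensor,
        causal_mask: np.ndarray,
        rng: np.random.Generator,
        p_drop: float = 0.0,
        training: bool = False,
    ) -> tuple[Tensor, np.ndarray]:
        a, _ = self.self_mha(x, x, causal_mask)
        x = self.ln1(x + dropout(a, p_drop, rng, training))
        c, cross_map = self.cross_mha(x, enc)
        x = self.ln2(x + dropout(c, p_drop, rng, training))
        f = self.ff(x)
        x = self.ln3(x + dropout(f, p_drop, rng, training))
        return x, cross_map

    @property
    def params(self) -> list[Tensor]:
        return [
            *self.self_mha.params, *self.cross_mha.params,
            *self.ln1.params, *self.ln2.params, *self.ff.params, *self.ln3.params,
        ]


def causal_mask(L: int) -> np.ndarray:
    """Additive mask forbidding attention to future slots."""
    return np.where(np.triu(np.ones((L, L)), k=1) > 0, -1e9, 0.0)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
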