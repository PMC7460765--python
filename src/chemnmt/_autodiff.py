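"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation builds a node
holding its inputs and a closure that accumulates gradients into them.
``Tensor.backward()`` runs the tape in reverse topological order.  Only
the operations required by the character-level seq2seq models live here
(dense algebra, pointwise nonlinearities, embedding lookup, 1-D
convolution, masked softmax / cross-entropy).  All computation is float32.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "scale",
    "tanh",
    "sigmoid",
    "relu",
    "concat",
    "swap_last",
    "reshape",
    "slice_cols",
    "embedding",
    "conv1d",
    "masked_softmax",
    "softmax_cross_entropy",
    "Adam",
    "global_norm_clip",
    "glorot_uniform",
]

_DTYPE = np.float32


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = True,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def constant(data: np.ndarray) -> Tensor:
    """A tensor that takes no gradient (masks, inputs)."""
    return Tensor(data, requires_grad=False)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    if any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=tuple(parents), backward=backward)
    return Tensor(data, requires_grad=False)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def scale(a: Tensor, s: float) -> Tensor:
    out_data = a.data * _DTYPE(s)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * _DTYPE(s))

    return _node(out_data, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports batched operands via numpy matmul rules."""
    out_data = a.data @ b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._parents:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bwd)


def swap_last(a: Tensor) -> Tensor:
    """Transpose the two trailing axes."""
    out_data = np.swapaxes(a.data, -1, -2)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(np.swapaxes(g, -1, -2))

    return _node(out_data, (a,), bwd)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g.reshape(a.data.shape))

    return _node(out_data, (a,), bwd)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * (1.0 - out_data * out_data))

    return _node(out_data, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * (a.data > 0.0))

    return _node(out_data, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), bwd)


def slice_cols(a: Tensor, start: int, stop: int) -> Tensor:
    """Slice the last axis of ``a``; gradient scatters back into place."""
    out_data = a.data[..., start:stop]

    def bwd(g: np.ndarray) -> None:
        full = np.zeros_like(a.data)
        full[..., start:stop] = g
        a._accumulate(full)

    return _node(out_data, (a,), bwd)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def bwd(g: np.ndarray) -> None:
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        table._accumulate(full)

    return _node(out_data, (table,), bwd)


def conv1d(x: Tensor, w: Tensor, b: Tensor, padding: str) -> Tensor:
    """1-D convolution over (batch, time, channels) input.

    ``w`` has shape (kernel, c_in, c_out).  ``padding`` is ``"same"``
    (centred zero padding) or ``"causal"`` (all padding on the left, so
    output at step t sees input steps <= t only).
    """
    k = w.data.shape[0]
    if padding == "same":
        left = (k - 1) // 2
    elif padding == "causal":
        left = k - 1
    else:
        raise ValueError(f"unknown padding {padding!r}")
    right = k - 1 - left
    B, T, c_in = x.data.shape
    c_out = w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    # im2col: one BLAS matmul instead of k small ones
    cols = np.empty((B, T, k * c_in), dtype=_DTYPE)
    for j in range(k):
        cols[:, :, j * c_in : (j + 1) * c_in] = xp[:, j : j + T, :]
    cols_flat = cols.reshape(B * T, k * c_in)
    w_flat = w.data.reshape(k * c_in, c_out)
    out_data = (cols_flat @ w_flat).reshape(B, T, c_out) + b.data

    def bwd(g: np.ndarray) -> None:
        g_flat = g.reshape(B * T, c_out)
        if b.requires_grad:
            b._accumulate(g_flat.sum(axis=0))
        if w.requires_grad:
            w._accumulate((cols_flat.T @ g_flat).reshape(w.data.shape))
        if x.requires_grad or x._parents:
            gcols = (g_flat @ w_flat.T).reshape(B, T, k, c_in)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j : j + T, :] += gcols[:, :, j, :]
            x._accumulate(gxp[:, left : left + T, :])

    return _node(out_data, (x, w, b), bwd)


def masked_softmax(scores: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; positions where ``mask`` is 0 get weight 0."""
    z = scores.data
    if mask is not None:
        z = np.where(mask, z, _DTYPE(-1e9))
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def bwd(g: np.ndarray) -> None:
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        gs = out_data * (g - dot)
        if mask is not None:
            gs = np.where(mask, gs, 0.0)
        scores._accumulate(gs)

    return _node(out_data, (scores,), bwd)


def softmax_cross_entropy(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray
) -> tuple[Tensor, np.ndarray]:
    """Summed cross-entropy over rows of ``logits`` (n, vocab).

    ``targets`` holds class indices (n,); rows with ``mask`` 0 contribute
    nothing.  Returns (scalar loss tensor, per-row argmax) so training can
    track accuracy without a second forward pass.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    idx = np.arange(n)
    logp = z[idx, targets] - np.log(e.sum(axis=-1))
    loss_val = -(logp * mask).sum()
    argmax = probs.argmax(axis=-1)

    def bwd(g: np.ndarray) -> None:
        gl = probs.copy()
        gl[idx, targets] -= 1.0
        gl *= (g * mask)[:, None]
        logits._accumulate(gl)

    return _node(np.asarray(loss_val), (logits,), bwd), argmax


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    if len(shape) == 3:  # conv kernels: (k, c_in, c_out)
        fan_in = shape[0] * shape[1]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def global_norm_clip(params: Iterable[Tensor], max_norm: float) -> None:
    grads = [p.grad for p in params if p.grad is not None]
    if not grads:
        return
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm and total > 0:
        factor = _DTYPE(max_norm / total)
        for g in grads:
            g *= factor


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * (p.grad * p.grad)
            p.data -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
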