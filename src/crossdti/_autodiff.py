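"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The training core needs only a small, fixed set of differentiable
operations (batched matmul, broadcast add/mul, slicing, concatenation,
ReLU/sigmoid, masked softmax, embedding lookup, and a numerically stable
binary cross-entropy on logits), so a compact tape-based engine keeps the
package dependency-light while remaining fully testable: every operation
here is checked against finite differences in the test suite.

All tensors are float32; gradients are float32 as well.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product with NumPy broadcasting of leading axes.

    Two broadcast patterns are routed through single large GEMMs instead
    of NumPy's per-slice batched loop, because they dominate training
    cost: (batch..., n, m) @ (m, p) with a 2-D right operand, and the
    per-head projection (B, 1, n, m) @ (h, m, p).
    """
    a, b = _as_tensor(a), _as_tensor(b)
    ad, bd = a.data, b.data

    if bd.ndim == 2 and ad.ndim >= 2:
        lead = ad.shape[:-1]
        data = (ad.reshape(-1, ad.shape[-1]) @ bd).reshape(*lead, bd.shape[1])

        def backward(g):
            g2 = g.reshape(-1, bd.shape[1])
            if a.requires_grad:
                a._accumulate((g2 @ bd.T).reshape(ad.shape))
            if b.requires_grad:
                b._accumulate(ad.reshape(-1, ad.shape[-1]).T @ g2)

        return _make(data, (a, b), backward)

    if (bd.ndim == 3 and ad.ndim == 4 and ad.shape[1] == 1
            and bd.shape[0] > 1):
        B, _, n, m = ad.shape
        h, _, p = bd.shape
        # (B*n, m) @ (m, h*p) -> (B, h, n, p)
        flat = ad.reshape(B * n, m) @ bd.transpose(1, 0, 2).reshape(m, h * p)
        data = flat.reshape(B, n, h, p).transpose(0, 2, 1, 3)

        def backward(g):
            if a.requires_grad:
                ga = np.tensordot(g, bd, axes=([1, 3], [0, 2]))
                a._accumulate(ga.reshape(ad.shape))
            if b.requires_grad:
                gb = np.tensordot(ad[:, 0], g, axes=([0, 1], [0, 2]))
                b._accumulate(gb.transpose(1, 0, 2))

        return _make(data, (a, b), backward)

    data = ad @ bd

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(bd, -1, -2)
            a._accumulate(_unbroadcast(ga, ad.shape))
        if b.requires_grad:
            gb = np.swapaxes(ad, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, bd.shape))

    return _make(data, (a, b), backward)


# -- shape ops ----------------------------------------------------------

def getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] += g  # basic slicing never aliases within one index
            a._accumulate(full)

    return _make(data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


# -- nonlinearities -----------------------------------------------------

def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = _sigmoid_np(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient goes to the first argument."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.maximum(a.data, b.data)
    take_a = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    return _make(data, (a, b), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g2, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor) -> Tensor:
    n = a.data.size
    return mul(tsum(a), 1.0 / n)


# -- attention / model-specific ops -------------------------------------

def masked_softmax(scores: Tensor, key_mask: np.ndarray | None) -> Tensor:
    """Softmax over the last axis, excluding masked-out key positions.

    key_mask broadcasts against `scores` and is True for attendable keys.
    Raises if any row has no attendable position.
    """
    x = scores.data
    if key_mask is not None:
        mask = np.broadcast_to(key_mask, x.shape)
        if not mask.any(axis=-1).all():
            raise ValueError("no attendable positions")
        x = np.where(mask, x, -np.inf)
    shifted = x - x.max(axis=-1, keepdims=True)
    ex = np.exp(shifted)
    data = (ex / ex.sum(axis=-1, keepdims=True)).astype(_DTYPE)

    def backward(g):
        if scores.requires_grad:
            inner = (g * data).sum(axis=-1, keepdims=True)
            scores._accumulate(data * (g - inner))

    return _make(data, (scores,), backward)


def _scatter_add_rows(n_rows: int, idx: np.ndarray,
                      rows: np.ndarray) -> np.ndarray:
    """Sum `rows` (k, d) into an (n_rows, d) array at `idx` (k,) via a
    sort + reduceat sweep (much faster than np.add.at)."""
    out = np.zeros((n_rows, rows.shape[1]), dtype=rows.dtype)
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    starts = np.flatnonzero(np.r_[True, sorted_idx[1:] != sorted_idx[:-1]])
    out[sorted_idx[starts]] = np.add.reduceat(rows[order], starts, axis=0)
    return out


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup `table[indices]` with scatter-add backward."""
    indices = np.asarray(indices)
    data = table.data[indices]

    def backward(g):
        if table.requires_grad:
            flat_idx = indices.reshape(-1)
            rows = g.reshape(flat_idx.shape[0], -1)
            table._accumulate(_scatter_add_rows(table.data.shape[0],
                                                flat_idx, rows))

    return _make(data, (table,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from pre-sigmoid logits."""
    z = logits.data
    y = np.asarray(targets, dtype=_DTYPE)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    data = loss.mean()

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(g * (_sigmoid_np(z) - y) / z.size)

    return _make(data, (logits,), backward)


# -- parameters / optimiser ---------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimiser (Kingma & Ba) over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= (self.lr * (m / b1t) /
                       (np.sqrt(v / b2t) + self.eps)).astype(_DTYPE)
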