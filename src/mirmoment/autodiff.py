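"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is a deliberately small tape-based engine: a :class:`Tensor` wraps a
float64 ndarray, records its parents and a backward closure, and
``Tensor.backward()`` runs the chain rule over a topological ordering.  It
provides exactly the primitives the moment-convolution network needs
(broadcasting arithmetic, matmul, elementwise powers, sigmoid/tanh/relu,
softplus, clipping, signed log1p, row/column gather, reductions) — nothing
more.  Everything is float64 and single-threaded numpy, so runs are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def _accum(p: "Tensor", g: np.ndarray) -> None:
        if p.requires_grad:
            p.grad = g if p.grad is None else p.grad + g

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bw(g):
            Tensor._accum(a, _unbroadcast(g, a.shape))
            Tensor._accum(b, _unbroadcast(g, b.shape))

        return Tensor._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._node(-a.data, (a,), lambda g: Tensor._accum(a, -g))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bw(g):
            Tensor._accum(a, _unbroadcast(g * b.data, a.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.shape))

        return Tensor._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bw(g):
            Tensor._accum(a, _unbroadcast(g / b.data, a.shape))
            Tensor._accum(b, _unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._node(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bw(g):
            g2 = np.atleast_2d(g)
            bd = np.atleast_2d(b.data) if b.data.ndim == 1 else b.data
            ad = np.atleast_2d(a.data) if a.data.ndim == 1 else a.data
            if b.data.ndim == 1:  # (n,d)@(d,) -> (n,)
                Tensor._accum(a, np.outer(g, b.data).reshape(a.shape))
                Tensor._accum(b, a.data.T @ g)
            elif a.data.ndim == 1:  # (d,)@(d,m) -> (m,)
                Tensor._accum(a, (g2 @ bd.T).reshape(a.shape))
                Tensor._accum(b, np.outer(a.data, g))
            else:
                Tensor._accum(a, g2 @ bd.T)
                Tensor._accum(b, ad.T @ g2)

        return Tensor._node(a.data @ b.data, (a, b), bw)

    def ipow(self, k: int):
        """Elementwise integer power with constant exponent."""
        a = self
        if k == 0:
            return Tensor(np.ones_like(a.data))
        if k == 1:
            return a

        def bw(g):
            Tensor._accum(a, g * k * a.data ** (k - 1))

        return Tensor._node(a.data**k, (a,), bw)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._node(out_data, (a,), lambda g: Tensor._accum(a, g * out_data))

    def log(self):
        a = self
        return Tensor._node(np.log(a.data), (a,), lambda g: Tensor._accum(a, g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._node(
            out_data, (a,), lambda g: Tensor._accum(a, g * 0.5 / out_data)
        )

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._node(
            out_data, (a,), lambda g: Tensor._accum(a, g * (1.0 - out_data**2))
        )

    def sigmoid(self):
        a = self
        out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # stable logistic
        return Tensor._node(
            out_data, (a,), lambda g: Tensor._accum(a, g * out_data * (1.0 - out_data))
        )

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._node(
            np.where(mask, a.data, 0.0), (a,), lambda g: Tensor._accum(a, g * mask)
        )

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        a = self
        out_data = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * a.data))
        return Tensor._node(out_data, (a,), lambda g: Tensor._accum(a, g * sig))

    def clip(self, lo: float, hi: float):
        """Clamp to [lo, hi]; gradient is zero outside the interval."""
        a = self
        inside = (a.data >= lo) & (a.data <= hi)
        return Tensor._node(
            np.clip(a.data, lo, hi), (a,), lambda g: Tensor._accum(a, g * inside)
        )

    def maximum0(self):
        """max(x, 0) with subgradient 0 at the kink (alias of relu)."""
        return self.relu()

    def signed_log1p(self):
        """sign(x) * log(1 + |x|); gradient 1 / (1 + |x|)."""
        a = self
        out_data = np.sign(a.data) * np.log1p(np.abs(a.data))
        return Tensor._node(
            out_data, (a,), lambda g: Tensor._accum(a, g / (1.0 + np.abs(a.data)))
        )

    # -- reductions and shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                Tensor._accum(a, np.broadcast_to(g, a.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                Tensor._accum(a, np.broadcast_to(ge, a.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        return Tensor._node(
            a.data.reshape(*shape),
            (a,),
            lambda g: Tensor._accum(a, g.reshape(a.shape)),
        )

    def take_rows(self, idx):
        """Gather rows (axis 0); backward scatter-adds into the source
        (as a one-hot matmul, which is much faster than np.add.at)."""
        a = self
        idx = np.asarray(idx, dtype=np.int64)

        def bw(g):
            if a.requires_grad:
                onehot = np.zeros((len(idx), a.data.shape[0]))
                onehot[np.arange(len(idx)), idx] = 1.0
                flat = onehot.T @ g.reshape(len(idx), -1)
                Tensor._accum(a, flat.reshape(a.shape))

        return Tensor._node(a.data[idx], (a,), bw)

    def take_cols(self, idx):
        """Gather columns (axis 1)."""
        a = self
        idx = np.asarray(idx, dtype=np.int64)

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full.T, idx, g.T)
                Tensor._accum(a, full)

        return Tensor._node(a.data[:, idx], (a,), bw)

    def transpose(self, *axes):
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._node(
            a.data.transpose(axes),
            (a,),
            lambda g: Tensor._accum(a, g.transpose(inv)),
        )

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        parts = tuple(tensors)
        sizes = [t.data.shape[axis] for t in parts]

        def bw(g):
            offset = 0
            for t, s in zip(parts, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                Tensor._accum(t, g[tuple(sl)])
                offset += s

        return Tensor._node(
            np.concatenate([t.data for t in parts], axis=axis), parts, bw
        )

    # -- batched linear algebra ---------------------------------------------

    @staticmethod
    def graph_matmul(adj: np.ndarray, p: "Tensor") -> "Tensor":
        """Apply a constant (n, n) matrix to each slice of a (K, n, d) stack.

        Uses per-slice BLAS matmul so the K = 1 slice is bit-identical to
        ``adj @ p[k]``.
        """
        adj = np.asarray(adj, dtype=np.float64)

        def bw(g):
            Tensor._accum(p, np.stack([adj.T @ g[k] for k in range(g.shape[0])]))

        out = np.stack([adj @ p.data[k] for k in range(p.data.shape[0])])
        return Tensor._node(out, (p,), bw)

    @staticmethod
    def bmm(a: "Tensor", b: "Tensor") -> "Tensor":
        """Batched matmul: (K, n, d) @ (K, d, h) -> (K, n, h)."""

        def bw(g):
            K = g.shape[0]
            Tensor._accum(a, np.stack([g[k] @ b.data[k].T for k in range(K)]))
            Tensor._accum(b, np.stack([a.data[k].T @ g[k] for k in range(K)]))

        out = np.stack(
            [a.data[k] @ b.data[k] for k in range(a.data.shape[0])]
        )
        return Tensor._node(out, (a, b), bw)

    # -- backprop -----------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Softmax along ``axis``; with ``mask`` (0/1 constant array broadcastable
    to x) masked entries get exactly zero probability and no gradient."""
    shift = np.max(
        np.where(mask > 0, x.data, -np.inf) if mask is not None else x.data,
        axis=axis,
        keepdims=True,
    )
    shift = np.where(np.isfinite(shift), shift, 0.0)
    e = (x - Tensor(shift)).exp()
    if mask is not None:
        e = e * Tensor(np.asarray(mask, dtype=np.float64))
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer with decoupled-style L2 weight decay added to the
    gradient (the convention of classic Adam implementations)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
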