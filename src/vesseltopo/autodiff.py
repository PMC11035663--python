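"""Minimal tape-based reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the segmentation network and its losses
need: broadcasted arithmetic, reductions, matrix products, 3D convolution
(kernel 1 or 3, zero padding, stride 1), 2x2x2 max-pooling with argmax
indices and its index-driven unpooling, a stride-1 3x3x3 max filter (soft
dilation), activations, and softmax — plus an Adam optimizer.

Tensors hold float arrays; ``Tensor.backward()`` accumulates gradients into
every ``requires_grad`` leaf.  Gradient checks against central finite
differences live in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Tensor", "as_tensor", "concat", "where", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind != "f" else None)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()
        self.name = name

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo_order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo_order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo_order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _needs_tape(self, *others) -> bool:
        return self.requires_grad or any(
            isinstance(o, Tensor) and o.requires_grad for o in others
        )

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # keep dtype: no array promotion
            out = Tensor(self.data + other, self.requires_grad)
            if out.requires_grad:
                out._parents = (self,)

                def bwd(g):
                    self._accum(g)

                out._backward = bwd
            return out
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self._needs_tape(other))
        if out.requires_grad:
            out._parents = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))

            out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, self.requires_grad)
            if out.requires_grad:
                out._parents = (self,)

                def bwd(g):
                    self._accum(g * other)

                out._backward = bwd
            return out
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self._needs_tape(other))
        if out.requires_grad:
            out._parents = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))

            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        out = Tensor(np.power(self.data, p), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                self._accum(g * p * np.power(self.data, p - 1.0))

            out._backward = bwd
        return out

    def square(self):
        return self * self

    def sqrt(self):
        return self.pow(0.5)

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            sign = np.sign(self.data)

            def bwd(g):
                self._accum(g * sign)

            out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                self._accum(g * out.data)

            out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                self._accum(g / self.data)

            out._backward = bwd
        return out

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            shape = self.data.shape

            def bwd(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, shape).copy())

            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            orig = self.data.shape

            def bwd(g):
                self._accum(g.reshape(orig))

            out._backward = bwd
        return out

    def matmul(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self._needs_tape(other))
        if out.requires_grad:
            out._parents = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)

            out._backward = bwd
        return out

    # -- activations --------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            mask = self.data > 0

            def bwd(g):
                self._accum(g * mask)

            out._backward = bwd
        return out

    def sigmoid(self):
        out = Tensor(expit(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                self._accum(g * out.data * (1.0 - out.data))

            out._backward = bwd
        return out

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            sig = expit(self.data)

            def bwd(g):
                self._accum(g * sig)

            out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum((g - dot) * y)

            out._backward = bwd
        return out

    # -- structured ops -----------------------------------------------------
    def conv3d(self, weight: "Tensor", bias: "Tensor" = None):
        """3D convolution, NCDHW layout, stride 1, zero 'same' padding.

        weight: (C_out, C_in, k, k, k) with k odd (1 or 3 in practice).
        Forward and both gradients are computed as k^3 shifted tensor
        contractions, avoiding any large im2col buffer.
        """
        x, w = self.data, weight.data
        n, c, d, h, ww = x.shape
        co, ci, k, _, _ = w.shape
        if ci != c:
            raise ValueError(f"channel mismatch: input {c}, weight {ci}")
        p = k // 2
        k3 = k * k * k
        wmat = w.reshape(co, c * k3)

        def _cols(arr):
            ap = np.pad(arr, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else arr
            v = sliding_window_view(ap, (k, k, k), axis=(2, 3, 4))
            return np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
                n * d * h * ww, c * k3
            )

        cols = _cols(x)
        out_data = (cols @ wmat.T).reshape(n, d, h, ww, co).transpose(0, 4, 1, 2, 3)
        if bias is not None:
            out_data += bias.data.reshape(1, co, 1, 1, 1)
        out = Tensor(out_data, self._needs_tape(weight, bias))
        if out.requires_grad:
            out._parents = tuple(t for t in (self, weight, bias) if t is not None)

            def bwd(g):
                gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(n * d * h * ww, co)
                if bias is not None and bias.requires_grad:
                    bias._accum(g.sum(axis=(0, 2, 3, 4)))
                if weight.requires_grad:
                    weight._accum((gm.T @ _cols(x)).reshape(w.shape))
                if self.requires_grad:
                    gcols = (gm @ wmat).reshape(n, d, h, ww, c, k, k, k)
                    gxp = np.zeros(
                        (n, c, d + 2 * p, h + 2 * p, ww + 2 * p), dtype=g.dtype
                    )
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                gxp[:, :, i : i + d, j : j + h, l : l + ww] += (
                                    gcols[..., i, j, l].transpose(0, 4, 1, 2, 3)
                                )
                    self._accum(gxp[:, :, p : p + d, p : p + h, p : p + ww] if p else gxp)

            out._backward = bwd
        return out

    def max_pool3d(self):
        """2x2x2 stride-2 max pooling; returns (pooled, index record).

        Window argmax ties break toward the lowest linear index within the
        window.  The index record is consumed by :meth:`max_unpool3d`.
        """
        n, c, d, h, w = self.data.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2x2 pooling, got {(d, h, w)}")
        d2, h2, w2 = d // 2, h // 2, w // 2
        win = (
            self.data.reshape(n, c, d2, 2, h2, 2, w2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d2, h2, w2, 8)
        )
        idx = win.argmax(axis=-1)
        pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        out = Tensor(pooled, self.requires_grad)
        record = {"idx": idx, "in_shape": (n, c, d, h, w)}
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                gwin = np.zeros((n, c, d2, h2, w2, 8), dtype=g.dtype)
                np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
                gx = (
                    gwin.reshape(n, c, d2, h2, w2, 2, 2, 2)
                    .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                    .reshape(n, c, d, h, w)
                )
                self._accum(gx)

            out._backward = bwd
        return out, record

    def max_unpool3d(self, record: dict):
        """Place each value at its recorded window argmax; zeros elsewhere."""
        n, c, d, h, w = record["in_shape"]
        idx = record["idx"]
        if self.data.shape != idx.shape:
            raise ValueError(
                f"index record shape {idx.shape} does not match input {self.data.shape}"
            )
        d2, h2, w2 = d // 2, h // 2, w // 2
        win = np.zeros((n, c, d2, h2, w2, 8), dtype=self.data.dtype)
        np.put_along_axis(win, idx[..., None], self.data[..., None], axis=-1)
        out_data = (
            win.reshape(n, c, d2, h2, w2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )
        out = Tensor(out_data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                gwin = (
                    g.reshape(n, c, d2, 2, h2, 2, w2, 2)
                    .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                    .reshape(n, c, d2, h2, w2, 8)
                )
                self._accum(np.take_along_axis(gwin, idx[..., None], axis=-1)[..., 0])

            out._backward = bwd
        return out

    def max_filter3(self):
        """Stride-1 3x3x3 max filter with zero padding (soft dilation).

        Gradient routes to each window's argmax (first index on ties).
        """
        n, c, d, h, w = self.data.shape
        xp = np.pad(self.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)), constant_values=-np.inf)
        win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4)).reshape(n, c, d, h, w, 27)
        idx = win.argmax(axis=-1)
        out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                gp = np.zeros((n, c, d + 2, h + 2, w + 2), dtype=g.dtype)
                oz, oy, ox = np.unravel_index(idx, (3, 3, 3))
                nn, cc, dd, hh, wwi = np.indices(idx.shape, sparse=True)
                np.add.at(gp, (nn, cc, dd + oz, hh + oy, wwi + ox), g)
                self._accum(gp[:, :, 1:-1, 1:-1, 1:-1])

            out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    return Tensor(arr if arr.dtype.kind == "f" else arr.astype(np.float64))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        out._backward = bwd
    return out


def where(cond, a, b) -> Tensor:
    """Elementwise select with a constant boolean condition."""
    cond = np.asarray(cond, dtype=bool)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.where(cond, a.data, b.data), a.requires_grad or b.requires_grad)
    if out.requires_grad:
        out._parents = (a, b)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))

        out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
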