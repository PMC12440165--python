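"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tensor engine: enough operations to express the
convolutional backbone, the MsHop block, the variational autoencoder and the
self-supervised losses, with deterministic single-threaded semantics.  Graphs
are built eagerly; :meth:`Tensor.backward` runs a topological sweep and
accumulates gradients into ``.grad`` (a plain ndarray).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (e.g. for evaluation)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:  # float32 passes through; all else -> f64
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping --------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic ---------------------------------------------------------
    # python scalars take a fast path that neither joins the graph nor
    # promotes float32 data to float64
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._make(self.data + other, (self,), lambda g: (g,))
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._make(self.data * other, (self,), lambda g: (g * other,))
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        out_data = other / self.data if isinstance(other, (int, float)) else None
        if out_data is not None:
            return self._make(out_data, (self,), lambda g: (-g * out_data / self.data,))
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bwd(g):
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bwd)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_ = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_, self.shape).copy(),)

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[a] for a in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)
        return self._make(out_data, (self,), lambda g: (g.transpose(inv),))

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)
        return self._make(out_data, (self,), lambda g: (np.swapaxes(g, a, b),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return self._make(out_data, (self,), bwd)

    # -- structured ops -----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias=None, stride: int = 1, padding=0):
        """2-D cross-correlation, NCHW layout.

        ``padding`` is an int or an ``(ph, pw)`` pair of symmetric zero pads.
        """
        w = as_tensor(weight)
        b = as_tensor(bias) if bias is not None else None
        x = self.data
        n, c, h, wd = x.shape
        o, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
        ph, pw = (padding, padding) if isinstance(padding, int) else padding
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        ho = (h + 2 * ph - kh) // stride + 1
        wo = (wd + 2 * pw - kw) // stride + 1

        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw
        )
        wmat = w.data.reshape(o, c * kh * kw)
        out = cols @ wmat.T
        out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
        if b is not None:
            out = out + b.data[None, :, None, None]

        def bwd(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
            gw = (gmat.T @ cols).reshape(o, c, kh, kw)
            gcols = gmat @ wmat
            gwin = gcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :, :, i : i + stride * ho : stride, j : j + stride * wo : stride
                    ] += gwin[:, :, :, :, i, j]
            gx = gxp[:, :, ph : ph + h, pw : pw + wd]
            gb = g.sum(axis=(0, 2, 3)) if b is not None else None
            return (gx, gw, gb) if b is not None else (gx, gw)

        parents = (self, w, b) if b is not None else (self, w)
        return self._make(out, parents, bwd)

    def upsample_nearest(self, factor: int):
        """Nearest-neighbour spatial upsampling by an integer factor (NCHW)."""
        x = self.data
        n, c, h, w = x.shape
        out = x.repeat(factor, axis=2).repeat(factor, axis=3)

        def bwd(g):
            g_ = g.reshape(n, c, h, factor, w, factor)
            return (g_.sum(axis=(3, 5)),)

        return self._make(out, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    out = tensors[0]._make(out_data, tuple(tensors), bwd)
    return out
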