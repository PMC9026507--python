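"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's numerical engine: a small define-by-run tape with the
operations the translation networks need (2-D convolution and transposed
convolution, batch statistics, element-wise activations, reductions,
concatenation and matrix products). Arrays are NCHW for images/feature maps.
Gradients of every primitive are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "leaky_relu",
    "no_grad",
    "relu",
    "tanh",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

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
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another node's gradient buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
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
                # free the closure so intermediate buffers can be collected
                t._backward = None
                t._parents = ()

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _scalar_op(self, out_data, local_grad):
        """Elementwise op with a python-scalar operand (dtype-preserving)."""
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g if local_grad is None else g * local_grad)

        return Tensor._make(out_data, (a,), backward)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.data + other, None)
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.data - other, None)
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.data * other, float(other))
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(self.data / other, 1.0 / float(other))
        a, b = self, Tensor._coerce(other)
        out_data = a.data / b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * out_data / b.data, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data**e

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def abs(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * np.sign(a.data))

        return Tensor._make(np.abs(a.data), (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)


# -- activations ---------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(mask, 1.0, slope))

    return Tensor._make(np.where(mask, x.data, slope * x.data), (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data * out_data))

    return Tensor._make(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# -- convolution ----------------------------------------------------------------


def _out_size(size: int, k: int, s: int, p: int) -> int:
    return (size + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    if p > 0:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    view = view[:, :, ::s, ::s]  # (N, C, OH, OW, k, k)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, k: int, s: int, p: int, h: int, w: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back to an (N,C,H,W) array."""
    n = cols.shape[0]
    c = cols.shape[1] // (k * k)
    oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
    cols = cols.reshape(n, c, k, k, oh, ow)
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + s * oh : s, j : j + s * ow : s] += cols[:, :, i, j]
    return out[:, :, p : p + h, p : p + w]


def _conv_forward(x, w, s, p):
    n, _, h, wd = x.shape
    co, ci, k, _ = w.shape
    cols = _im2col(x, k, s, p)
    y = w.reshape(co, ci * k * k) @ cols
    return y.reshape(n, co, _out_size(h, k, s, p), _out_size(wd, k, s, p)), cols


def _conv_backward_input(dy, w, s, p, h, wd):
    co, ci, k, _ = w.shape
    n = dy.shape[0]
    dcols = w.reshape(co, ci * k * k).T @ dy.reshape(n, co, -1)
    return _col2im(dcols, k, s, p, h, wd)


def _conv_backward_weight(dy, cols, w_shape):
    co, ci, k, _ = w_shape
    n = dy.shape[0]
    dw = np.matmul(dy.reshape(n, co, -1), cols.transpose(0, 2, 1)).sum(axis=0)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), weight layout (Cout, Cin, k, k)."""
    n, ci_x, h, wd = x.shape
    co, ci, k, _ = w.shape
    if ci != ci_x:
        raise ValueError(f"channel mismatch: input {ci_x}, weight expects {ci}")
    if _out_size(h, k, stride, padding) < 1 or _out_size(wd, k, stride, padding) < 1:
        raise ValueError(f"input {h}x{wd} too small for kernel {k}/stride {stride}")
    y, cols = _conv_forward(x.data, w.data, stride, padding)
    if b is not None:
        y = y + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_backward_input(g, w.data, stride, padding, h, wd))
        if w.requires_grad:
            w._accumulate(_conv_backward_weight(g, cols, w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution, weight layout (Cin, Cout, k, k).

    Output spatial size is (H-1)*stride - 2*padding + k, the exact adjoint of
    conv2d with the same geometry.
    """
    n, ci_x, h, wd = x.shape
    ci, co, k, _ = w.shape
    if ci != ci_x:
        raise ValueError(f"channel mismatch: input {ci_x}, weight expects {ci}")
    oh = (h - 1) * stride - 2 * padding + k
    ow = (wd - 1) * stride - 2 * padding + k
    y = _conv_backward_input(x.data, w.data, stride, padding, oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        cols = None
        if x.requires_grad or w.requires_grad:
            cols = _im2col(g, k, stride, padding)
        if x.requires_grad:
            gx = w.data.reshape(ci, co * k * k) @ cols
            x._accumulate(gx.reshape(n, ci, h, wd))
        if w.requires_grad:
            # dW[ci,co,k,k] = sum_n x[n,ci,:] (outer) patches of g
            dw = np.matmul(x.data.reshape(n, ci, -1),
                           cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)
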