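"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the operations the ΔΔG network needs are
implemented (broadcast arithmetic, batched matmul, reductions, indexing,
concatenation, 2-D convolution and max-pooling).  Gradients of every
operation are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d_same", "maxpool2x2", "relu", "softmax_lastdim"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._prev = _prev
        self._backward = _backward

    # -- plumbing --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # dtype-preserving scalar path
            out = Tensor(self.data + other, _prev=(self,))

            def _backward_s(g):
                self._accumulate(g)

            out._backward = _backward_s
            return out
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # dtype-preserving scalar path
            out = Tensor(self.data * other, _prev=(self,))

            def _backward_s(g):
                self._accumulate(g * other)

            out._backward = _backward_s
            return out
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _backward(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _backward(g):
            self._accumulate(
                _unbroadcast(np.matmul(g, other.data.swapaxes(-1, -2)), self.data.shape)
            )
            other._accumulate(
                _unbroadcast(np.matmul(self.data.swapaxes(-1, -2), g), other.data.shape)
            )

        out._backward = _backward
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _backward(g):
            self._accumulate(g * out.data)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _backward(g):
            self._accumulate(g / self.data)

        out._backward = _backward
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = _backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def _backward(g):
            self._accumulate(g.transpose(inv))

        out._backward = _backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))

    def _backward(g):
        x._accumulate(g * (x.data > 0))

    out._backward = _backward
    return out


def softmax_lastdim(x: Tensor) -> Tensor:
    # subtracting the (detached) row max is gradient-transparent: softmax is
    # shift invariant, so treating the max as a constant is exact
    shifted = x - x.data.max(axis=-1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """2-D convolution with 'same' zero padding and stride 1.

    x: (B, C, H, W); weight: (O, C, kh, kw); bias: (O,).  Implemented as
    im2col + matmul in the forward pass; the input gradient is scattered
    back one kernel offset at a time (k ≤ 7, so at most 49 vectorised adds).
    """
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # strided view (B, C, H, W, kh, kw); einsum contracts it without the
    # explicit im2col copy
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    y = np.einsum("bchwij,ocij->bohw", windows, weight.data, optimize=True)
    y += bias.data[None, :, None, None]
    out = Tensor(y, _prev=(x, weight, bias))

    def _backward(g):
        bias._accumulate(g.sum(axis=(0, 2, 3)))
        weight._accumulate(np.einsum("bchwij,bohw->ocij", windows, g, optimize=True))
        gy = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (B, H, W, O)
        gxp = np.zeros_like(xp)
        wmat = weight.data  # (O, C, kh, kw)
        for i in range(kh):
            for j in range(kw):
                # (B,H,W,O) @ (O,C) -> (B,H,W,C), scattered at offset (i,j)
                gxp[:, :, i : i + H, j : j + W] += (gy @ wmat[:, :, i, j]).transpose(0, 3, 1, 2)
        x._accumulate(gxp[:, :, ph : ph + H, pw : pw + W])

    out._backward = _backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped.

    Gradient is routed to the first maximal element of each window.
    """
    B, C, H, W = x.data.shape
    Ho, Wo = H // 2, W // 2
    if Ho < 1 or Wo < 1:
        raise ValueError(f"spatial size {H}x{W} too small for 2x2 pooling")
    cropped = x.data[:, :, : 2 * Ho, : 2 * Wo]
    win = cropped.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
    arg = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, arg[..., None], axis=-1)[..., 0], _prev=(x,))

    def _backward(g):
        gwin = np.zeros((B, C, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : 2 * Ho, : 2 * Wo] = (
            gwin.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, 2 * Ho, 2 * Wo)
        )
        x._accumulate(gx)

    out._backward = _backward
    return out
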