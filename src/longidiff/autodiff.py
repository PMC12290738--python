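"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the 2D encoder-decoder noise predictor:
broadcast arithmetic, (batched) matmul, convolution via im2col, group
normalization, softmax, SiLU, nearest-neighbour upsampling, concatenation
and reductions.  Gradients are accumulated by walking the tape in reverse
topological order; every primitive's backward pass is exercised against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "matmul", "conv2d", "group_norm", "softmax",
           "silu", "upsample_nearest2", "swap_last2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(orig),))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- backward driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g
        # self may itself be a leaf
        if self._backward is None and self.requires_grad and self._parents == ():
            pass


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor._make(out_data, (a, b), backward)


def swap_last2(x: Tensor) -> Tensor:
    return Tensor._make(np.swapaxes(x.data, -1, -2), (x,),
                        lambda g: (np.swapaxes(g, -1, -2),))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * s

    def backward(g):
        return (g * (s * (1.0 + x.data * (1.0 - s))),)

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor._make(y, (x,), backward)


# -- convolution --------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    cols = np.ascontiguousarray(view).reshape(n, c * kh * kw, ho * wo)
    return cols, ho, wo


def _col2im(gcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    gx = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    g6 = gcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += g6[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:hp - pad, pad:wp - pad]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout, square stride/padding."""
    n = x.data.shape[0]
    oc, ic, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    w2 = w.data.reshape(oc, ic * kh * kw)
    out = np.matmul(w2, cols).reshape(n, oc, ho, wo)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(n, oc, ho * wo)
        gw = np.matmul(g2, np.swapaxes(cols, 1, 2)).sum(axis=0).reshape(w.data.shape)
        gcols = np.matmul(w2.T, g2)
        gx = _col2im(gcols, x.data.shape, kh, kw, stride, pad, ho, wo)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._make(out, parents, backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over (C/G, H, W) statistics per sample and group."""
    n, c, h, w = x.data.shape
    g_ = groups
    xg = x.data.reshape(n, g_, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        dxhat = (g * gamma.data[None, :, None, None]).reshape(n, g_, -1)
        xh = xhat.reshape(n, g_, -1)
        m = dxhat.shape[2]
        gx = inv * (dxhat - dxhat.mean(axis=2, keepdims=True)
                    - xh * (dxhat * xh).sum(axis=2, keepdims=True) / m)
        return gx.reshape(n, c, h, w), ggamma, gbeta

    return Tensor._make(out, (x, gamma, beta), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling, NCHW."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), backward)
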