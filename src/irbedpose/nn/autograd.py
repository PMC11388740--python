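"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set needed by the pose network, the pose
discriminator and the cover-synthesis GAN: broadcast arithmetic, matmul,
2-D convolution (im2col), pooling, nearest-neighbor resizing, channel-wise
spatial softmax and the SELU / ReLU / sigmoid nonlinearities.  Arrays are
float64 throughout; the models in this package are deliberately small, so
numerical robustness is preferred over single-precision speed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data + b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data * b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data ** e

        def bwd(g):
            a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data @ b.data

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (a, b), bwd)

    # -------------------------------------------------------------- unary ops
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def selu(self):
        # Klambauer et al. self-normalizing constants
        a = self
        alpha, scale = 1.6732632423543772, 1.0507009873554805
        pos = a.data > 0
        expm = np.exp(np.minimum(a.data, 0.0)) - 1.0
        out_data = scale * np.where(pos, a.data, alpha * expm)

        def bwd(g):
            deriv = scale * np.where(pos, 1.0, alpha * (expm + 1.0))
            a._accum(g * deriv)

        return Tensor._make(out_data, (a,), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy()
                         if np.ndim(g) else np.full_like(a.data, g))
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def std(self):
        """Population standard deviation over all elements."""
        mu = self.mean()
        var = ((self - mu) ** 2.0).mean()
        return (var + 1e-12) ** 0.5

    # ----------------------------------------------------------- shape manip
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = a.data.shape

        def bwd(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def pad2d(self, pad_h: int, pad_w: int, mode: str = "constant"):
        """Pad the last two axes symmetrically ('constant' or 'reflect')."""
        a = self
        if pad_h == 0 and pad_w == 0:
            return a
        h, w = a.shape[-2], a.shape[-1]
        if mode == "constant":
            width = [(0, 0)] * (a.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
            out_data = np.pad(a.data, width)
            sl = (Ellipsis, slice(pad_h, pad_h + h), slice(pad_w, pad_w + w))

            def bwd(g):
                a._accum(g[sl])

            return Tensor._make(out_data, (a,), bwd)
        if mode != "reflect":
            raise ValueError(f"unsupported pad mode {mode!r}")
        # reflect padding as a separable gather; gradients fold back by
        # scatter-add onto the source indices
        ri = np.pad(np.arange(h), (pad_h, pad_h), mode="reflect")
        ci = np.pad(np.arange(w), (pad_w, pad_w), mode="reflect")
        out_data = a.data[..., ri[:, None], ci[None, :]]

        def bwd(g):
            tmp = np.zeros(a.data.shape[:-2] + (h, len(ci)), dtype=np.float64)
            np.add.at(np.moveaxis(tmp, -2, 0), ri, np.moveaxis(g, -2, 0))
            dx = np.zeros_like(a.data)
            np.add.at(np.moveaxis(dx, -1, 0), ci, np.moveaxis(tmp, -1, 0))
            a._accum(dx)

        return Tensor._make(out_data, (a,), bwd)

    # -------------------------------------------------------------- image ops
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """NCHW convolution. weight: (F, C, kh, kw), bias: (F,)."""
        a, w = self, weight
        n, c, h, wid = a.shape
        f, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        s = int(stride)
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else a.data
        ho = (xp.shape[2] - kh) // s + 1
        wo = (xp.shape[3] - kw) // s + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, kh, kw) -> (N, Ho*Wo, C*kh*kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
        wflat = w.data.reshape(f, -1)
        out_data = cols @ wflat.T
        if bias is not None:
            out_data = out_data + bias.data
        out_data = out_data.transpose(0, 2, 1).reshape(n, f, ho, wo)

        def bwd(g):
            gmat = g.reshape(n, f, ho * wo).transpose(0, 2, 1)  # (N, HoWo, F)
            if w.requires_grad:
                gw = np.einsum("nlf,nlk->fk", gmat, cols, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=(0, 1)))
            if a.requires_grad:
                dcols = gmat @ wflat  # (N, HoWo, C*kh*kw)
                dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[..., i, j]
                if padding:
                    dxp = dxp[:, :, padding:padding + h, padding:padding + wid]
                a._accum(dxp)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out_data, parents, bwd)

    def _pool_windows(self, k: int, s: int, padding: int, pad_value: float):
        xp = self.data
        if padding:
            xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                        constant_values=pad_value)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        return xp, win

    def max_pool2d(self, kernel: int, stride: int | None = None, padding: int = 0):
        a = self
        k, s = int(kernel), int(stride or kernel)
        xp, win = a._pool_windows(k, s, padding, -np.inf)
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def bwd(g):
            dxp = np.zeros_like(xp)
            ai, aj = np.divmod(arg, k)
            for i in range(k):
                for j in range(k):
                    mask = (ai == i) & (aj == j)
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += g * mask
            if padding:
                dxp = dxp[:, :, padding:xp.shape[2] - padding,
                          padding:xp.shape[3] - padding]
            a._accum(dxp)

        return Tensor._make(out_data, (a,), bwd)

    def avg_pool2d(self, kernel: int, stride: int | None = None, padding: int = 0):
        a = self
        k, s = int(kernel), int(stride or kernel)
        xp, win = a._pool_windows(k, s, padding, 0.0)
        n, c, ho, wo = win.shape[:4]
        out_data = win.mean(axis=(-1, -2))

        def bwd(g):
            dxp = np.zeros_like(xp)
            gk = g / (k * k)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gk
            if padding:
                dxp = dxp[:, :, padding:xp.shape[2] - padding,
                          padding:xp.shape[3] - padding]
            a._accum(dxp)

        return Tensor._make(out_data, (a,), bwd)

    def resize_nearest(self, out_h: int, out_w: int):
        """Nearest-neighbor resize of the last two axes (differentiable)."""
        a = self
        h, w = a.shape[-2], a.shape[-1]
        if (h, w) == (out_h, out_w):
            return a
        ri = np.minimum((np.arange(out_h) * h // out_h), h - 1)
        ci = np.minimum((np.arange(out_w) * w // out_w), w - 1)
        out_data = a.data[..., ri[:, None], ci[None, :]]

        def bwd(g):
            # separable scatter-add: rows then columns
            tmp = np.zeros(a.data.shape[:-2] + (h, out_w), dtype=np.float64)
            gm = np.moveaxis(g, -2, 0)
            tm = np.moveaxis(tmp, -2, 0)
            np.add.at(tm, ri, gm)
            dx = np.zeros_like(a.data)
            tm2 = np.moveaxis(tmp, -1, 0)
            dm = np.moveaxis(dx, -1, 0)
            np.add.at(dm, ci, tm2)
            a._accum(dx)

        return Tensor._make(out_data, (a,), bwd)

    def upsample_nearest(self, factor: int):
        h, w = self.shape[-2], self.shape[-1]
        return self.resize_nearest(h * factor, w * factor)

    def spatial_softmax(self):
        """Softmax over the last two axes, independently per (N, C) channel."""
        a = self
        m = a.data.max(axis=(-1, -2), keepdims=True)  # constant shift
        e = (a - Tensor(m)).exp()
        return e / e.sum(axis=(-1, -2), keepdims=True)


def concat(tensors, axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(ts), bwd)
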