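"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` propagates gradients
through the recorded graph in reverse topological order.  The op set is
exactly what the detector family needs: broadcasting arithmetic,
sigmoid/ReLU/arctan/sqrt nonlinearities, reductions, shape manipulation,
batched matmul, grouped/dilated 2-D convolution, 2x2 max pooling and
nearest-neighbour upsampling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "mac_counter"]

_grad_enabled = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _grad_enabled.append(False)
        return self

    def __exit__(self, *exc):
        _grad_enabled.pop()
        return False


def is_grad_enabled() -> bool:
    return _grad_enabled[-1]


class _MacCounter:
    """Global multiply-accumulate counter, armed by ``count_flops``."""

    def __init__(self):
        self.active = False
        self.total = 0

    def add(self, n: int):
        if self.active:
            self.total += int(n)

    def reset(self):
        self.total = 0


mac_counter = _MacCounter()


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # numpy defers to Tensor in mixed expressions

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        arr = np.asarray(data)
        # float64 is preserved (for high-precision checks); everything else
        # is computed in float32
        if arr.dtype != np.float64:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and is_grad_enabled()
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction ----------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=False)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._make(np.power(a.data, p), (a,), bwd)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def arctan(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / (1.0 + a.data * a.data))

        return Tensor._make(np.arctan(a.data), (a,), bwd)

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        amask = a.data >= b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * amask, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~amask), b.data.shape))

        return Tensor._make(np.maximum(a.data, b.data), (a, b), bwd)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        amask = a.data <= b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * amask, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~amask), b.data.shape))

        return Tensor._make(np.minimum(a.data, b.data), (a, b), bwd)

    def clip(self, lo: float, hi: float):
        return self.maximum(lo).minimum(hi)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    @staticmethod
    def concat(tensors: list, axis: int = 0) -> "Tensor":
        tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(int(s), int(e))
                    t._accum(np.ascontiguousarray(g[tuple(sl)]))

        return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                            tensors, bwd)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        mac_counter.add(np.prod(np.broadcast_shapes(a.data.shape[:-2], b.data.shape[:-2]), dtype=np.int64)
                        * a.data.shape[-2] * a.data.shape[-1] * b.data.shape[-1])

        def bwd(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bwd)

    __matmul__ = matmul

    # -- spatial ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride=1, padding=0, dilation=1, groups: int = 1):
        """Grouped, dilated 2-D cross-correlation (NCHW)."""
        return _conv2d(self, weight, bias, stride, padding, dilation, groups)

    def maxpool2x2(self):
        a = self
        n, c, h, w = a.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2x2 requires even spatial dims")
        r = a.data.reshape(n, c, h // 2, 2, w // 2, 2)
        out_data = r.max(axis=(3, 5))

        def bwd(g):
            if not a.requires_grad:
                return
            mask = (r == out_data[:, :, :, None, :, None])
            cnt = mask.sum(axis=(3, 5), keepdims=True)
            ga = mask * (g[:, :, :, None, :, None] / cnt)
            a._accum(ga.reshape(n, c, h, w))

        return Tensor._make(out_data, (a,), bwd)

    def upsample2x(self):
        """Nearest-neighbour x2 upsampling on the two trailing axes."""
        a = self
        n, c, h, w = a.data.shape
        out_data = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._make(out_data, (a,), bwd)

    def pad2d(self, ph: int, pw: int):
        if ph == 0 and pw == 0:
            return self
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(np.ascontiguousarray(g[:, :, ph:g.shape[2] - ph, pw:g.shape[3] - pw]))

        return Tensor._make(
            np.pad(a.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))), (a,), bwd)


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def _conv2d(x: Tensor, weight: Tensor, bias, stride, padding, dilation, groups):
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    n, cin, hin, win = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin != cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight expects {cin_g * groups}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    ekh, ekw = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    hp, wp = xp.shape[2], xp.shape[3]
    if hp < ekh or wp < ekw:
        raise ValueError("conv2d: input smaller than effective kernel")
    oh = (hp - ekh) // sh + 1
    ow = (wp - ekw) // sw + 1

    # cols[n, c, oh, ow, i, j] — dilated/strided window view
    v = sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
    cols = v[:, :, ::sh, ::sw, ::dh, ::dw]
    cols = np.ascontiguousarray(cols)

    cg = cols.reshape(n, groups, cin // groups, oh, ow, kh, kw)
    wg = weight.data.reshape(groups, cout // groups, cin // groups, kh, kw)
    out = np.einsum("ngchwij,gocij->ngohw", cg, wg, optimize=True)
    out = out.reshape(n, cout, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    mac_counter.add(n * cout * oh * ow * (cin // groups) * kh * kw)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gg = g.reshape(n, groups, cout // groups, oh, ow)
        if weight.requires_grad:
            gw = np.einsum("ngchwij,ngohw->gocij", cg, gg, optimize=True)
            weight._accum(gw.reshape(cout, cin // groups, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("gocij,ngohw->ngchwij", wg, gg, optimize=True)
            gcols = gcols.reshape(n, cin, oh, ow, kh, kw)
            gxp = np.zeros((n, cin, hp, wp), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * dh:i * dh + oh * sh:sh,
                        j * dw:j * dw + ow * sw:sw] += gcols[:, :, :, :, i, j]
            if ph or pw:
                gxp = gxp[:, :, ph:hp - ph, pw:wp - pw]
            x._accum(np.ascontiguousarray(gxp))

    return Tensor._make(out, parents, bwd)
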