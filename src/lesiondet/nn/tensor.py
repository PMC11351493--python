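"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations the detector actually uses are provided: broadcasting
arithmetic, the usual pointwise nonlinearities, reductions, shape surgery,
grouped/dilated 2-D convolution, stride-1 max pooling and nearest-neighbour
upsampling.  Gradients are accumulated into ``Tensor.grad`` (plain numpy
arrays) by :meth:`Tensor.backward`, which walks the tape in reverse
topological order.

All data is float64; the networks built here are desk-scale, so numerical
headroom is preferred over speed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "sigmoid",
    "silu",
    "hardswish",
    "relu",
    "exp",
    "log",
    "sqrt",
    "absolute",
    "clip",
    "maximum",
    "conv2d",
    "maxpool2d",
    "upsample2x",
    "bce_with_logits",
]


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- bookkeeping ----------------------------------------------------
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

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda a, b, g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda a, b, g: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * np.power(a.data, p - 1.0))

        return _node(np.power(a.data, p), (a,), bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape surgery --------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            a._accum(g.reshape(a.data.shape))

        return _node(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return _node(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return _node(a.data[idx], (a,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad for p in parents):
        return Tensor(data, _parents=parents, _backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = fwd(a.data, b.data)

    def bw(g):
        ga, gb = grads(a.data, b.data, g)
        if a.requires_grad:
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bw)


# -- pointwise nonlinearities ------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)

    def bw(g):
        x._accum(g * e)

    return _node(e, (x,), bw)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bw(g):
        x._accum(g / x.data)

    return _node(np.log(x.data), (x,), bw)


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bw(g):
        x._accum(g * np.sign(x.data))

    return _node(np.abs(x.data), (x,), bw)


def _sigmoid_np(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = _sigmoid_np(x.data)

    def bw(g):
        x._accum(g * s * (1.0 - s))

    return _node(s, (x,), bw)


def silu(x: Tensor) -> Tensor:
    return x * sigmoid(x)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return _node(x.data * mask, (x,), bw)


def hardswish(x: Tensor) -> Tensor:
    """x * relu6(x + 3) / 6 — the piecewise-linear swish approximation."""
    x = as_tensor(x)
    v = x.data
    inner = np.clip(v + 3.0, 0.0, 6.0)
    out = v * inner / 6.0

    def bw(g):
        d = np.where(v <= -3.0, 0.0, np.where(v >= 3.0, 1.0, (2.0 * v + 3.0) / 6.0))
        x._accum(g * d)

    return _node(out, (x,), bw)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through zero gradient outside [lo, hi]."""
    x = as_tensor(x)
    mask = (x.data >= lo) & (x.data <= hi)

    def bw(g):
        x._accum(g * mask)

    return _node(np.clip(x.data, lo, hi), (x,), bw)


def maximum(x: Tensor, floor: float) -> Tensor:
    x = as_tensor(x)
    mask = x.data >= floor

    def bw(g):
        x._accum(g * mask)

    return _node(np.maximum(x.data, floor), (x,), bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad:
                t._accum(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# -- convolution --------------------------------------------------------

def _same_padding(k: int, dilation: int) -> int:
    eff = (k - 1) * dilation + 1
    if eff % 2 == 0:
        raise ValueError(f"effective kernel length {eff} is even; cannot pad symmetrically")
    return eff // 2


def conv2d_forward(x: np.ndarray, w: np.ndarray, b=None, *, stride: int = 1,
                   padding=None, dilation: int = 1, groups: int = 1) -> np.ndarray:
    """Plain-numpy grouped 2-D cross-correlation (NCHW).

    ``padding=None`` means shape-preserving ('same') for stride 1.
    """
    out, _ = _conv2d_core(x, w, b, stride, padding, dilation, groups)
    return out


def _conv2d_core(x, w, b, stride, padding, dilation, groups):
    n, c, h, wd = x.shape
    cout, cg, kh, kw = w.shape
    if c % groups or cout % groups or cg != c // groups:
        raise ValueError("channel counts incompatible with group count")
    if padding is None:
        ph, pw = _same_padding(kh, dilation), _same_padding(kw, dilation)
    elif np.isscalar(padding):
        ph = pw = int(padding)
    else:
        ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    if eh > xp.shape[2] or ew > xp.shape[3]:
        raise ValueError("kernel larger than padded input")
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    ho, wo = win.shape[2], win.shape[3]
    wing = win.reshape(n, groups, cg, ho, wo, kh, kw)
    wg = w.reshape(groups, cout // groups, cg, kh, kw)
    out = np.einsum("ngcijab,gocab->ngoij", wing, wg, optimize=True)
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    meta = (xp.shape, ph, pw, ho, wo, wing, wg)
    return np.ascontiguousarray(out), meta


def conv2d(x: Tensor, w: Tensor, b=None, *, stride: int = 1, padding=None,
           dilation: int = 1, groups: int = 1) -> Tensor:
    x, w = as_tensor(x), as_tensor(w)
    bt = as_tensor(b) if b is not None else None
    out, meta = _conv2d_core(x.data, w.data, None if bt is None else bt.data,
                             stride, padding, dilation, groups)
    xp_shape, ph, pw, ho, wo, wing, wg = meta
    n, c = x.data.shape[:2]
    cout, cg, kh, kw = w.data.shape

    def bw(g):
        gg = g.reshape(n, groups, cout // groups, ho, wo)
        if bt is not None and bt.requires_grad:
            bt._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("ngcijab,ngoij->gocab", wing, gg, optimize=True)
            w._accum(dw.reshape(cout, cg, kh, kw))
        if x.requires_grad:
            dxp = np.zeros(xp_shape)
            dxp_g = dxp.reshape(n, groups, cg, xp_shape[2], xp_shape[3])
            for a in range(kh):
                for bb in range(kw):
                    t = np.einsum("ngoij,goc->ngcij", gg, wg[:, :, :, a, bb],
                                  optimize=True)
                    ia, jb = a * dilation, bb * dilation
                    dxp_g[:, :, :,
                          ia:ia + (ho - 1) * stride + 1:stride,
                          jb:jb + (wo - 1) * stride + 1:stride] += t
            h, wd = x.data.shape[2:]
            x._accum(dxp[:, :, ph:ph + h, pw:pw + wd])

    parents = (x, w) if bt is None else (x, w, bt)
    return _node(out, parents, bw)


def maxpool2d_forward(x: np.ndarray, k: int) -> np.ndarray:
    """Stride-1, shape-preserving k×k max pooling (odd k)."""
    p = _same_padding(k, 1)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win.max(axis=(-2, -1))


def maxpool2d(x: Tensor, k: int) -> Tensor:
    x = as_tensor(x)
    p = _same_padding(k, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = x.data.shape
    flat = win.reshape(n, c, h, w, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros(xp.shape)
        ni, ci, hi, wi = np.indices((n, c, h, w))
        a, bb = idx // k, idx % k
        np.add.at(dxp, (ni, ci, hi + a, wi + bb), g)
        x._accum(dxp[:, :, p:p + h, p:p + w])

    return _node(out, (x,), bw)


def upsample2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _node(out, (x,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits, numerically stable."""
    t = np.asarray(targets, dtype=np.float64)
    return relu(logits) - logits * t + log(1.0 + exp(-absolute(logits)))
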