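"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each primitive builds an output
:class:`Tensor` holding a closure that propagates the upstream gradient to its
parents.  Only the primitives the network and its losses need are provided.
Arrays keep whatever float dtype they come in with (float32 for training,
float64 in gradient-check tests).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "neg", "div", "matmul", "relu", "sigmoid",
    "log", "pow_const", "clamp", "tsum", "tmean", "concat", "reshape",
    "conv2d", "max_pool2d", "avg_pool_block", "global_avg_pool", "tmax",
    "bilinear_resize", "dropout", "as_tensor",
]


class Tensor:
    """An array plus the bookkeeping needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __truediv__(self, other):
        return div(self, other)

    # -- backprop ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if p.requires_grad:
                        stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad],
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = as_tensor(a)

    def backward(g):
        a._accum(-g)

    return _make(-a.data, (a,), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# nonlinearities and scalar functions
# ---------------------------------------------------------------------------

def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accum(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    # numerically stable two-sided form
    out_data = np.where(a.data >= 0,
                        1.0 / (1.0 + np.exp(-np.clip(a.data, None, 60))),
                        np.exp(np.clip(a.data, -60, None)) /
                        (1.0 + np.exp(np.clip(a.data, -60, None))))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        a._accum(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def pow_const(a, exponent: float):
    a = as_tensor(a)
    out_data = a.data ** exponent

    def backward(g):
        base = np.maximum(a.data, np.finfo(a.data.dtype).tiny)
        a._accum(g * exponent * base ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def clamp(a, lo=None, hi=None):
    """Clip values; gradient passes only where the input is inside bounds."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        mask &= a.data >= lo
    if hi is not None:
        mask &= a.data <= hi

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g_ = g
        if axis is not None and not keepdims:
            g_ = np.expand_dims(g_, axis)
        a._accum(np.broadcast_to(g_, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# convolution and pooling (NCHW)
# ---------------------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(x: np.ndarray, kh: int, kw: int, stride, padding):
    n, c, h, w = x.shape
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::sh, ::sw]                  # n,c,ho,wo,kh,kw
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, padding, ho, wo):
    n, c, h, w = x_shape
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    hp, wp = h + 2 * ph, w + 2 * pw
    xpad = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            xpad[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += cols[:, :, :, :, i, j]
    return xpad[:, :, ph:hp - ph, pw:wp - pw]


def conv2d(x, weight, bias=None, stride=1, padding=0):
    """2-D convolution (cross-correlation), NCHW, weight (Cout, Cin, kh, kw).

    ``stride``/``padding`` may be ints or (h, w) pairs.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    cout, cin, kh, kw = weight.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {cin}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T                                   # (n*ho*wo, cout)
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, cout, 1, 1)
        parents.append(bias)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)  # (n*ho*wo, cout)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = gmat @ wmat
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, padding, ho, wo))

    return _make(out, parents, backward)


def max_pool2d(x, kernel=3, stride=2, padding=1):
    x = as_tensor(x)
    n, c, h, w = x.shape
    neg_inf = np.array(-np.inf, dtype=x.data.dtype)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg_inf) if padding else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(n, c, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gpad = np.zeros((n, c, hp, wp), dtype=g.dtype)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oi[None, None] * stride + ki
        cols_ = oj[None, None] * stride + kj
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gpad, (np.broadcast_to(ni, arg.shape), np.broadcast_to(ci, arg.shape),
                         rows, cols_), g)
        if padding:
            x._accum(gpad[:, :, padding:-padding, padding:-padding])
        else:
            x._accum(gpad)

    return _make(out, (x,), backward)


def avg_pool_block(x, factor: int):
    """Average pooling over non-overlapping factor x factor blocks."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError("avg_pool_block requires spatial size divisible by factor")
    ho, wo = h // factor, w // factor
    out = x.data.reshape(n, c, ho, factor, wo, factor).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, factor, axis=2), factor, axis=3) / (factor * factor)
        x._accum(gx)

    return _make(out, (x,), backward)


def tmax(a, axis: int, keepdims=False):
    """Max-reduction along one axis; gradient flows to the (first) argmax."""
    a = as_tensor(a)
    arg = a.data.argmax(axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(arg, axis), axis=axis)
    out_data = out if keepdims else out.squeeze(axis)

    def backward(g):
        g_ = g if keepdims else np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(arg, axis), g_, axis=axis)
        a._accum(ga)

    return _make(out_data, (a,), backward)


def global_avg_pool(x):
    """(N, C, H, W) -> (N, C) spatial mean."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None], x.shape) / (h * w))

    return _make(out, (x,), backward)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """1-D linear interpolation matrix, half-pixel-centre convention."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


def bilinear_resize(x, out_hw):
    """Bilinear spatial resize of an NCHW tensor (separable linear map)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    oh, ow = out_hw
    rmat = _interp_matrix(h, oh, x.data.dtype)
    cmat = _interp_matrix(w, ow, x.data.dtype)
    out = np.einsum("ih,nchw,jw->ncij", rmat, x.data, cmat, optimize=True)

    def backward(g):
        x._accum(np.einsum("ih,ncij,jw->nchw", rmat, g, cmat, optimize=True))

    return _make(out, (x,), backward)


def dropout(x, p: float, rng: np.random.Generator, training: bool):
    x = as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)

    def backward(g):
        x._accum(g * keep)

    return _make(x.data * keep, (x,), backward)
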