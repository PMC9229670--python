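"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation returns a :class:`Tensor` that
remembers its parents and a closure propagating the output gradient to them.
``Tensor.backward()`` walks the graph in reverse topological order.  All data
is float32 (NCHW layout for feature maps).  The op set is exactly what the
encoder–decoder GAN needs: 2-D (transposed) convolution, instance
normalization, LeakyReLU/tanh/sigmoid, dropout, channel concatenation and the
reductions used by the losses.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_F32)
    return a


class Tensor:
    """An array plus (optionally) a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parent."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (two U-Nets)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __neg__(self):
        return mul(self, -1.0)

    def mean(self):
        return mean(self)

    def sum(self):
        return tsum(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(_F32, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    y = a.data + b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(y, (a, b), bwd)


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    y = a.data - b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _node(y, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    y = a.data * b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(y, (a, b), bwd)


def absolute(a) -> Tensor:
    a = _wrap(a)
    y = np.abs(a.data)

    def bwd(g):
        _accumulate(a, g * np.sign(a.data))

    return _node(y, (a,), bwd)


def log(a) -> Tensor:
    a = _wrap(a)
    y = np.log(a.data)

    def bwd(g):
        _accumulate(a, g / a.data)

    return _node(y, (a,), bwd)


def mean(a) -> Tensor:
    a = _wrap(a)
    y = a.data.mean(dtype=_F32)

    def bwd(g):
        _accumulate(a, np.broadcast_to(g / a.data.size, a.data.shape))

    return _node(y, (a,), bwd)


def tsum(a) -> Tensor:
    a = _wrap(a)
    y = a.data.sum(dtype=_F32)

    def bwd(g):
        _accumulate(a, np.broadcast_to(g, a.data.shape))

    return _node(y, (a,), bwd)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = _wrap(a)
    pos = a.data >= 0
    y = np.where(pos, a.data, negative_slope * a.data)

    def bwd(g):
        _accumulate(a, g * np.where(pos, _F32(1.0), _F32(negative_slope)))

    return _node(y, (a,), bwd)


def tanh(a) -> Tensor:
    a = _wrap(a)
    y = np.tanh(a.data)

    def bwd(g):
        _accumulate(a, g * (1.0 - y * y))

    return _node(y, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _accumulate(a, g * y * (1.0 - y))

    return _node(y, (a,), bwd)


def dropout(a, p: float, rng: np.random.Generator, training: bool = True) -> Tensor:
    """Inverted dropout; the rng draw happens even when p == 0 is skipped."""
    a = _wrap(a)
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(_F32) / _F32(1.0 - p)
    y = a.data * keep

    def bwd(g):
        _accumulate(a, g * keep)

    return _node(y, (a,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    y = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return _node(y, tuple(ts), bwd)


# ---------------------------------------------------------------------------
# convolution primitives (NCHW; weight OCHW)
# ---------------------------------------------------------------------------

def _pad2d(x: np.ndarray, pt: int, pb: int, pl: int, pr: int) -> np.ndarray:
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))


def _windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    if stride != 1:
        v = v[:, :, ::stride, ::stride]
    return v


def _conv2d_raw(x, w, stride, pad):
    xp = _pad2d(x, *pad)
    kh, kw = w.shape[2], w.shape[3]
    v = _windows(xp, kh, kw, stride)
    return np.einsum("nchwij,ocij->nohw", v, w, optimize=True).astype(_F32, copy=False)


def _conv2d_wgrad(x, gy, kh, kw, stride, pad):
    xp = _pad2d(x, *pad)
    v = _windows(xp, kh, kw, stride)
    return np.einsum("nchwij,nohw->ocij", v, gy, optimize=True).astype(_F32, copy=False)


def _conv2d_xgrad(gy, w, stride, pad, in_hw):
    """Adjoint of _conv2d_raw with respect to its input."""
    h, wdt = in_hw
    pt, pb, pl, pr = pad
    kh, kw = w.shape[2], w.shape[3]
    hp, wp = h + pt + pb, wdt + pl + pr
    n, o = gy.shape[0], gy.shape[1]
    gz = np.zeros((n, o, hp - kh + 1, wp - kw + 1), dtype=_F32)
    gz[:, :, ::stride, ::stride] = gy
    gzp = _pad2d(gz, kh - 1, kh - 1, kw - 1, kw - 1)
    v = _windows(gzp, kh, kw, 1)
    wf = w[:, :, ::-1, ::-1]
    gxp = np.einsum("nohwij,ocij->nchw", v, wf, optimize=True).astype(_F32, copy=False)
    return gxp[:, :, pt : pt + h, pl : pl + wdt]


def _norm_pad(padding, kh, kw):
    if padding == "same":
        # total pad k-1, split with the extra pixel on the trailing side
        return (kh - 1) // 2, kh - 1 - (kh - 1) // 2, (kw - 1) // 2, kw - 1 - (kw - 1) // 2
    if isinstance(padding, int):
        return padding, padding, padding, padding
    pt, pb, pl, pr = padding
    return pt, pb, pl, pr


def conv2d(x, w, b=None, stride: int = 1, padding="same") -> Tensor:
    """Cross-correlation of a NCHW batch with an OCHW weight tensor."""
    x, w = _wrap(x), _wrap(w)
    pad = _norm_pad(padding, w.data.shape[2], w.data.shape[3])
    y = _conv2d_raw(x.data, w.data, stride, pad)
    if b is not None:
        b = _wrap(b)
        y = y + b.data.reshape(1, -1, 1, 1)
        parents = (x, w, b)
    else:
        parents = (x, w)
    kh, kw = w.data.shape[2], w.data.shape[3]
    in_hw = (x.data.shape[2], x.data.shape[3])

    def bwd(g):
        _accumulate(x, _conv2d_xgrad(g, w.data, stride, pad, in_hw))
        _accumulate(w, _conv2d_wgrad(x.data, g, kh, kw, stride, pad))
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))

    return _node(y, parents, bwd)


def conv_transpose2d(x, w, b=None, stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution: the exact adjoint of ``conv2d`` with the same
    weight, stride and (symmetric) padding.  Weight layout is (in, out, kh, kw);
    the output spatial side is ``stride`` times the input side.
    """
    x, w = _wrap(x), _wrap(w)
    kh, kw = w.data.shape[2], w.data.shape[3]
    pad = (padding, padding, padding, padding)
    out_hw = (x.data.shape[2] * stride, x.data.shape[3] * stride)
    expect = (out_hw[0] + 2 * padding - kh) // stride + 1
    if expect != x.data.shape[2]:
        raise ValueError(
            f"conv_transpose2d: kernel {kh}, stride {stride}, padding {padding} "
            f"cannot double a side of {x.data.shape[2]}"
        )
    y = _conv2d_xgrad(x.data, w.data, stride, pad, out_hw)
    if b is not None:
        b = _wrap(b)
        y = y + b.data.reshape(1, -1, 1, 1)
        parents = (x, w, b)
    else:
        parents = (x, w)

    def bwd(g):
        _accumulate(x, _conv2d_raw(g, w.data, stride, pad))
        _accumulate(w, _conv2d_wgrad(g, x.data, kh, kw, stride, pad))
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))

    return _node(y, parents, bwd)


# ---------------------------------------------------------------------------
# normalization and losses
# ---------------------------------------------------------------------------

def instance_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gview = gamma.data.reshape(1, -1, 1, 1)
    y = gview * xhat + beta.data.reshape(1, -1, 1, 1)
    m = x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        gxhat = g * gview
        s1 = gxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(2, 3), keepdims=True)
        gx = (inv / m) * (m * gxhat - s1 - xhat * s2)
        _accumulate(x, gx.astype(_F32, copy=False))
        _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accumulate(beta, g.sum(axis=(0, 2, 3)))

    return _node(y, (x, gamma, beta), bwd)


def binary_cross_entropy(p, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean BCE of probabilities ``p`` against a constant 0/1 target map.

    Probabilities are clamped to [eps, 1-eps] before the logs, so saturated
    discriminator outputs cannot produce log(0).
    """
    p = _wrap(p)
    t = np.broadcast_to(np.asarray(target, dtype=_F32), p.data.shape)
    pc = np.clip(p.data, eps, 1.0 - eps)
    y = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean(dtype=_F32)
    n = p.data.size

    def bwd(g):
        _accumulate(p, g * (pc - t) / (pc * (1.0 - pc)) / n)

    return _node(y, (p,), bwd)
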