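"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set needed by the segmentation network:
elementwise arithmetic with broadcasting, matmul, ReLU/sigmoid, reductions,
stride-1 same-padding 2-D convolution, 2x2 max pooling, bilinear 2x
upsampling, channel concatenation and a numerically stable binary
cross-entropy on logits.  Gradients are accumulated by a topological sweep
from the loss node; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "maxpool2",
    "upsample_bilinear2",
    "bce_with_logits",
    "relu",
    "sigmoid",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an associated gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype != np.float64 else np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        # store the first contribution as-is (never mutated afterwards);
        # later contributions allocate a fresh sum
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    # ------------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
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
                t._parents = ()
                t._backward = None  # free the graph as we go

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for a in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, a)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


# ----------------------------------------------------------------------
# nonlinearities


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


# ----------------------------------------------------------------------
# structural ops


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1, same-padding 2-D convolution (cross-correlation).

    x: (N, C, H, W); weight: (Co, C, k, k) with odd k; bias: (Co,).
    Implemented as one im2col matrix product in channels-last layout; the
    column buffer is rebuilt from the padded input during backward rather
    than retained, keeping the graph's memory footprint small.
    """
    n, c, h, w = x.data.shape
    co, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel size must be odd")
    ph, pw = kh // 2, kw // 2
    dt = x.data.dtype
    # channels-last padded copy, then gather the kh*kw shifted patches
    xpt = np.pad(x.data.transpose(0, 2, 3, 1), ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def im2col():
        cols = np.empty((n, h, w, kh * kw, c), dtype=dt)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, :, i * kw + j, :] = xpt[:, i:i + h, j:j + w, :]
        return cols.reshape(n * h * w, kh * kw * c)

    wflat = weight.data.transpose(2, 3, 1, 0).reshape(kh * kw * c, co).astype(dt)
    out = (im2col() @ wflat + bias.data.astype(dt)).reshape(n, h, w, co).transpose(0, 3, 1, 2)

    def backward(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(n * h * w, co).astype(dt)
        if bias.requires_grad:
            bias._accumulate(gflat.sum(axis=0).astype(bias.data.dtype))
        if weight.requires_grad:
            dw = (im2col().T @ gflat).reshape(kh, kw, c, co).transpose(3, 2, 0, 1)
            weight._accumulate(dw.astype(weight.data.dtype))
        if x.requires_grad:
            dcols = (gflat @ wflat.T).reshape(n, h, w, kh * kw, c)
            dxpt = np.zeros_like(xpt)
            for i in range(kh):
                for j in range(kw):
                    dxpt[:, i:i + h, j:j + w, :] += dcols[:, :, :, i * kw + j, :]
            x._accumulate(
                dxpt[:, ph:h + ph, pw:w + pw, :].transpose(0, 3, 1, 2).astype(dt)
            )

    return Tensor._make(out, (x, weight, bias), backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalization over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)`` where the statistics are plain
    arrays of shape (1, C, 1, 1) for running-average bookkeeping.
    """
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    ivstd = 1.0 / np.sqrt(var + eps)
    xn = xc * ivstd
    out = gamma.data * xn + beta.data

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes, keepdims=True).astype(beta.data.dtype))
        if gamma.requires_grad:
            gamma._accumulate((g * xn).sum(axis=axes, keepdims=True).astype(gamma.data.dtype))
        if x.requires_grad:
            dxn = g * gamma.data
            t1 = dxn.sum(axis=axes, keepdims=True)
            t2 = (dxn * xn).sum(axis=axes, keepdims=True)
            x._accumulate((ivstd * (dxn - t1 / m - xn * t2 / m)).astype(x.data.dtype))

    return Tensor._make(out, (x, gamma, beta), backward), mu, var


def maxpool2(x: Tensor) -> Tensor:
    """2x2 non-overlapping max pooling; ties resolved to the first element."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    h2, w2 = h // 2, w // 2
    windows = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(dx)

    return Tensor._make(out, (x,), backward)


def _bilinear_coeffs(n_in: int):
    """Source indices and weights for 2x bilinear upsampling (half-pixel centers)."""
    o = np.arange(2 * n_in)
    src = (o + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0)
    w1[src < 0] = 0.0
    w0 = 1.0 - w1
    return i0, i1, w0, w1


def upsample_bilinear2(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of an (N, C, H, W) tensor."""
    n, c, h, w = x.data.shape
    ri0, ri1, rw0, rw1 = _bilinear_coeffs(h)
    ci0, ci1, cw0, cw1 = _bilinear_coeffs(w)
    dt = x.data.dtype
    rw0 = rw0.astype(dt)[:, None]
    rw1 = rw1.astype(dt)[:, None]
    cw0 = cw0.astype(dt)
    cw1 = cw1.astype(dt)
    rows = x.data[:, :, ri0, :] * rw0 + x.data[:, :, ri1, :] * rw1  # (N,C,2H,W)
    out = rows[:, :, :, ci0] * cw0 + rows[:, :, :, ci1] * cw1  # (N,C,2H,2W)

    def backward(g):
        if not x.requires_grad:
            return
        drows = np.zeros((n, c, 2 * h, w), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), ci0), g * cw0)
        np.add.at(drows, (slice(None), slice(None), slice(None), ci1), g * cw1)
        dx = np.zeros((n, c, h, w), dtype=g.dtype)
        np.add.at(dx, (slice(None), slice(None), ri0, slice(None)), drows * rw0)
        np.add.at(dx, (slice(None), slice(None), ri1, slice(None)), drows * rw1)
        x._accumulate(dx)

    return Tensor._make(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (s - t) / n)

    return Tensor._make(loss.mean(), (logits,), backward)
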