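"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations
applied to it; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients.  Only the primitives needed
by the model layers are implemented (broadcast-aware arithmetic,
matmul, reductions, elementwise nonlinearities, im2col convolution,
max-pooling, concatenation, reshaping).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray):
        grad = grad.astype(DTYPE, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = _make(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = _make(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def gelu(self):
        # exact GELU: x * Phi(x); d/dx = Phi(x) + x * phi(x)
        from scipy.special import erf

        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x * DTYPE(1.0 / np.sqrt(2.0))))
        out = _make(x * phi_cdf, (self,))

        def bw(g):
            pdf = np.exp(-0.5 * x * x) * DTYPE(1.0 / np.sqrt(2.0 * np.pi))
            self._accum(g * (phi_cdf + x * pdf))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data.astype(np.float64)))
        s = s.astype(DTYPE)
        out = _make(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _make(r, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / r)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


# -- free functions --------------------------------------------------------

def concat(tensors: list, axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _make(data, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Column matrix (B*Ho*Wo, C*kh*kw) for BLAS-backed convolution."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (B, Ho, Wo, C, kh, kw), (s0, s2 * stride, s3 * stride, s1, s2, s3)
    )
    return np.ascontiguousarray(view).reshape(B * Ho * Wo, C * kh * kw), Ho, Wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, Ho, Wo):
    """Fold (B*Ho*Wo, C*kh*kw) gradients back onto the input grid."""
    B, C, H, W = xshape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    d6 = dcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((B, C, Hp, Wp), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += d6[
                :, :, :, :, i, j
            ]
    if pad:
        dxp = dxp[:, :, pad : Hp - pad, pad : Wp - pad]
    return dxp


def _conv2d_depthwise(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 depthwise convolution by shift-and-add (fast for small kernels)."""
    B, C, H, W = x.shape
    _, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out_data = np.zeros((B, C, Ho, Wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            out_data += w.data[:, 0, i, j][None, :, None, None] * xp[
                :, :, i : i + Ho, j : j + Wo
            ]
    if b is not None:
        out_data += b.data.reshape(1, C, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)

    def bw(g):
        gw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + Ho, j : j + Wo]
                gw[:, 0, i, j] = (g * patch).sum(axis=(0, 2, 3))
                dxp[:, :, i : i + Ho, j : j + Wo] += (
                    w.data[:, 0, i, j][None, :, None, None] * g
                )
        w._accum(gw)
        x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0,
           groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) with im2col; supports depthwise."""
    B, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    if C != Cg * groups:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Cg * groups}")
    if groups != 1:
        if groups == C and O == C and stride == 1:
            return _conv2d_depthwise(x, w, b, pad)
        raise NotImplementedError("only groups==1 or stride-1 depthwise supported")
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, pad)  # (B*Ho*Wo, C*kh*kw)
    wm = w.data.reshape(O, C * kh * kw)
    out_data = (cols @ wm.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    out_data = np.ascontiguousarray(out_data)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
        w._accum((g2.T @ cols).reshape(w.shape))
        dcols = g2 @ wm
        x._accum(_col2im(dcols, x.shape, kh, kw, stride, pad, Ho, Wo))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
              var: np.ndarray, axes: tuple, eps: float, use_batch_stats: bool) -> Tensor:
    """Fused batch-normalization over `axes` with channel params gamma/beta.

    `mean`/`var` are the statistics to normalize with (batch statistics in
    training, running statistics in eval); gradients through the batch
    statistics are only propagated when `use_batch_stats` is True.
    """
    bshape = [1] * x.ndim
    chan_axis = next(a for a in range(x.ndim) if a not in axes)
    bshape[chan_axis] = -1
    bshape = tuple(bshape)
    inv_std = (1.0 / np.sqrt(var + eps)).astype(DTYPE).reshape(bshape)
    xhat = (x.data - mean.reshape(bshape)) * inv_std
    g_b = gamma.data.reshape(bshape)
    out = _make(xhat * g_b + beta.data.reshape(bshape), (x, gamma, beta))
    n = int(np.prod([x.shape[a] for a in axes]))

    def bw(g):
        gamma._accum((g * xhat).sum(axis=axes))
        beta._accum(g.sum(axis=axes))
        gx_hat = g * g_b
        if use_batch_stats:
            m1 = gx_hat.sum(axis=axes, keepdims=True)
            m2 = (gx_hat * xhat).sum(axis=axes, keepdims=True)
            x._accum(inv_std * (gx_hat - (m1 + xhat * m2) * DTYPE(1.0 / n)))
        else:
            x._accum(inv_std * gx_hat)

    out._backward = bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max-pooling with stride k; trailing rows/cols are dropped."""
    B, C, H, W = x.shape
    Ho, Wo = H // k, W // k
    xv = x.data[:, :, : Ho * k, : Wo * k].reshape(B, C, Ho, k, Wo, k)
    xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, k * k)
    idx = xv.argmax(axis=-1)
    out = _make(np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0], (x,))

    def bw(g):
        dxv = np.zeros((B, C, Ho, Wo, k * k), dtype=DTYPE)
        np.put_along_axis(dxv, idx[..., None], g[..., None], axis=-1)
        dxv = dxv.reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * k, : Wo * k] = dxv.reshape(B, C, Ho * k, Wo * k)
        x._accum(dx)

    out._backward = bw
    return out
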