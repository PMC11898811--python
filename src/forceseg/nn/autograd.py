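"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Provides exactly the operations the segmentation network needs: broadcasted
arithmetic, matmul, dense and depthwise im2col convolutions, bilinear
resampling, 3×3 min-pooling, softmax, sigmoid and reductions. Gradients are
accumulated by topological traversal of the recorded graph. The engine is
deliberately small — it is infrastructure for the model, not a framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "set_dtype", "get_dtype"]

_grad_enabled = True
_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global compute dtype (float32 default; float64 for checks)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype)


def get_dtype():
    return _DTYPE


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` back down to `shape` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)

        def bw(g):
            self._accumulate(-g)

        out._backward = bw if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def pow(self, exponent: float):
        out = Tensor._make(self.data**exponent, (self,), None)

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self):
        return self.pow(0.5)

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def bw(g):
            self._accumulate(g / self.data)

        out._backward = bw if out.requires_grad else None
        return out

    def exp(self):
        out = Tensor._make(np.exp(self.data), (self,), None)

        def bw(g):
            self._accumulate(g * out.data)

        out._backward = bw if out.requires_grad else None
        return out

    def clip(self, lo: float, hi: float):
        """Clamp with straight-through-zero gradient outside the range."""
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accumulate(g * inside)

        out._backward = bw if out.requires_grad else None
        return out

    # -- activations -------------------------------------------------------

    def relu(self):
        out = Tensor._make(np.maximum(self.data, 0.0), (self,), None)

        def bw(g):
            self._accumulate(g * (self.data > 0))

        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor._make(s, (self,), None)

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        out._backward = bw if out.requires_grad else None
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(s, (self,), None)

        def bw(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - inner))

        out._backward = bw if out.requires_grad else None
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,), None)

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(*axes), (self,), None)
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(*inv))

        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for a in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, a)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __matmul__ = matmul

    # -- structured ops ----------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """Dense 2-D convolution, input (N,C,H,W), weight (O,C,kh,kw)."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        O, _, kh, kw = w.shape
        cols, Ho, Wo = _im2col(x, kh, kw, stride, padding)  # (N,C,kh,kw,Ho,Wo)
        colsr = np.ascontiguousarray(cols).reshape(N, C * kh * kw, Ho * Wo)
        wmat = w.reshape(O, -1)
        y = np.matmul(wmat, colsr).reshape(N, O, Ho, Wo)
        if bias is not None:
            y = y + bias.data[None, :, None, None]
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor._make(y, parents, None)

        def bw(g):
            g2 = g.reshape(N, O, Ho * Wo)
            if weight.requires_grad:
                dw = np.matmul(g2, colsr.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(dw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.matmul(wmat.T, g2).reshape(N, C, kh, kw, Ho, Wo)
                self._accumulate(_col2im(dcols, x.shape, stride, padding))

        out._backward = bw if out.requires_grad else None
        return out

    def batch_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Fused train-mode batch normalization over (N, H, W) per channel.

        Returns (out, batch_mean, batch_var) with the statistics as plain
        arrays for running-average tracking.
        """
        x = self.data
        axes = (0, 2, 3)
        n = x.shape[0] * x.shape[2] * x.shape[3]
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        gm = gamma.data[None, :, None, None]
        y = xhat * gm + beta.data[None, :, None, None]
        out = Tensor._make(y, (self, gamma, beta), None)

        def bw(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if self.requires_grad:
                dxhat = g * gm
                m1 = dxhat.mean(axis=axes, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
                self._accumulate(inv * (dxhat - m1 - xhat * m2))

        out._backward = bw if out.requires_grad else None
        return out, mu.ravel(), var.ravel() * (n / max(1, n - 1))

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0):
        """Depthwise convolution, weight (C,kh,kw), one filter per channel."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        _, kh, kw = w.shape
        cols, Ho, Wo = _im2col(x, kh, kw, stride, padding)  # (N,C,kh,kw,Ho,Wo)
        y = np.einsum("ncijhw,cij->nchw", cols, w, optimize=True)
        if bias is not None:
            y = y + bias.data[None, :, None, None]
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor._make(y, parents, None)

        def bw(g):
            if weight.requires_grad:
                weight._accumulate(np.einsum("nchw,ncijhw->cij", g, cols, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = g[:, :, None, None, :, :] * w[None, :, :, :, None, None]
                self._accumulate(_col2im(dcols, x.shape, stride, padding))

        out._backward = bw if out.requires_grad else None
        return out

    def bilinear_resize(self, out_h: int, out_w: int):
        """Bilinear resampling of an (N,C,H,W) map via interpolation matrices."""
        N, C, H, W = self.data.shape
        Mr = _interp_matrix(H, out_h)
        Mc = _interp_matrix(W, out_w)
        y = Mr @ self.data @ Mc.T
        out = Tensor._make(y, (self,), None)

        def bw(g):
            self._accumulate(Mr.T @ g @ Mc)

        out._backward = bw if out.requires_grad else None
        return out

    def minpool3(self):
        """3×3 stride-1 min-pool with zero padding (background behaviour)."""
        x = self.data
        N, C, H, W = x.shape
        cols, Ho, Wo = _im2col(x, 3, 3, 1, 1)  # (N,C,3,3,H,W)
        flat = cols.reshape(N, C, 9, H, W)
        idx = flat.argmin(axis=2)
        y = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        out = Tensor._make(y, (self,), None)

        def bw(g):
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[:, :, None], g[:, :, None], axis=2)
            self._accumulate(_col2im(dflat.reshape(cols.shape), x.shape, 1, 1))

        out._backward = bw if out.requires_grad else None
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), None)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# im2col / col2im and interpolation helpers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        (N, C, kh, kw, Ho, Wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return cols, Ho, Wo


def _col2im(dcols: np.ndarray, x_shape: tuple, stride: int, pad: int) -> np.ndarray:
    N, C, H, W = x_shape
    kh, kw = dcols.shape[2], dcols.shape[3]
    Ho, Wo = dcols.shape[4], dcols.shape[5]
    dx = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation matrix, half-pixel centers."""
    key = (n_in, n_out, _DTYPE)
    m = _INTERP_CACHE.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=_DTYPE)
        src = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w = src - i0
        m[np.arange(n_out), i0] += 1 - w
        m[np.arange(n_out), i1] += w
        _INTERP_CACHE[key] = m
    return m
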