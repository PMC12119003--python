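"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a
``float32`` numpy array and remembers the operation that produced it.
Calling :meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True`` (and every intermediate).

Only the operations the detector needs are implemented; convolution and the
pooling primitives live in their own functions below because they carry
custom backward rules (im2col / col2im, argmax routing, median routing).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "upsample_nearest2x",
    "global_median_pool",
    "stack",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- graph bookkeeping ---------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        out = Tensor(np.power(self.data, p), _prev=(self,))

        def _bw(g):
            self._accumulate(g * p * np.power(self.data, p - 1.0))

        out._backward = _bw
        return out

    __pow__ = pow

    # -- unary ----------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / np.maximum(out.data, 1e-12))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))

        def _bw(g):
            self._accumulate(g * (s * (1.0 + self.data * (1.0 - s))))

        out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def arctan(self):
        out = Tensor(np.arctan(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / (1.0 + self.data * self.data))
        return out

    def maximum(self, other):
        other = _as_tensor(other)
        out = Tensor(np.maximum(self.data, other.data), _prev=(self, other))

        def _bw(g):
            mask = self.data >= other.data
            self._accumulate(_unbroadcast(g * mask, self.data.shape))
            other._accumulate(_unbroadcast(g * ~mask, other.data.shape))

        out._backward = _bw
        return out

    def minimum(self, other):
        other = _as_tensor(other)
        out = Tensor(np.minimum(self.data, other.data), _prev=(self, other))

        def _bw(g):
            mask = self.data <= other.data
            self._accumulate(_unbroadcast(g * mask, self.data.shape))
            other._accumulate(_unbroadcast(g * ~mask, other.data.shape))

        out._backward = _bw
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None):
        """Clip values; gradient passes through where not clipped."""
        out_data = np.clip(self.data, lo, hi)
        out = Tensor(out_data, _prev=(self,))
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data > lo
        if hi is not None:
            mask &= self.data < hi

        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _bw
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = True):
        """Max-reduction over ``axis`` (int or tuple); subgradient to argmax."""
        out_data = self.data.max(axis=axis, keepdims=True)
        out = Tensor(out_data if keepdims else np.squeeze(out_data, axis), _prev=(self,))

        def _bw(g):
            if not keepdims:
                g = np.reshape(g, out_data.shape)
            mask = self.data == out_data
            # split gradient evenly across ties
            counts = mask.sum(axis=axis, keepdims=True)
            self._accumulate(g * mask / counts)

        out._backward = _bw
        return out

    def softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            dot = (g * out.data).sum(axis=axis, keepdims=True)
            self._accumulate(out.data * (g - dot))

        out._backward = _bw
        return out


# ----------------------------------------------------------------------
# joining ops
# ----------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out._backward = _bw
    return out


# ----------------------------------------------------------------------
# convolution (im2col) and pooling primitives
# ----------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad_h: int, pad_w: int):
    """Return columns of shape (B, C, kh, kw, Hout, Wout) plus padded input shape."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad_h, pad_h), (pad_w, pad_w)))
    hout = (h + 2 * pad_h - kh) // stride + 1
    wout = (w + 2 * pad_w - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # windows: (B, C, Hp-kh+1, Wp-kw+1, kh, kw)
    windows = windows[:, :, ::stride, ::stride]  # (B, C, Hout, Wout, kh, kw)
    cols = np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3))
    return cols, xp.shape, hout, wout


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    padding: int | tuple[int, int] | None = None,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation with grouped-channel support.

    ``weight`` has shape (Cout, Cin/groups, Kh, Kw).  ``padding=None`` means
    "same" padding for odd kernels ((K-1)//2 per side).
    """
    cout, cin_g, kh, kw = weight.data.shape
    b, c, h, w = x.data.shape
    if c != cin_g * groups:
        raise ValueError(f"conv2d: input channels {c} != {cin_g}*groups({groups})")
    if cout % groups:
        raise ValueError("conv2d: out_channels must divide by groups")
    if padding is None:
        pad_h, pad_w = (kh - 1) // 2, (kw - 1) // 2
    elif isinstance(padding, tuple):
        pad_h, pad_w = padding
    else:
        pad_h = pad_w = padding

    cols, xp_shape, hout, wout = _im2col(x.data, kh, kw, stride, pad_h, pad_w)
    # group reshape: (B, g, cin_g*kh*kw, L)
    L = hout * wout
    cols_g = cols.reshape(b, groups, cin_g * kh * kw, L)
    w_g = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.einsum("gok,bgkl->bgol", w_g, cols_g, optimize=True)
    out = out.reshape(b, cout, hout, wout)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    prev = (x, weight) if bias is None else (x, weight, bias)
    res = Tensor(out, _prev=prev)

    def _bw(g):
        g4 = g.reshape(b, groups, cout // groups, L)
        # weight grad
        dw = np.einsum("bgol,bgkl->gok", g4, cols_g, optimize=True)
        weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        # input grad via col2im
        dcols = np.einsum("gok,bgol->bgkl", w_g, g4, optimize=True)
        dcols = dcols.reshape(b, c, kh, kw, hout, wout)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + hout * stride : stride, j : j + wout * stride : stride] += dcols[:, :, i, j]
        dx = dxp[:, :, pad_h : pad_h + h, pad_w : pad_w + w]
        x._accumulate(dx)

    res._backward = _bw
    return res


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int | None = None) -> Tensor:
    if padding is None:
        padding = (kernel - 1) // 2
    b, c, h, w = x.data.shape
    neg = np.finfo(np.float32).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    hout = (h + 2 * padding - kernel) // stride + 1
    wout = (w + 2 * padding - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B,C,Hout,Wout,k,k)
    flat = windows.reshape(b, c, hout, wout, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    res = Tensor(out, _prev=(x,))

    def _bw(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.divmod(idx, kernel)
        bi, ci, oi, oj = np.indices(idx.shape, sparse=False)
        rows = oi * stride + ki
        cols_ = oj * stride + kj
        np.add.at(dxp, (bi, ci, rows, cols_), g)
        x._accumulate(dxp[:, :, padding : padding + h, padding : padding + w])

    res._backward = _bw
    return res


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    res = Tensor(out, _prev=(x,))

    def _bw(g):
        b, c, h2, w2 = g.shape
        x._accumulate(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    res._backward = _bw
    return res


def global_median_pool(x: Tensor) -> Tensor:
    """Per-channel median over all H*W values -> (B, C, 1, 1).

    For an even count the median is the mean of the two middle values; the
    gradient is routed (half each) to those elements, matching the forward
    convention.
    """
    b, c, h, w = x.data.shape
    n = h * w
    flat = x.data.reshape(b, c, n)
    order = np.argsort(flat, axis=-1, kind="stable")
    if n % 2:
        mids = (order[:, :, n // 2],)
        weights = (1.0,)
    else:
        mids = (order[:, :, n // 2 - 1], order[:, :, n // 2])
        weights = (0.5, 0.5)
    med = sum(wgt * np.take_along_axis(flat, m[..., None], axis=-1)[..., 0]
              for wgt, m in zip(weights, mids))
    res = Tensor(med.reshape(b, c, 1, 1), _prev=(x,))

    def _bw(g):
        gflat = np.zeros_like(flat)
        g2 = g.reshape(b, c)
        bi, ci = np.indices((b, c))
        for wgt, m in zip(weights, mids):
            np.add.at(gflat, (bi, ci, m), wgt * g2)
        x._accumulate(gflat.reshape(x.data.shape))

    res._backward = _bw
    return res
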