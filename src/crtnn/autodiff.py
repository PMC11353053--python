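"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core on which every network in this package is built:
a small, tape-based autodiff engine in the style of classic define-by-run
frameworks.  A :class:`Tensor` wraps an ``ndarray`` together with a gradient
buffer and a closure that propagates the adjoint to its parents.  The op set
is deliberately restricted to what the models here need — elementwise
arithmetic, (batched) matmul, reductions, shape manipulation, a full-height
1-D convolution, and max pooling — each with an analytically derived
backward pass that is verified against central finite differences in the
test suite.

Convolutions are expressed as im2col gathers followed by a single GEMM, so
all heavy lifting happens inside BLAS.  The input-gradient scatter loops
over kernel taps only (indices for a fixed tap are unique, so vectorised
fancy-index accumulation is safe), never over batch or position.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (LSTM over time)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * out_data / other.data, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return Tensor._op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._accum(g * (self.data > 0))

        return Tensor._op(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(g):
            self._accum(g * np.where(self.data > 0, 1.0, neg + alpha))

        return Tensor._op(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g):
            gx = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(gx, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(gx)

        out = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._op(out, (self,), backward)

    # -- shape ops ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.data.shape

        def backward(g):
            self._accum(g.reshape(in_shape))

        return Tensor._op(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._op(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            self._accum(gx)

        return Tensor._op(out_data, (self,), backward)

    def pad_last(self, left: int, right: int):
        """Zero-pad the last axis (used for 'same' and causal convolutions)."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(left, right)]
        out_data = np.pad(self.data, width)
        T = self.data.shape[-1]

        def backward(g):
            self._accum(g[..., left : left + T])

        return Tensor._op(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._op(out_data, tuple(tensors), backward)


#: kernel width above which the dilation-1 convolution switches to the FFT path
_FFT_KERNEL_THRESHOLD = 8


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, dilation: int = 1) -> Tensor:
    """Valid multi-channel 1-D convolution (cross-correlation).

    ``x`` is ``(B, C, T)``, ``weight`` is ``(F, C, k)``; output ``(B, F, P)``
    with ``P = floor((T - (k-1)*dilation - 1)/stride) + 1``.  Padding (causal
    or 'same') is applied by the caller via :meth:`Tensor.pad_last`.

    Two execution paths compute the same quantity: narrow or dilated kernels
    use per-tap GEMMs; wide dilation-1 kernels go through circular
    cross-correlation in the Fourier domain, which is exact for the valid
    output range because the linear correlation never wraps.  Both paths are
    gradient-checked against finite differences in the test suite.
    """
    B, C, T = x.data.shape
    F, Cw, k = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv1d channel mismatch: input has {C}, weight expects {Cw}")
    span = (k - 1) * dilation + 1
    if T < span:
        raise ValueError(f"conv1d input length {T} shorter than kernel span {span}")
    P = (T - span) // stride + 1
    if dilation == 1 and k > _FFT_KERNEL_THRESHOLD:
        return _conv1d_fft(x, weight, bias, stride, P)
    return _conv1d_taps(x, weight, bias, stride, dilation, P)


def _conv1d_taps(x: Tensor, weight: Tensor, bias: Tensor | None,
                 stride: int, dilation: int, P: int) -> Tensor:
    """Direct path: one (F, C) GEMM per kernel tap."""
    B, C, T = x.data.shape
    F, _, k = weight.data.shape
    out = np.zeros((B, F, P), dtype=x.data.dtype)
    hi = stride * P
    for j in range(k):
        seg = x.data[:, :, j * dilation : j * dilation + hi : stride]  # (B, C, P)
        out += np.einsum("fc,bcp->bfp", weight.data[:, :, j], seg, optimize=True)
    if bias is not None:
        out += bias.data[:, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):  # g: (B, F, P)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(weight.data) if weight.requires_grad else None
        for j in range(k):
            sl = slice(j * dilation, j * dilation + hi, stride)
            if gw is not None:
                gw[:, :, j] = np.einsum("bfp,bcp->fc", g, x.data[:, :, sl],
                                        optimize=True)
            if gx is not None:
                gx[:, :, sl] += np.einsum("fc,bfp->bcp", weight.data[:, :, j], g,
                                          optimize=True)
        if gw is not None:
            weight._accum(gw)
        if gx is not None:
            x._accum(gx)

    return Tensor._op(out, parents, backward)


def _conv1d_fft(x: Tensor, weight: Tensor, bias: Tensor | None,
                stride: int, P: int) -> Tensor:
    """Fourier path for wide dilation-1 kernels.

    Cross-correlation theorem with transform length T: the first
    ``T - k + 1`` circular-correlation outputs equal the valid linear
    correlation, and both backward passes (a full convolution for the input
    gradient, a cross-correlation for the weight gradient) stay within the
    no-wrap range for the same reason.
    """
    B, C, T = x.data.shape
    F, _, k = weight.data.shape
    xf = np.fft.rfft(x.data, axis=-1)                 # (B, C, L)
    wf = np.fft.rfft(weight.data, n=T, axis=-1)       # (F, C, L)
    cf = np.einsum("bcl,fcl->bfl", xf, wf.conj(), optimize=True)
    full = np.fft.irfft(cf, n=T, axis=-1)             # (B, F, T)
    out = np.ascontiguousarray(full[:, :, : stride * P : stride])
    out = out.astype(x.data.dtype, copy=False)
    if bias is not None:
        out += bias.data[:, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):  # g: (B, F, P)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if not (x.requires_grad or weight.requires_grad):
            return
        gup = np.zeros((B, F, T), dtype=g.dtype)      # strided upsample of g
        gup[:, :, : stride * P : stride] = g
        gf = np.fft.rfft(gup, axis=-1)
        if x.requires_grad:
            gxf = np.einsum("bfl,fcl->bcl", gf, wf, optimize=True)
            gx = np.fft.irfft(gxf, n=T, axis=-1).astype(x.data.dtype, copy=False)
            x._accum(gx)
        if weight.requires_grad:
            gwf = np.einsum("bcl,bfl->fcl", xf, gf.conj(), optimize=True)
            gw = np.fft.irfft(gwf, n=T, axis=-1)[:, :, :k]
            weight._accum(gw.astype(weight.data.dtype, copy=False))

    return Tensor._op(out, parents, backward)


def maxpool1d(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Max pooling over the last axis of ``(..., T)``; valid windows only."""
    T = x.data.shape[-1]
    if T < kernel:
        raise ValueError(f"maxpool1d input length {T} shorter than kernel {kernel}")
    win = sliding_window_view(x.data, kernel, axis=-1)[..., ::stride, :]  # (..., P, k)
    idx = np.argmax(win, axis=-1)  # (..., P)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    P = out_data.shape[-1]

    def backward(g):
        gx = np.zeros_like(x.data)
        flat_gx = gx.reshape(-1, T)
        src = (stride * np.arange(P)[None, :] + idx.reshape(-1, P))
        rows = np.arange(flat_gx.shape[0])[:, None]
        np.add.at(flat_gx, (rows, src), g.reshape(-1, P))
        x._accum(gx)

    return Tensor._op(out_data, (x,), backward)
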