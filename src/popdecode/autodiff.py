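"""Minimal reverse-mode automatic differentiation on numpy arrays.

The decoder networks in this package (gated-recurrent variational
autoencoder with per-dimension classifier heads, plus the convolutional
and residual block families) are built on this engine.  It provides a
``Tensor`` wrapper around ``numpy.ndarray`` recording a dynamic
computation graph, and the operations the network families need:
broadcast arithmetic, matrix products, the usual nonlinearities,
reductions, shape manipulation, and 2-D convolution / transposed
convolution / max-pooling implemented via im2col.

Gradients are accumulated by a topologically ordered backward sweep.
All arrays are float64; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            self._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-grad * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        def backward(grad, out):
            self._accum(grad * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad, out):
            self._accum(grad * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad, out):
            self._accum(grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(grad, out):
            self._accum(grad * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(grad, out):
            self._accum(grad * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad, out):
            self._accum(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, alpha)

        def backward(grad, out):
            self._accum(grad * factor)

        return Tensor._make(self.data * factor, (self,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - logsumexp
        softmax = np.exp(out_data)

        def backward(grad, out):
            self._accum(grad - softmax * grad.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(grad, out):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ----------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(grad, out):
            self._accum(grad.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(self.data.ndim - 1, -1, -1))
        inverse = np.argsort(axes)

        def backward(grad, out):
            self._accum(grad.transpose(inverse))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(grad, out):
            g = np.zeros_like(self.data)
            np.add.at(g, key, grad)
            self._accum(g)

        return Tensor._make(self.data[key], (self,), backward)

    # -- backward sweep -------------------------------------------------------

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)


# -- multi-input ops ----------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(grad[tuple(idx)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(grad, out):
        pieces = np.moveaxis(grad, axis, 0)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# -- convolution via im2col ---------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: tuple[int, int, int, int]):
    """(B, C, H, W) -> columns (B, C*kh*kw, oh*ow) with zero padding."""
    pt, pb, pl, pr = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    b, c, h, w = xp.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return view.reshape(b, c * kh * kw, oh * ow), (xp.shape, oh, ow)


def _col2im(cols: np.ndarray, xp_shape, kh, kw, stride, pad, oh, ow) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back to the padded image."""
    b, c, h, w = xp_shape
    xg = np.zeros(xp_shape)
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += cols[
                :, :, i, j
            ]
    pt, pb, pl, pr = pad
    return xg[:, :, pt : h - pb, pl : w - pr]


def _same_pad(size: int, k: int, stride: int = 1) -> tuple[int, int]:
    total = max((int(np.ceil(size / stride)) - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: str = "same") -> Tensor:
    """2-D convolution (cross-correlation).  x: (B, Cin, H, W); weight: (Cout, Cin, kh, kw)."""
    b, cin, h, w = x.data.shape
    cout, _, kh, kw = weight.data.shape
    if padding == "same":
        pt, pb = _same_pad(h, kh, stride)
        pl, pr = _same_pad(w, kw, stride)
    else:
        pt = pb = pl = pr = 0
    pad = (pt, pb, pl, pr)
    cols, (xp_shape, oh, ow) = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, -1)
    out_data = np.einsum("ok,bkp->bop", wmat, cols, optimize=True)
    out_data = out_data.reshape(b, cout, oh, ow) + bias.data.reshape(1, cout, 1, 1)

    def backward(grad, out):
        gmat = grad.reshape(b, cout, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", gmat, cols, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("ok,bop->bkp", wmat, gmat, optimize=True)
            x._accum(_col2im(gcols, xp_shape, kh, kw, stride, pad, oh, ow))

    return Tensor._make(out_data, (x, weight, bias), backward)


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor, stride: int = 2
) -> Tensor:
    """Transposed 2-D convolution (adjoint of a stride-``stride`` VALID conv).

    x: (B, Cin, H, W); weight: (Cin, Cout, kh, kw); output spatial size
    (H-1)*stride + kh.
    """
    b, cin, h, w = x.data.shape
    _, cout, kh, kw = weight.data.shape
    oh = (h - 1) * stride + kh
    ow = (w - 1) * stride + kw
    wmat = weight.data.reshape(cin, cout * kh * kw)
    cols = np.einsum("bip,ik->bkp", x.data.reshape(b, cin, h * w), wmat, optimize=True)
    out_data = _col2im(
        cols, (b, cout, oh, ow), kh, kw, stride, (0, 0, 0, 0), h, w
    ) + bias.data.reshape(1, cout, 1, 1)

    def backward(grad, out):
        gcols, _ = _im2col(grad, kh, kw, stride, (0, 0, 0, 0))
        if x.requires_grad:
            gx = np.einsum("bkp,ik->bip", gcols, wmat, optimize=True)
            x._accum(gx.reshape(b, cin, h, w))
        if weight.requires_grad:
            gw = np.einsum("bip,bkp->ik", x.data.reshape(b, cin, h * w), gcols, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 2, 3)))

    return Tensor._make(out_data, (x, weight, bias), backward)


def maxpool2d(x: Tensor, k: int = 2, stride: int = 2) -> Tensor:
    """Max pooling; trailing rows/columns not covered by a full window are dropped."""
    b, c, h, w = x.data.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    if oh < 1 or ow < 1:  # degenerate spatial size: pass through
        return x
    cols, (xp_shape, _, _) = _im2col(
        x.data.reshape(b * c, 1, h, w), k, k, stride, (0, 0, 0, 0)
    )
    # cols: (b*c, k*k, oh*ow)
    arg = cols.argmax(axis=1)
    out_data = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]

    def backward(grad, out):
        gcols = np.zeros_like(cols)
        np.put_along_axis(
            gcols, arg[:, None, :], grad.reshape(b * c, 1, oh * ow), axis=1
        )
        gx = _col2im(gcols, xp_shape, k, k, stride, (0, 0, 0, 0), oh, ow)
        x._accum(gx.reshape(b, c, h, w))

    return Tensor._make(out_data.reshape(b, c, oh, ow), (x,), backward)


def crop2d(x: Tensor, target_h: int, target_w: int) -> Tensor:
    """Center-crop the two trailing spatial axes to (target_h, target_w)."""
    _, _, h, w = x.data.shape
    top = (h - target_h) // 2
    left = (w - target_w) // 2
    return x[:, :, top : top + target_h, left : left + target_w]


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    normed = centered * (var + eps) ** -0.5
    return normed * gain + bias
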