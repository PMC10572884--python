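"""Minimal reverse-mode autodiff engine with the 2-D conv-net operations
needed for encoder--decoder segmentation networks.

Arrays are NCHW float32.  The engine supports exactly the graph shapes the
segmentation models build: broadcastable elementwise arithmetic, reductions,
"same"-padded dilated convolution, 2x max-pooling, 2x nearest-neighbour
upsampling, channel concatenation/slicing and a stable channel softmax.
Convolution is evaluated as a sum over kernel offsets of pointwise channel
contractions, which keeps everything inside BLAS matmuls and is fast enough
to train small models on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "softmax",
    "instance_norm",
    "conv2d",
    "max_pool2d",
    "upsample2d",
    "concat",
    "Adam",
    "he_init",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to our operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data)
        out._parents = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent)
        out._parents = (self,)

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        out._parents = (self,)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- nonlinearities ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0))
    out._parents = (x,)
    mask = x.data > 0
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p)
    out._parents = (x,)

    def bw(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))

    out._backward = bw
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial dimensions,
    with learned scale/shift.  Keeps activations in range so deep relu
    stacks neither saturate the SoftMax head nor die."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gam = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xhat * gam + beta.data.reshape(1, -1, 1, 1))
    out._parents = (x, gamma, beta)

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gx = g * gam
        m1 = gx.mean(axis=(2, 3), keepdims=True)
        m2 = (gx * xhat).mean(axis=(2, 3), keepdims=True)
        x._accumulate(inv * (gx - m1 - xhat * m2))

    out._backward = bw
    return out


# -- spatial ops ------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 2-D convolution (odd kernels), NCHW."""
    n, c, h, wd = x.shape
    f, c2, kh, kw = w.shape
    if c2 != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ph = dilation * (kh // 2)
    pw = dilation * (kw // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out_d = np.zeros((n, f, h, wd), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd]
            out_d += np.einsum("fc,nchw->nfhw", w.data[:, :, i, j], xs, optimize=True)
    if b is not None:
        out_d += b.data.reshape(1, f, 1, 1)
    out = Tensor(out_d)
    out._parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd]
                dw[:, :, i, j] = np.einsum("nfhw,nchw->fc", g, xs, optimize=True)
                dxp[:, :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd] += np.einsum(
                    "fc,nfhw->nchw", w.data[:, :, i, j], g, optimize=True
                )
        x._accumulate(dxp[:, :, ph : ph + h, pw : pw + wd])
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    xw = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xw.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0])
    out._parents = (x,)

    def bw(g):
        gw = np.zeros_like(xw)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        x._accumulate(
            gw.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    out._backward = bw
    return out


def upsample2d(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3))
    out._parents = (x,)

    def bw(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


# -- parameters and optimisation --------------------------------------------

def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    """He-normal initialised parameter tensor (fan-in from all but dim 0)."""
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    std = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
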