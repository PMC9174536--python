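"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine provides exactly the primitives the segmentation network needs:
dense/depthwise 2-D convolution, strided transposed convolution, batch
normalization, pooling, nearest-neighbour upsampling, batched matrix products
and the usual pointwise algebra.  Arrays are float32 throughout; image batches
use the (B, C, H, W) layout.

It is intentionally small: no graphs are retained after ``backward`` and no
in-place mutation of tensor data is supported.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Linear",
    "Adam",
    "concat",
    "avg_pool2d",
    "upsample_nearest",
    "softmax",
    "clip_ste",
]

_F32 = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # defer to Tensor's reflected operators instead of numpy broadcasting
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=_F32), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

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
        self.grad = np.asarray(grad, dtype=_F32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free graph references as we go
                t._backward = None
                t._parents = ()

    # -- shape/properties ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- algebra ------------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bw(g):
            self._accum(g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        src = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, src))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        src = self.data.shape
        n = self.data.size if axis is None else np.prod(
            [src[a] for a in np.atleast_1d(axis)]
        )

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, src) / _F32(n))

        return Tensor._make(self.data.mean(axis=axis, keepdims=keepdims), (self,), bw)

    # -- pointwise nonlinearities -------------------------------------------
    def relu6(self):
        y = np.minimum(np.maximum(self.data, 0.0), 6.0)
        mask = ((self.data > 0.0) & (self.data < 6.0)).astype(_F32)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(y, (self,), bw)

    def sigmoid(self):
        z = self.data
        y = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                     np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z)))).astype(_F32)

        def bw(g):
            self._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def clip_ste(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; the gradient passes through unclipped positions only."""
    x = Tensor._coerce(x)
    mask = ((x.data > lo) & (x.data < hi)).astype(_F32)

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(np.clip(x.data, lo, hi), (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._coerce(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor._make(y, (x,), bw)


def avg_pool2d(x: Tensor, n: int) -> Tensor:
    """Non-overlapping n x n average pooling on (B, C, H, W)."""
    x = Tensor._coerce(x)
    B, C, H, W = x.data.shape
    if H % n or W % n:
        raise ValueError(f"pool size {n} does not divide spatial dims {(H, W)}")
    y = x.data.reshape(B, C, H // n, n, W // n, n).mean(axis=(3, 5))

    def bw(g):
        gx = np.repeat(np.repeat(g, n, axis=2), n, axis=3) / _F32(n * n)
        x._accum(gx)

    return Tensor._make(y, (x,), bw)


def upsample_nearest(x: Tensor, n: int) -> Tensor:
    x = Tensor._coerce(x)
    B, C, H, W = x.data.shape
    y = np.repeat(np.repeat(x.data, n, axis=2), n, axis=3)

    def bw(g):
        gx = g.reshape(B, C, H, n, W, n).sum(axis=(3, 5))
        x._accum(gx)

    return Tensor._make(y, (x,), bw)


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (B, C, Ho, Wo, kh, kw) over a padded (B, C, H, W) array."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation of (B, C, H, W) with (Cout, C/g, kh, kw)."""
    x, w = Tensor._coerce(x), Tensor._coerce(w)
    B, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    if C != Cg * groups or Cout % groups:
        raise ValueError("channel/group mismatch in conv2d")

    if kh == kw == 1 and padding == 0:
        return _conv1x1(x, w, stride, groups)
    if groups == C and Cg == 1 and Cout == C:
        return _conv_depthwise(x, w, stride, padding)

    pad = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    win = _windows(xp, kh, kw, stride)  # (B, C, Ho, Wo, kh, kw)
    Ho, Wo = win.shape[2], win.shape[3]

    G = groups
    Cog = Cout // G
    wv = w.data.reshape(G, Cog, Cg * kh * kw)
    winv = (
        win.reshape(B, G, Cg, Ho, Wo, kh, kw)
        .transpose(0, 1, 3, 4, 2, 5, 6)
        .reshape(B, G, Ho * Wo, Cg * kh * kw)
    )
    y = np.matmul(winv, wv.transpose(0, 2, 1))  # (B, G, HoWo, Cog)
    y = y.transpose(0, 1, 3, 2).reshape(B, Cout, Ho, Wo)

    def bw(g):
        g = np.ascontiguousarray(g)
        gv = g.reshape(B, G, Cog, Ho * Wo)
        if w.requires_grad:
            gw = np.matmul(gv, winv).sum(axis=0)  # (G, Cog, CgK)
            w._accum(gw.reshape(Cout, Cg, kh, kw))
        if x.requires_grad:
            gc = np.matmul(wv.transpose(0, 2, 1), gv)  # (B, G, CgK, HoWo)
            gcol = gc.reshape(B, C, kh, kw, Ho, Wo)
            gx = np.zeros_like(xp)
            for a in range(kh):
                for b in range(kw):
                    gx[:, :, a:a + stride * Ho:stride,
                       b:b + stride * Wo:stride] += gcol[:, :, a, b]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return Tensor._make(y, (x, w), bw)


def _conv_depthwise(x: Tensor, w: Tensor, stride: int, padding: int) -> Tensor:
    """Per-channel 3x3 (or kxk) convolution as k*k shifted multiply-adds."""
    B, C, H, W = x.data.shape
    _, _, kh, kw = w.data.shape
    pad = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    y = np.zeros((B, C, Ho, Wo), dtype=_F32)
    for a in range(kh):
        for b in range(kw):
            y += w.data[None, :, 0, a, b, None, None] * \
                xp[:, :, a:a + stride * Ho:stride, b:b + stride * Wo:stride]

    def bw(g):
        if w.requires_grad:
            gw = np.empty((C, 1, kh, kw), dtype=_F32)
            for a in range(kh):
                for b in range(kw):
                    gw[:, 0, a, b] = (
                        g * xp[:, :, a:a + stride * Ho:stride,
                               b:b + stride * Wo:stride]
                    ).sum(axis=(0, 2, 3))
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for a in range(kh):
                for b in range(kw):
                    gx[:, :, a:a + stride * Ho:stride,
                       b:b + stride * Wo:stride] += \
                        w.data[None, :, 0, a, b, None, None] * g
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return Tensor._make(y, (x, w), bw)


def _conv1x1(x: Tensor, w: Tensor, stride: int, groups: int) -> Tensor:
    B, C, H, W = x.data.shape
    Cout = w.data.shape[0]
    xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    Ho, Wo = xd.shape[2], xd.shape[3]
    if groups != 1:
        raise NotImplementedError("grouped 1x1 convolution is not used")
    wv = w.data.reshape(Cout, C)
    x3 = np.ascontiguousarray(xd).reshape(B, C, Ho * Wo)
    y = np.matmul(wv, x3).reshape(B, Cout, Ho, Wo)

    def bw(g):
        g3 = np.ascontiguousarray(g).reshape(B, Cout, Ho * Wo)
        if w.requires_grad:
            gw = np.matmul(g3, x3.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(Cout, C, 1, 1))
        if x.requires_grad:
            gxd = np.matmul(wv.T, g3).reshape(B, C, Ho, Wo)
            if stride > 1:
                gx = np.zeros_like(x.data)
                gx[:, :, ::stride, ::stride] = gxd
            else:
                gx = gxd
            x._accum(gx)

    return Tensor._make(y, (x, w), bw)


def conv_transpose2d(x: Tensor, w: Tensor, stride: int = 2,
                     padding: int = 1) -> Tensor:
    """Transposed convolution; ``w`` has shape (Cin, Cout, kh, kw)."""
    x, w = Tensor._coerce(x), Tensor._coerce(w)
    B, C, H, W = x.data.shape
    Cin, Cout, kh, kw = w.data.shape
    if C != Cin:
        raise ValueError("channel mismatch in conv_transpose2d")
    Ho = (H - 1) * stride + kh - 2 * padding
    Wo = (W - 1) * stride + kw - 2 * padding

    wv = w.data.reshape(Cin, Cout * kh * kw)
    col = np.matmul(
        x.data.transpose(0, 2, 3, 1).reshape(B, H * W, Cin), wv
    ).reshape(B, H, W, Cout, kh, kw)
    col = col.transpose(0, 3, 4, 5, 1, 2)  # (B, Cout, kh, kw, H, W)
    yp = np.zeros((B, Cout, Ho + 2 * padding, Wo + 2 * padding), dtype=_F32)
    for a in range(kh):
        for b in range(kw):
            yp[:, :, a:a + stride * H:stride, b:b + stride * W:stride] += col[:, :, a, b]
    y = yp[:, :, padding:padding + Ho, padding:padding + Wo] if padding else yp

    def bw(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else g
        win = _windows(gp, kh, kw, stride)  # (B, Cout, H, W, kh, kw)
        if x.requires_grad:
            gx = np.einsum("boijhw,cohw->bcij", win, w.data, optimize=True)
            x._accum(gx)
        if w.requires_grad:
            gw = np.einsum("bcij,boijhw->cohw", x.data, win, optimize=True)
            w._accum(gw)

    return Tensor._make(y, (x, w), bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization on (B, C, H, W).

    ``running_mean``/``running_var`` are plain float32 arrays mutated in place
    when ``training`` is true.
    """
    x = Tensor._coerce(x)
    B, C, H, W = x.data.shape
    m = B * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        # unbiased estimate for the running buffer, as is conventional
        unbiased = var * (m / max(m - 1, 1))
        running_var += momentum * (unbiased - running_var)
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        gamma._accum(np.einsum("bchw,bchw->c", g, xhat, optimize=True))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxh = g * gamma.data[None, :, None, None]
        if training:
            s1 = gxh.sum(axis=(0, 2, 3))
            s2 = (gxh * xhat).sum(axis=(0, 2, 3))
            gx = (gxh - (s1[None, :, None, None]
                         + xhat * s2[None, :, None, None]) / m) \
                * inv[None, :, None, None]
        else:
            gx = gxh * inv[None, :, None, None]
        x._accum(gx)

    return Tensor._make(y, (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny module system with named parameters and train/eval modes."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module"):
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=_F32).reshape(p.data.shape)
        for n, b in self.named_buffers():
            b[...] = np.asarray(state["buffer:" + n], dtype=_F32)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_F32)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel_size, stride=1, padding=0, groups=1,
                 bias=False, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (cin // groups) * k * k
        self.weight = Parameter(
            kaiming_uniform(rng, (cout, cin // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=_F32)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def __call__(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, self.stride, self.padding, self.groups)
        if self.bias is not None:
            y = y + self.bias.reshape(1, -1, 1, 1)
        return y


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, kernel_size=4, stride=2, padding=1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.weight = Parameter(
            kaiming_uniform(rng, (cin, cout, k, k), cin * k * k))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=_F32))
        self.beta = Parameter(np.zeros(c, dtype=_F32))
        self.register_buffer("running_mean", np.zeros(c, dtype=_F32))
        self.register_buffer("running_var", np.ones(c, dtype=_F32))
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class Linear(Module):
    def __init__(self, fin, fout, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(kaiming_uniform(rng, (fin, fout), fin))
        self.bias = Parameter(np.zeros(fout, dtype=_F32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Adam:
    """Adam with additive (coupled) L2 weight decay."""

    def __init__(self, params, lr=4e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
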