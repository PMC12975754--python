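"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The counting network, its attention blocks and the composite loss are all
expressed with the :class:`Tensor` type defined here.  The engine is
deliberately small: dense broadcasting ops, matmul, 2-D/1-D convolution with
im2col, pooling, batch normalization, softmax and indexing — exactly what a
VGG-style backbone with attention and point-proposal heads needs.  Gradients
are accumulated by topological sort over the recorded graph.

Arrays keep whatever float dtype they come in with (float32 for network
parameters, float64 where exact arithmetic matters in tests).
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

# ---------------------------------------------------------------------------
# Graph recording
# ---------------------------------------------------------------------------

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference / metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # release graph references as we go
            node._backward = None
            node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float):
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a, eps: float = 0.0):
    a = astensor(a)
    out_data = np.sqrt(a.data + eps)

    def backward(g):
        a._accum(g * 0.5 / np.maximum(out_data, 1e-12))

    return _make(out_data, (a,), backward)


def relu(a):
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def hinge(a):
    """max(0, a) — alias of relu kept for loss readability."""
    return relu(a)


def maximum(a, b):
    a, b = astensor(a), astensor(b)
    amask = a.data >= b.data
    out_data = np.where(amask, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * amask, a.shape))
        b._accum(_unbroadcast(g * (~amask), b.shape))

    return _make(out_data, (a, b), backward)


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).astype(a.dtype))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def softmax(a, axis=-1):
    a = astensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    return _make(s, (a,), backward)


# ---------------------------------------------------------------------------
# Shape / indexing
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = astensor(a)
    out_data = a.data.reshape(shape)
    in_shape = a.shape

    def backward(g):
        a._accum(g.reshape(in_shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes=None):
    a = astensor(a)
    out_data = a.data.transpose(axes)
    if axes is None:
        inv = None
    else:
        inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(out_data, (a,), backward)


def take(a, idx):
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accum(buf)

    return _make(out_data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return _make(out_data, tuple(tensors), backward)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# Convolution / pooling (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D convolution, x (N,Cin,H,W), w (Cout,Cin,kh,kw), b (Cout,)."""
    x, w = astensor(x), astensor(w)
    N, Cin, H, W = x.shape
    Cout, _, kh, kw = w.shape
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (xp.shape[2] - kh) // s + 1
    Wo = (xp.shape[3] - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (N,Cin,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out = cols @ wmat.T  # (N, Ho*Wo, Cout)
    if b is not None:
        b = astensor(b)
        out = out + b.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1).reshape(N, Cout, Ho, Wo))

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(N, Cout, Ho * Wo).transpose(0, 2, 1)  # (N, HoWo, Cout)
        gw = np.einsum("npc,npk->ck", gmat, cols, optimize=True)
        w._accum(gw.reshape(w.shape))
        if b is not None:
            b._accum(gmat.sum(axis=(0, 1)))
        gcols = gmat @ wmat  # (N, HoWo, Cin*kh*kw)
        gcols = gcols.reshape(N, Ho, Wo, Cin, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        gx = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gx[:, :, u : u + s * Ho : s, v : v + s * Wo : s] += gcols[:, :, u, v]
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)

    return _make(out_data, parents, backward)


def depthwise_conv2d(x, w, b=None, padding: int = 1):
    """Depthwise 3x3-style convolution, w (C,kh,kw), stride 1."""
    x, w = astensor(x), astensor(w)
    N, C, H, W = x.shape
    _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwuv,cuv->nchw", win, w.data, optimize=True)
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gw = np.einsum("nchw,nchwuv->cuv", g, win, optimize=True)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gx = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gx[:, :, u : u + H, v : v + W] += g * w.data[None, :, u, v, None, None]
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)

    return _make(out_data, parents, backward)


def conv1d_channels(x, w):
    """1-D convolution along the channel axis with zero padding (ECA).

    x: (N, C) per-channel descriptors; w: (k,) kernel, k odd.
    """
    x, w = astensor(x), astensor(w)
    N, C = x.shape
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (N, C, k)
    out_data = win @ w.data

    def backward(g):
        w._accum(np.einsum("nc,nck->k", g, win, optimize=True))
        gx = np.zeros_like(xp)
        for u in range(k):
            gx[:, u : u + C] += g * w.data[u]
        x._accum(gx[:, p : p + C] if p else gx)

    return _make(out_data, (x, w), backward)


def maxpool2d(x, k: int = 2):
    x = astensor(x)
    N, C, H, W = x.shape
    Ho, Wo = H // k, W // k
    win = x.data[:, :, : Ho * k, : Wo * k].reshape(N, C, Ho, k, Wo, k)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros((N, C, Ho, Wo, k * k), dtype=x.dtype)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gwin = gflat.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, : Ho * k, : Wo * k] = gwin.reshape(N, C, Ho * k, Wo * k)
        x._accum(gx)

    return _make(out_data, (x,), backward)


def global_avg_pool(x):
    """(N,C,H,W) -> (N,C) channel descriptors."""
    x = astensor(x)
    N, C, H, W = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (H * W), x.shape).astype(x.dtype))

    return _make(out_data, (x,), backward)


def upsample_nearest(x, factor: int):
    x = astensor(x)
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    N, C, H, W = x.shape

    def backward(g):
        gx = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
        x._accum(gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny nn-module: tracks parameters and submodules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, m in self._modules.items():
            for k, v in m._buffers().items():
                d[f"{n}.{k}"] = v.copy()
        return d

    def load_state_dict(self, d: dict) -> None:
        params = dict(self.named_parameters())
        for name, arr in d.items():
            if name in params:
                params[name].data = arr.copy()
            else:
                self._set_buffer(name, arr)

    def _buffers(self) -> dict:
        out = {}
        for k in getattr(self, "_buffer_names", ()):
            out[k] = getattr(self, k)
        for n, m in self._modules.items():
            for k, v in m._buffers().items():
                out[f"{n}.{k}"] = v
        return out

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj._modules[p]
        object.__setattr__(obj, parts[-1], arr.copy())


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        name = str(len(self._items))
        self._items.append(m)
        self._modules[name] = m
        return self

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


def _kaiming(shape, fan_in, rng, dtype=np.float32):
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, padding=None, rng=None, init_scale=1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.kernel = k
        self.cin, self.cout = cin, cout
        w = _kaiming((cout, cin, k, k), cin * k * k, rng) * init_scale
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels, k=3, rng=None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((channels, k, k), dtype=np.float32)
        else:
            w = _kaiming((channels, k, k), k * k, rng)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.padding = k // 2

    def __call__(self, x):
        return depthwise_conv2d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    def __init__(self, cin, cout, rng=None, init_scale=1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming((cin, cout), cin, rng) * init_scale, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        object.__setattr__(self, "running_mean", np.zeros(channels, dtype=np.float32))
        object.__setattr__(self, "running_var", np.ones(channels, dtype=np.float32))

    def __call__(self, x):
        x = astensor(x)
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean[:] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[:] = (1 - self.momentum) * self.running_var + self.momentum * var
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat_data = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]

            def backward(g):
                # grads w.r.t. gamma/beta then the batchnorm input formula
                self.gamma._accum((g * xhat_data).sum(axis=(0, 2, 3)))
                self.beta._accum(g.sum(axis=(0, 2, 3)))
                gxhat = g * self.gamma.data[None, :, None, None]
                t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (gxhat * xhat_data).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv[None, :, None, None] / n) * (n * gxhat - t1 - xhat_data * t2)
                x._accum(gx.astype(x.dtype))

            out_data = xhat_data * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
            return _make(out_data, (x, self.gamma, self.beta), backward)
        # eval: affine transform with frozen statistics
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * inv
        shift = self.beta.data - self.running_mean * scale
        return x * Tensor(scale[None, :, None, None]) + Tensor(shift[None, :, None, None])


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = ModuleList([l for l in layers if isinstance(l, Module)])
        self._chain = layers

    def __call__(self, x):
        for l in self._chain:
            x = l(x) if isinstance(l, Module) else l(x)
        return x


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adam with parameter groups; per-group lr scale and L2 weight decay.

    Each group: {"params": [Tensor], "lr_scale": float, "weight_decay": float}.
    step(lr) uses lr * lr_scale for each group.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {}
        for g in self.groups:
            for p in g["params"]:
                self.state[id(p)] = (
                    np.zeros_like(p.data, dtype=np.float32),
                    np.zeros_like(p.data, dtype=np.float32),
                )

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for g in self.groups:
            glr = lr * g.get("lr_scale", 1.0)
            wd = g.get("weight_decay", 0.0)
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad
                if wd:
                    grad = grad + wd * p.data
                m, v = self.state[id(p)]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                p.data = p.data - glr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    total = math.sqrt(total)
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total
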