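"""Minimal reverse-mode autodiff and neural-network layers on numpy.

The model components in this package (dilated-attention image branch, temporal
convolutional chemical branch, gated fusion) are small enough to train on a
single CPU, so the whole stack runs on a compact tape-based autodiff engine:
:class:`Tensor` records the operations applied to it, ``Tensor.backward()``
replays them in reverse topological order.  Layers follow the familiar
``Module`` / ``Parameter`` idiom; all parameter initialisation is driven by an
explicit :class:`numpy.random.Generator`, so identical seeds give identical
models and training runs.

Shapes follow the channels-first convention: images are ``(N, C, H, W)``,
sequences ``(N, C, T)``.
"""

from __future__ import annotations

import copy
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Sequential", "ModuleList",
    "Linear", "Conv2d", "Conv1dCausal", "BatchNorm1d", "BatchNorm2d",
    "AdamW",
    "add", "sub", "mul", "div", "neg", "matmul", "concat", "reshape",
    "relu", "relu6", "sigmoid", "sqrt", "tensor_sum", "tensor_mean",
    "conv2d", "depthwise_conv2d", "conv1d_causal", "tile_spatial",
    "softmax_cross_entropy", "softmax",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# Tensor and autodiff core
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for stacked convs
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # Operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _node(data, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    req = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, requires_grad=req,
                  parents=tuple(parents), backward=backward if req else None)


# ---------------------------------------------------------------------------
# Elementwise / linear algebra ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(-_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(-g)

    return _node(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _node(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _node(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def relu6(a: Tensor) -> Tensor:
    mask = (a.data > 0) & (a.data < 6)

    def backward(g):
        a._accumulate(g * mask)

    return _node(np.clip(a.data, 0.0, 6.0), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    s = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / s)

    return _node(s, (a,), backward)


def tensor_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.shape).astype(a.data.dtype))

    return _node(out_data, (a,), backward)


def tensor_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.data.size / out_data.size

    def backward(g):
        gg = np.asarray(g) / count
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.shape).astype(a.data.dtype))

    return _node(out_data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _node(out_data, tuple(tensors), backward)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _node(a.data.reshape(shape), (a,), backward)


def tile_spatial(a: Tensor, h: int, w: int) -> Tensor:
    """Broadcast an (N, C, 1, 1) map to (N, C, h, w).

    This is what bilinear interpolation of a 1x1 map degenerates to, so the
    global-context branch uses it directly.
    """
    if a.shape[-2:] != (1, 1):
        raise ValueError("tile_spatial expects an (N, C, 1, 1) input")
    out_data = np.broadcast_to(a.data, a.shape[:-2] + (h, w)).copy()

    def backward(g):
        a._accumulate(g.sum(axis=(-2, -1), keepdims=True))

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

def _conv_out_size(size: int, k: int, stride: int, pad: int, dil: int) -> int:
    return (size + 2 * pad - dil * (k - 1) - 1) // stride + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, ``x`` (N,C,H,W) with ``w`` (O,C,kh,kw).

    Implemented as im2col + one GEMM so the heavy lifting happens in BLAS.
    """
    n, c, h_in, w_in = x.shape
    o, c_w, kh, kw = w.shape
    if c != c_w:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c_w}")
    oh = _conv_out_size(h_in, kh, stride, padding, dilation)
    ow = _conv_out_size(w_in, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win_h = (kh - 1) * dilation + 1
    win_w = (kw - 1) * dilation + 1
    swv = np.lib.stride_tricks.sliding_window_view(xp, (win_h, win_w),
                                                   axis=(2, 3))
    swv = swv[:, :, ::stride, ::stride, ::dilation, ::dilation]
    # (N, C, OH, OW, kh, kw) -> (N*OH*OW, C*kh*kw)
    patches = np.ascontiguousarray(swv.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * kh * kw)
    w2 = w.data.reshape(o, c * kh * kw)
    out = (patches @ w2.T).reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            n * oh * ow, o)
        w._accumulate((g2.T @ patches).reshape(w.shape))
        dpatches = (g2 @ w2).reshape(n, oh, ow, c, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i * dilation: i * dilation + (oh - 1) * stride + 1: stride,
                    j * dilation: j * dilation + (ow - 1) * stride + 1: stride] += \
                    dpatches[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Depthwise 2-D convolution, ``w`` of shape (C, kh, kw)."""
    n, c, h_in, w_in = x.shape
    c_w, kh, kw = w.shape
    if c != c_w:
        raise ValueError(f"depthwise_conv2d channel mismatch: input {c}, weight {c_w}")
    oh = _conv_out_size(h_in, kh, stride, padding, dilation)
    ow = _conv_out_size(w_in, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out = np.zeros((n, c, oh, ow), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * dilation: i * dilation + (oh - 1) * stride + 1: stride,
                    j * dilation: j * dilation + (ow - 1) * stride + 1: stride]
            out += xs * w.data[None, :, i, j, None, None]
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                sl_h = slice(i * dilation, i * dilation + (oh - 1) * stride + 1, stride)
                sl_w = slice(j * dilation, j * dilation + (ow - 1) * stride + 1, stride)
                xs = xp[:, :, sl_h, sl_w]
                dw[:, i, j] = (g * xs).sum(axis=(0, 2, 3))
                dxp[:, :, sl_h, sl_w] += g * w.data[None, :, i, j, None, None]
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv1d_causal(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                  dilation: int = 1) -> Tensor:
    """Causal dilated 1-D convolution preserving sequence length.

    ``x`` is (N, C, T), ``w`` is (O, C, K).  The input is left-padded with
    ``dilation * (K - 1)`` zeros so output step t only sees inputs at steps
    <= t, spaced ``dilation`` apart.
    """
    n, c, t = x.shape
    o, c_w, k = w.shape
    if c != c_w:
        raise ValueError(f"conv1d_causal channel mismatch: input {c}, weight {c_w}")
    pad = dilation * (k - 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, 0)))
    out = np.zeros((n, o, t), dtype=x.data.dtype)
    for i in range(k):
        xs = xp[:, :, i * dilation: i * dilation + t]
        out += np.matmul(w.data[:, :, i], xs)
    if b is not None:
        out += b.data[None, :, None]

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(k):
            sl = slice(i * dilation, i * dilation + t)
            xs = xp[:, :, sl]
            dw[:, :, i] = np.tensordot(g, xs, axes=([0, 2], [0, 2]))
            dxp[:, :, sl] += np.matmul(w.data[:, :, i].T, g)
        if pad:
            dxp = dxp[:, :, pad:]
        x._accumulate(dxp)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    labels = np.asarray(labels)
    p = softmax(logits.data)
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = nll.mean()

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    return _node(np.asarray(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterable["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- persistence -------------------------------------------------------
    def _named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(full + ".")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p in self.named_parameters()}
        bufs = dict(self._named_buffers())
        for name, value in state.items():
            if name in own:
                if own[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = value.copy()
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")


class ModuleList(Module):
    def __init__(self, mods: Sequence[Module] = ()):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._n = len(mods)

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __len__(self):
        return self._n

    def append(self, m: Module) -> None:
        setattr(self, str(self._n), m)
        self._n += 1


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class ReLU6(Module):
    def forward(self, x):
        return relu6(x)


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int,
             dtype=np.float32) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


class Conv2d(Module):
    """2-D convolution; ``groups`` must be 1 (dense) or ``in_channels`` (depthwise)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1, padding: int = 0,
                 dilation: int = 1, groups: int = 1, bias: bool = True):
        super().__init__()
        if groups not in (1, in_channels):
            raise ValueError("groups must be 1 or in_channels")
        if groups == in_channels and out_channels != in_channels:
            raise ValueError("depthwise conv requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.depthwise = groups != 1
        k = kernel_size
        if self.depthwise:
            self.weight = Parameter(_kaiming(rng, (in_channels, k, k), k * k))
        else:
            self.weight = Parameter(
                _kaiming(rng, (out_channels, in_channels, k, k), in_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        fn = depthwise_conv2d if self.depthwise else conv2d
        return fn(x, self.weight, self.bias, stride=self.stride,
                  padding=self.padding, dilation=self.dilation)


class Conv1dCausal(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, dilation: int = 1, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.dilation = dilation
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels, kernel_size),
                     in_channels * kernel_size))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return conv1d_causal(x, self.weight, self.bias, dilation=self.dilation)


class _BatchNorm(Module):
    def __init__(self, num_features: int, eps: float = BN_EPS,
                 momentum: float = BN_MOMENTUM):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = tuple(self.num_features if i == 1 else 1 for i in range(x.ndim))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu = self.running_mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
        out = self.weight.data.reshape(shape) * xhat + self.bias.data.reshape(shape)
        gamma, beta, training = self.weight, self.bias, self.training

        def backward(g):
            gamma._accumulate((g * xhat).sum(axis=axes))
            beta._accumulate(g.sum(axis=axes))
            gi = gamma.data.reshape(shape) * inv.reshape(shape)
            if training:
                mean_g = g.mean(axis=axes).reshape(shape)
                mean_gx = (g * xhat).mean(axis=axes).reshape(shape)
                x._accumulate(gi * (g - mean_g - xhat * mean_gx))
            else:
                x._accumulate(gi * g)

        return _node(out, (x, self.weight, self.bias), backward)


class BatchNorm1d(_BatchNorm):
    pass


class BatchNorm2d(_BatchNorm):
    pass


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - self.lr * (update + self.weight_decay * p.data).astype(
                p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clone_state(module: Module) -> dict[str, np.ndarray]:
    """Deep-copied state dict, for best-checkpoint bookkeeping."""
    return copy.deepcopy(module.state_dict())
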