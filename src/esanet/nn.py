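"""Minimal numpy neural-network core.

Implements exactly the layer zoo needed by the classifiers in this package:
2-D convolution (grouped / depthwise included), batch normalization, ReLU /
ReLU6, max / average / adaptive-average pooling, linear layers, dropout and a
handful of containers, each with an explicit ``forward``/``backward`` pair so
models can be trained with reverse-mode gradients without an autograd engine.

Conventions follow the mainstream deep-learning frameworks: tensors are
``float32`` arrays laid out N×C×H×W, convolution weights are
``(C_out, C_in/groups, k, k)``, batch-norm keeps running statistics updated
with momentum 0.1, and convolutions are initialised with fan-out-scaled
normal weights.

Every leaf layer also knows its own static complexity (``num_params`` and
``macs(input_shape)``) and shape arithmetic (``out_shape``), which is what the
:mod:`esanet.complexity` profiler walks — profiling never requires a forward
pass.
"""

from __future__ import annotations

import copy
import math
from typing import Iterator

import numpy as np

# ---------------------------------------------------------------------------
# Global RNG — all stochastic components (weight init, dropout, shuffling,
# augmentation) draw from this generator so a single seed fixes a run.
# ---------------------------------------------------------------------------

_GLOBAL_RNG = np.random.default_rng(0)


def set_rng(seed: int) -> None:
    """Re-seed the package-wide random generator."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _GLOBAL_RNG


class Parameter:
    """A learnable array together with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class: tracks child modules/parameters, train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def children(self) -> list["Module"]:
        return list(self._children.values())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for c in self._children.values():
            c.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.value.copy() for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            state[n] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for n, p in own.items():
            if n not in state:
                raise KeyError(f"missing parameter {n!r} in state dict")
            if state[n].shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {n!r}: {state[n].shape} vs {p.value.shape}"
                )
            p.value = np.array(state[n], dtype=np.float32)
        for n, _ in self.named_buffers():
            if n in state:
                self._set_buffer_by_path(n, np.array(state[n]))

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):  # leaf classes declare
            yield prefix + name, getattr(self, name)
        for name, child in self._children.items():
            yield from child.named_buffers(prefix + name + ".")

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        parts = path.split(".")
        mod = self
        for p in parts[:-1]:
            mod = mod._children[p]
        object.__setattr__(mod, parts[-1], value)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- compute ------------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    # -- complexity ---------------------------------------------------------
    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError

    def profile_rows(self, in_shape, prefix=""):
        """Yield ``(name, kind, params, macs)`` rows; return the output shape.

        Containers override this to mirror their forward dataflow; leaf
        layers get the default single-row implementation.
        """
        rows = [(prefix.rstrip("."), type(self).__name__, self.num_params(),
                 self.macs(in_shape))]
        return rows, self.out_shape(in_shape)

    def macs(self, in_shape: tuple[int, ...]) -> int:
        return 0


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Module):
    """Grouped 2-D convolution (cross-correlation, as in every framework).

    ``groups=in_channels`` with ``out_channels=in_channels`` is a depthwise
    convolution; ``kernel_size=1, groups=1`` is a pointwise convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = False):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_out = kernel_size * kernel_size * out_channels // groups
        w = get_rng().normal(
            0.0, math.sqrt(2.0 / fan_out),
            size=(out_channels, in_channels // groups, kernel_size, kernel_size),
        )
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._x = None

    # shape arithmetic -------------------------------------------------------
    def _spatial_out(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def out_shape(self, in_shape):
        n, c, h, w = in_shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        ho, wo = self._spatial_out(h, w)
        return (n, self.out_channels, ho, wo)

    def macs(self, in_shape):
        n, _, h, w = in_shape
        ho, wo = self._spatial_out(h, w)
        per_out = (self.in_channels // self.groups) * self.kernel_size ** 2
        if self.bias is not None:
            per_out += 1
        return n * self.out_channels * ho * wo * per_out

    # compute ----------------------------------------------------------------
    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, g = self.kernel_size, self.stride, self.groups
        ho, wo = self._spatial_out(h, w)
        if ho < 1 or wo < 1:
            raise ValueError("input spatially smaller than the kernel")
        xp = _pad2d(x, self.padding)
        self._x = x
        self._xp_shape = xp.shape
        og = self.out_channels // g
        cg = self.in_channels // g
        y = np.zeros((n, self.out_channels, ho, wo), dtype=np.float32)
        xg = xp.reshape(n, g, cg, xp.shape[2], xp.shape[3])
        yg = y.reshape(n, g, og, ho, wo)
        wg = self.weight.value.reshape(g, og, cg, k, k)
        hi = (ho - 1) * s + 1
        wi = (wo - 1) * s + 1
        for i in range(k):
            for j in range(k):
                xs = xg[:, :, :, i:i + hi:s, j:j + wi:s]
                yg += np.einsum("ngchw,goc->ngohw", xs, wg[:, :, :, i, j],
                                optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._xp = xp if self.padding else x
        return y

    def backward(self, dy):
        x = self._x
        n = x.shape[0]
        k, s, g, p = self.kernel_size, self.stride, self.groups, self.padding
        ho, wo = dy.shape[2], dy.shape[3]
        og = self.out_channels // g
        cg = self.in_channels // g
        xp = self._xp
        xg = xp.reshape(n, g, cg, xp.shape[2], xp.shape[3])
        dyg = dy.reshape(n, g, og, ho, wo)
        wg = self.weight.value.reshape(g, og, cg, k, k)
        dwg = self.weight.grad.reshape(g, og, cg, k, k)
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        dxg = dxp.reshape(n, g, cg, dxp.shape[2], dxp.shape[3])
        hi = (ho - 1) * s + 1
        wi = (wo - 1) * s + 1
        for i in range(k):
            for j in range(k):
                xs = xg[:, :, :, i:i + hi:s, j:j + wi:s]
                dwg[:, :, :, i, j] += np.einsum("ngchw,ngohw->goc", xs, dyg,
                                                optimize=True)
                dxg[:, :, :, i:i + hi:s, j:j + wi:s] += np.einsum(
                    "ngohw,goc->ngchw", dyg, wg[:, :, :, i, j], optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with affine transform."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        object.__setattr__(self, "_buffers", ("running_mean", "running_var"))
        object.__setattr__(self, "running_mean", np.zeros(num_features, np.float32))
        object.__setattr__(self, "running_var", np.ones(num_features, np.float32))

    def out_shape(self, in_shape):
        return in_shape

    def macs(self, in_shape):
        # calibrated profiler convention: 4 ops per element for affine BN
        return 4 * int(np.prod(in_shape))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            nel = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * nel / max(nel - 1, 1)
            self._set_buffer_by_path(
                "running_mean", (1 - m) * self.running_mean + m * mu)
            self._set_buffer_by_path(
                "running_var", (1 - m) * self.running_var + m * unbiased)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv = xhat, inv
        return (self.weight.value[None, :, None, None] * xhat
                + self.bias.value[None, :, None, None])

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.weight.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        g = self.weight.value[None, :, None, None]
        if not self.training:
            return dy * g * inv[None, :, None, None]
        nel = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dy.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        s2 = (dy * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        dx = (g * inv[None, :, None, None] / nel) * (nel * dy - s1 - xhat * s2)
        return dx.astype(np.float32)


class ReLU(Module):
    def __init__(self, max_value: float | None = None):
        super().__init__()
        self.max_value = max_value

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x):
        y = np.maximum(x, 0.0)
        if self.max_value is not None:
            y = np.minimum(y, self.max_value)
        self._mask = (x > 0.0) if self.max_value is None else ((x > 0.0) & (x < self.max_value))
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def out_shape(self, in_shape):
        n, c, h, w = in_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        return (n, c, (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def forward(self, x):
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        _, _, ho, wo = self.out_shape(x.shape)
        hi = (ho - 1) * s + 1
        wi = (wo - 1) * s + 1
        best = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
        idx = np.zeros((n, c, ho, wo), dtype=np.int8)
        for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            xs = xp[:, :, i:i + hi:s, j:j + wi:s]
            m = xs > best
            best = np.where(m, xs, best)
            idx[m] = t
        self._idx, self._in_shape = idx, x.shape
        return best

    def backward(self, dy):
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = self._in_shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        ho, wo = dy.shape[2], dy.shape[3]
        hi = (ho - 1) * s + 1
        wi = (wo - 1) * s + 1
        for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            dxp[:, :, i:i + hi:s, j:j + wi:s] += dy * (self._idx == t)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class AvgPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size

    def out_shape(self, in_shape):
        n, c, h, w = in_shape
        k, s = self.kernel_size, self.stride
        return (n, c, (h - k) // s + 1, (w - k) // s + 1)

    def forward(self, x):
        k, s = self.kernel_size, self.stride
        _, _, ho, wo = self.out_shape(x.shape)
        hi = (ho - 1) * s + 1
        wi = (wo - 1) * s + 1
        y = np.zeros((x.shape[0], x.shape[1], ho, wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                y += x[:, :, i:i + hi:s, j:j + wi:s]
        self._in_shape = x.shape
        return y / (k * k)

    def backward(self, dy):
        k, s = self.kernel_size, self.stride
        dx = np.zeros(self._in_shape, dtype=np.float32)
        ho, wo = dy.shape[2], dy.shape[3]
        hi = (ho - 1) * s + 1
        wi = (wo - 1) * s + 1
        d = dy / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + hi:s, j:j + wi:s] += d
        return dx


class AdaptiveAvgPool2d(Module):
    """Average pooling to a fixed output grid (framework-standard bin edges)."""

    def __init__(self, output_size: int):
        super().__init__()
        self.output_size = output_size

    def out_shape(self, in_shape):
        n, c, _, _ = in_shape
        return (n, c, self.output_size, self.output_size)

    @staticmethod
    def _edges(inp: int, out: int):
        starts = [(i * inp) // out for i in range(out)]
        ends = [-(-((i + 1) * inp) // out) for i in range(out)]
        return starts, ends

    def forward(self, x):
        n, c, h, w = x.shape
        o = self.output_size
        hs, he = self._edges(h, o)
        ws, we = self._edges(w, o)
        y = np.empty((n, c, o, o), dtype=np.float32)
        for i in range(o):
            for j in range(o):
                y[:, :, i, j] = x[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._in_shape
        o = self.output_size
        hs, he = self._edges(h, o)
        ws, we = self._edges(w, o)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(o):
            for j in range(o):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i]:he[i], ws[j]:we[j]] += (
                    dy[:, :, i, j][:, :, None, None] / area)
        return dx


class GlobalAvgPool(Module):
    """Global average pooling N×C×H×W → N×C."""

    def out_shape(self, in_shape):
        n, c, _, _ = in_shape
        return (n, c)

    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._in_shape).astype(np.float32)


class Flatten(Module):
    def out_shape(self, in_shape):
        return (in_shape[0], int(np.prod(in_shape[1:])))

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(
            get_rng().uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Parameter(
            get_rng().uniform(-bound, bound, size=out_features)) if bias else None

    def out_shape(self, in_shape):
        return (in_shape[0], self.out_features)

    def macs(self, in_shape):
        return in_shape[0] * self.in_features * self.out_features

    def forward(self, x):
        self._x = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (get_rng().random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._order = []
        for i, m in enumerate(modules):
            setattr(self, str(i), m)
            self._order.append(str(i))

    def __iter__(self):
        return iter(self._children[n] for n in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._children[self._order[i]]

    def forward(self, x):
        for m in self:
            x = m(x)
        return x

    def backward(self, dy):
        for m in reversed(list(self)):
            dy = m.backward(dy)
        return dy

    def out_shape(self, in_shape):
        for m in self:
            in_shape = m.out_shape(in_shape)
        return in_shape

    def profile_rows(self, in_shape, prefix=""):
        rows = []
        for name in self._order:
            r, in_shape = self._children[name].profile_rows(
                in_shape, prefix + name + ".")
            rows += r
        return rows, in_shape


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._order = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        name = str(len(self._order))
        setattr(self, name, m)
        self._order.append(name)

    def __iter__(self):
        return iter(self._children[n] for n in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._children[self._order[i]]


# ---------------------------------------------------------------------------
# Optimizer / loss
# ---------------------------------------------------------------------------


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay (classic behaviour:
    the decay term is added to the gradient)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Numerically stable mean cross-entropy on raw scores.

    Returns ``(loss, dlogits)`` — the gradient is with respect to the mean,
    ready to feed into ``Module.backward``.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    p = softmax(logits)
    p[np.arange(n), labels] -= 1.0
    return loss, (p / n).astype(np.float32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype if z.dtype.kind == "f" else np.float64)


def clone_state(state: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return copy.deepcopy(state)
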