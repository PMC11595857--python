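"""Effective spatial attention (ESA).

A parameter-light gating mechanism for convolutional feature maps: the input
N×C×H×W map is globally pooled to a 1×1×C descriptor, the descriptor is
transposed to a length-C vector and convolved along the *channel* axis with a
small odd kernel (so the number of learnable weights is independent of C —
no channel dimensionality reduction is ever performed), a sigmoid turns the
result into per-channel gates in (0, 1), and the gates rescale the original
map channel-wise.

Despite the historical name, the mechanism is channel attention: the gate is
constant over the spatial grid, so it emphasises informative channels rather
than pixels. Because the pooling is global the gates are invariant to any
spatial permutation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

POOL_KINDS = ("global_average", "global_max")
PLACEMENTS = ("per_block_pre_add", "per_stage_exit")


@dataclass(frozen=True)
class EsaConfig:
    """Configuration of the ESA gate.

    Parameters
    ----------
    pool_kind:
        How the spatial descriptor is pooled: ``"global_average"`` (default)
        or ``"global_max"``.
    kernel_size:
        Odd extent of the cross-channel convolution (default 3). The kernel
        slides along the channel axis with zero padding, so the parameter
        count (``kernel_size`` weights + optional bias) does not depend on C.
    placement:
        Where the gate sits in a residual network: ``"per_block_pre_add"``
        applies it to the residual-branch output just before the skip
        addition (default); ``"per_stage_exit"`` applies one gate after the
        last block of each stage.
    bias:
        Whether the cross-channel convolution carries a scalar bias.
    """

    pool_kind: str = "global_average"
    kernel_size: int = 3
    placement: str = "per_block_pre_add"
    bias: bool = True

    def __post_init__(self):
        if self.pool_kind not in POOL_KINDS:
            raise ValueError(f"pool_kind must be one of {POOL_KINDS}, got {self.pool_kind!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")


def _check_input(x: np.ndarray) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected an N×C×H×W feature map, got shape {x.shape}")
    if x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError(f"zero-sized spatial dimensions in shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in the input feature map")


class EffectiveSpatialAttention(nn.Module):
    """The ESA gate as a trainable layer.

    ``forward`` returns the rescaled feature map; :meth:`attention_weights`
    exposes the raw per-channel gates.
    """

    def __init__(self, config: EsaConfig | None = None):
        super().__init__()
        self.config = config or EsaConfig()
        k = self.config.kernel_size
        # init mirrors a 1-D conv with fan-in k
        bound = 1.0 / np.sqrt(k)
        self.weight = nn.Parameter(nn.get_rng().uniform(-bound, bound, size=k))
        self.bias = (nn.Parameter(nn.get_rng().uniform(-bound, bound, size=1))
                     if self.config.bias else None)

    # -- descriptor ---------------------------------------------------------
    def _pool(self, x: np.ndarray) -> np.ndarray:
        if self.config.pool_kind == "global_average":
            return x.mean(axis=(2, 3))
        d = x.reshape(x.shape[0], x.shape[1], -1)
        self._argmax = d.argmax(axis=2)
        return d.max(axis=2)

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gates, shape N×C, every entry strictly in (0, 1)."""
        _check_input(x)
        d = self._pool(x)  # N×C descriptor ("1×1×C feature map")
        k = self.config.kernel_size
        pad = k // 2
        dp = np.pad(d, ((0, 0), (pad, pad)))
        z = np.zeros_like(d)
        for t in range(k):  # 1-D convolution along the channel axis
            z += self.weight.value[t] * dp[:, t:t + d.shape[1]]
        if self.bias is not None:
            z += self.bias.value[0]
        gate = nn.sigmoid(z)
        self._d, self._dp, self._gate = d, dp, gate
        return gate

    # -- Module interface ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        gate = self.attention_weights(x)
        self._x = x
        return (x * gate[:, :, None, None].astype(x.dtype)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, gate, dp = self._x, self._gate, self._dp
        n, c, h, w = x.shape
        k = self.config.kernel_size
        dx = dy * gate[:, :, None, None]
        dgate = (dy * x).sum(axis=(2, 3))                      # N×C
        dz = (dgate * gate * (1.0 - gate)).astype(np.float32)  # sigmoid'
        for t in range(k):
            self.weight.grad[t] += float((dz * dp[:, t:t + c]).sum())
        if self.bias is not None:
            self.bias.grad[0] += float(dz.sum())
        # gradient w.r.t. the descriptor: correlation transpose
        pad = k // 2
        dd_p = np.zeros_like(dp)
        for t in range(k):
            dd_p[:, t:t + c] += self.weight.value[t] * dz
        dd = dd_p[:, pad:pad + c] if pad else dd_p
        if self.config.pool_kind == "global_average":
            dx = dx + dd[:, :, None, None] / (h * w)
        else:
            flat = np.zeros((n, c, h * w), dtype=np.float32)
            np.put_along_axis(flat, self._argmax[:, :, None], dd[:, :, None], axis=2)
            dx = dx + flat.reshape(n, c, h, w)
        return dx.astype(np.float32)

    # -- complexity ---------------------------------------------------------
    def out_shape(self, in_shape):
        return in_shape

    def macs(self, in_shape):
        n, c = in_shape[0], in_shape[1]
        per = self.config.kernel_size + (1 if self.bias is not None else 0)
        return n * c * per  # the cross-channel conv; pooling/sigmoid are free


def esa_attention_weights(x: np.ndarray, config: EsaConfig,
                          learned_weights) -> np.ndarray:
    """Functional form: compute the per-channel gate N×C for ``x``.

    ``learned_weights`` is either an :class:`EffectiveSpatialAttention`
    module or a ``(weight, bias)`` pair (``bias`` may be ``None``) with
    ``weight`` of length ``config.kernel_size``.
    """
    mod = _as_module(config, learned_weights)
    return mod.attention_weights(np.asarray(x, dtype=np.float32))


def esa_forward(x: np.ndarray, config: EsaConfig, learned_weights) -> np.ndarray:
    """Functional form: apply the gate, returning a map of the input's shape."""
    mod = _as_module(config, learned_weights)
    return mod(np.asarray(x, dtype=np.float32))


def _as_module(config: EsaConfig, learned_weights) -> EffectiveSpatialAttention:
    if isinstance(learned_weights, EffectiveSpatialAttention):
        return learned_weights
    weight, bias = learned_weights
    weight = np.asarray(weight, dtype=np.float32)
    if weight.shape != (config.kernel_size,):
        raise ValueError(
            f"weight must have shape ({config.kernel_size},), got {weight.shape}")
    cfg = config if (bias is not None) == config.bias else EsaConfig(
        config.pool_kind, config.kernel_size, config.placement, bias is not None)
    mod = EffectiveSpatialAttention(cfg)
    mod.weight.value = weight
    if bias is not None:
        mod.bias.value = np.asarray(bias, dtype=np.float32).reshape(1)
    return mod
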