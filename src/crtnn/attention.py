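"""Attention mechanisms: channel-selection attention (CSAM), multi-head
self-attention (MHSA), and the squeeze-excitation / efficient-channel
baselines used for comparison.

CSAM scores each EEG channel from its time-averaged activity: the per-window
channel vector is lifted ``C -> 2C`` by a linear map, refined by a kernel-3
1-D convolution over the three window positions — applied twice with one
tied weight set — passed through tanh after each application, projected back
``2C -> C``, gated by a sigmoid and normalised by a softmax over channels.
The resulting per-(sample, window) weight vector sums to one and multiplies
the corresponding channels of the input.  With the tied convolution the
block holds exactly 16,544 trainable scalars at C=32
(2112 + 12,352 + 2080).
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv1d
from .nn import Conv1dSame, Dropout, Linear, Module, softmax, uniform_init

__all__ = [
    "CSAM",
    "MHSA",
    "SENet",
    "ECANet",
    "scaled_dot_attention",
    "eca_kernel_size",
    "make_channel_attention",
]


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         mask: np.ndarray | None = None) -> Tensor:
    """``softmax(q k^T / sqrt(d_k)) v`` with optional additive masking.

    ``q, k, v`` are ``(..., S, d)``; masked (False) positions receive -inf
    before the softmax, so attention rows remain normalised over the
    unmasked positions.
    """
    q, k, v = map(Tensor.as_tensor, (q, k, v))
    d_k = q.shape[-1]
    if k.shape[-1] != d_k:
        raise ValueError(f"query dim {d_k} != key dim {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("key and value sequence lengths differ")
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    if mask is not None:
        scores = scores + np.where(mask, 0.0, -1e30)
    return softmax(scores, axis=-1) @ v


class MHSA(Module):
    """Multi-head self-attention: per-head q/k/v projections, concatenation,
    output projection, dropout (training mode only).  ``embed_dim`` must be
    divisible by ``n_heads`` (default 8 heads)."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.1):
        super().__init__()
        if embed_dim % n_heads != 0:
            raise ValueError(f"embed dim {embed_dim} not divisible by {n_heads} heads")
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.d_k = embed_dim // n_heads
        self.w_q = Linear(embed_dim, embed_dim, rng)
        self.w_k = Linear(embed_dim, embed_dim, rng)
        self.w_v = Linear(embed_dim, embed_dim, rng)
        self.w_o = Linear(embed_dim, embed_dim, rng)
        self.dropout = Dropout(dropout, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        B, S, _ = x.shape
        return x.reshape(B, S, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, S, D = x.shape
        if D != self.embed_dim:
            raise ValueError(f"expected embed dim {self.embed_dim}, got {D}")
        q = self._split_heads(self.w_q(x))
        k = self._split_heads(self.w_k(x))
        v = self._split_heads(self.w_v(x))
        heads = scaled_dot_attention(q, k, v, mask)  # (B, H, S, d_k)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, S, D)
        return self.dropout(self.w_o(merged))

    __call__ = forward


class CSAM(Module):
    """Channel-selection attention over ``(B, 3, C, T)`` EEG samples.

    ``gate`` selects sigmoid-then-softmax (default) or softmax only.  The
    weights are computed independently per 3 s window; output shape equals
    input shape and the returned weights are ``(B, 3, C)`` summing to one
    over channels.
    """

    GATES = ("sigmoid_softmax", "softmax_only")

    def __init__(self, n_channels: int = 32, rng: np.random.Generator | None = None,
                 gate: str = "sigmoid_softmax"):
        super().__init__()
        if gate not in self.GATES:
            raise ValueError(f"gate must be one of {self.GATES}, got {gate!r}")
        rng = np.random.default_rng(0) if rng is None else rng
        hidden = 2 * n_channels
        self.n_channels = n_channels
        self.gate = gate
        self.linear_up = Linear(n_channels, hidden, rng)
        # one kernel-3 convolution over the window axis, applied twice (tied)
        self.conv = Conv1dSame(hidden, hidden, 3, rng)
        self.linear_down = Linear(hidden, n_channels, rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        B, W, C, _ = x.shape
        if C != self.n_channels:
            raise ValueError(f"expected {self.n_channels} channels, got {C}")
        pooled = x.mean(axis=-1)                     # (B, W, C): global average pool
        u = self.linear_up(pooled)                   # (B, W, 2C)
        h = u.transpose(0, 2, 1)                     # features as conv channels, W as length
        h = self.conv(h).tanh()
        h = self.conv(h).tanh()                      # same weights applied twice
        d = self.linear_down(h.transpose(0, 2, 1))   # (B, W, C)
        if self.gate == "sigmoid_softmax":
            d = d.sigmoid()
        return softmax(d, axis=-1)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x = Tensor.as_tensor(x)
        w = self.channel_weights(x)
        return x * w.reshape(*w.shape, 1), w

    __call__ = forward


class SENet(Module):
    """Squeeze-and-excitation channel gate (reduction-ratio bottleneck).

    Drop-in replacement for :class:`CSAM`: same ``(B, 3, C, T)`` contract,
    weights computed per window from the time-pooled channel vector.
    """

    def __init__(self, n_channels: int = 32, rng: np.random.Generator | None = None,
                 reduction: int = 4):
        super().__init__()
        rng = np.random.default_rng(0) if rng is None else rng
        squeezed = max(1, n_channels // reduction)
        self.n_channels = n_channels
        self.fc1 = Linear(n_channels, squeezed, rng)
        self.fc2 = Linear(squeezed, n_channels, rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.n_channels:
            raise ValueError(f"expected {self.n_channels} channels, got {x.shape[2]}")
        pooled = x.mean(axis=-1)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x = Tensor.as_tensor(x)
        w = self.channel_weights(x)
        return x * w.reshape(*w.shape, 1), w

    __call__ = forward


def eca_kernel_size(n_channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive kernel of efficient channel attention: odd value nearest
    ``|log2(C)/gamma + b/gamma|``."""
    t = int(abs(math.log2(n_channels) / gamma + b / gamma))
    return t if t % 2 == 1 else t + 1


class ECANet(Module):
    """Efficient channel attention: a bias-free 1-D convolution of adaptive
    odd kernel size slides over the pooled channel vector; sigmoid gate."""

    def __init__(self, n_channels: int = 32, rng: np.random.Generator | None = None):
        super().__init__()
        rng = np.random.default_rng(0) if rng is None else rng
        self.n_channels = n_channels
        self.kernel_size = eca_kernel_size(n_channels)
        self.weight = uniform_init(rng, (1, 1, self.kernel_size), self.kernel_size)

    def channel_weights(self, x: Tensor) -> Tensor:
        B, W, C, _ = x.shape
        if C != self.n_channels:
            raise ValueError(f"expected {self.n_channels} channels, got {C}")
        pooled = x.mean(axis=-1).reshape(B * W, 1, C)
        pad = self.kernel_size // 2
        gated = conv1d(pooled.pad_last(pad, pad), self.weight).sigmoid()
        return gated.reshape(B, W, C)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x = Tensor.as_tensor(x)
        w = self.channel_weights(x)
        return x * w.reshape(*w.shape, 1), w

    __call__ = forward


def make_channel_attention(kind: str, n_channels: int, rng: np.random.Generator,
                           gate: str = "sigmoid_softmax") -> Module | None:
    """Factory for the ``channel_attention`` config key."""
    if kind in (None, "none"):
        return None
    if kind == "csam":
        return CSAM(n_channels, rng, gate=gate)
    if kind == "senet":
        return SENet(n_channels, rng)
    if kind == "ecanet":
        return ECANet(n_channels, rng)
    raise ValueError(f"unknown channel attention {kind!r}")
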