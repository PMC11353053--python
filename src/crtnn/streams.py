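"""The two local feature-extraction streams.

CRNN (fixed parameters): each 1 s window ``(C, 128)`` is convolved with 40
full-height ``(C, 40)`` filters at stride 1 (valid), ELU-activated,
max-pooled with kernel ``(1, 75)`` stride 10, and flattened to an
80-dimensional vector; the three windows form a length-3 sequence for a
two-layer LSTM with hidden size 64.  MHSA-CRNN adds multi-head
self-attention (8 heads, dim 64) on top of the LSTM output.

SA-CRNN (adaptive parameters): the three windows are concatenated in time
into one ``(C, 384)`` map, and the convolution stride, pooling kernel and
pooling stride are derived from the kernel width ``w``:

    stride = floor(w / 10),  pool kernel = (1, floor((w - 1) / 2)),
    pool stride = floor(w / 10).

For the default ``(32, 40)`` kernel this gives stride 4 and pool ``(1, 19)``
stride 4, hence conv width 87, pooled width 18 and a flattened feature of
40 * 18 = 720 — the input size of its two-layer LSTM.  The single 720-vector
is repeated into a length-3 sequence so the stream's output aligns with
MHSA-CRNN's ``(B, 3, 64)`` for concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import MHSA
from .autodiff import Tensor, concat, conv1d, maxpool1d
from .nn import LSTM, Module, uniform_init

__all__ = [
    "AdaptiveConvSpec",
    "adaptive_params",
    "conv_output_width",
    "CRNN",
    "MHSACRNN",
    "SACRNN",
]


@dataclass(frozen=True)
class AdaptiveConvSpec:
    """Stride/pool parameters derived from a convolution kernel size."""

    conv_kernel: tuple[int, int]
    conv_stride: int
    pool_kernel: tuple[int, int]
    pool_stride: int


def adaptive_params(conv_kernel: tuple[int, int]) -> AdaptiveConvSpec:
    """Derive stride and pooling parameters from the kernel's last dimension
    by floor division (see module docstring).  Widths below 3 are rejected
    because the pool kernel would vanish."""
    width = int(conv_kernel[-1])
    if width < 3:
        raise ValueError(f"kernel width must be >= 3, got {width}")
    stride = width // 10
    return AdaptiveConvSpec(
        conv_kernel=tuple(int(k) for k in conv_kernel),
        conv_stride=stride,
        pool_kernel=(1, (width - 1) // 2),
        pool_stride=stride,
    )


def conv_output_width(length: int, kernel: int, stride: int) -> int:
    """Valid-convolution output width ``floor((L - k)/s) + 1``; must be >= 1."""
    width = (length - kernel) // stride + 1
    if width < 1:
        raise ValueError(
            f"kernel {kernel} at stride {stride} does not fit length {length}"
        )
    return width


class CRNN(Module):
    """Fixed-parameter convolutional-recurrent stream, ``(B,3,C,128) -> (B,3,64)``."""

    def __init__(self, n_channels: int = 32, rng: np.random.Generator | None = None,
                 n_filters: int = 40, kernel_width: int = 40,
                 pool_kernel: int = 75, pool_stride: int = 10,
                 window_len: int = 128, hidden: int = 64):
        super().__init__()
        rng = np.random.default_rng(0) if rng is None else rng
        self.n_channels = n_channels
        self.window_len = window_len
        self.pool_kernel = pool_kernel
        self.pool_stride = pool_stride
        conv_w = conv_output_width(window_len, kernel_width, 1)
        pooled_w = conv_output_width(conv_w, pool_kernel, pool_stride)
        self.feature_dim = n_filters * pooled_w  # 40 * 2 = 80 at the defaults
        self.conv_weight = uniform_init(
            rng, (n_filters, n_channels, kernel_width), n_channels * kernel_width
        )
        self.conv_bias = uniform_init(rng, (n_filters,), n_channels * kernel_width)
        self.lstm = LSTM(self.feature_dim, hidden, num_layers=2, rng=rng)

    def _check(self, x: Tensor) -> None:
        if x.shape[2] != self.n_channels or x.shape[3] != self.window_len:
            raise ValueError(
                f"expected windows of shape ({self.n_channels}, {self.window_len}),"
                f" got ({x.shape[2]}, {x.shape[3]})"
            )

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor.as_tensor(x)
        B, W, C, T = x.shape
        self._check(x)
        folded = x.reshape(B * W, C, T)          # windows into the batch axis
        h = conv1d(folded, self.conv_weight, self.conv_bias).elu()
        h = maxpool1d(h, self.pool_kernel, self.pool_stride)
        h = h.reshape(B, W, self.feature_dim)
        return self.lstm(h)

    __call__ = forward


class MHSACRNN(Module):
    """CRNN followed by multi-head self-attention over the 3-step sequence."""

    def __init__(self, n_channels: int = 32, rng: np.random.Generator | None = None,
                 n_heads: int = 8, dropout: float = 0.1):
        super().__init__()
        rng = np.random.default_rng(0) if rng is None else rng
        self.crnn = CRNN(n_channels, rng)
        self.mhsa = MHSA(64, n_heads, rng, dropout=dropout)

    def forward(self, x: Tensor) -> Tensor:
        return self.mhsa(self.crnn(x))

    __call__ = forward


class SACRNN(Module):
    """Adaptive convolutional-recurrent stream over the full 3 s window."""

    #: how the single flattened vector becomes a length-3 sequence
    SEQUENCE_MODES = ("repeat",)

    def __init__(self, n_channels: int = 32, rng: np.random.Generator | None = None,
                 conv_kernel: tuple[int, int] = (32, 40), n_filters: int = 40,
                 window_len: int = 128, n_windows: int = 3, hidden: int = 64,
                 sequence_mode: str = "repeat"):
        super().__init__()
        if sequence_mode not in self.SEQUENCE_MODES:
            raise ValueError(f"unknown sequence mode {sequence_mode!r}")
        rng = np.random.default_rng(0) if rng is None else rng
        self.n_channels = n_channels
        self.window_len = window_len
        self.n_windows = n_windows
        self.spec = adaptive_params(conv_kernel)
        if self.spec.conv_stride < 1:
            raise ValueError(
                f"kernel width {conv_kernel[-1]} yields a zero adaptive stride;"
                " widths >= 10 are required to build this stream"
            )
        kernel_width = self.spec.conv_kernel[-1]
        total_len = window_len * n_windows
        conv_w = conv_output_width(total_len, kernel_width, self.spec.conv_stride)
        pooled_w = conv_output_width(conv_w, self.spec.pool_kernel[1],
                                     self.spec.pool_stride)
        self.conv_width = conv_w      # 87 at the defaults
        self.pooled_width = pooled_w  # 18 at the defaults
        self.feature_dim = n_filters * pooled_w  # 720 at the defaults
        fan_in = n_channels * kernel_width
        self.conv_weight = uniform_init(rng, (n_filters, n_channels, kernel_width), fan_in)
        self.conv_bias = uniform_init(rng, (n_filters,), fan_in)
        self.lstm = LSTM(self.feature_dim, hidden, num_layers=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor.as_tensor(x)
        B, W, C, T = x.shape
        if C != self.n_channels or T != self.window_len or W != self.n_windows:
            raise ValueError(
                f"expected input (*, {self.n_windows}, {self.n_channels},"
                f" {self.window_len}), got {tuple(x.shape)}"
            )
        joined = x.transpose(0, 2, 1, 3).reshape(B, C, W * T)  # chronological 3 s map
        h = conv1d(joined, self.conv_weight, self.conv_bias,
                   stride=self.spec.conv_stride).elu()
        h = maxpool1d(h, self.spec.pool_kernel[1], self.spec.pool_stride)
        feat = h.reshape(B, 1, self.feature_dim)
        seq = concat([feat] * self.n_windows, axis=1)  # repeat to a length-3 sequence
        return self.lstm(seq)

    __call__ = forward
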