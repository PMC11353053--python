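"""Causal dilated temporal convolution stack with self-attention (MHSA-TCN).

The global extractor treats the concatenated stream output ``(B, 6, 64)`` as
a 6-channel sequence of length 64: the 64-dimensional recurrent feature axis
is the temporal axis.  Four residual blocks with 25 channels, kernel 2 and
dilations 1, 2, 4, 8 follow; each block applies two weight-normalised causal
convolutions with ELU activation and dropout, then adds the (1x1-projected,
if channel counts differ) input.  Multi-head self-attention (8 heads,
embedding 64) sits between the first and second hidden layers, attending
across the 25 channel positions — 64 is divisible by 8 heads, 25 is not.

The receptive-field bookkeeping follows ``F = (k-1) * sum(d_i) + k``, which
describes a causal ladder with one convolution per listed dilation plus a
leading dilation-1 convolution (``F = 1 + (k-1)(1 + sum d_i)``);
:func:`build_measurement_stack` constructs exactly that ladder so the
formula can be validated against a perturbation measurement.  Counting both
convolutions of every residual block instead is exposed via
``convs_per_level=2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import MHSA
from .autodiff import Tensor, conv1d
from .nn import Dropout, Module, WeightNormCausalConv1d, uniform_init

__all__ = [
    "TCNConfig",
    "receptive_field",
    "TCNBlock",
    "MHSATCN",
    "build_measurement_stack",
    "measure_receptive_field",
]


@dataclass(frozen=True)
class TCNConfig:
    """Hyperparameters of the temporal convolution stack."""

    channels: int = 25
    kernel_size: int = 2
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    dropout: float = 0.1
    in_channels: int = 6

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ValueError("kernel size must be >= 1")
        d = self.dilations
        if not d or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("dilations must be non-empty and strictly increasing")


def receptive_field(kernel_size: int, dilations, convs_per_level: int = 1) -> int:
    """``F = (k-1) * convs_per_level * sum(d_i) + k``.

    With the default single count, k=2 and dilations (1, 2, 4, 8) give 17;
    a pointwise kernel (k=1) always sees a single step.
    """
    if kernel_size < 1:
        raise ValueError("kernel size must be >= 1")
    dilations = list(dilations)
    if not dilations:
        raise ValueError("dilations must be non-empty")
    return (kernel_size - 1) * convs_per_level * int(sum(dilations)) + kernel_size


class TCNBlock(Module):
    """One residual block: two weight-normalised causal convolutions with the
    same dilation, ELU + dropout after each, plus a residual connection
    (1x1 projection when the channel count changes).  Time length preserved."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = WeightNormCausalConv1d(in_channels, out_channels,
                                            kernel_size, dilation, rng)
        self.conv2 = WeightNormCausalConv1d(out_channels, out_channels,
                                            kernel_size, dilation, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        if in_channels != out_channels:
            self.proj_weight = uniform_init(rng, (out_channels, in_channels, 1),
                                            in_channels)
            self.proj_bias = uniform_init(rng, (out_channels,), in_channels)
        else:
            self.proj_weight = None
            self.proj_bias = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop1(self.conv1(x).elu())
        h = self.drop2(self.conv2(h).elu())
        if self.proj_weight is not None:
            res = conv1d(x, self.proj_weight, self.proj_bias)
        else:
            res = x
        return h + res

    __call__ = forward


class MHSATCN(Module):
    """TCN with self-attention between the first and second hidden layers.

    ``(B, in_channels, T) -> (B, channels, T)``; with the defaults and the
    dual-stream input this is ``(B, 6, 64) -> (B, 25, 64)``.
    """

    def __init__(self, config: TCNConfig | None = None,
                 rng: np.random.Generator | None = None, n_heads: int = 8,
                 embed_dim: int = 64, mhsa_position: int = 1):
        super().__init__()
        config = TCNConfig() if config is None else config
        rng = np.random.default_rng(0) if rng is None else rng
        if not 1 <= mhsa_position <= len(config.dilations):
            raise ValueError("mhsa_position must index a hidden layer")
        self.config = config
        self.mhsa_position = mhsa_position
        self.blocks = []
        c_in = config.in_channels
        for d in config.dilations:
            self.blocks.append(TCNBlock(c_in, config.channels, config.kernel_size,
                                        d, config.dropout, rng))
            c_in = config.channels
        self.mhsa = MHSA(embed_dim, n_heads, rng, dropout=config.dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        h = x
        for i, block in enumerate(self.blocks, start=1):
            h = block(h)
            if i == self.mhsa_position:
                # attend across channel positions: sequence length = channels,
                # embedding = the temporal axis (divisible by the head count)
                h = self.mhsa(h)
        return h

    __call__ = forward


def build_measurement_stack(kernel_size: int, dilations,
                            rng: np.random.Generator) -> list[WeightNormCausalConv1d]:
    """Randomly weighted causal ladder realising :func:`receptive_field`:
    one convolution per listed dilation behind a leading dilation-1 layer."""
    ladder = [1] + list(dilations) if kernel_size > 1 else list(dilations)
    return [WeightNormCausalConv1d(1, 1, kernel_size, d, rng) for d in ladder]


def measure_receptive_field(layers, length: int) -> int:
    """Earliest input index that influences the last output of a causal stack,
    found by perturbing one input position at a time."""
    def run(x: np.ndarray) -> float:
        h = Tensor(x[None, None, :])
        for layer in layers:
            h = layer(h)
        return float(h.data[0, 0, -1])

    base = np.zeros(length, dtype=np.float64)
    ref = run(base)
    influencing = []
    for t in range(length):
        probe = base.copy()
        probe[t] = 1.0
        if abs(run(probe) - ref) > 1e-9:
            influencing.append(t)
    if not influencing:
        raise ValueError("no input position influences the output")
    return length - min(influencing)
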