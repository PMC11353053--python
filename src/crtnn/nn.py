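"""Neural-network building blocks on top of :mod:`crtnn.autodiff`.

Parameter conventions matter here because the package reports exact
trainable-parameter budgets:

* tied weights (one :class:`~crtnn.autodiff.Tensor` used in several places)
  are counted once — parameter discovery deduplicates by object identity;
* the LSTM carries a single bias vector per gate set per layer,
  ``4*(d_in*d_h + d_h**2 + d_h)`` parameters per layer — the convention under
  which the recurrent budgets in this package are quoted.

Initialisation is uniform fan-in, ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``,
drawn from a caller-supplied :class:`numpy.random.Generator` so that model
construction is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, maxpool1d

__all__ = [
    "Module",
    "Linear",
    "Conv1dSame",
    "WeightNormCausalConv1d",
    "LSTM",
    "Dropout",
    "softmax",
    "log_softmax",
    "uniform_init",
]

DTYPE = np.float32


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(DTYPE), requires_grad=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift, grad-transparent
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    shift = x - m
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


class Module:
    """Minimal module base: attribute-scanned parameters, train/eval mode."""

    def __init__(self):
        self.training = True

    # attribute scan keeps declaration order, which Adam relies on for
    # deterministic state alignment
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def n_params(self) -> int:
        """Number of distinct trainable scalars (tied weights counted once)."""
        return int(sum(p.size for p in self.parameters()))

    def submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                yield from (v for v in value if isinstance(v, Module))

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = uniform_init(rng, (out_features, in_features), in_features)
        self.bias = uniform_init(rng, (out_features,), in_features) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose()
        if self.bias is not None:
            y = y + self.bias
        return y

    __call__ = forward


class Conv1dSame(Module):
    """1-D convolution with symmetric zero padding (odd kernel), stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("Conv1dSame requires an odd kernel size")
        fan_in = in_channels * kernel_size
        self.weight = uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.bias = uniform_init(rng, (out_channels,), fan_in) if bias else None
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        pad = self.kernel_size // 2
        return conv1d(x.pad_last(pad, pad), self.weight, self.bias)

    __call__ = forward


class WeightNormCausalConv1d(Module):
    """Causal dilated 1-D convolution with weight normalisation.

    The effective kernel is ``g * v / ||v||`` with the norm taken per output
    filter; ``(k-1)*dilation`` zeros are prepended so output time ``t`` sees
    inputs at times ``<= t`` only, and the time length is preserved.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight_v = uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.weight_g = Tensor(
            np.linalg.norm(self.weight_v.data.reshape(out_channels, -1), axis=1)
            .astype(DTYPE),
            requires_grad=True,
        )
        self.bias = uniform_init(rng, (out_channels,), fan_in)
        self.kernel_size = kernel_size
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        v = self.weight_v
        norm = ((v * v).sum(axis=(1, 2), keepdims=True) + 1e-12) ** 0.5
        w = v * (self.weight_g.reshape(-1, 1, 1) / norm)
        pad = (self.kernel_size - 1) * self.dilation
        return conv1d(x.pad_last(pad, 0), w, self.bias, dilation=self.dilation)

    __call__ = forward


class LSTM(Module):
    """Stacked LSTM with one bias vector per gate set per layer.

    Input ``(B, S, D)`` -> output ``(B, S, H)`` (hidden states of the top
    layer at every step).  Gates are ordered input, forget, cell, output.
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.layers = []
        d_in = input_size
        for _ in range(num_layers):
            layer = Module()
            layer.w_ih = uniform_init(rng, (4 * hidden_size, d_in), hidden_size)
            layer.w_hh = uniform_init(rng, (4 * hidden_size, hidden_size), hidden_size)
            layer.bias = uniform_init(rng, (4 * hidden_size,), hidden_size)
            self.layers.append(layer)
            d_in = hidden_size

    def forward(self, x: Tensor) -> Tensor:
        B, S, _ = x.shape
        H = self.hidden_size
        seq = [x[:, t, :] for t in range(S)]
        for layer in self.layers:
            h = Tensor(np.zeros((B, H), dtype=x.dtype))
            c = Tensor(np.zeros((B, H), dtype=x.dtype))
            out_seq = []
            for step in seq:
                z = step @ layer.w_ih.transpose() + h @ layer.w_hh.transpose() + layer.bias
                i = z[:, 0 * H : 1 * H].sigmoid()
                f = z[:, 1 * H : 2 * H].sigmoid()
                g = z[:, 2 * H : 3 * H].tanh()
                o = z[:, 3 * H : 4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                out_seq.append(h)
            seq = out_seq
        return concat([h.reshape(B, 1, H) for h in seq], axis=1)

    __call__ = forward


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Needs an RNG for the mask."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)

    __call__ = forward


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999) over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
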