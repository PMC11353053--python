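"""Model assembly: channel attention, dual streams, global extractor,
classifier — plus the four ablation variants and exact parameter counting.

The full model processes a batch of 3 s samples ``(B, 3, C, 128)`` as

    channel attention -> SA-CRNN and MHSA-CRNN in parallel -> concatenate
    along the window axis to (B, 6, 64) -> MHSA-TCN -> mean over the 25
    channel positions -> 64-vector -> affine map -> softmax probabilities.

Variants ablate exactly one component each:

====================  ====  ========  =========  ========
variant               CSAM  SA-CRNN   MHSA-CRNN  MHSA-TCN
====================  ====  ========  =========  ========
full                   yes    yes        yes       yes
sa_crtnn               no     yes        yes       yes
csa_crtnn              yes    no         yes       yes
ca_sa_crtnn            yes    yes        no        yes
csa_sa_crnn            yes    yes        yes       no
====================  ====  ========  =========  ========

With a single stream the temporal extractor's input shrinks to 3 channels;
without the temporal extractor the concatenated stream output is mean-pooled
over its sequence axis and classified directly.  The classifier maps the
64-vector to ``n_classes`` (130 trainable scalars for two classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .attention import make_channel_attention
from .autodiff import Tensor, concat
from .nn import Linear, Module, softmax
from .streams import MHSACRNN, SACRNN
from .tcn import MHSATCN, TCNConfig

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "EmotionClassifier",
    "build_model",
    "count_params",
    "save_checkpoint",
    "load_checkpoint",
]

#: variant name -> (channel attention, SA-CRNN, MHSA-CRNN, MHSA-TCN) presence
VARIANTS = {
    "full": (True, True, True, True),
    "sa_crtnn": (False, True, True, True),
    "csa_crtnn": (True, False, True, True),
    "ca_sa_crtnn": (True, True, False, True),
    "csa_sa_crnn": (True, True, True, False),
}


@dataclass
class ModelConfig:
    """Everything needed to build one model variant deterministically."""

    variant: str = "full"
    channel_attention: str | None = None  # None -> csam when the variant has one
    n_classes: int = 2
    n_channels: int = 32
    csam_gate: str = "sigmoid_softmax"
    sa_kernel: tuple[int, int] = (32, 40)
    mhsa_dropout: float = 0.1
    tcn: TCNConfig = field(default_factory=TCNConfig)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {sorted(VARIANTS)}")
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        has_attention = VARIANTS[self.variant][0]
        if not has_attention and self.channel_attention not in (None, "none"):
            raise ValueError(
                f"variant {self.variant!r} has no channel attention;"
                f" got channel_attention={self.channel_attention!r}"
            )

    @property
    def attention_kind(self) -> str | None:
        if not VARIANTS[self.variant][0]:
            return None
        return self.channel_attention or "csam"


class EmotionClassifier(Module):
    """An assembled variant; see module docstring for the data flow."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        _, has_sa, has_mhsa_crnn, has_tcn = VARIANTS[config.variant]
        kind = config.attention_kind
        self.channel_attention = (
            make_channel_attention(kind, config.n_channels, rng, gate=config.csam_gate)
            if kind else None
        )
        self.sa_crnn = (
            SACRNN(config.n_channels, rng, conv_kernel=config.sa_kernel)
            if has_sa else None
        )
        self.mhsa_crnn = (
            MHSACRNN(config.n_channels, rng, dropout=config.mhsa_dropout)
            if has_mhsa_crnn else None
        )
        n_stream_steps = 3 * ((1 if has_sa else 0) + (1 if has_mhsa_crnn else 0))
        self.tcn = (
            MHSATCN(replace(config.tcn, in_channels=n_stream_steps), rng)
            if has_tcn else None
        )
        self.classifier = Linear(64, config.n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        """Pre-classifier 64-vector per sample."""
        x = Tensor.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.config.n_channels:
            raise ValueError(
                f"expected (B, 3, {self.config.n_channels}, 128) input,"
                f" got {tuple(x.shape)}"
            )
        if self.channel_attention is not None:
            x, _ = self.channel_attention(x)
        streams = []
        if self.sa_crnn is not None:
            streams.append(self.sa_crnn(x))
        if self.mhsa_crnn is not None:
            streams.append(self.mhsa_crnn(x))
        h = streams[0] if len(streams) == 1 else concat(streams, axis=1)
        if self.tcn is not None:
            # (B, steps, 64) read as (B, channels, time): the recurrent
            # feature axis is the temporal axis of the causal stack
            h = self.tcn(h)
            return h.mean(axis=1)  # pool over the 25 channel positions
        return h.mean(axis=1)

    def logits(self, x: Tensor) -> Tensor:
        return self.classifier(self.features(x))

    def forward(self, x: Tensor) -> Tensor:
        """Class probabilities ``(B, n_classes)``; rows sum to one."""
        return softmax(self.logits(x), axis=-1)

    __call__ = forward


def build_model(config: ModelConfig) -> EmotionClassifier:
    """Build one variant; identical configs (incl. seed) give identical weights."""
    return EmotionClassifier(config)


#: named scopes accepted by :func:`count_params`
_SCOPES = ("model", "channel_attention", "csam", "sa_crnn", "mhsa_crnn",
           "crnn", "tcn", "mhsa_tcn", "classifier")


def count_params(model: EmotionClassifier, scope: str = "model") -> int:
    """Exact trainable-scalar count of the model or one named block.

    Tied weights are counted once; the LSTM single-bias convention is built
    into the layers themselves.
    """
    if scope == "model":
        return model.n_params()
    target = {
        "channel_attention": model.channel_attention,
        "csam": model.channel_attention,
        "sa_crnn": model.sa_crnn,
        "mhsa_crnn": model.mhsa_crnn,
        "crnn": model.mhsa_crnn.crnn if model.mhsa_crnn is not None else None,
        "tcn": model.tcn,
        "mhsa_tcn": model.tcn,
        "classifier": model.classifier,
    }.get(scope)
    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}; one of {_SCOPES}")
    if target is None:
        raise ValueError(f"scope {scope!r} is not present in variant"
                         f" {model.config.variant!r}")
    return target.n_params()


def save_checkpoint(model: EmotionClassifier, path) -> None:
    """Write weights plus a config echo to HDF5 (one dataset per parameter)."""
    cfg = model.config
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = cfg.variant
        f.attrs["channel_attention"] = cfg.attention_kind or "none"
        f.attrs["n_classes"] = cfg.n_classes
        f.attrs["n_channels"] = cfg.n_channels
        f.attrs["csam_gate"] = cfg.csam_gate
        f.attrs["sa_kernel"] = list(cfg.sa_kernel)
        f.attrs["seed"] = cfg.seed
        grp = f.create_group("weights")
        for name, p in model.named_parameters():
            grp.create_dataset(name, data=p.data)


def load_checkpoint(path) -> EmotionClassifier:
    with h5py.File(path, "r") as f:
        attention = str(f.attrs["channel_attention"])
        config = ModelConfig(
            variant=str(f.attrs["variant"]),
            channel_attention=None if attention == "none" else attention,
            n_classes=int(f.attrs["n_classes"]),
            n_channels=int(f.attrs["n_channels"]),
            csam_gate=str(f.attrs["csam_gate"]),
            sa_kernel=tuple(int(k) for k in f.attrs["sa_kernel"]),
            seed=int(f.attrs["seed"]),
        )
        model = build_model(config)
        state = {name: np.asarray(ds) for name, ds in f["weights"].items()}
    model.load_state_dict(state)
    return model
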