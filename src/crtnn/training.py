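"""Training loop, cross-validation and experiment drivers.

Models are trained with Adam (learning rate 0.001), batch size 128 and a
cross-entropy loss; 30 epochs is the working default (40 for the
62-channel 3-class layout).  Evaluation reports accuracy and a per-class
confusion matrix; cross-validation trains one fresh model per fold on
stratified folds within one subject (subject-dependent protocol) and
aggregates fold accuracies as mean +/- SD.  Everything is deterministic
under the configured seed on a single device.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .assembly import VARIANTS, EmotionClassifier, ModelConfig, build_model
from .autodiff import Tensor
from .nn import Adam, log_softmax
from .preprocessing import SegmentSet, make_splits

__all__ = [
    "TrainConfig",
    "Metrics",
    "History",
    "cross_entropy",
    "train",
    "evaluate",
    "run_cv",
    "run_ablation_suite",
    "run_attention_comparison",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 30
    folds: int = 10
    holdout: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs, self.folds) <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass
class Metrics:
    """Evaluation result: accuracy = trace(confusion)/n."""

    accuracy: float
    confusion: np.ndarray
    n: int


@dataclass
class History:
    """Per-epoch training record."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(model: EmotionClassifier, segments: SegmentSet, config: TrainConfig,
          val: SegmentSet | None = None, stop_at_accuracy: float | None = None,
          ) -> History:
    """Mini-batch gradient training; returns the per-epoch history.

    ``stop_at_accuracy`` optionally ends training early once the epoch's
    training accuracy reaches the given level.  Raises if the label range
    does not match the model's class count, or if the loss goes non-finite.
    """
    n_classes = model.config.n_classes
    if segments.labels.max(initial=0) >= n_classes or segments.labels.min(initial=0) < 0:
        raise ValueError(
            f"labels outside 0..{n_classes - 1} for a {n_classes}-class model"
        )
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = History()
    model.train()
    for _ in range(config.epochs):
        losses, hits, seen = [], 0, 0
        for idx in _batches(len(segments), config.batch_size, rng):
            x = Tensor(segments.samples[idx])
            y = segments.labels[idx]
            logits = model.logits(x)
            loss = cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data) * len(idx))
            hits += int((logits.data.argmax(axis=1) == y).sum())
            seen += len(idx)
        history.loss.append(sum(losses) / seen)
        history.accuracy.append(hits / seen)
        if val is not None:
            m = evaluate(model, val)
            history.val_accuracy.append(m.accuracy)
            model.train()
        if stop_at_accuracy is not None and history.accuracy[-1] >= stop_at_accuracy:
            break
    model.eval()
    return history


def evaluate(model: EmotionClassifier, segments: SegmentSet,
             batch_size: int = 256) -> Metrics:
    """Accuracy and confusion matrix on ``segments``; no parameter updates."""
    if len(segments) == 0:
        raise ValueError("cannot evaluate on an empty segment set")
    model.eval()
    preds = []
    for start in range(0, len(segments), batch_size):
        x = Tensor(segments.samples[start : start + batch_size])
        preds.append(model.logits(x).data.argmax(axis=1))
    preds = np.concatenate(preds)
    cm = confusion_matrix(segments.labels, preds,
                          labels=np.arange(model.config.n_classes))
    return Metrics(accuracy=float(np.trace(cm)) / len(segments), confusion=cm,
                   n=len(segments))


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    mean_accuracy: float
    sd_accuracy: float


def run_cv(model_config: ModelConfig, segments: SegmentSet, config: TrainConfig,
           ) -> CVResult:
    """Stratified k-fold cross-validation with one fresh model per fold."""
    splits = make_splits(segments.labels, ratio=config.holdout,
                         folds=config.folds, seed=config.seed)
    fold_metrics = []
    for i, (train_idx, test_idx) in enumerate(splits["folds"]):
        model = build_model(replace(model_config, seed=model_config.seed + i))
        train(model, segments.subset(train_idx), config)
        fold_metrics.append(evaluate(model, segments.subset(test_idx)))
    accs = np.array([m.accuracy for m in fold_metrics])
    return CVResult(fold_metrics, float(accs.mean()), float(accs.std(ddof=1)))


def _cv_table_row(name: str, result: CVResult) -> dict:
    return {
        "model": name,
        "mean_accuracy": result.mean_accuracy,
        "sd_accuracy": result.sd_accuracy,
        **{f"fold_{i}": m.accuracy for i, m in enumerate(result.fold_metrics)},
    }


def run_ablation_suite(segments: SegmentSet, model_config: ModelConfig,
                       config: TrainConfig) -> pd.DataFrame:
    """Cross-validate the full model and its four ablations under identical
    folds and seeds; one row per variant."""
    rows = []
    for variant in VARIANTS:
        cfg = replace(model_config, variant=variant,
                      channel_attention=None)
        rows.append(_cv_table_row(variant, run_cv(cfg, segments, config)))
    return pd.DataFrame(rows)


def run_attention_comparison(segments: SegmentSet, model_config: ModelConfig,
                             config: TrainConfig,
                             kinds: tuple[str, ...] = ("csam", "senet", "ecanet"),
                             ) -> pd.DataFrame:
    """Cross-validate the full model under different channel attentions."""
    rows = []
    for kind in kinds:
        cfg = replace(model_config, variant="full", channel_attention=kind)
        rows.append(_cv_table_row(kind, run_cv(cfg, segments, config)))
    return pd.DataFrame(rows)
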