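"""From raw trials to model-ready samples.

The pipeline is: (1) anti-aliased downsampling to 128 Hz, (2) segmentation
into 1 s windows, (3) baseline removal — the arithmetic mean of the first
three 1 s pre-stimulus segments is subtracted from every remaining segment —
(4) chronological assembly of consecutive non-overlapping triples of 1 s
windows into 3 s samples of shape ``(3, C, 128)``, and (5) rating-to-class
annotation with 5 (binary) or 4/6 (ternary) thresholds, boundary scores
going to the lower class.  Processing is per subject throughout
(subject-dependent protocol): samples from different subjects are never
mixed inside one segment set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly
from sklearn.model_selection import StratifiedKFold, train_test_split

from .synthetic import RawTrialSet

__all__ = [
    "LabelScheme",
    "SegmentSet",
    "downsample",
    "segment_1s",
    "remove_baseline",
    "assemble_3s",
    "assign_label",
    "make_splits",
    "preprocess_subject",
]

#: (lower, upper] rating intervals per class, lower interval closed at 1
SCHEME_EDGES = {2: (1.0, 5.0, 9.0), 3: (1.0, 4.0, 6.0, 9.0)}

CLASS_NAMES = {
    (2, "arousal"): ("LA", "HA"),
    (2, "valence"): ("LV", "HV"),
    (3, "arousal"): ("LA", "MA", "HA"),
    (3, "valence"): ("LV", "MV", "HV"),
}


@dataclass(frozen=True)
class LabelScheme:
    """Annotation scheme: 2-class (threshold 5) or 3-class (thresholds 4, 6)."""

    n_classes: int = 2
    dimension: str = "arousal"  # rating column: arousal or valence

    def __post_init__(self):
        if self.n_classes not in SCHEME_EDGES:
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if self.dimension not in ("valence", "arousal"):
            raise ValueError(f"dimension must be valence or arousal, got {self.dimension}")

    @property
    def edges(self) -> tuple[float, ...]:
        return SCHEME_EDGES[self.n_classes]

    @property
    def class_names(self) -> tuple[str, ...]:
        return CLASS_NAMES[(self.n_classes, self.dimension)]

    @property
    def rating_column(self) -> int:
        return 0 if self.dimension == "valence" else 1


@dataclass
class SegmentSet:
    """Model-ready samples ``(N, 3, C, 128)`` with class labels and provenance."""

    samples: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    trials: np.ndarray

    def __post_init__(self):
        n = len(self.samples)
        if not (len(self.labels) == len(self.subjects) == len(self.trials) == n):
            raise ValueError("samples, labels and provenance arrays disagree in length")

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(self.samples[idx], self.labels[idx],
                          self.subjects[idx], self.trials[idx])


def downsample(trials: RawTrialSet, to_rate: float) -> RawTrialSet:
    """Polyphase anti-aliased resampling of the time axis to ``to_rate``.

    Upsampling is refused; equal rates are an exact no-op.
    """
    if to_rate <= 0:
        raise ValueError(f"target rate must be positive, got {to_rate}")
    if to_rate > trials.rate:
        raise ValueError(f"refusing to upsample {trials.rate} Hz -> {to_rate} Hz")
    if to_rate == trials.rate:
        return trials
    frac = Fraction(to_rate / trials.rate).limit_denominator(1000)
    data = resample_poly(trials.data, frac.numerator, frac.denominator, axis=-1)
    return replace(trials, data=data.astype(trials.data.dtype), rate=float(to_rate))


def segment_1s(trial: np.ndarray, rate: float) -> np.ndarray:
    """Split one ``(C, T)`` trial into 1 s windows ``(n_seg, C, rate)``.

    A trailing remainder shorter than 1 s is dropped.
    """
    win = int(round(rate))
    n_seg = trial.shape[-1] // win
    return trial[:, : n_seg * win].reshape(trial.shape[0], n_seg, win).swapaxes(0, 1)


def remove_baseline(segments: np.ndarray, n_baseline: int = 3) -> np.ndarray:
    """Subtract the mean of the first ``n_baseline`` segments from the rest.

    ``segments`` is ``(n_seg, C, L)`` in chronological order; returns the
    ``n_seg - n_baseline`` stimulus segments, baseline-corrected.  For the
    63-segment DEAP-like trial this yields exactly 60 corrected segments.
    """
    segments = np.asarray(segments)
    if segments.shape[0] < n_baseline + 1:
        raise ValueError(
            f"need at least {n_baseline + 1} segments, got {segments.shape[0]}"
        )
    baseline = segments[:n_baseline].mean(axis=0)
    return segments[n_baseline:] - baseline


def assemble_3s(segments: np.ndarray, trial: int | None = None) -> np.ndarray:
    """Group consecutive non-overlapping 1 s triples into 3 s samples.

    ``(n_seg, C, L) -> (n_seg//3, 3, C, L)``, order preserved; ``n_seg`` must
    be divisible by 3 (callers truncate beforehand when a remainder is
    expected, e.g. long clips without a fixed 60 s stimulus).
    """
    segments = np.asarray(segments)
    n_seg = segments.shape[0]
    if n_seg % 3 != 0:
        where = "" if trial is None else f" (trial {trial})"
        raise ValueError(f"segment count {n_seg} not divisible by 3{where}")
    return segments.reshape(n_seg // 3, 3, *segments.shape[1:])


def assign_label(score: float, scheme: LabelScheme) -> int:
    """Class index of a 1-9 rating; boundary scores go to the lower class."""
    if not 1.0 <= score <= 9.0:
        raise ValueError(f"rating {score} outside [1, 9]")
    edges = scheme.edges
    for cls, upper in enumerate(edges[1:]):
        if score <= upper:
            return cls
    raise AssertionError("unreachable: edges cover [1, 9]")


def make_splits(labels: np.ndarray, ratio: float = 0.2, folds: int = 10,
                seed: int = 0) -> dict:
    """Stratified 8:2 holdout indices plus ``folds`` disjoint CV folds.

    Returns ``{"train", "test", "folds"}`` where ``folds`` is a list of
    ``(train_idx, test_idx)`` pairs covering all samples.  Deterministic
    under ``seed``; stratified by class whenever every class has at least
    ``folds`` members.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    idx = np.arange(n)
    train, test = train_test_split(idx, test_size=ratio, random_state=seed,
                                   stratify=labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_pairs = [(tr, te) for tr, te in skf.split(idx, labels)]
    return {"train": np.sort(train), "test": np.sort(test), "folds": fold_pairs}


def preprocess_subject(raw: RawTrialSet, scheme: LabelScheme | None = None,
                       to_rate: float = 128.0) -> SegmentSet:
    """Full pipeline for one subject's raw trials.

    DEAP-like input (continuous ratings, 3 s baseline): downsample, segment,
    remove baseline, assemble 3 s samples, annotate the scheme's rating
    dimension.  SEED-like input (categorical labels, no baseline): the
    baseline step is skipped and labels are used as-is; the segment count is
    truncated to a multiple of 3.
    """
    raw = downsample(raw, to_rate)
    n_baseline = int(round(raw.baseline_seconds))
    samples, labels, trial_idx = [], [], []
    for t in range(raw.n_trials):
        segs = segment_1s(raw.data[t], raw.rate)
        if n_baseline > 0:
            segs = remove_baseline(segs, n_baseline)
        segs = segs[: (segs.shape[0] // 3) * 3]
        grouped = assemble_3s(segs, trial=t)
        if raw.layout == "deap":
            if scheme is None:
                raise ValueError("a LabelScheme is required for rating-labelled trials")
            label = assign_label(float(raw.labels[t, scheme.rating_column]), scheme)
        else:
            label = int(raw.labels[t])
        samples.append(grouped)
        labels.extend([label] * len(grouped))
        trial_idx.extend([t] * len(grouped))
    samples = (np.concatenate(samples, axis=0) if samples
               else np.empty((0, 3, raw.n_channels, int(raw.rate)), dtype=np.float32))
    return SegmentSet(
        samples.astype(np.float32),
        np.asarray(labels, dtype=np.int64),
        np.full(len(samples), raw.subject, dtype=np.int64),
        np.asarray(trial_idx, dtype=np.int64),
    )
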