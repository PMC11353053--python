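"""Synthetic multi-channel EEG with known class structure.

Real affective-EEG corpora in this problem's two standard layouts are
access-restricted, so the package ships a generator that emulates both:

* a DEAP-like layout — per subject ``(n_trials, 32, rate*(3 + 60))`` samples
  (3 s pre-stimulus baseline followed by a 60 s stimulus window at 128 Hz,
  i.e. 8064 samples per channel per trial) with continuous 1-9 ratings for
  valence, arousal, dominance and liking;
* a SEED-like layout — per subject ``(n_trials, 62, rate*stimulus)`` samples
  with categorical negative/neutral/positive labels and no baseline.

The signal model is deliberately minimal: Gaussian broadband noise plus a
sum of band-limited sinusoids (random frequencies within the band, random
phases, independent per channel) whose band depends on a latent emotion
class.  Band-power differences are the smallest structure a spectro-temporal
classifier can exploit, which makes the generator a sufficient test bench
for every downstream stage without pretending to be biophysically realistic
EEG.  Optionally the class signal is confined to an informative-channel
subset so channel-attention mechanisms have ground truth to recover.

Ratings are drawn *backwards* from the latent class: the class picks the
matching rating interval of the 2-/3-class annotation scheme and the rating
is drawn uniformly inside it, so downstream label assignment recovers the
latent class exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "SimulationSpec",
    "RawTrialSet",
    "simulate_deap_like",
    "simulate_seed_like",
    "deap_spec",
    "seed_spec",
]

#: rating interval (closed below at the lower bound, closed above) per class,
#: matching the annotation schemes used downstream
RATING_INTERVALS = {
    2: [(1.0, 5.0), (5.0, 9.0)],
    3: [(1.0, 4.0), (4.0, 6.0), (6.0, 9.0)],
}

#: default per-class spectral signatures: theta, alpha, low-gamma
DEFAULT_CLASS_BANDS = [(4.0, 7.0), (8.0, 13.0), (30.0, 45.0)]


@dataclass(frozen=True)
class Band:
    """A band-limited sinusoid mixture: edges in Hz and RMS-scaled amplitude."""

    low_hz: float
    high_hz: float
    amplitude: float = 2.0
    n_components: int = 3


@dataclass
class SimulationSpec:
    """Configuration of one simulated study.

    ``class_bands[k]`` lists the spectral signature added to class-``k``
    trials during the stimulus window; the baseline window carries noise
    only.  ``informative_channels=None`` means every channel carries the
    class signal.
    """

    n_subjects: int = 2
    n_trials: int = 24
    n_channels: int = 32
    rate: float = 128.0
    stimulus_seconds: float = 60.0
    baseline_seconds: float = 3.0
    n_classes: int = 2
    class_bands: list[list[Band]] = field(default_factory=list)
    informative_channels: list[int] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.stimulus_seconds < 0 or self.baseline_seconds < 0:
            raise ValueError("durations must be non-negative")
        if self.n_trials < 0 or self.n_subjects <= 0 or self.n_channels <= 0:
            raise ValueError("counts must be positive (n_trials may be zero)")
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if not self.class_bands:
            self.class_bands = [
                [Band(*DEFAULT_CLASS_BANDS[k])] for k in range(self.n_classes)
            ]
        if len(self.class_bands) != self.n_classes:
            raise ValueError("class_bands must provide one band list per class")
        if self.informative_channels is not None:
            chans = list(self.informative_channels)
            if any(c < 0 or c >= self.n_channels for c in chans):
                raise ValueError("informative channels outside 0..n_channels-1")
            self.informative_channels = chans

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.rate * (self.baseline_seconds + self.stimulus_seconds)))

    @property
    def baseline_samples(self) -> int:
        return int(round(self.rate * self.baseline_seconds))


@dataclass
class RawTrialSet:
    """One subject's trials: ``data`` is (trial, channel, time).

    ``labels`` is (n_trials, 4) continuous ratings for the DEAP-like layout
    (valence, arousal, dominance, liking, each in [1, 9]) or (n_trials,)
    integer classes for the SEED-like layout.  ``latent`` records the
    generator's ground-truth class per trial.
    """

    data: np.ndarray
    labels: np.ndarray
    rate: float
    baseline_seconds: float
    layout: str
    subject: int = 0
    latent: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def deap_spec(**kwargs) -> SimulationSpec:
    """A DEAP-like spec (32 channels, 3 s baseline); overrides via kwargs."""
    base = dict(n_channels=32, baseline_seconds=3.0, rate=128.0)
    base.update(kwargs)
    return SimulationSpec(**base)


def seed_spec(**kwargs) -> SimulationSpec:
    """A SEED-like spec (62 channels, no baseline, 3 classes, 15 clips)."""
    base = dict(
        n_channels=62, baseline_seconds=0.0, rate=128.0, n_classes=3,
        n_trials=15, stimulus_seconds=60.0,
    )
    base.update(kwargs)
    return SimulationSpec(**base)


def _balanced_classes(n_trials: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """As balanced as n_trials allows, in shuffled order."""
    classes = np.arange(n_trials) % n_classes
    rng.shuffle(classes)
    return classes


def _band_signal(band: Band, n_channels: int, t: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Sum of sinusoids with per-channel random frequencies and phases."""
    freqs = rng.uniform(band.low_hz, band.high_hz, size=(n_channels, band.n_components))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, band.n_components))
    scale = band.amplitude / np.sqrt(band.n_components)
    return scale * np.sin(
        2.0 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None]
    ).sum(axis=1)


def _simulate_subject(spec: SimulationSpec, subject: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_t = spec.samples_per_trial
    n_base = spec.baseline_samples
    data = rng.normal(0.0, spec.noise_sd, size=(spec.n_trials, spec.n_channels, n_t))
    latent = _balanced_classes(spec.n_trials, spec.n_classes, rng)
    chans = (np.arange(spec.n_channels) if spec.informative_channels is None
             else np.asarray(spec.informative_channels))
    t = np.arange(n_t - n_base) / spec.rate
    for trial, cls in enumerate(latent):
        for band in spec.class_bands[cls]:
            sig = _band_signal(band, len(chans), t, rng)
            data[trial, chans, n_base:] += sig
    return data.astype(np.float32), latent


def _ratings_from_class(latent: np.ndarray, n_classes: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n, 4) ratings; valence/arousal drawn inside the latent class interval."""
    intervals = RATING_INTERVALS[n_classes]
    n = len(latent)
    ratings = np.empty((n, 4))
    eps = 1e-6  # keep draws off the shared boundary so class round-trips exactly
    for i, cls in enumerate(latent):
        lo, hi = intervals[cls]
        lo_open = lo + eps if cls > 0 else lo
        ratings[i, 0] = rng.uniform(lo_open, hi)  # valence
        ratings[i, 1] = rng.uniform(lo_open, hi)  # arousal
    ratings[:, 2] = rng.uniform(1.0, 9.0, size=n)  # dominance
    ratings[:, 3] = rng.uniform(1.0, 9.0, size=n)  # liking
    return ratings


def simulate_deap_like(spec: SimulationSpec) -> list[RawTrialSet]:
    """Generate a DEAP-like study, one :class:`RawTrialSet` per subject.

    Requires a DEAP-like configuration: 32 channels, a 3 s baseline and a
    sampling rate of 128 or 512 Hz.  Trial time axes have length
    ``rate*(baseline+stimulus)`` (8064 at 128 Hz with the default 63 s).
    """
    if spec.n_channels != 32:
        raise ValueError(f"DEAP-like layout has 32 channels, got {spec.n_channels}")
    if spec.baseline_seconds != 3.0:
        raise ValueError("DEAP-like layout has a 3 s baseline")
    if spec.rate not in (128.0, 512.0):
        raise ValueError(f"DEAP-like rate must be 128 or 512 Hz, got {spec.rate}")
    rng = np.random.default_rng(spec.seed)
    out = []
    for subject in range(spec.n_subjects):
        data, latent = _simulate_subject(spec, subject, rng)
        ratings = _ratings_from_class(latent, spec.n_classes, rng)
        out.append(RawTrialSet(data, ratings, spec.rate, spec.baseline_seconds,
                               "deap", subject, latent))
    return out


def simulate_seed_like(spec: SimulationSpec) -> list[RawTrialSet]:
    """Generate a SEED-like study: 62 channels, categorical labels, no baseline."""
    if spec.n_channels != 62:
        raise ValueError(f"SEED-like layout has 62 channels, got {spec.n_channels}")
    if spec.baseline_seconds != 0.0:
        raise ValueError("SEED-like layout has no baseline window")
    if spec.n_classes != 3:
        raise ValueError("SEED-like labels are 3-class (negative/neutral/positive)")
    rng = np.random.default_rng(spec.seed)
    out = []
    for subject in range(spec.n_subjects):
        data, latent = _simulate_subject(spec, subject, rng)
        out.append(RawTrialSet(data, latent.copy(), spec.rate, 0.0,
                               "seed", subject, latent))
    return out
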