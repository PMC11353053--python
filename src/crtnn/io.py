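"""HDF5 / NPZ persistence for trial sets and segment sets.

Trial studies are stored with one group per subject (datasets ``data``,
``labels`` and, when available, the generator's ground-truth ``latent``
classes) and root attributes ``rate``, ``baseline_seconds`` and ``layout``.
"""

from __future__ import annotations

import h5py
import numpy as np

from .preprocessing import SegmentSet
from .synthetic import RawTrialSet

__all__ = [
    "save_trials_h5",
    "load_trials_h5",
    "save_trials_npz",
    "load_trials_npz",
    "save_segments_h5",
    "load_segments_h5",
]


def save_trials_h5(subjects: list[RawTrialSet], path) -> None:
    first = subjects[0]
    with h5py.File(path, "w") as f:
        f.attrs["rate"] = first.rate
        f.attrs["baseline_seconds"] = first.baseline_seconds
        f.attrs["layout"] = first.layout
        for s in subjects:
            grp = f.create_group(f"subject_{s.subject:02d}")
            grp.create_dataset("data", data=s.data)
            grp.create_dataset("labels", data=s.labels)
            if s.latent is not None:
                grp.create_dataset("latent", data=s.latent)


def load_trials_h5(path) -> list[RawTrialSet]:
    out = []
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate"])
        baseline = float(f.attrs["baseline_seconds"])
        layout = str(f.attrs["layout"])
        for name in sorted(f.keys()):
            grp = f[name]
            out.append(RawTrialSet(
                data=np.asarray(grp["data"]),
                labels=np.asarray(grp["labels"]),
                rate=rate,
                baseline_seconds=baseline,
                layout=layout,
                subject=int(name.split("_")[-1]),
                latent=np.asarray(grp["latent"]) if "latent" in grp else None,
            ))
    return out


def save_trials_npz(subjects: list[RawTrialSet], path) -> None:
    arrays: dict[str, np.ndarray] = {
        "rate": np.array(subjects[0].rate),
        "baseline_seconds": np.array(subjects[0].baseline_seconds),
        "layout": np.array(subjects[0].layout),
    }
    for s in subjects:
        arrays[f"data_{s.subject:02d}"] = s.data
        arrays[f"labels_{s.subject:02d}"] = s.labels
        if s.latent is not None:
            arrays[f"latent_{s.subject:02d}"] = s.latent
    np.savez_compressed(path, **arrays)


def load_trials_npz(path) -> list[RawTrialSet]:
    with np.load(path, allow_pickle=False) as f:
        rate = float(f["rate"])
        baseline = float(f["baseline_seconds"])
        layout = str(f["layout"])
        subjects = sorted(int(k.split("_")[-1]) for k in f.files if k.startswith("data_"))
        return [
            RawTrialSet(
                data=f[f"data_{s:02d}"],
                labels=f[f"labels_{s:02d}"],
                rate=rate,
                baseline_seconds=baseline,
                layout=layout,
                subject=s,
                latent=f[f"latent_{s:02d}"] if f"latent_{s:02d}" in f.files else None,
            )
            for s in subjects
        ]


def save_segments_h5(segments: SegmentSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=segments.samples)
        f.create_dataset("labels", data=segments.labels)
        f.create_dataset("subjects", data=segments.subjects)
        f.create_dataset("trials", data=segments.trials)


def load_segments_h5(path) -> SegmentSet:
    with h5py.File(path, "r") as f:
        return SegmentSet(
            samples=np.asarray(f["samples"]),
            labels=np.asarray(f["labels"]),
            subjects=np.asarray(f["subjects"]),
            trials=np.asarray(f["trials"]),
        )
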