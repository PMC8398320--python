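"""Core data containers for multi-subject epoched EEG.

An :class:`Epochs` object holds one subject's segmented EEG as a
``[T × C × N]`` tensor (time samples × channels × trials) together with
binary trial labels, the sampling rate, the channel montage and the epoch
onset relative to the stimulus.  A :class:`MultiSubjectDataset` maps subject
ids to train/test :class:`Epochs` pairs sharing a common montage.

Datasets round-trip through a self-describing on-disk fixture: a
``dataset.json`` sidecar plus one HDF5 file per subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Epochs",
    "MultiSubjectDataset",
    "load_dataset",
    "save_dataset",
    "select_channels",
    "concatenate_epochs",
    "epochs_from_mne",
]

#: label encoding used throughout: 1 = left-hand imagery, 2 = right-hand imagery
CLASS_MAP = {1: "left_hand", 2: "right_hand"}


class FormatError(RuntimeError):
    """Raised when an on-disk fixture does not follow the expected layout."""


class ValidationError(ValueError):
    """Raised when container invariants are violated."""


@dataclass
class Epochs:
    """Segmented EEG from one subject and one split.

    Parameters
    ----------
    data
        Array of shape ``(T, C, N)``: time samples × channels × trials.
    labels
        Length-``N`` integer class labels; exactly two distinct values.
    fs
        Sampling rate in Hz, strictly positive.
    channels
        ``C`` channel names (10-20 system).
    t0
        Time of the first sample relative to stimulus onset, in seconds.
        Sample ``k`` sits at ``t0 + k / fs``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 3-D [T, C, N], got shape {self.data.shape}")
        T, C, N = self.data.shape
        if len(self.channels) != C:
            raise ValidationError(f"{len(self.channels)} channel names for {C} data channels")
        if self.labels.shape != (N,):
            raise ValidationError(f"{self.labels.shape[0]} labels for {N} trials")
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite samples")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(np.unique(self.labels)) != 2:
            raise ValidationError(
                f"expected exactly two classes, got labels {sorted(np.unique(self.labels))}"
            )

    # --- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def class_ids(self) -> np.ndarray:
        """Sorted distinct labels (length 2)."""
        return np.unique(self.labels)

    def class_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "Epochs":
        return Epochs(self.data.copy(), self.labels.copy(), self.fs, list(self.channels), self.t0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Epochs):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.channels == other.channels
            and self.t0 == other.t0
        )


@dataclass
class MultiSubjectDataset:
    """A named collection of subjects, each with a train and a test split."""

    subjects: dict[str, dict[str, Epochs]]
    name: str
    montage: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.montage = list(self.montage)
        self.subjects = {sid: self.subjects[sid] for sid in sorted(self.subjects)}
        self.validate()

    def validate(self) -> None:
        if not self.subjects:
            raise ValidationError("dataset has no subjects")
        ref = None
        for sid, splits in self.subjects.items():
            for split in ("train", "test"):
                if split not in splits:
                    raise ValidationError(f"subject {sid!r} lacks a {split!r} split")
                e = splits[split]
                if e.channels != self.montage:
                    raise ValidationError(
                        f"subject {sid!r} {split} montage {e.channels} differs from "
                        f"dataset montage {self.montage}"
                    )
                key = (e.fs, e.t0, e.n_samples)
                if ref is None:
                    ref = key
                elif key != ref:
                    raise ValidationError(
                        f"subject {sid!r} {split} has (fs, t0, T)={key}, expected {ref}"
                    )
            tr, te = splits["train"], splits["test"]
            if set(tr.class_ids) != set(te.class_ids):
                raise ValidationError(
                    f"subject {sid!r}: train classes {tr.class_ids.tolist()} != "
                    f"test classes {te.class_ids.tolist()}"
                )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    @property
    def fs(self) -> float:
        first = next(iter(self.subjects.values()))
        return first["train"].fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiSubjectDataset):
            return NotImplemented
        return (
            self.name == other.name
            and self.montage == other.montage
            and self.subject_ids == other.subject_ids
            and all(
                self.subjects[s][k] == other.subjects[s][k]
                for s in self.subjects
                for k in ("train", "test")
            )
        )


# --- fixture i/o ---------------------------------------------------------------

def save_dataset(d: MultiSubjectDataset, path: str | Path) -> None:
    """Write ``d`` as a fixture directory readable by :func:`load_dataset`.

    Layout: ``dataset.json`` with name, montage, fs, t0, class map and subject
    list, plus one ``subj_<id>.h5`` per subject holding ``/train|test/data``
    and ``/train|test/labels``.  Two saves of the same dataset are
    byte-identical (fixed HDF5 layout, no timestamps).
    """
    d.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    first = next(iter(d.subjects.values()))["train"]
    meta = {
        "name": d.name,
        "montage": d.montage,
        "fs": first.fs,
        "t0": first.t0,
        "class_map": {str(k): v for k, v in CLASS_MAP.items()},
        "subjects": d.subject_ids,
        "meta": d.meta,
    }
    (path / "dataset.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    for sid, splits in d.subjects.items():
        with h5py.File(path / f"subj_{sid}.h5", "w", track_order=False) as h5:
            for split in ("train", "test"):
                g = h5.create_group(split)
                # track_times=False keeps repeated saves byte-identical
                g.create_dataset("data", data=splits[split].data, track_times=False)
                g.create_dataset("labels", data=splits[split].labels, track_times=False)


def load_dataset(path: str | Path) -> MultiSubjectDataset:
    """Load a fixture directory written by :func:`save_dataset`."""
    path = Path(path)
    meta_path = path / "dataset.json"
    if not meta_path.exists():
        raise FormatError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("name", "montage", "fs", "t0", "subjects"):
        if key not in meta:
            raise FormatError(f"dataset.json lacks required key {key!r}")
    subjects: dict[str, dict[str, Epochs]] = {}
    for sid in sorted(meta["subjects"]):
        h5_path = path / f"subj_{sid}.h5"
        if not h5_path.exists():
            raise FormatError(f"missing subject file {h5_path}")
        with h5py.File(h5_path, "r") as h5:
            splits = {}
            for split in ("train", "test"):
                if split not in h5:
                    raise FormatError(f"{h5_path} lacks group /{split}")
                splits[split] = Epochs(
                    data=h5[split]["data"][()],
                    labels=h5[split]["labels"][()],
                    fs=meta["fs"],
                    channels=meta["montage"],
                    t0=meta["t0"],
                )
        subjects[sid] = splits
    return MultiSubjectDataset(
        subjects=subjects, name=meta["name"], montage=meta["montage"], meta=meta.get("meta", {})
    )


# --- channel handling ----------------------------------------------------------

def select_channels(e: Epochs, names: list[str]) -> Epochs:
    """Slice and reorder channels to match ``names`` exactly.

    Used to harmonize two datasets to a shared motor-cortex montage before
    cross-dataset training.  Raises listing all missing names if any requested
    channel is absent.
    """
    missing = [n for n in names if n not in e.channels]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    idx = [e.channels.index(n) for n in names]
    return Epochs(e.data[:, idx, :].copy(), e.labels.copy(), e.fs, list(names), e.t0)


def concatenate_epochs(parts: list[Epochs]) -> Epochs:
    """Concatenate trials from several Epochs sharing montage, fs and window."""
    if not parts:
        raise ValidationError("nothing to concatenate")
    ref = parts[0]
    for e in parts[1:]:
        if e.channels != ref.channels or e.fs != ref.fs or e.n_samples != ref.n_samples:
            raise ValidationError("epochs to concatenate have inconsistent montage/fs/window")
    return Epochs(
        np.concatenate([e.data for e in parts], axis=2),
        np.concatenate([e.labels for e in parts]),
        ref.fs,
        list(ref.channels),
        ref.t0,
    )


def epochs_from_mne(mne_epochs, label_map: dict[int, int]) -> Epochs:
    """Convert an ``mne.Epochs`` object (e.g. read from EDF/BrainVision).

    ``label_map`` maps mne event codes to the internal {1, 2} encoding.
    Convenience adapter only; the fixture format is the tested contract.
    """
    data = mne_epochs.get_data()  # (N, C, T)
    labels = np.array([label_map[int(code)] for code in mne_epochs.events[:, 2]])
    return Epochs(
        data=np.transpose(data, (2, 1, 0)),
        labels=labels,
        fs=float(mne_epochs.info["sfreq"]),
        channels=list(mne_epochs.ch_names),
        t0=float(mne_epochs.tmin),
    )
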