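"""Core data containers shared across the pipeline.

The analysis operates on fixed-length multichannel EEG epochs. Each epoch
carries three labels: the subject it came from, the subject's group
(``"M"`` or ``"H"``), and the cognitive task being solved (``"verb"``,
``"ar"`` or ``"sq"``). Downstream stages never look at raw recordings
again, so :class:`EpochSet` is the single interchange object, with an
HDF5 round-trip for persistence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("M", "H")
TASKS = ("verb", "ar", "sq")

#: The seven analysis bands (name, low Hz, high Hz) spanning 4-24 Hz.
DEFAULT_BANDS = (
    ("theta1", 4.0, 6.0),
    ("theta2", 6.0, 8.0),
    ("alpha1", 8.0, 10.0),
    ("alpha2", 10.0, 12.0),
    ("beta1", 12.0, 16.0),
    ("beta2", 16.0, 20.0),
    ("beta3", 20.0, 24.0),
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.high >= fs / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz >= Nyquist {fs / 2.0} Hz"
            )


def default_bands() -> list[BandDefinition]:
    """The seven standard theta/alpha/beta sub-bands."""
    return [BandDefinition(n, lo, hi) for n, lo, hi in DEFAULT_BANDS]


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-epoch subject/group/task labels.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Epoch signals in volts.
    fs : float
        Sampling rate in Hz.
    ch_names : sequence of str
        Unique channel names, one per channel.
    ch_pos : ndarray, shape (n_channels, 3)
        3-D sensor positions (unit sphere for the synthetic montage).
    subject, group, task : sequences, length n_epochs
        Per-epoch labels; ``group`` values are ``"M"``/``"H"``.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    ch_pos: np.ndarray
    subject: np.ndarray
    group: np.ndarray
    task: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite samples")
        n = self.n_epochs
        self.subject = _as_str_array(self.subject)
        self.group = _as_str_array(self.group)
        self.task = _as_str_array(self.task)
        for name, arr in (("subject", self.subject), ("group", self.group), ("task", self.task)):
            if arr.shape != (n,):
                raise ValueError(f"label array {name!r} must have length {n}")
        self.ch_pos = np.asarray(self.ch_pos, dtype=float)
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length must match channel axis")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset epochs by boolean mask or index array (labels follow)."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            subject=self.subject[mask],
            group=self.group[mask],
            task=self.task[mask],
        )

    def select_task(self, task: str) -> "EpochSet":
        if task not in set(self.task):
            raise ValueError(f"task {task!r} not present")
        return self.select(self.task == task)

    def select_subjects(self, subjects) -> "EpochSet":
        subjects = set(subjects)
        return self.select(np.array([s in subjects for s in self.subject]))

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subject:
            seen.setdefault(s, None)
        return list(seen)

    def subject_groups(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s, g in zip(self.subject, self.group):
            prev = out.setdefault(s, g)
            if prev != g:
                raise ValueError(f"subject {s!r} appears with two groups")
        return out

    # ---------------------------------------------------------------- I/O
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.data)
            f.create_dataset("positions", data=self.ch_pos)
            str_dt = "S64"
            f.create_dataset("ch_names", data=np.array(self.ch_names, dtype=str_dt))
            f.create_dataset("subject", data=self.subject.astype(str_dt))
            f.create_dataset("group", data=self.group.astype(str_dt))
            f.create_dataset("task", data=self.task.astype(str_dt))
            f.attrs["fs"] = self.fs
            f.attrs["meta"] = json.dumps(self.meta, default=str)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            dec = lambda a: [x.decode() for x in a[()]]
            return cls(
                data=f["epochs"][()],
                fs=float(f.attrs["fs"]),
                ch_names=dec(f["ch_names"]),
                ch_pos=f["positions"][()],
                subject=dec(f["subject"]),
                group=dec(f["group"]),
                task=dec(f["task"]),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )


@dataclass
class BandEpochs:
    """Filter-bank output: epochs decomposed into the analysis bands.

    ``data`` has shape (n_bands, n_epochs, n_channels, n_samples).
    """

    data: np.ndarray
    bands: list[BandDefinition]
    source: EpochSet

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.bands):
            raise ValueError("band axis must match band list")


@dataclass
class PSDSet:
    """Band-integrated multitaper power, (n_epochs, n_channels, n_bands), in V^2."""

    power: np.ndarray
    bands: list[BandDefinition]
    source: EpochSet

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 3 or self.power.shape[2] != len(self.bands):
            raise ValueError("power must be (epochs, channels, bands)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def subject_mean(self, epochs_mask=None) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Average power per subject; returns (subjects, groups, subj x ch x band)."""
        src = self.source
        mask = np.ones(src.n_epochs, bool) if epochs_mask is None else np.asarray(epochs_mask)
        subs = []
        seen = set()
        for s in src.subject[mask]:
            if s not in seen:
                seen.add(s)
                subs.append(s)
        gmap = src.subject_groups()
        out = np.stack(
            [self.power[mask & (src.subject == s)].mean(axis=0) for s in subs]
        )
        return subs, np.array([gmap[s] for s in subs], dtype=object), out


@dataclass
class FeatureMatrix:
    """Epochs x features design matrix with names and pipeline provenance."""

    values: np.ndarray
    feature_names: list[str]
    pipeline: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs, features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match feature axis")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=self.feature_names).to_csv(path, index=False)
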