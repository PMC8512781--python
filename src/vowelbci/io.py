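"""Recording containers, file IO, montage handling and trial extraction.

A :class:`Recording` is a channels x time voltage matrix with a sampling rate
and ordered electrode labels (e.g. ``E1 .. E14`` for the 14-channel left-
hemisphere montage, or ``F3, F4, C3, C5, P3, P4`` for the 6-channel montage).
Trials are the task intervals of a continuous session; everything downstream
operates on equal-length trial segments.

Sample indices are 0-based and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "TrialSet",
    "electrode_pairs",
    "extract_trials",
    "protocol_intervals",
    "read_recording",
    "write_recording",
]


@dataclasses.dataclass
class Recording:
    """Multichannel EEG segment: ``samples`` is channels x time in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    electrode_labels: tuple[str, ...]
    subject: str | int | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError(f"samples must be 2-D (channels x time), got shape {self.samples.shape}")
        self.electrode_labels = tuple(str(l) for l in self.electrode_labels)
        if len(self.electrode_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.electrode_labels)} electrode labels for {self.samples.shape[0]} channel rows"
            )
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    def slice(self, start: int, end: int) -> "Recording":
        """Half-open time slice ``[start, end)`` sharing labels and rate."""
        if not (0 <= start <= end <= self.n_samples):
            raise ValueError(f"slice [{start}, {end}) outside recording of {self.n_samples} samples")
        return Recording(
            self.samples[:, start:end].copy(),
            self.sampling_rate,
            self.electrode_labels,
            subject=self.subject,
            metadata=dict(self.metadata),
        )


@dataclasses.dataclass
class TrialSet:
    """Ordered trial segments with vowel labels and extraction provenance."""

    trials: list[Recording]
    labels: list[str]
    trial_indices: list[int]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.trials) == len(self.labels) == len(self.trial_indices)):
            raise ValueError("trials, labels and trial_indices must have equal length")
        if self.trials:
            n_ch = self.trials[0].n_channels
            fs = self.trials[0].sampling_rate
            for k, t in enumerate(self.trials):
                if t.n_channels != n_ch or t.sampling_rate != fs:
                    raise ValueError(f"trial {k} has inconsistent channel count or sampling rate")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(zip(self.trials, self.labels, self.trial_indices))


def electrode_pairs(n_channels: int) -> list[tuple[int, int]]:
    """All unordered channel index pairs ``(i, j)``, ``i < j``, lexicographic.

    0-based indices; pair ``(0, 1)`` corresponds to electrodes E1-E2. The
    14-channel montage yields 91 pairs, the 6-channel montage 15.
    """
    if n_channels < 2:
        raise ValueError(f"need at least 2 channels to form pairs, got {n_channels}")
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def protocol_intervals(
    n_cycles: int, on_duration: float, off_duration: float, sampling_rate: float
) -> list[tuple[int, int]]:
    """On-interval boundaries for a cyclic light-on/light-off cue protocol.

    Each cycle is ``on_duration`` seconds of task followed by ``off_duration``
    seconds of rest; only the on intervals are returned, as half-open sample
    index ranges.
    """
    on = int(round(on_duration * sampling_rate))
    period = on + int(round(off_duration * sampling_rate))
    return [(k * period, k * period + on) for k in range(n_cycles)]


def extract_trials(
    recording: Recording,
    intervals: Sequence[tuple[int, int]],
    labels: Sequence[str] | str,
) -> TrialSet:
    """Cut the task intervals out of a continuous session.

    Parameters
    ----------
    recording : continuous session.
    intervals : half-open ``[start, end)`` sample ranges of the task periods
        (e.g. from :func:`protocol_intervals`); rest periods are discarded.
    labels : one vowel label per interval, or a single label applied to all.
    """
    intervals = list(intervals)
    if isinstance(labels, str):
        labels = [labels] * len(intervals)
    labels = list(labels)
    if len(labels) != len(intervals):
        raise ValueError(f"{len(labels)} labels for {len(intervals)} intervals")
    trials: list[Recording] = []
    for k, (start, end) in enumerate(intervals):
        if start < 0 or end > recording.n_samples or start > end:
            raise ValueError(
                f"interval {k} = [{start}, {end}) outside recording of {recording.n_samples} samples"
            )
        trials.append(recording.slice(start, end))
    return TrialSet(
        trials,
        labels,
        list(range(len(trials))),
        provenance={"intervals": intervals, "source_samples": recording.n_samples},
    )


def write_recording(recording: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as delimited text (.csv/.tsv) or HDF5 (.h5/.hdf5).

    Delimited layout is one row per sample, one column per channel, with the
    electrode labels as header. HDF5 stores a ``samples`` dataset with ``fs``
    and ``labels`` attributes.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "delimited":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.DataFrame(recording.samples.T, columns=list(recording.electrode_labels))
        df.to_csv(path, sep=sep, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("samples", data=recording.samples)
            dset.attrs["fs"] = recording.sampling_rate
            dset.attrs["labels"] = list(recording.electrode_labels)
            if recording.subject is not None:
                dset.attrs["subject"] = str(recording.subject)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_recording(
    path: str | Path,
    format: str | None = None,
    sampling_rate: float | None = None,
    drop_reference: Iterable[str] = (),
) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``sampling_rate`` is required for delimited files (text has no rate
    sidecar). Channels named in ``drop_reference`` (e.g. forehead reference
    electrodes) are removed at ingestion. Orientation is normalized to
    channels x time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "delimited":
        if sampling_rate is None:
            raise ValueError("sampling_rate is required when reading delimited text")
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            col = bad[0]
            row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
            raise ValueError(f"{path}: non-numeric value in column {col!r}, data row {row}")
        labels = [str(c) for c in df.columns]
        samples = df.to_numpy(dtype=float).T
        fs = sampling_rate
        subject = None
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "samples" not in f:
                raise ValueError(f"{path}: missing 'samples' dataset")
            dset = f["samples"]
            samples = np.asarray(dset)
            fs = float(dset.attrs["fs"]) if sampling_rate is None else sampling_rate
            labels = [l if isinstance(l, str) else l.decode() for l in dset.attrs["labels"]]
            subject = str(dset.attrs["subject"]) if "subject" in dset.attrs else None
        if samples.shape[0] != len(labels) and samples.shape[1] == len(labels):
            samples = samples.T
    else:
        raise ValueError(f"unknown format {fmt!r}")
    drop = set(drop_reference)
    if drop:
        keep = [k for k, l in enumerate(labels) if l not in drop]
        samples = samples[keep]
        labels = [labels[k] for k in keep]
    if samples.shape[0] < 2:
        raise ValueError(f"{path}: fewer than 2 channels after ingestion")
    return Recording(samples, fs, tuple(labels), subject=subject, metadata={"source": str(path)})


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".csv", ".tsv", ".txt"}:
        return "delimited"
    if suffix in {".h5", ".hdf5"}:
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")
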