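"""Frequency x electrode-pair spectral images from filtered EEG trials.

Each trial (or concatenation of one subject/vowel's trials) is cut into
64-sample windows at 85% overlap (stride 10). Per window, the magnitude of
the complex difference of the channel DFTs, ``|FFT(Ei) - FFT(Ej)|``, is
evaluated for every unordered electrode pair ``i < j`` and restricted to the
32 lowest non-negative frequency bins; the resulting frequency x pair matrix
is min-max normalized to [0, 1]. A 14-channel montage yields 32 x 91 images,
a 6-channel montage 32 x 15.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TrialSet, electrode_pairs

__all__ = [
    "SpectralImage",
    "SpectralImageSet",
    "WindowingSpec",
    "build_image_set",
    "normalize_image",
    "pair_difference_spectrum",
    "segment_windows",
]


@dataclasses.dataclass
class WindowingSpec:
    """Sliding-window parameters.

    ``stride = window_length - round(overlap_fraction * window_length)``
    (64 - 54 = 10 at the defaults). ``concatenate_trials`` pools all trials
    of one (subject, vowel) into a single time series before windowing —
    the configuration that yields 1274 windows per vowel from 25 trials of
    512 samples. ``n_freq_bins`` rows of the DFT are kept, starting at
    ``first_bin`` (0 keeps DC; set 1 for bins 1-32).
    """

    window_length: int = 64
    overlap_fraction: float = 0.85
    concatenate_trials: bool = True
    n_freq_bins: int = 32
    first_bin: int = 0
    magnitude_difference: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 1 <= self.stride <= self.window_length:
            raise ValueError(f"derived stride {self.stride} outside [1, window_length]")
        if self.first_bin + self.n_freq_bins > self.window_length // 2 + 1:
            raise ValueError("requested frequency bins exceed the non-negative DFT range")

    @property
    def stride(self) -> int:
        return self.window_length - int(round(self.overlap_fraction * self.window_length))


@dataclasses.dataclass
class SpectralImage:
    """One labelled frequency x electrode-pair matrix in [0, 1]."""

    values: np.ndarray
    freq_axis: np.ndarray
    pair_axis: list[tuple[int, int]]
    label: str
    subject: int | str | None = None
    window_offset: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass
class SpectralImageSet:
    """Collection of equal-shape spectral images with provenance."""

    images: list[SpectralImage]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for img in self.images:
            counts[img.label] = counts.get(img.label, 0) + 1
        return counts

    def stack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, subjects) arrays: X is n_images x n_freq x n_pairs."""
        X = np.stack([img.values for img in self.images])
        y = np.array([img.label for img in self.images])
        subjects = np.array([img.subject for img in self.images])
        return X, y, subjects

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image": range(len(self.images)),
                "subject": [img.subject for img in self.images],
                "vowel": [img.label for img in self.images],
                "window_offset": [img.window_offset for img in self.images],
            }
        )


def segment_windows(signal: np.ndarray, spec: WindowingSpec | None = None) -> list[np.ndarray]:
    """Cut a channels x time array into overlapping fixed-length windows.

    Windows start at 0, stride, 2*stride, ...; the count is
    ``floor((T - window_length) / stride) + 1``.
    """
    spec = spec or WindowingSpec()
    signal = np.asarray(signal, dtype=float)
    T = signal.shape[-1]
    L, s = spec.window_length, spec.stride
    if T < L:
        raise ValueError(f"signal of {T} samples is shorter than the {L}-sample window")
    n = (T - L) // s + 1
    return [signal[..., k * s : k * s + L] for k in range(n)]


def pair_difference_spectrum(
    window: np.ndarray,
    pairs: Sequence[tuple[int, int]] | None = None,
    spec: WindowingSpec | None = None,
) -> np.ndarray:
    """``|FFT(Ei) - FFT(Ej)|`` for every electrode pair, pre-normalization.

    Returns an ``n_freq_bins x n_pairs`` matrix: column for pair (i, j) is
    the magnitude of the complex DFT difference of channels i and j on the
    retained non-negative frequency bins. With ``spec.magnitude_difference``
    the alternative ``| |FFT(Ei)| - |FFT(Ej)| |`` reading is used.
    """
    spec = spec or WindowingSpec()
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError(f"window must be channels x time, got shape {window.shape}")
    n_ch, L = window.shape
    if L != spec.window_length:
        raise ValueError(f"window length {L} does not match spec window_length {spec.window_length}")
    if pairs is None:
        pairs = electrode_pairs(n_ch)
    F = np.fft.fft(window, axis=1)[:, spec.first_bin : spec.first_bin + spec.n_freq_bins]
    if spec.magnitude_difference:
        F = np.abs(F)
    out = np.empty((spec.n_freq_bins, len(pairs)))
    for c, (i, j) in enumerate(pairs):
        if not (0 <= i < n_ch and 0 <= j < n_ch):
            raise ValueError(f"pair ({i}, {j}) invalid for {n_ch} channels")
        out[:, c] = np.abs(F[i] - F[j])
    return out


def normalize_image(matrix: np.ndarray) -> np.ndarray:
    """Per-image min-max scaling to [0, 1]; a constant matrix maps to zeros."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("cannot normalize a matrix with non-finite entries")
    lo, hi = matrix.min(), matrix.max()
    if hi == lo:
        return np.zeros_like(matrix)
    return (matrix - lo) / (hi - lo)


def build_image_set(
    trialset: TrialSet,
    spec: WindowingSpec | None = None,
    filter=None,
    filter_per_window: bool = False,
) -> SpectralImageSet:
    """Convert a trial set into labelled spectral images.

    Per (subject, vowel): optionally filter each trial (``filter`` maps a
    channels x time array to a same-shape array, e.g.
    ``APITMEMD().transform_frame``), concatenate the vowel's trials when the
    spec says so, window, transform, normalize and label. With
    ``filter_per_window`` the filter runs on each 64-sample window instead
    of on whole trials (the alternative ordering of the two stages).
    """
    spec = spec or WindowingSpec()
    images: list[SpectralImage] = []
    if len(trialset) == 0:
        return SpectralImageSet([], provenance={"windowing": dataclasses.asdict(spec)})
    n_ch = trialset.trials[0].n_channels
    fs = trialset.trials[0].sampling_rate
    pairs = electrode_pairs(n_ch)
    freq_axis = np.fft.fftfreq(spec.window_length, d=1.0 / fs)[
        spec.first_bin : spec.first_bin + spec.n_freq_bins
    ]

    by_group: dict[tuple, list[np.ndarray]] = {}
    for rec, label, _idx in trialset:
        key = (rec.subject, label)
        x = rec.samples
        if filter is not None and not filter_per_window:
            x = filter(x)
        by_group.setdefault(key, []).append(np.asarray(x, dtype=float))

    for (subject, label), blocks in by_group.items():
        series = [np.concatenate(blocks, axis=1)] if spec.concatenate_trials else blocks
        for block in series:
            for k, window in enumerate(segment_windows(block, spec)):
                if filter is not None and filter_per_window:
                    window = filter(window)
                raw = pair_difference_spectrum(window, pairs, spec)
                images.append(
                    SpectralImage(
                        normalize_image(raw),
                        freq_axis.copy(),
                        pairs,
                        label=label,
                        subject=subject,
                        window_offset=k * spec.stride,
                    )
                )
    return SpectralImageSet(
        images,
        provenance={
            "windowing": dataclasses.asdict(spec),
            "n_channels": n_ch,
            "sampling_rate": fs,
            "filtered": filter is not None,
        },
    )


def save_image_set(imageset: SpectralImageSet, path: str | Path) -> Path:
    """Write an image set as an HDF5 container (images + labels + axes)."""
    import h5py

    path = Path(path)
    X, y, subjects = imageset.stack() if len(imageset) else (np.zeros((0, 0, 0)), np.array([]), np.array([]))
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=X)
        f.create_dataset("labels", data=np.asarray(y, dtype="S8"))
        f.create_dataset("subjects", data=np.asarray([str(s) for s in subjects], dtype="S16"))
        if len(imageset):
            f.create_dataset("freq_axis", data=imageset.images[0].freq_axis)
    return path


def load_image_set(path: str | Path) -> SpectralImageSet:
    """Read an HDF5 image container written by :func:`save_image_set`."""
    import h5py

    with h5py.File(path, "r") as f:
        X = np.asarray(f["images"])
        labels = [l.decode() for l in f["labels"]]
        subjects = [s.decode() for s in f["subjects"]]
        freq_axis = np.asarray(f["freq_axis"]) if "freq_axis" in f else np.array([])
    n_pairs = X.shape[2] if X.ndim == 3 and X.shape[0] else 0
    n_ch = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2) if n_pairs else 0
    pairs = electrode_pairs(n_ch) if n_ch >= 2 else []
    images = [
        SpectralImage(X[k], freq_axis.copy(), pairs, label=labels[k], subject=subjects[k])
        for k in range(X.shape[0])
    ]
    return SpectralImageSet(images, provenance={"source": str(path)})
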