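"""Synthetic imagined-vowel EEG with class-dependent spectral structure.

The generator emulates the cue-paced acquisition protocol of the 14-channel
imagined-vowel recordings this toolkit targets: per subject and vowel, the
cue light stays on for ``on_duration`` seconds (the subject imagines the
vowel) and off for ``off_duration`` seconds (rest), repeated
``n_trials_per_vowel`` times as one continuous session.

Each vowel class is given a set of narrowband oscillatory *signatures*
(channel, center frequency, bandwidth, amplitude) embedded in 1/f-plus-white
background noise. The default signatures place each vowel's energy on a
distinct channel/band combination, qualitatively mirroring the electrode-pair
and frequency-band activations reported for imagined Spanish vowels (e.g.
/a/ contrast on the E1-E7 pair in the beta/gamma range), so downstream
class-activation maps have a known ground truth. Amplitudes are free
parameters: the real recordings give no quantitative effect sizes.

Randomness is counter-based: one master seed, with independent streams per
(subject, vowel, trial) derived via ``numpy.random.SeedSequence`` spawn keys,
so any subset of the dataset is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Recording, TrialSet, extract_trials, protocol_intervals, write_recording

VOWELS = ("a", "e", "i", "o", "u")

__all__ = [
    "ClassSignature",
    "SyntheticConfig",
    "default_signatures",
    "generate_trial",
    "generate_session",
    "generate_dataset",
    "dataset_trialsets",
    "write_dataset",
]


@dataclasses.dataclass(frozen=True)
class ClassSignature:
    """One narrowband oscillation: planted on ``channel`` at ``freq`` Hz.

    ``bandwidth`` is the width of the uniform per-trial frequency jitter;
    ``amplitude`` is the peak amplitude in the same (arbitrary microvolt)
    units as the background noise.
    """

    channel: int
    freq: float
    bandwidth: float = 2.0
    amplitude: float = 1.0


def default_signatures(n_channels: int) -> dict[str, list[ClassSignature]]:
    """Per-vowel default signatures, folded onto ``n_channels`` channels.

    Channel/band choices echo the qualitative class-activation structure
    reported for imagined vowels on the 14-channel montage: /a/ on E1 in the
    beta band, /e/ on E2 near 37 Hz, /i/ on E5 in theta/alpha, /o/ on E6 near
    31 Hz, /u/ on E10 near 26 Hz.
    """
    base = {
        "a": [(0, 30.0)],
        "e": [(1, 37.0)],
        "i": [(4, 8.0)],
        "o": [(5, 31.0)],
        "u": [(9, 26.0)],
    }
    return {
        v: [ClassSignature(ch % n_channels, f) for ch, f in sigs]
        for v, sigs in base.items()
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Study-shaped generator configuration.

    Defaults describe the 50-subject database: 50 subjects x 5 vowels x 25
    trials of 4 s at 128 Hz on 14 channels, 4 s-on / 3 s-off cue protocol.
    ``snr`` is the RMS ratio of signature signal to background noise;
    ``snr = 0`` means the signatures are absent entirely (pure noise) and
    ``snr = inf`` disables the noise.
    """

    n_subjects: int = 50
    n_trials_per_vowel: int = 25
    n_channels: int = 14
    sampling_rate: float = 128.0
    trial_duration: float = 4.0
    on_duration: float = 4.0
    off_duration: float = 3.0
    class_signatures: Mapping[str, Sequence[ClassSignature]] | None = None
    pink_exponent: float = 1.5
    white_sd: float = 0.05
    snr: float = 1.0
    subject_gain_sd: float = 0.1
    subject_freq_jitter: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("n_subjects and n_channels must be >= 1")
        if self.n_trials_per_vowel < 0:
            raise ValueError("n_trials_per_vowel must be >= 0")
        for name in ("sampling_rate", "trial_duration", "on_duration", "off_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.class_signatures is None:
            self.class_signatures = default_signatures(self.n_channels)
        for vowel, sigs in self.class_signatures.items():
            for s in sigs:
                if not 0 <= s.channel < self.n_channels:
                    raise ValueError(f"signature channel {s.channel} out of range for vowel {vowel!r}")
                if s.freq >= self.sampling_rate / 2:
                    raise ValueError(
                        f"signature frequency {s.freq} Hz for vowel {vowel!r} is at or above "
                        f"Nyquist ({self.sampling_rate / 2} Hz)"
                    )

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    @property
    def electrode_labels(self) -> tuple[str, ...]:
        return tuple(f"E{k + 1}" for k in range(self.n_channels))

    def _reference_rms(self, vowel: str) -> float:
        """Signature-signal RMS scale used to set the noise level."""
        sigs = list(self.class_signatures.get(vowel, ()))
        if not sigs:
            return 1.0 / math.sqrt(2.0)
        return float(np.mean([abs(s.amplitude) for s in sigs])) / math.sqrt(2.0)


def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def _subject_effects(config: SyntheticConfig, subject: int) -> tuple[np.ndarray, float]:
    """Per-subject channel gains and signature frequency offset (Hz)."""
    rng = _rng(config, 0, subject)
    gains = np.exp(rng.normal(0.0, config.subject_gain_sd, size=config.n_channels))
    jitter = rng.uniform(-config.subject_freq_jitter, config.subject_freq_jitter)
    return gains, jitter


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, beta: float) -> np.ndarray:
    """1/f^beta noise, unit RMS per channel."""
    if n == 0:
        return np.zeros((n_channels, 0))
    spec = rng.normal(size=(n_channels, n // 2 + 1)) + 1j * rng.normal(size=(n_channels, n // 2 + 1))
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _noise_block(config: SyntheticConfig, rng: np.random.Generator, n: int, vowel: str) -> np.ndarray:
    """Background noise scaled so signature RMS / noise RMS = snr."""
    if math.isinf(config.snr):
        return np.zeros((config.n_channels, n))
    raw = _pink_noise(rng, config.n_channels, n, config.pink_exponent)
    raw = raw + config.white_sd * rng.normal(size=(config.n_channels, n))
    unit = raw / math.sqrt(1.0 + config.white_sd**2)
    ref = config._reference_rms(vowel)
    scale = ref if config.snr == 0 else ref / config.snr
    return scale * unit


def _signature_signal(
    config: SyntheticConfig, rng: np.random.Generator, vowel: str, subject: int, n: int
) -> np.ndarray:
    """Sum of the vowel's narrowband oscillations; zero when snr == 0."""
    sig = np.zeros((config.n_channels, n))
    if config.snr == 0 or n == 0:
        return sig
    gains, subj_jitter = _subject_effects(config, subject)
    t = np.arange(n) / config.sampling_rate
    nyq = config.sampling_rate / 2.0
    for s in config.class_signatures.get(vowel, ()):
        f = s.freq + subj_jitter + rng.uniform(-s.bandwidth / 2.0, s.bandwidth / 2.0)
        f = min(max(f, 0.5), nyq - 0.5)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        sig[s.channel] += gains[s.channel] * s.amplitude * np.sin(2.0 * math.pi * f * t + phase)
    return sig


def _vowel_index(vowel: str) -> int:
    try:
        return VOWELS.index(vowel)
    except ValueError:
        raise ValueError(f"unknown vowel {vowel!r}; expected one of {VOWELS}") from None


def generate_trial(config: SyntheticConfig, subject: int, vowel: str, trial: int) -> Recording:
    """One imagination-interval trial, deterministic in (seed, subject, vowel, trial)."""
    vi = _vowel_index(vowel)
    if not 0 <= subject < config.n_subjects:
        raise ValueError(f"subject index {subject} out of range [0, {config.n_subjects})")
    if not 0 <= trial < max(config.n_trials_per_vowel, 1):
        raise ValueError(f"trial index {trial} out of range [0, {config.n_trials_per_vowel})")
    n = config.samples_per_trial
    rng = _rng(config, 1, subject, vi, trial)
    x = _signature_signal(config, rng, vowel, subject, n) + _noise_block(config, rng, n, vowel)
    return Recording(
        x,
        config.sampling_rate,
        config.electrode_labels,
        subject=subject,
        metadata={"vowel": vowel, "trial": trial, "synthetic": True},
    )


def generate_session(config: SyntheticConfig, subject: int, vowel: str) -> tuple[Recording, list[tuple[int, int]]]:
    """Continuous on/off session for one (subject, vowel).

    Returns the recording plus ground-truth on-interval boundaries. The
    content of each on interval is exactly :func:`generate_trial` for the
    same indices; off intervals contain background noise only.
    """
    vi = _vowel_index(vowel)
    n_on = int(round(config.on_duration * config.sampling_rate))
    n_off = int(round(config.off_duration * config.sampling_rate))
    blocks: list[np.ndarray] = []
    for trial in range(config.n_trials_per_vowel):
        blocks.append(generate_trial(config, subject, vowel, trial).samples)
        off_rng = _rng(config, 2, subject, vi, trial)
        blocks.append(_noise_block(config, off_rng, n_off, vowel))
    samples = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((config.n_channels, 0))
    )
    intervals = protocol_intervals(
        config.n_trials_per_vowel, config.on_duration, config.off_duration, config.sampling_rate
    )
    # protocol arithmetic assumes on-block length == trial length
    assert n_on == config.samples_per_trial or config.on_duration != config.trial_duration
    rec = Recording(
        samples,
        config.sampling_rate,
        config.electrode_labels,
        subject=subject,
        metadata={"vowel": vowel, "synthetic": True},
    )
    return rec, intervals


def generate_dataset(
    config: SyntheticConfig,
    subjects: Iterable[int] | None = None,
    vowels: Iterable[str] | None = None,
) -> tuple[dict[tuple[int, str], tuple[Recording, list[tuple[int, int]]]], pd.DataFrame]:
    """Sessions for every requested (subject, vowel), plus a trial manifest.

    The manifest has one row per trial: subject, vowel, trial, interval
    start/end sample.
    """
    subjects = list(subjects) if subjects is not None else list(range(config.n_subjects))
    vowels = list(vowels) if vowels is not None else list(VOWELS)
    sessions = {}
    rows = []
    for s in subjects:
        for v in vowels:
            rec, intervals = generate_session(config, s, v)
            sessions[(s, v)] = (rec, intervals)
            for k, (start, end) in enumerate(intervals):
                rows.append({"subject": s, "vowel": v, "trial": k, "start": start, "end": end})
    manifest = pd.DataFrame(rows, columns=["subject", "vowel", "trial", "start", "end"])
    return sessions, manifest


def dataset_trialsets(
    config: SyntheticConfig,
    subjects: Iterable[int] | None = None,
    vowels: Iterable[str] | None = None,
) -> dict[int, TrialSet]:
    """Per-subject trial sets pooling all vowels (convenience for protocols)."""
    subjects = list(subjects) if subjects is not None else list(range(config.n_subjects))
    vowels = list(vowels) if vowels is not None else list(VOWELS)
    out: dict[int, TrialSet] = {}
    for s in subjects:
        trials: list[Recording] = []
        labels: list[str] = []
        indices: list[int] = []
        for v in vowels:
            rec, intervals = generate_session(config, s, v)
            ts = extract_trials(rec, intervals, v)
            trials.extend(ts.trials)
            labels.extend(ts.labels)
            indices.extend(ts.trial_indices)
        out[s] = TrialSet(trials, labels, indices, provenance={"subject": s, "config_seed": config.seed})
    return out


def trial_disjoint_trialsets(
    config: SyntheticConfig,
    subject: int,
    n_train_trials: int,
    n_test_trials: int,
    vowels: Iterable[str] | None = None,
) -> tuple[TrialSet, TrialSet]:
    """Train/test trial sets drawn from disjoint trials of each session.

    Windows cut from one continuous session overlap heavily (85%), so a
    window-level random split leaks noise realizations between train and
    test; splitting at the trial level keeps the underlying data disjoint.
    Requires ``n_train_trials + n_test_trials <= config.n_trials_per_vowel``.
    """
    vowels = list(vowels) if vowels is not None else list(VOWELS)
    if n_train_trials + n_test_trials > config.n_trials_per_vowel:
        raise ValueError("train + test trials exceed n_trials_per_vowel")
    sets = []
    for which, (lo, hi) in enumerate(
        [(0, n_train_trials), (n_train_trials, n_train_trials + n_test_trials)]
    ):
        trials, labels, idxs = [], [], []
        for v in vowels:
            rec, intervals = generate_session(config, subject, v)
            ts = extract_trials(rec, intervals[lo:hi], v)
            trials += ts.trials
            labels += ts.labels
            idxs += list(range(lo, hi))
        sets.append(
            TrialSet(trials, labels, idxs, provenance={"subject": subject, "trial_range": (lo, hi)})
        )
    return sets[0], sets[1]


def write_dataset(
    config: SyntheticConfig,
    outdir: str | Path,
    subjects: Iterable[int] | None = None,
    vowels: Iterable[str] | None = None,
    format: str = "delimited",
) -> Path:
    """Write sessions plus a manifest table under ``outdir``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions, manifest = generate_dataset(config, subjects, vowels)
    suffix = ".csv" if format == "delimited" else ".h5"
    files = {}
    for (s, v), (rec, _intervals) in sessions.items():
        fname = f"subject{s:03d}_vowel_{v}{suffix}"
        write_recording(rec, outdir / fname, format=format)
        files[(s, v)] = fname
    manifest = manifest.assign(file=[files[(r.subject, r.vowel)] for r in manifest.itertuples()])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
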