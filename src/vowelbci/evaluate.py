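"""Intra-subject and inter-subject (leave-one-subject-out) evaluation.

Intra-subject: each subject's image set is split into a stratified 70%
training / 30% testing partition and an ensemble is trained and scored per
subject. Inter-subject: for every held-out subject, the ensemble is trained
on a random 70% of the *other* subjects' pooled images and scored on a
random 30% of the held-out subject's images (the published protocol
subsamples the test side too; ``test_fraction=1.0`` scores on all of it).

Split sizes use floor-based per-class rounding: train size =
floor(train_fraction * n) per class.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .ensemble import CNNeegClassifier
from .images import SpectralImageSet

__all__ = [
    "ProtocolResult",
    "accuracy_and_confusion",
    "intra_subject_protocol",
    "inter_subject_protocol",
]


@dataclasses.dataclass
class ProtocolResult:
    """Per-subject accuracies with summary statistics and confusion matrices."""

    protocol: str
    per_subject: pd.DataFrame  # columns: subject, accuracy, n_train, n_test
    confusions: dict  # subject -> (labels, matrix)
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_subject["accuracy"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.per_subject["accuracy"].std(ddof=1)) if len(self.per_subject) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        """One-row table in the mean/SD layout of the published results."""
        return pd.DataFrame(
            {"protocol": [self.protocol], "mean": [self.mean_accuracy], "sd": [self.sd_accuracy]}
        )


def accuracy_and_confusion(
    predictions: Sequence, truths: Sequence, labels: Sequence[str] | None = None
) -> tuple[float, np.ndarray, list[str]]:
    """Accuracy plus a confusion matrix with rows = truth, columns = prediction."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError(f"{len(predictions)} predictions for {len(truths)} truths")
    if len(truths) == 0:
        raise ValueError("empty prediction set: accuracy undefined")
    if labels is None:
        labels = sorted(set(truths.tolist()) | set(predictions.tolist()))
    labels = list(labels)
    index = {c: k for k, c in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truths, predictions):
        confusion[index[t], index[p]] += 1
    accuracy = float((predictions == truths).mean())
    return accuracy, confusion, labels


def _as_arrays(images) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(images, SpectralImageSet):
        X, y, _ = images.stack()
        return X, y
    X, y = images
    return np.asarray(X), np.asarray(y)


def _split_indices(
    y: np.ndarray, fraction: float, rng: np.random.Generator, stratify: bool
) -> tuple[np.ndarray, np.ndarray]:
    if stratify:
        parts_in, parts_out = [], []
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            k = int(fraction * len(idx))
            parts_in.append(idx[:k])
            parts_out.append(idx[k:])
        return np.sort(np.concatenate(parts_in)), np.sort(np.concatenate(parts_out))
    idx = rng.permutation(len(y))
    k = int(fraction * len(y))
    return np.sort(idx[:k]), np.sort(idx[k:])


def _default_estimator(seed: int) -> BaseEstimator:
    return CNNeegClassifier(random_state=seed)


def intra_subject_protocol(
    subject_images: Mapping,
    estimator: BaseEstimator | None = None,
    train_fraction: float = 0.70,
    seed: int = 0,
    required_classes: Sequence[str] | None = None,
) -> ProtocolResult:
    """Stratified 70/30 train/test evaluation within each subject."""
    rows = []
    confusions = {}
    for subject, images in subject_images.items():
        X, y = _as_arrays(images)
        classes = np.unique(y)
        if required_classes is not None:
            missing = [c for c in required_classes if c not in classes]
            if missing:
                raise ValueError(f"subject {subject!r} is missing class(es) {missing}")
        if len(classes) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 classes")
        key = zlib.crc32(str(subject).encode())  # stable across processes, unlike hash()
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
        tr, te = _split_indices(y, train_fraction, rng, stratify=True)
        assert not np.intersect1d(tr, te).size  # disjointness by construction
        est = clone(estimator) if estimator is not None else _default_estimator(seed)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        acc, confusion, labels = accuracy_and_confusion(pred, y[te], labels=sorted(classes.tolist()))
        rows.append({"subject": subject, "accuracy": acc, "n_train": len(tr), "n_test": len(te)})
        confusions[subject] = (labels, confusion)
    if not rows:
        raise ValueError("no subjects provided")
    return ProtocolResult("intra", pd.DataFrame(rows), confusions, seed)


def inter_subject_protocol(
    subject_images: Mapping,
    estimator: BaseEstimator | None = None,
    train_fraction: float = 0.70,
    test_fraction: float = 0.30,
    seed: int = 0,
) -> ProtocolResult:
    """Leave-one-subject-out evaluation across subjects.

    For each held-out subject: train on a random ``train_fraction`` of the
    pooled other-subject images, test on a random ``test_fraction`` of the
    held-out subject's images.
    """
    subjects = list(subject_images.keys())
    if len(subjects) < 2:
        raise ValueError("inter-subject protocol needs at least 2 subjects")
    data = {s: _as_arrays(images) for s, images in subject_images.items()}
    rows = []
    confusions = {}
    for fold, held_out in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(fold,)))
        X_pool = np.concatenate([data[s][0] for s in subjects if s != held_out])
        y_pool = np.concatenate([data[s][1] for s in subjects if s != held_out])
        tr, _ = _split_indices(y_pool, train_fraction, rng, stratify=False)
        X_te_all, y_te_all = data[held_out]
        if test_fraction < 1.0:
            te, _ = _split_indices(y_te_all, test_fraction, rng, stratify=False)
        else:
            te = np.arange(len(y_te_all))
        est = clone(estimator) if estimator is not None else _default_estimator(seed)
        est.fit(X_pool[tr], y_pool[tr])
        pred = est.predict(X_te_all[te])
        labels = sorted(set(np.unique(y_pool).tolist()) | set(np.unique(y_te_all).tolist()))
        acc, confusion, labels = accuracy_and_confusion(pred, y_te_all[te], labels=labels)
        rows.append({"subject": held_out, "accuracy": acc, "n_train": len(tr), "n_test": len(te)})
        confusions[held_out] = (labels, confusion)
    return ProtocolResult("inter", pd.DataFrame(rows), confusions, seed)
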