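"""One-vs-one ensemble of binary CNNs with majority-vote fusion.

Five vowel classes give C(5,2) = 10 binary classifiers, one per unordered
class pair; each is trained only on its two classes' images. At prediction
time every classifier casts one vote and the class with the largest tally
wins (each class appears in 4 pairs, so tallies sum to 10 and no tally can
exceed 4). Ties are broken by the larger summed softmax confidence across
the tied classes' classifiers, then by fixed label order.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .cnn import BinaryCNN

__all__ = ["CNNeegClassifier", "VoteResult", "vote_fuse"]


@dataclasses.dataclass
class VoteResult:
    """Fused decision for one input."""

    tally: dict[str, int]
    winner: str
    tie_broken: bool
    decisions: dict[tuple[str, str], str]
    confidences: dict[tuple[str, str], float]

    @property
    def votes(self) -> int:
        return sum(self.tally.values())


def vote_fuse(
    decisions: Mapping[tuple[str, str], str],
    confidences: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
    classes: Sequence[str] | None = None,
) -> VoteResult:
    """Fuse per-pair binary decisions into a multiclass winner.

    Parameters
    ----------
    decisions : mapping ``(class_a, class_b) -> predicted class`` with
        exactly one entry per unordered class pair.
    confidences : optional mapping ``pair -> {class: softmax probability}``
        used for tie-breaking; missing confidences fall back to label order.
    classes : expected class set; inferred from the pair keys if omitted.
    """
    if classes is None:
        classes = sorted({c for pair in decisions for c in pair})
    classes = list(classes)
    expected = {tuple(sorted(p)) for p in itertools.combinations(classes, 2)}
    seen = {tuple(sorted(p)) for p in decisions}
    if seen != expected:
        missing = expected - seen
        extra = seen - expected
        raise ValueError(f"pair set mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
    if len(decisions) != len(expected):
        raise ValueError("duplicate pair keys in decisions")

    tally = {c: 0 for c in classes}
    conf_by_class = {c: 0.0 for c in classes}
    for pair, winner in decisions.items():
        a, b = pair
        if winner not in (a, b):
            raise ValueError(f"decision {winner!r} is not a member of pair {pair}")
        tally[winner] += 1
        if confidences is not None:
            for c in pair:
                conf_by_class[c] += float(confidences[pair].get(c, 0.0))

    top = max(tally.values())
    leaders = [c for c in classes if tally[c] == top]
    tie_broken = len(leaders) > 1
    if tie_broken and confidences is not None:
        best = max(conf_by_class[c] for c in leaders)
        leaders = [c for c in leaders if conf_by_class[c] == best]
    winner = sorted(leaders)[0]
    return VoteResult(
        tally=tally,
        winner=winner,
        tie_broken=tie_broken,
        decisions=dict(decisions),
        confidences={p: float(confidences[p].get(winner, 0.0)) for p in decisions} if confidences else {},
    )


class CNNeegClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-one ensemble of :class:`BinaryCNN` models.

    ``fit`` trains one binary model per unordered class pair, each on its
    two classes' images only; ``predict`` runs all models and fuses their
    votes. Any scikit-learn binary classifier can be substituted through
    ``base_estimator`` (images are flattened for estimators that do not
    declare an ``input_shape`` parameter).
    """

    def __init__(
        self,
        base_estimator: BaseEstimator | None = None,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        epochs: int = 50,
        batch_size: int = 128,
        dropout_rate: float = 0.25,
        dropout_mode: str = "exact",
        adapt_narrow_input: bool = False,
        random_state: int = 0,
    ) -> None:
        self.base_estimator = base_estimator
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.dropout_mode = dropout_mode
        self.adapt_narrow_input = adapt_narrow_input
        self.random_state = random_state

    def _make_binary(self, pair_index: int) -> BaseEstimator:
        if self.base_estimator is not None:
            return clone(self.base_estimator)
        return BinaryCNN(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            epochs=self.epochs,
            batch_size=self.batch_size,
            train_fraction=1.0,  # splits are the caller's business
            dropout_rate=self.dropout_rate,
            dropout_mode=self.dropout_mode,
            adapt_narrow_input=self.adapt_narrow_input,
            random_state=self.random_state + 1000 * (pair_index + 1),
        )

    def _flattens(self, est: BaseEstimator) -> bool:
        return self.base_estimator is not None and "input_shape" not in est.get_params()

    def fit(self, X: np.ndarray, y: np.ndarray, classes: Sequence[str] | None = None) -> "CNNeegClassifier":
        X = np.asarray(X)
        y = np.asarray(y)
        present = set(np.unique(y).tolist())
        if classes is not None:
            missing = [c for c in classes if c not in present]
            if missing:
                raise ValueError(f"training data is missing class(es): {missing}")
            self.classes_ = np.asarray(sorted(classes))
        else:
            self.classes_ = np.asarray(sorted(present))
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")

        self.models_ = {}
        self.training_classes_ = {}
        for k, (a, b) in enumerate(itertools.combinations(self.classes_.tolist(), 2)):
            mask = (y == a) | (y == b)
            est = self._make_binary(k)
            Xp = X[mask].reshape(mask.sum(), -1) if self._flattens(est) else X[mask]
            est.fit(Xp, y[mask])
            self.models_[(a, b)] = est
            self.training_classes_[(a, b)] = (a, b)
        return self

    def predict_votes(self, X: np.ndarray) -> list[VoteResult]:
        """Full fused vote structure for every image in the batch."""
        X = np.asarray(X)
        n = len(X)
        per_pair: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for pair, est in self.models_.items():
            Xp = X.reshape(n, -1) if self._flattens(est) else X
            if hasattr(est, "predict_proba"):
                proba = np.asarray(est.predict_proba(Xp))
                pred = np.asarray(est.classes_)[proba.argmax(axis=1)]
            else:
                pred = np.asarray(est.predict(Xp))
                proba = None
            per_pair[pair] = (pred, proba, np.asarray(est.classes_))
        results = []
        for i in range(n):
            decisions = {pair: str(pred[i]) for pair, (pred, _p, _c) in per_pair.items()}
            confidences = {
                pair: (
                    {str(c): float(p[i, j]) for j, c in enumerate(cls)}
                    if p is not None
                    else {pair[0]: 0.0, pair[1]: 0.0}
                )
                for pair, (pred, p, cls) in per_pair.items()
            }
            results.append(vote_fuse(decisions, confidences, classes=self.classes_.tolist()))
        return results

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray([r.winner for r in self.predict_votes(X)])

    def pair_model(self, a: str, b: str) -> BaseEstimator:
        """The trained binary model for an unordered class pair."""
        key = tuple(sorted((a, b)))
        if key not in self.models_:
            raise KeyError(f"no model for pair {key}")
        return self.models_[key]
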