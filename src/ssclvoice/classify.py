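"""Prototype labeling and record-level classification.

Each prototype centroid from the competitive-learning stage is labeled by a
majority vote of its R nearest neighbors in the labeled training set, and
every record then inherits its prototype's label (the semi-supervised
propagation step).  A conventional K-nearest-neighbor record-level classifier
and a thin RBF-SVM adapter serve as supervised baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import ConfigError
from .sscl import SSCLModel

_WEIGHT_EPS = 1e-12  # neighbor weight 1 / (distance + eps)


@dataclass
class LabeledSet:
    """Training patterns with known class labels."""

    patterns: np.ndarray  # (P, L)
    labels: np.ndarray  # (P,) ints

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.patterns.shape[0]:
            raise ValueError("labels length does not match patterns")
        if len(self.labels) == 0:
            raise ValueError("labeled set is empty")

    @property
    def size(self) -> int:
        return self.patterns.shape[0]


@dataclass
class Prediction:
    record_labels: np.ndarray  # predicted class per record
    scores: np.ndarray  # positive-class support in [0, 1]
    centroid_labels: np.ndarray | None = None  # per prototype, SSCL only
    prototype_of: np.ndarray | None = None  # record -> prototype index


def nearest_labeled(
    sk: np.ndarray, training: LabeledSet, r: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The R training patterns closest to a query centroid.

    Returns (indices, labels, distances) sorted by increasing distance;
    distance ties are broken by stable training-set order.
    """
    if not 1 <= r <= training.size:
        raise ConfigError(f"R must satisfy 1 <= R <= P={training.size}, got {r}")
    d = cdist(np.atleast_2d(np.asarray(sk, dtype=float)), training.patterns)[0]
    order = np.argsort(d, kind="stable")[:r]
    return order, training.labels[order], d[order]


def vote_label(neighbor_labels: np.ndarray) -> int:
    """Majority vote over neighbor labels ordered by increasing distance.

    A tie between classes is resolved in favor of the tied class whose member
    appears first in the ordering (i.e. the single nearest neighbor among the
    tied classes).
    """
    labels = np.asarray(neighbor_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty neighbor list")
    classes, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    tied = set(classes[counts == best])
    if len(tied) == 1:
        return int(tied.pop())
    for lab in labels:  # first (nearest) occurrence among tied classes
        if lab in tied:
            return int(lab)
    raise AssertionError("unreachable")


def _positive_score(labels: np.ndarray, distances: np.ndarray, positive: int = 1) -> float:
    """Inverse-distance-weighted positive-class vote share in [0, 1]."""
    w = 1.0 / (np.asarray(distances, dtype=float) + _WEIGHT_EPS)
    return float(w[np.asarray(labels) == positive].sum() / w.sum())


def classify_prototypes(
    model: SSCLModel, training: LabeledSet, r: int, positive: int = 1
) -> Prediction:
    """Label every prototype centroid by R-NN vote and propagate to members."""
    k = model.k
    centroid_labels = np.empty(k, dtype=int)
    centroid_scores = np.empty(k, dtype=float)
    for j in range(k):
        _, labels, dists = nearest_labeled(model.centroids[j], training, r)
        centroid_labels[j] = vote_label(labels)
        centroid_scores[j] = _positive_score(labels, dists, positive)
    return Prediction(
        record_labels=centroid_labels[model.assignments],
        scores=centroid_scores[model.assignments],
        centroid_labels=centroid_labels,
        prototype_of=model.assignments.copy(),
    )


def knn_baseline(
    training: LabeledSet, test: np.ndarray, k: int = 7, positive: int = 1
) -> Prediction:
    """Record-level K-nearest-neighbor majority vote baseline.

    The score is the unweighted positive vote fraction among the K neighbors;
    ties in the vote follow the same nearest-among-tied-classes rule as the
    prototype classifier.
    """
    if not 1 <= k <= training.size:
        raise ConfigError(f"K must satisfy 1 <= K <= P={training.size}, got {k}")
    test = np.atleast_2d(np.asarray(test, dtype=float))
    d = cdist(test, training.patterns)
    labels_out = np.empty(len(test), dtype=int)
    scores = np.empty(len(test), dtype=float)
    for i in range(len(test)):
        order = np.argsort(d[i], kind="stable")[:k]
        neigh = training.labels[order]
        labels_out[i] = vote_label(neigh)
        scores[i] = float(np.mean(neigh == positive))
    return Prediction(record_labels=labels_out, scores=scores)


def svm_baseline(
    training: LabeledSet,
    test: np.ndarray,
    sigma: float = 4.0,
    positive: int = 1,
    rng_seed: int = 0,
) -> Prediction:
    """RBF-kernel SVM baseline (thin adapter around scikit-learn).

    The kernel spread sigma maps to sklearn's gamma = 1 / (2 sigma^2); scores
    are Platt-calibrated positive-class probabilities.
    """
    from sklearn.svm import SVC

    clf = SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma**2), probability=True,
              random_state=rng_seed)
    clf.fit(training.patterns, training.labels)
    test = np.atleast_2d(np.asarray(test, dtype=float))
    proba = clf.predict_proba(test)
    pos_col = list(clf.classes_).index(positive)
    return Prediction(
        record_labels=clf.predict(test).astype(int),
        scores=proba[:, pos_col],
    )
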