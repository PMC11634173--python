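"""Point classifier: inverse-distance-weighted K-nearest neighbours.

Each line coordinate is classified independently from its four normalised
milestone features. Training stores the points and reports 10-fold
cross-validated pixel-level accuracy, with folds grouped by line sample so
neighbouring points of one line never straddle a fold boundary.

The prediction rule is deterministic: Euclidean distances on the 4-feature
vectors, votes weighted by inverse distance (an exact feature match wins
outright), ties broken by the smallest mean neighbour distance and then by
the fixed class order good < expert < poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import accuracy_score
from sklearn.model_selection import GroupKFold

from .config import KNNConfig
from .containers import CLASSES, ContractError, Dataset, ICGFAError, LineSample

__all__ = ["PointModel", "TrainingError", "train_knn", "predict_knn"]


class TrainingError(ICGFAError):
    """Dataset unsuitable for training (missing class, k > n, ...)."""


@dataclass
class PointModel:
    """Trained weighted-KNN point classifier."""

    X: np.ndarray
    y: np.ndarray
    k: int
    weighting: str = "inverse-distance"
    cv_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.X):
            raise TrainingError(f"k={self.k} outside [1, {len(self.X)}]")


def _stack_points(samples: list[LineSample]):
    X = np.concatenate([s.features for s in samples])
    y = np.concatenate([s.labels for s in samples])
    groups = np.concatenate([
        np.full(len(s), i) for i, s in enumerate(samples)])
    return X, y, groups


def _vote(dists: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Inverse-distance-weighted vote, vectorised over query rows.

    ``dists`` is (n_query, n_train). A zero-distance neighbour dominates
    (its class wins; among several exact matches the tie rules apply).
    """
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    nd = np.take_along_axis(dists, order, axis=1)
    nl = labels[order]
    exact = nd <= 0.0
    with np.errstate(divide="ignore"):
        wts = np.where(exact, np.inf, 1.0 / np.where(exact, 1.0, nd))
    # rows with exact matches: those neighbours get weight 1, others 0
    has_exact = exact.any(axis=1)
    wts = np.where(has_exact[:, None], exact.astype(float), wts)

    n_classes = len(CLASSES)
    votes = np.zeros((len(dists), n_classes))
    mean_d = np.full((len(dists), n_classes), np.inf)
    for c in range(n_classes):
        m = nl == c
        votes[:, c] = np.where(m, wts, 0.0).sum(axis=1)
        cnt = m.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_d[:, c] = np.where(cnt > 0,
                                    np.where(m, nd, 0.0).sum(axis=1)
                                    / np.maximum(cnt, 1), np.inf)
    # lexicographic: max votes, then min mean distance, then class order
    best_votes = votes.max(axis=1, keepdims=True)
    tied = votes >= best_votes - 1e-12 * np.maximum(best_votes, 1.0)
    key = np.where(tied, mean_d, np.inf)
    best_key = key.min(axis=1, keepdims=True)
    tied &= key <= best_key + 1e-12
    return tied.argmax(axis=1)


def train_knn(dataset: Dataset, config: KNNConfig | None = None,
              seed: int = 0) -> PointModel:
    """Fit the point model and record grouped 10-fold CV accuracy.

    Folds are assigned by line sample (seeded shuffle of the sample order)
    so that all coordinates of one line share a fold.
    """
    config = config or KNNConfig()
    train = dataset.subset("train") or dataset.samples
    X, y, groups = _stack_points(train)
    if len(np.unique(y)) < len(CLASSES):
        raise TrainingError("all three classes must be present for training")
    if config.k > len(X):
        raise TrainingError(f"k={config.k} exceeds {len(X)} training points")
    n_groups = len(np.unique(groups))
    if n_groups < config.n_folds:
        raise TrainingError(
            f"{n_groups} line samples cannot fill {config.n_folds} folds")
    rng = np.random.default_rng(seed)
    remap = rng.permutation(n_groups)
    fold_accs = []
    for tr, te in GroupKFold(n_splits=config.n_folds).split(
            X, y, groups=remap[groups]):
        d = cdist(X[te], X[tr])
        pred = _vote(d, y[tr], min(config.k, len(tr)))
        fold_accs.append(accuracy_score(y[te], pred))
    report = {"fold_accuracy": [float(a) for a in fold_accs],
              "mean_accuracy": float(np.mean(fold_accs)),
              "n_folds": config.n_folds}
    return PointModel(X=X, y=y, k=config.k, cv_report=report)


def predict_knn(model: PointModel, sample: LineSample) -> np.ndarray:
    """Classify every coordinate of a line independently."""
    feats = np.asarray(sample.features, dtype=float)
    if feats.ndim != 2 or feats.shape[1] != model.X.shape[1]:
        raise ContractError("feature matrix must be (n, 4), normalised")
    if not np.isfinite(feats).all():
        raise ContractError("features contain NaN/inf; normalise first")
    d = cdist(feats, model.X)
    return _vote(d, model.y, model.k)
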