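"""Embedding-quality metrics.

Three complementary views of how well a low-dimensional representation
preserves a high-dimensional manifold: Pearson correlation between
geodesic distances computed in both spaces, DEMaP (Spearman rank
correlation between high-dimensional geodesics and low-dimensional
Euclidean distances), and k-NN classification accuracy of labels in the
representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier

from .outline import DistanceMatrix, geodesic_distances, pairwise_euclidean

__all__ = ["MetricReport", "pearson_geodesic", "demap", "knn_accuracy"]


class EvaluationError(ValueError):
    """Invalid input to a metric computation."""


@dataclass(frozen=True)
class MetricReport:
    """Collected metrics with the settings that produced them."""

    pearson_geodesic: float | None
    demap: float | None
    knn_accuracy: float | None
    k_graph: int = 10
    k_classifier: int = 5
    n_splits: int = 5
    seed: int = 0


def _geodesic_uppertri(X: np.ndarray, k_graph: int) -> np.ndarray:
    geo = geodesic_distances(pairwise_euclidean(X), k_graph=k_graph)
    iu = np.triu_indices(geo.n_points, k=1)
    return geo.d[iu]


def _check_pair(X_hd: np.ndarray, X_ld: np.ndarray) -> None:
    if len(X_hd) != len(X_ld):
        raise EvaluationError("sample counts differ between spaces")
    if len(X_hd) < 10:
        raise EvaluationError("need at least 10 samples for correlation metrics")


def pearson_geodesic(X_hd: np.ndarray, X_ld: np.ndarray, k_graph: int = 10) -> float:
    """Pearson correlation between geodesic distance vectors of the two spaces."""
    _check_pair(X_hd, X_ld)
    g_hd = _geodesic_uppertri(X_hd, k_graph)
    g_ld = _geodesic_uppertri(X_ld, k_graph)
    if np.ptp(g_hd) == 0 or np.ptp(g_ld) == 0:
        raise EvaluationError("constant distance vector; correlation undefined")
    return float(stats.pearsonr(g_hd, g_ld).statistic)


def demap(X_hd: np.ndarray, X_ld: np.ndarray, k_graph: int = 10) -> float:
    """Spearman correlation of high-dim geodesics vs low-dim Euclidean distances."""
    _check_pair(X_hd, X_ld)
    g_hd = _geodesic_uppertri(X_hd, k_graph)
    euc = pairwise_euclidean(X_ld)
    iu = np.triu_indices(euc.n_points, k=1)
    e_ld = euc.d[iu]
    if np.ptp(g_hd) == 0 or np.ptp(e_ld) == 0:
        raise EvaluationError("constant distance vector; correlation undefined")
    return float(stats.spearmanr(g_hd, e_ld).statistic)


def knn_accuracy(
    X_ld: np.ndarray,
    labels: np.ndarray,
    k_classifier: int = 5,
    reps: int = 5,
    seed: int = 0,
) -> float:
    """Mean k-NN accuracy over seeded stratified 70/30 train/test splits."""
    X_ld = np.asarray(X_ld, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise EvaluationError("need at least 2 classes")
    if counts.min() < k_classifier + 1:
        raise EvaluationError(
            f"smallest class has {counts.min()} members; "
            f"need at least k_classifier + 1 = {k_classifier + 1}"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=reps, train_size=0.7, test_size=0.3, random_state=seed
    )
    accs = []
    for train, test in splitter.split(X_ld, labels):
        clf = KNeighborsClassifier(n_neighbors=k_classifier)
        clf.fit(X_ld[train], labels[train])
        accs.append(clf.score(X_ld[test], labels[test]))
    return float(np.mean(accs))
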