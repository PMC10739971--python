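"""Manifold outline construction.

The outline orders samples along a one-dimensional sweep of the data
manifold: pairwise distances between label/output vectors are turned into
geodesic (shortest-path) distances over a k-nearest-neighbour graph, an
extremal endpoint is located, and the distances from that endpoint are
discretized into pseudo-label bins with a closed-form optimal histogram
width derived from a zero-mean folded-Gaussian model of the distance
density.  The normalized endpoint distance doubles as the color scale used
in visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import (
    connected_components,
    csgraph_from_dense,
    dijkstra,
    floyd_warshall,
)
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "OutlineModel",
    "pairwise_euclidean",
    "geodesic_distances",
    "find_endpoint",
    "folded_gaussian_sigma",
    "optimal_bin_width",
    "bin_by_endpoint_distance",
    "build_outline",
]

# Above this size the O(n^3) Floyd-Warshall pass is replaced by Dijkstra.
_FLOYD_WARSHALL_MAX_N = 1500


class OutlineError(ValueError):
    """Invalid input to an outline-construction step."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances.

    Attributes
    ----------
    d : ndarray of shape (n_points, n_points)
        Symmetric, nonnegative, zero diagonal.
    metric_tag : {"euclidean", "geodesic"}
        Whether entries are straight-line or graph shortest-path distances.
    """

    d: np.ndarray
    metric_tag: str

    @property
    def n_points(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class OutlineModel:
    """Result of the outline stage.

    Attributes
    ----------
    endpoint : int
        Index of the sample at one extreme of the manifold.
    dist_from_endpoint : ndarray of shape (n,)
        Manifold (geodesic) distance of every sample from the endpoint.
    sigma_hat : float
        Folded-Gaussian scale fitted to the pairwise distance sample.
    h_star : float
        Optimal histogram bin width.
    K : int
        Number of non-empty bins.
    pseudo_labels : ndarray of shape (n,), int
        Bin index of each sample, 1..K, increasing with endpoint distance.
    color : ndarray of shape (n,)
        dist_from_endpoint / max(dist_from_endpoint); in [0, 1].
    """

    endpoint: int
    dist_from_endpoint: np.ndarray
    sigma_hat: float
    h_star: float
    K: int
    pseudo_labels: np.ndarray
    color: np.ndarray


def _as_matrix(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise OutlineError(f"expected a 2-d sample matrix, got ndim={pts.ndim}")
    return pts


def pairwise_euclidean(points: np.ndarray) -> DistanceMatrix:
    """Euclidean distances between all pairs of rows of ``points``."""
    pts = _as_matrix(points)
    if pts.shape[0] < 2:
        raise OutlineError("need at least 2 samples for pairwise distances")
    if not np.isfinite(pts).all():
        raise OutlineError("non-finite values in input points")
    d = squareform(pdist(pts, metric="euclidean"))
    return DistanceMatrix(d=d, metric_tag="euclidean")


def _knn_graph(d: np.ndarray, k_graph: int) -> np.ndarray:
    """Symmetric k-NN graph as a dense weight matrix (inf = no edge)."""
    n = d.shape[0]
    w = np.full((n, n), np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    for i in range(n):
        neigh = [j for j in order[i] if j != i][:k_graph]
        w[i, neigh] = d[i, neigh]
    w = np.minimum(w, w.T)  # union of directed k-NN relations
    np.fill_diagonal(w, 0.0)
    return w


def _offdiag(w: np.ndarray) -> np.ndarray:
    """Diagonal set to inf (= no self edge) for csgraph_from_dense."""
    out = w.copy()
    np.fill_diagonal(out, np.inf)
    return out


def _bridge_components(w: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Connect components by repeatedly adding the single shortest bridge edge."""
    w = w.copy()
    while True:
        graph = csgraph_from_dense(_offdiag(w), null_value=np.inf)
        n_comp, labels = connected_components(graph, directed=False)
        if n_comp == 1:
            return w
        # minimal Euclidean edge between any two distinct components
        cross = labels[:, None] != labels[None, :]
        dd = np.where(cross, d, np.inf)
        i, j = np.unravel_index(np.argmin(dd), dd.shape)
        w[i, j] = w[j, i] = d[i, j]


def geodesic_distances(D: DistanceMatrix, k_graph: int = 10) -> DistanceMatrix:
    """Graph shortest-path distances over a symmetric k-NN graph.

    Edges are weighted by the input (Euclidean) distance; disconnected
    components are bridged by their minimal connecting edge so every
    geodesic is finite.
    """
    n = D.n_points
    if n < 2:
        raise OutlineError("need at least 2 points for geodesic distances")
    if not (1 <= k_graph < n):
        raise OutlineError(f"k_graph must be in [1, {n - 1}], got {k_graph}")
    w = _knn_graph(D.d, k_graph)
    w = _bridge_components(w, D.d)
    # null_value=inf keeps explicit zero-weight edges (duplicate points)
    graph = csgraph_from_dense(_offdiag(w), null_value=np.inf)
    if n <= _FLOYD_WARSHALL_MAX_N:
        g = floyd_warshall(graph, directed=False)
    else:
        g = dijkstra(graph, directed=False)
    return DistanceMatrix(d=g, metric_tag="geodesic")


def find_endpoint(G: DistanceMatrix) -> int:
    """Index of the point maximizing total geodesic distance to all others.

    Ties are broken toward the lowest index.
    """
    if not np.isfinite(G.d).all():
        raise OutlineError("geodesic matrix contains non-finite entries")
    return int(np.argmax(G.d.sum(axis=1)))


def folded_gaussian_sigma(dists: np.ndarray) -> float:
    """Maximum-likelihood scale of a zero-mean folded Gaussian, sqrt(mean d^2)."""
    d = np.asarray(dists, dtype=float).ravel()
    if d.size == 0:
        raise OutlineError("empty distance sample")
    if (d < 0).any() or not np.isfinite(d).all():
        raise OutlineError("distances must be finite and nonnegative")
    return float(np.sqrt(np.mean(d**2)))


def optimal_bin_width(sigma_hat: float, m: int) -> float:
    """Closed-form optimal histogram bin width for folded-Gaussian distances.

    h* = 12^(1/3) * pi^(1/6) * sigma * ((m^2 - m)/2)^(-1/3), where the pair
    count (m^2 - m)/2 is the size of the pairwise-distance sample whose
    density the folded Gaussian models.
    """
    if m < 2:
        raise OutlineError(f"need m >= 2 samples, got {m}")
    if sigma_hat < 0:
        raise OutlineError("sigma_hat must be nonnegative")
    pairs = (m * m - m) / 2.0
    return float(12.0 ** (1.0 / 3.0) * np.pi ** (1.0 / 6.0) * sigma_hat * pairs ** (-1.0 / 3.0))


def bin_by_endpoint_distance(
    dist_from_endpoint: np.ndarray, h_star: float
) -> tuple[np.ndarray, int]:
    """Histogram endpoint distances into equal-width bins of width ``h_star``.

    Bins span [min, max]; empty bins are dropped and the survivors are
    renumbered 1..K in order of increasing distance.  A zero width or a
    constant input collapses to a single bin.
    """
    d = np.asarray(dist_from_endpoint, dtype=float).ravel()
    if h_star < 0:
        raise OutlineError("h_star must be nonnegative")
    lo, hi = float(d.min()), float(d.max())
    if h_star == 0.0 or hi == lo:
        return np.ones(d.size, dtype=int), 1
    raw = np.floor((d - lo) / h_star).astype(int)
    n_raw = int(np.ceil((hi - lo) / h_star))
    raw = np.clip(raw, 0, n_raw - 1)  # the max lands on the last edge
    occupied = np.unique(raw)
    relabel = {b: i + 1 for i, b in enumerate(occupied)}
    labels = np.array([relabel[b] for b in raw], dtype=int)
    return labels, int(occupied.size)


def build_outline(
    source: np.ndarray, mode: str = "targets", k_graph: int = 10
) -> OutlineModel:
    """Compose the full outline: distances, geodesics, endpoint, bins, colors.

    Parameters
    ----------
    source : ndarray (n_samples, n_dims) or (n_samples,)
        Target vectors, network outputs, or raw features depending on mode.
    mode : {"targets", "outputs", "inputs"}
        Recorded provenance of the source matrix; the computation is the
        same for all three.
    k_graph : int
        Neighbour count for the geodesic graph.

    Notes
    -----
    One-dimensional scalar sources lie on a line manifold: distances reduce
    to absolute differences and the graph step is skipped.
    """
    if mode not in ("targets", "outputs", "inputs"):
        raise OutlineError(f"unknown outline mode {mode!r}")
    pts = _as_matrix(source)
    n = pts.shape[0]
    if n < 3:
        raise OutlineError("need at least 3 samples to build an outline")
    if pts.shape[1] == 1:
        # line manifold: geodesic along the line equals |difference|
        euc = pairwise_euclidean(pts)
        geo = DistanceMatrix(d=euc.d, metric_tag="geodesic")
    else:
        euc = pairwise_euclidean(pts)
        geo = geodesic_distances(euc, k_graph=min(k_graph, n - 1))
    endpoint = find_endpoint(geo)
    dist = geo.d[endpoint].copy()
    iu = np.triu_indices(n, k=1)
    sigma_hat = folded_gaussian_sigma(geo.d[iu])
    h_star = optimal_bin_width(sigma_hat, n)
    labels, K = bin_by_endpoint_distance(dist, h_star)
    dmax = dist.max()
    color = dist / dmax if dmax > 0 else np.zeros_like(dist)
    return OutlineModel(
        endpoint=endpoint,
        dist_from_endpoint=dist,
        sigma_hat=sigma_hat,
        h_star=h_star,
        K=K,
        pseudo_labels=labels,
        color=color,
    )
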