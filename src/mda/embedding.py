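"""Parametric 2-D embedding of the projected data.

A fuzzy neighbourhood graph is built over the projected matrix U: each
point's edge probabilities to its k nearest neighbours are locally scaled
(shift by the nearest-neighbour distance rho_i, bandwidth sigma_i
calibrated so the smoothed neighbour count is log2 k) and symmetrized by
probabilistic union.  A single affine layer mapping R-dim points to the
plane is then trained with Adam against the cross-entropy between the
graph probabilities and a heavy-tailed low-dimensional kernel
q_ij = (1 + a |v_i - v_j|^(2b))^-1.

For n <= 2000 the exact loss over all point pairs is optimized; larger
inputs use an unbiased negative-sampling estimator of the repulsive term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EmbeddingConfig",
    "FuzzyGraph",
    "EmbeddingModel",
    "calibrate_bandwidths",
    "directed_probabilities",
    "symmetrize",
    "build_fuzzy_graph",
    "low_dim_probability",
    "cross_entropy",
    "fit_embedding",
]

_Q_CLAMP = 1e-12
_SIGMA_FLOOR = 1e-10
_EXACT_MAX_N = 2000


class EmbeddingError(ValueError):
    """Invalid input or failed optimization in the embedding stage."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Kernel shape, graph size and optimizer settings (defaults as used
    throughout: a = b = 1, k = 30, Adam at lr 0.001, 2-D output)."""

    a: float = 1.0
    b: float = 1.0
    k: int = 30
    lr: float = 0.001
    epochs: int = 200
    neg_samples: int = 5
    seed: int = 0
    L: int = 2


@dataclass(frozen=True)
class FuzzyGraph:
    """Locally-scaled neighbourhood graph over the projected points."""

    knn_edges: np.ndarray  # (E, 2) directed (i, j)
    rho: np.ndarray
    sigma: np.ndarray
    p_dir: sparse.csr_matrix
    p_sym: sparse.csr_matrix


@dataclass(frozen=True)
class EmbeddingModel:
    """Affine map from the R-dim projected space to L-dim coordinates."""

    map_W: np.ndarray  # L x R
    map_b: np.ndarray  # L
    V: np.ndarray  # n x L
    loss_history: np.ndarray = field(default=None, repr=False)

    def map(self, U: np.ndarray) -> np.ndarray:
        return np.asarray(U, dtype=float) @ self.map_W.T + self.map_b


def _knn(U: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k nearest neighbours (self excluded)."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(U)
    dist, idx = nn.kneighbors(U)
    return idx[:, 1:], dist[:, 1:]


def calibrate_bandwidths(U: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-point local connectivity rho and bandwidth sigma.

    rho_i is the distance to the nearest neighbour; sigma_i solves

        sum_{j in kNN(i)} exp(-max(0, d_ij - rho_i) / sigma_i) = log2(k)

    by bisection.  When every neighbour sits at distance rho_i the sum is k
    for any sigma, so sigma_i is set to a small floor.
    """
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    if not (2 <= k < n):
        raise EmbeddingError(f"need 2 <= k < n; got k={k}, n={n}")
    _, dist = _knn(U, k)
    rho = dist[:, 0].copy()
    target = np.log2(k)
    sigma = np.empty(n)
    for i in range(n):
        gaps = np.maximum(0.0, dist[i] - rho[i])
        if gaps.max() <= 0.0:
            sigma[i] = _SIGMA_FLOOR
            continue
        lo, hi = 1e-12, 1.0
        # grow hi until the smoothed count exceeds the target
        while np.exp(-gaps / hi).sum() < target and hi < 1e12:
            hi *= 2.0
        for _ in range(100):
            mid = (lo + hi) / 2.0
            if np.exp(-gaps / mid).sum() >= target:
                hi = mid
            else:
                lo = mid
        sigma[i] = max(hi, _SIGMA_FLOOR)
    return rho, sigma


def directed_probabilities(
    U: np.ndarray,
    rho: np.ndarray,
    sigma: np.ndarray,
    knn_edges: np.ndarray,
) -> sparse.csr_matrix:
    """Edge probabilities p_{j|i} = exp(-max(0, d - rho_i)/sigma_i) on k-NN edges."""
    U = np.asarray(U, dtype=float)
    i, j = knn_edges[:, 0], knn_edges[:, 1]
    d = np.linalg.norm(U[i] - U[j], axis=1)
    p = np.exp(-np.maximum(0.0, d - rho[i]) / sigma[i])
    return sparse.csr_matrix((p, (i, j)), shape=(U.shape[0], U.shape[0]))


def symmetrize(p_dir: sparse.csr_matrix) -> sparse.csr_matrix:
    """Probabilistic union p_ij = p_{j|i} + p_{i|j} - p_{j|i} p_{i|j}."""
    pt = p_dir.T.tocsr()
    p_sym = p_dir + pt - p_dir.multiply(pt)
    return p_sym.tocsr()


def build_fuzzy_graph(U: np.ndarray, k: int) -> FuzzyGraph:
    """Full fuzzy-graph construction: kNN, bandwidths, directed + union probabilities."""
    U = np.asarray(U, dtype=float)
    idx, _ = _knn(U, k)
    n = U.shape[0]
    edges = np.column_stack(
        [np.repeat(np.arange(n), k), idx.ravel()]
    )
    rho, sigma = calibrate_bandwidths(U, k)
    p_dir = directed_probabilities(U, rho, sigma, edges)
    return FuzzyGraph(
        knn_edges=edges, rho=rho, sigma=sigma, p_dir=p_dir, p_sym=symmetrize(p_dir)
    )


def low_dim_probability(v_i: np.ndarray, v_j: np.ndarray, a: float = 1.0, b: float = 1.0):
    """Heavy-tailed kernel q_ij = (1 + a |v_i - v_j|^(2b))^-1."""
    d2 = np.sum((np.asarray(v_i, float) - np.asarray(v_j, float)) ** 2, axis=-1)
    return 1.0 / (1.0 + a * d2**b)


def cross_entropy(p_sym, q: np.ndarray) -> float:
    """Cross entropy sum_{i != j} p log(p/q) + (1-p) log((1-p)/(1-q)).

    ``q`` is clamped into the open unit interval; 0 log 0 terms vanish.
    """
    p = np.asarray(p_sym.todense() if sparse.issparse(p_sym) else p_sym, dtype=float)
    q = np.clip(np.asarray(q, dtype=float), _Q_CLAMP, 1.0 - _Q_CLAMP)
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    p = p[off]
    q = q[off]
    with np.errstate(divide="ignore", invalid="ignore"):
        att = np.where(p > 0, p * np.log(p / q), 0.0)
        rep = np.where(p < 1, (1 - p) * np.log((1 - p) / (1 - q)), 0.0)
    return float(att.sum() + rep.sum())


def _pairwise_sq(V: np.ndarray) -> np.ndarray:
    g = V @ V.T
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2 * g
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _loss_grad_exact(V: np.ndarray, P: np.ndarray, a: float, b: float):
    """Exact full-pair loss and its gradient with respect to V."""
    n = V.shape[0]
    d2 = _pairwise_sq(V)
    d2s = np.maximum(d2, 1e-12)
    denom = 1.0 + a * d2s**b
    q = np.clip(1.0 / denom, _Q_CLAMP, 1.0 - _Q_CLAMP)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        att = np.where(P > 0, P * np.log(np.maximum(P, _Q_CLAMP) / q), 0.0)
        rep = np.where(P < 1, (1 - P) * np.log((1 - P) / (1 - q)), 0.0)
    loss = float(att[off].sum() + rep[off].sum())
    # d loss / d d2 for each ordered pair
    g = P * a * b * d2s ** (b - 1.0) / denom - (1.0 - P) * b / (d2s * denom)
    np.fill_diagonal(g, 0.0)
    grad_V = 4.0 * (g.sum(axis=1)[:, None] * V - g @ V)
    return loss, grad_V


def _loss_grad_sampled(
    V: np.ndarray,
    edges: np.ndarray,
    p_edge: np.ndarray,
    edge_set: sparse.csr_matrix,
    a: float,
    b: float,
    neg_samples: int,
    rng: np.random.Generator,
):
    """On-edge terms exact; off-edge repulsion by uniform pair sampling.

    The estimator is unbiased for the exact loss: sampled ordered pairs are
    uniform over all n(n-1) pairs, pairs that happen to be graph edges
    contribute zero (their term is already counted exactly), and the sum is
    rescaled by n(n-1)/S.
    """
    n = V.shape[0]
    i, j = edges[:, 0], edges[:, 1]
    diff = V[i] - V[j]
    d2 = np.maximum((diff**2).sum(axis=1), 1e-12)
    denom = 1.0 + a * d2**b
    q = np.clip(1.0 / denom, _Q_CLAMP, 1.0 - _Q_CLAMP)
    p = p_edge
    with np.errstate(divide="ignore", invalid="ignore"):
        att = np.where(p > 0, p * np.log(np.maximum(p, _Q_CLAMP) / q), 0.0)
        rep = np.where(p < 1, (1 - p) * np.log((1 - p) / (1 - q)), 0.0)
    loss = float(att.sum() + rep.sum())
    g = p * a * b * d2 ** (b - 1.0) / denom - (1.0 - p) * b / (d2 * denom)
    grad_V = np.zeros_like(V)
    contrib = 2.0 * g[:, None] * diff
    np.add.at(grad_V, i, contrib)
    np.add.at(grad_V, j, -contrib)

    S = edges.shape[0] * neg_samples
    si = rng.integers(0, n, size=S)
    sj = rng.integers(0, n - 1, size=S)
    sj = np.where(sj >= si, sj + 1, sj)  # uniform over ordered pairs i != j
    on_edge = np.asarray(edge_set[si, sj]).ravel() > 0
    diff_s = V[si] - V[sj]
    d2s = np.maximum((diff_s**2).sum(axis=1), 1e-12)
    denom_s = 1.0 + a * d2s**b
    q_s = np.clip(1.0 / denom_s, _Q_CLAMP, 1.0 - _Q_CLAMP)
    term = np.where(on_edge, 0.0, -np.log(1.0 - q_s))
    scale = n * (n - 1) / S
    loss += float(scale * term.sum())
    g_s = np.where(on_edge, 0.0, -b / (d2s * denom_s)) * scale
    contrib_s = 2.0 * g_s[:, None] * diff_s
    np.add.at(grad_V, si, contrib_s)
    np.add.at(grad_V, sj, -contrib_s)
    return loss, grad_V


def _pca_init(U: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Affine init from the top-L principal directions, scaled to unit spread."""
    mean = U.mean(axis=0)
    Uc = U - mean
    _, s, vt = np.linalg.svd(Uc, full_matrices=False)
    W = vt[:L]  # L x R
    V0 = Uc @ W.T
    spread = V0.std()
    scale = 1.0 / spread if spread > 0 else 1.0
    W = W * scale
    bmap = -(W @ mean)
    return W, bmap


def fit_embedding(
    U: np.ndarray,
    graph: FuzzyGraph,
    config: EmbeddingConfig | None = None,
) -> EmbeddingModel:
    """Optimize the affine embedding map against the cross-entropy loss.

    Uses Adam; the exact all-pairs loss for n <= 2000, otherwise the
    negative-sampling estimator.  Deterministic given ``config.seed``.
    """
    config = config or EmbeddingConfig()
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    rng = np.random.default_rng(config.seed)
    W, bmap = _pca_init(U, config.L)

    exact = n <= _EXACT_MAX_N
    if exact:
        P = np.asarray(graph.p_sym.todense(), dtype=float)
        np.fill_diagonal(P, 0.0)
    else:
        coo = sparse.triu(graph.p_sym, k=1).tocoo()
        und_edges = np.column_stack([coo.row, coo.col])
        # both orientations so the exact on-edge part covers ordered pairs
        edges = np.vstack([und_edges, und_edges[:, ::-1]])
        p_edge = np.concatenate([coo.data, coo.data])
        edge_set = (graph.p_sym + graph.p_sym.T).tocsr()

    # Adam state
    mW = np.zeros_like(W)
    vW = np.zeros_like(W)
    mb = np.zeros_like(bmap)
    vb = np.zeros_like(bmap)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses = np.empty(config.epochs)

    for t in range(1, config.epochs + 1):
        V = U @ W.T + bmap
        if exact:
            loss, grad_V = _loss_grad_exact(V, P, config.a, config.b)
        else:
            loss, grad_V = _loss_grad_sampled(
                V, edges, p_edge, edge_set, config.a, config.b,
                config.neg_samples, rng,
            )
        if not np.isfinite(loss):
            raise EmbeddingError(
                f"non-finite loss at epoch {t}; last finite losses: "
                f"{losses[max(0, t - 4):t - 1]}"
            )
        losses[t - 1] = loss
        gW = grad_V.T @ U
        gb = grad_V.sum(axis=0)
        mW = beta1 * mW + (1 - beta1) * gW
        vW = beta2 * vW + (1 - beta2) * gW**2
        mb = beta1 * mb + (1 - beta1) * gb
        vb = beta2 * vb + (1 - beta2) * gb**2
        bc1 = 1 - beta1**t
        bc2 = 1 - beta2**t
        W = W - config.lr * (mW / bc1) / (np.sqrt(vW / bc2) + eps)
        bmap = bmap - config.lr * (mb / bc1) / (np.sqrt(vb / bc2) + eps)

    V = U @ W.T + bmap
    return EmbeddingModel(map_W=W, map_b=bmap, V=V, loss_history=losses)
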