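import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def knn_graph_oracle(D: np.ndarray, k: int) -> np.ndarray:
    """Brute-force symmetric k-NN graph with minimal-bridge connection.

    Independent double-loop construction used as the reference for the
    package's graph builder: directed k-NN relations from a full argsort,
    union-symmetrized, then disconnected components joined by their single
    shortest Euclidean bridge edge.
    """
    n = D.shape[0]
    w = np.full((n, n), np.inf)
    for i in range(n):
        order = [j for j in np.argsort(D[i], kind="stable") if j != i]
        for j in order[:k]:
            w[i, j] = D[i, j]
    for i in range(n):
        for j in range(n):
            w[i, j] = min(w[i, j], w[j, i])
        w[i, i] = 0.0

    def components(w):
        seen = [False] * n
        comps = []
        for s in range(n):
            if seen[s]:
                continue
            stack, comp = [s], []
            seen[s] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in range(n):
                    if not seen[v] and np.isfinite(w[u, v]) and u != v:
                        seen[v] = True
                        stack.append(v)
            comps.append(comp)
        return comps

    while True:
        comps = components(w)
        if len(comps) == 1:
            return w
        best = (np.inf, None, None)
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                for i in comps[a]:
                    for j in comps[b]:
                        if D[i, j] < best[0]:
                            best = (D[i, j], i, j)
        _, i, j = best
        w[i, j] = w[j, i] = D[i, j]


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the textbook Floyd-Warshall recurrence."""
    d = w.copy()
    n = d.shape[0]
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d
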