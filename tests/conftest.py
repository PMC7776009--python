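"""Shared fixtures and independent brute-force oracles for graph quantities.

The oracle implementations below deliberately avoid the package's own code
paths (and scipy's graph routines): distances come from a hand-rolled
Dijkstra, clustering from explicit triangle enumeration, and betweenness
from exhaustive shortest-path counting, so they can serve as independent
references on small graphs.
"""

import heapq
import itertools

import numpy as np
import pytest

from morphnet import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# brute-force oracles

def oracle_dijkstra(adj: np.ndarray, source: int) -> np.ndarray:
    """Single-source shortest distances with edge length 1/weight."""
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in range(n):
            if adj[u, v] > 0:
                nd = d + 1.0 / adj[u, v]
                if nd < dist[v] - 1e-15:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
    return dist


def oracle_distances(adj: np.ndarray) -> np.ndarray:
    return np.vstack([oracle_dijkstra(adj, s) for s in range(adj.shape[0])])


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = oracle_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def oracle_clustering(adj: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by explicit triangle enumeration."""
    n = adj.shape[0]
    w_hat = adj / adj.max()
    out = np.zeros(n)
    for i in range(n):
        nb = [v for v in range(n) if adj[i, v] > 0]
        k = len(nb)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.permutations(nb, 2):
            if adj[j, h] > 0:
                total += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        out[i] = total / (k * (k - 1))
    return out


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    terms = np.zeros(n)
    for i in range(n):
        nb = [v for v in range(n) if adj[i, v] > 0]
        if len(nb) >= 2:
            terms[i] = oracle_global_efficiency(adj[np.ix_(nb, nb)])
    return float(terms.mean())


def _all_shortest_paths(adj, s, t):
    """All minimal-length simple paths s->t by exhaustive enumeration."""
    n = adj.shape[0]
    best = [np.inf]
    paths = []

    def extend(path, length):
        u = path[-1]
        if length > best[0] + 1e-12:
            return
        if u == t:
            if length < best[0] - 1e-12:
                best[0] = length
                paths.clear()
            if abs(length - best[0]) <= 1e-12:
                paths.append(list(path))
            return
        for v in range(n):
            if adj[u, v] > 0 and v not in path:
                path.append(v)
                extend(path, length + 1.0 / adj[u, v])
                path.pop()

    extend([s], 0.0)
    return paths


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalised Freeman betweenness by exhaustive path counting."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def random_weighted_graph(n: int, p: float, seed: int) -> np.ndarray:
    """Random symmetric weighted adjacency with distinct positive weights."""
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = rng.uniform(0.1, 1.0)
    # guarantee at least a spanning path so the graph has edges
    for i in range(n - 1):
        if adj[i, i + 1] == 0:
            adj[i, i + 1] = adj[i + 1, i] = rng.uniform(0.1, 1.0)
    return adj


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_cohort():
    """12-region, 5+5-subject null cohort shared across tests."""
    spec = CohortSpec(
        n_group_a=5, n_group_b=5, n_regions=12,
        voxels_per_region=(60, 120), seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a strong planted effect on regions 1-4."""
    spec = CohortSpec(
        n_group_a=8, n_group_b=8, n_regions=12,
        voxels_per_region=(80, 140),
        effect_nodes=(1, 2, 3, 4), effect_size=3.0, seed=23,
    )
    return generate_cohort(spec)
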