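"""Sparsity thresholding, weighted graph metrics and AUC summarisation.

A similarity matrix is reduced to a weighted graph by keeping the fraction
``S`` of strongest edges (the sparsity).  At every threshold of the sparsity
grid (default 0.10..0.34 in steps of 0.01) the following are computed:

* global: clustering coefficient ``Cp`` (Onnela weighted variant, weights
  rescaled by the graph maximum), characteristic path length ``Lp``
  (harmonic-mean convention, ``Lp = 1 / Eglob``), global efficiency
  ``Eglob`` (mean inverse shortest-path distance, edge distance
  ``d = 1/weight``, unreachable pairs contribute 0), local efficiency
  ``Eloc`` (mean over nodes of the global efficiency of the neighbour-induced
  subgraph), and the small-world indices ``gamma = Cp/<Cp_null>``,
  ``lambda = Lp/<Lp_null>``, ``sigma = gamma/lambda`` against an ensemble of
  degree-preserving rewired null graphs;
* nodal: degree, efficiency (mean inverse distance to all other nodes) and
  unnormalised Freeman betweenness on the same distances.

Each metric's curve over the grid is summarised by its trapezoidal area
under the curve (AUC).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import SimilarityMatrix

GLOBAL_METRICS = ("cp", "lp", "gamma", "lambda", "sigma", "eloc", "eglob")
NODAL_METRICS = ("degree", "efficiency", "betweenness")

DEFAULT_N_RAND = 100


class GraphMetricError(ValueError):
    """Base class for graph-metric errors."""


class EmptyGraphError(GraphMetricError):
    pass


class RewireError(GraphMetricError):
    pass


class DegenerateNullError(GraphMetricError):
    pass


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity thresholds, each in (0, 1)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or np.any(v <= 0) or np.any(v >= 1):
            raise GraphMetricError("sparsity values must lie in (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise GraphMetricError("sparsity values must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def from_range(
        cls, s_min: float = 0.10, s_max: float = 0.34, step: float = 0.01
    ) -> "SparsityGrid":
        """Inclusive-endpoint grid; the default yields the 25 thresholds
        0.10, 0.11, ..., 0.34."""
        n = int(round((s_max - s_min) / step)) + 1
        return cls(tuple(s_min + i * step for i in range(n)))

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass
class ThresholdedGraph:
    """Weighted graph retained at one sparsity level (dense adjacency)."""

    adjacency: np.ndarray
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int((np.triu(self.adjacency) > 0).sum())

    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        """(E x 2 node-index array, E weight array), i < j row-major order."""
        i, j = np.nonzero(np.triu(self.adjacency))
        return np.column_stack([i, j]), self.adjacency[i, j]


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    eglob: float
    eloc: float
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


@dataclass
class AUCRecord:
    """A metric curve over the sparsity grid and its trapezoidal AUC.

    ``values`` has shape (T,) for a global metric or (T, R) for a nodal one;
    ``auc`` is the matching scalar or length-R vector.
    """

    metric: str
    thresholds: np.ndarray
    values: np.ndarray
    auc: np.ndarray | float = field(init=False)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        auc = np.trapezoid(self.values, self.thresholds, axis=0)
        self.auc = float(auc) if np.ndim(auc) == 0 else auc


def _as_values(matrix) -> np.ndarray:
    if isinstance(matrix, SimilarityMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def threshold_by_sparsity(matrix, s: float) -> ThresholdedGraph:
    """Keep the ``floor(s * R(R-1)/2)`` strongest off-diagonal edges.

    Ties are broken by ascending (i, j) lexicographic order so the result is
    deterministic; the diagonal is never considered.
    """
    values = _as_values(matrix)
    r = values.shape[0]
    if not 0 < s < 1:
        raise GraphMetricError(f"sparsity {s} outside (0, 1)")
    k = int(np.floor(s * r * (r - 1) / 2))
    if k == 0:
        raise EmptyGraphError(f"sparsity {s} retains no edges for R={r}")
    iu, ju = np.triu_indices(r, 1)
    w = values[iu, ju]
    # primary: weight descending; then i, then j ascending
    order = np.lexsort((ju, iu, -w))[:k]
    adj = np.zeros((r, r))
    adj[iu[order], ju[order]] = w[order]
    return ThresholdedGraph(adjacency=adj + adj.T, sparsity=float(s))


# ---------------------------------------------------------------------------
# metric primitives (dense numpy / scipy implementations)

def _onnela_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node Onnela weighted clustering, weights rescaled by the max."""
    w_max = adj.max()
    if w_max <= 0:
        return np.zeros(adj.shape[0])
    w3 = np.cbrt(adj / w_max)
    triangles = np.einsum("ij,jk,ki->i", w3, w3, w3)
    k = (adj > 0).sum(axis=1)
    denom = k * (k - 1)
    return np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge distance 1/weight."""
    with np.errstate(divide="ignore"):
        d = np.where(adj > 0, 1.0 / adj, 0.0)
    return shortest_path(csr_matrix(d), method="D", directed=False)


def _inverse_distances(sp: np.ndarray) -> np.ndarray:
    """1/d with zeros on the diagonal and for unreachable pairs."""
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
    return inv


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    inv = _inverse_distances(_distance_matrix(adj))
    return float(inv[np.triu_indices(n, 1)].mean())


def global_metrics(g: ThresholdedGraph) -> GlobalMetrics:
    """Cp, Lp, Eglob and Eloc of a thresholded weighted graph."""
    adj = g.adjacency
    if g.n_edges == 0:
        raise EmptyGraphError("graph has no edges")
    cp = float(_onnela_clustering(adj).mean())
    eglob = _global_efficiency(adj)
    lp = float(1.0 / eglob) if eglob > 0 else float("inf")
    eloc_terms = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nb = np.nonzero(adj[i])[0]
        if nb.size >= 2:
            eloc_terms[i] = _global_efficiency(adj[np.ix_(nb, nb)])
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, eloc=float(eloc_terms.mean()))


def nodal_metrics(g: ThresholdedGraph, degree_mode: str = "binary") -> NodalMetrics:
    """Per-node degree, efficiency and unnormalised weighted betweenness.

    ``degree_mode`` selects the incident-edge count (``binary``, default) or
    the summed incident weight (``weight``).
    """
    adj = g.adjacency
    if g.n_edges == 0:
        raise EmptyGraphError("graph has no edges")
    if degree_mode == "binary":
        degree = (adj > 0).sum(axis=1).astype(float)
    elif degree_mode == "weight":
        degree = adj.sum(axis=1)
    else:
        raise GraphMetricError(f"unknown degree_mode {degree_mode!r}")
    inv = _inverse_distances(_distance_matrix(adj))
    efficiency = inv.sum(axis=1) / (g.n_nodes - 1)
    edges, weights = g.edge_list()
    graph = ig.Graph(n=g.n_nodes, edges=[tuple(e) for e in edges])
    betweenness = np.asarray(
        graph.betweenness(weights=(1.0 / weights).tolist()), dtype=float
    )
    return NodalMetrics(degree=degree, efficiency=efficiency, betweenness=betweenness)


# ---------------------------------------------------------------------------
# degree-preserving null ensemble and small-world indices

#: Attempted Maslov-Sneppen double-edge swaps per null graph, as a multiple
#: of the edge count.
REWIRE_SWAPS_PER_EDGE = 10


def random_null_ensemble(
    g: ThresholdedGraph, n_rand: int, seed: int
) -> list[ThresholdedGraph]:
    """Degree-matched rewired null graphs with reshuffled weights.

    Each null applies ``10 * |E|`` attempted double-edge swaps (which exactly
    preserve the degree sequence) and then reassigns the original weight
    multiset to the rewired edges in random order.  Fully deterministic for a
    fixed seed.
    """
    edges, weights = g.edge_list()
    if edges.shape[0] < 2:
        raise RewireError("need >= 2 edges to rewire")
    base = ig.Graph(n=g.n_nodes, edges=[tuple(e) for e in edges])
    nulls = []
    for child in np.random.SeedSequence(seed).spawn(n_rand):
        state = child.generate_state(2)
        ig.set_random_number_generator(random.Random(int(state[0])))
        gi = base.copy()
        gi.rewire(n=REWIRE_SWAPS_PER_EDGE * edges.shape[0])
        new_edges = np.asarray(gi.get_edgelist())
        perm = np.random.default_rng(int(state[1])).permutation(weights)
        adj = np.zeros_like(g.adjacency)
        adj[new_edges[:, 0], new_edges[:, 1]] = perm
        nulls.append(ThresholdedGraph(adjacency=adj + adj.T, sparsity=g.sparsity))
    return nulls


def small_world_indices(
    g: ThresholdedGraph, nulls: list[ThresholdedGraph]
) -> tuple[float, float, float]:
    """gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda."""
    if not nulls:
        raise DegenerateNullError("null ensemble is empty")
    gm = global_metrics(g)
    null_cp = np.array([float(_onnela_clustering(n.adjacency).mean()) for n in nulls])
    null_eglob = np.array([_global_efficiency(n.adjacency) for n in nulls])
    if null_cp.mean() <= 0 or np.any(null_eglob <= 0):
        raise DegenerateNullError("null ensemble has zero mean Cp or Lp")
    null_lp = 1.0 / null_eglob
    gamma = gm.cp / null_cp.mean()
    lam = gm.lp / null_lp.mean()
    return float(gamma), float(lam), float(gamma / lam)


def metric_auc_curve(
    matrix,
    grid: SparsityGrid | None = None,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
    degree_mode: str = "binary",
) -> dict[str, AUCRecord]:
    """All global and nodal metric curves over the sparsity grid, with AUCs.

    Returns a mapping ``metric name -> AUCRecord``; nodal records hold one
    curve per node.  Null ensembles for gamma/lambda/sigma use per-threshold
    seeds derived from ``seed``.
    """
    grid = grid or SparsityGrid.from_range()
    thresholds = grid.as_array()
    values = _as_values(matrix)
    r = values.shape[0]
    curves: dict[str, np.ndarray] = {
        m: np.zeros(len(grid)) for m in GLOBAL_METRICS
    }
    curves.update({m: np.zeros((len(grid), r)) for m in NODAL_METRICS})
    threshold_seeds = np.random.SeedSequence(seed).spawn(len(grid))
    for t, s in enumerate(grid.values):
        g = threshold_by_sparsity(values, s)
        gm = global_metrics(g)
        nm = nodal_metrics(g, degree_mode=degree_mode)
        if n_rand > 0:
            seed_t = int(threshold_seeds[t].generate_state(1)[0] % 2**31)
            nulls = random_null_ensemble(g, n_rand, seed_t)
            gamma, lam, sigma = small_world_indices(g, nulls)
        else:
            gamma = lam = sigma = np.nan
        for name, val in (
            ("cp", gm.cp),
            ("lp", gm.lp),
            ("gamma", gamma),
            ("lambda", lam),
            ("sigma", sigma),
            ("eloc", gm.eloc),
            ("eglob", gm.eglob),
        ):
            curves[name][t] = val
        curves["degree"][t] = nm.degree
        curves["efficiency"][t] = nm.efficiency
        curves["betweenness"][t] = nm.betweenness
    return {
        name: AUCRecord(metric=name, thresholds=thresholds, values=vals)
        for name, vals in curves.items()
    }
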