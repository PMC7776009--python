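"""Network-based statistic (NBS) for localising subnetwork group differences.

An edgewise two-sample t statistic is computed on the connectome entries of
a selected node subset, edges exceeding a primary threshold (default
``|t| >= 2.9``) are kept, and each connected component of suprathreshold
edges is scored by its edge count against the permutation distribution of
the *maximum* component size under group-label reshuffling — which controls
the family-wise error rate over components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_T_THRESHOLD = 2.9
DEFAULT_N_PERM = 10_000


class NBSError(ValueError):
    pass


@dataclass
class EdgeStatMatrix:
    """Symmetric matrix of edgewise two-sample t values on a node subset.

    ``nodes`` are the original (1-based) region ids of the rows/columns.
    ``degenerate`` flags edges whose pooled variance was zero (t set to 0).
    """

    t: np.ndarray
    nodes: np.ndarray
    degenerate: np.ndarray


@dataclass
class Component:
    """A maximal connected set of suprathreshold edges."""

    nodes: list[int]
    edges: list[tuple[int, int]]
    p_value: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class NBSResult:
    components: list[Component]
    t_threshold: float
    n_perm: int
    null_max_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]


def _stack_edges(connectomes, node_subset: np.ndarray):
    """Stack subjects' upper-triangle entries of the subset submatrix."""
    sub_idx = node_subset - 1  # 0-based positions in the full matrix
    r = sub_idx.size
    iu, ju = np.triu_indices(r, 1)
    rows = []
    for m in connectomes:
        vals = np.asarray(getattr(m, "values", m), dtype=float)
        sub = vals[np.ix_(sub_idx, sub_idx)]
        rows.append(sub[iu, ju])
    return np.asarray(rows), (iu, ju)


def _pooled_t(data: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t over columns (edges)."""
    a = data[mask_a]
    b = data[~mask_a]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (a.mean(0) - b.mean(0)) / denom, 0.0)
    return t, denom == 0


def edgewise_t(connectomes_a, connectomes_b, node_subset) -> EdgeStatMatrix:
    """Pooled-variance two-sample t per edge, restricted to ``node_subset``.

    ``node_subset`` holds 1-based region ids; edges with zero pooled variance
    get t = 0 and a degeneracy flag.
    """
    node_subset = np.asarray(sorted(set(int(n) for n in node_subset)), dtype=int)
    if node_subset.size < 2:
        raise NBSError("node subset needs >= 2 nodes")
    if len(connectomes_a) < 2 or len(connectomes_b) < 2:
        raise NBSError("both groups need >= 2 subjects")
    data_a, (iu, ju) = _stack_edges(connectomes_a, node_subset)
    data_b, _ = _stack_edges(connectomes_b, node_subset)
    data = np.vstack([data_a, data_b])
    mask_a = np.zeros(data.shape[0], dtype=bool)
    mask_a[: data_a.shape[0]] = True
    t_flat, degen_flat = _pooled_t(data, mask_a)
    r = node_subset.size
    t = np.zeros((r, r))
    t[iu, ju] = t[ju, iu] = t_flat
    degenerate = np.zeros((r, r), dtype=bool)
    degenerate[iu, ju] = degenerate[ju, iu] = degen_flat
    return EdgeStatMatrix(t=t, nodes=node_subset, degenerate=degenerate)


def _component_sizes(adj_flat, iu, ju, r) -> list[tuple[list[int], list[int]]]:
    """Connected components (with >= 1 edge) of a suprathreshold edge mask.

    Returns (member node positions, member edge indices) per component.
    """
    keep = np.nonzero(adj_flat)[0]
    if keep.size == 0:
        return []
    adj = csr_matrix(
        (np.ones(keep.size), (iu[keep], ju[keep])), shape=(r, r)
    )
    n_comp, labels = connected_components(adj, directed=False)
    comps = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        if members.size < 2:
            continue
        edge_idx = keep[np.isin(iu[keep], members)]
        if edge_idx.size:
            comps.append((members.tolist(), edge_idx.tolist()))
    return comps


def suprathreshold_components(
    stats: EdgeStatMatrix, t_threshold: float, tail: str = "two"
) -> list[Component]:
    """Maximal connected components of edges exceeding the t threshold."""
    if t_threshold <= 0:
        raise NBSError("t threshold must be > 0")
    r = stats.nodes.size
    iu, ju = np.triu_indices(r, 1)
    t_flat = stats.t[iu, ju]
    if tail == "two":
        keep = np.abs(t_flat) >= t_threshold
    elif tail == "greater":
        keep = t_flat >= t_threshold
    elif tail == "less":
        keep = t_flat <= -t_threshold
    else:
        raise NBSError(f"unknown tail {tail!r}")
    comps = []
    for members, edge_idx in _component_sizes(keep, iu, ju, r):
        nodes = [int(stats.nodes[m]) for m in members]
        edges = [
            (int(stats.nodes[iu[e]]), int(stats.nodes[ju[e]])) for e in edge_idx
        ]
        comps.append(Component(nodes=nodes, edges=edges))
    comps.sort(key=lambda c: -c.n_edges)
    return comps


def nbs_test(
    connectomes_a,
    connectomes_b,
    node_subset,
    t_threshold: float = DEFAULT_T_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    tail: str = "two",
) -> NBSResult:
    """Full NBS: observed components plus the max-component permutation null.

    ``p(component) = (1 + #{perm : max component size >= observed size})
    / (n_perm + 1)``, where size is the edge count.
    """
    if n_perm < 1:
        raise NBSError("n_perm must be >= 1")
    stats = edgewise_t(connectomes_a, connectomes_b, node_subset)
    observed = suprathreshold_components(stats, t_threshold, tail=tail)

    node_subset = stats.nodes
    data_a, (iu, ju) = _stack_edges(connectomes_a, node_subset)
    data_b, _ = _stack_edges(connectomes_b, node_subset)
    data = np.vstack([data_a, data_b])
    n_a = data_a.shape[0]
    r = node_subset.size
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(data.shape[0])
        mask_a = np.zeros(data.shape[0], dtype=bool)
        mask_a[perm[:n_a]] = True
        t_flat, _ = _pooled_t(data, mask_a)
        if tail == "two":
            keep = np.abs(t_flat) >= t_threshold
        elif tail == "greater":
            keep = t_flat >= t_threshold
        else:
            keep = t_flat <= -t_threshold
        comps = _component_sizes(keep, iu, ju, r)
        null_max[b] = max((len(e) for _, e in comps), default=0)
    for comp in observed:
        hits = int(np.count_nonzero(null_max >= comp.n_edges))
        comp.p_value = (1 + hits) / (n_perm + 1)
    return NBSResult(
        components=observed,
        t_threshold=float(t_threshold),
        n_perm=n_perm,
        null_max_sizes=null_max,
    )
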