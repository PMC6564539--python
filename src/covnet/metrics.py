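"""Graph-theory metrics for binary undirected brain networks.

All functions operate on a dense 0/1 symmetric adjacency matrix with zero
diagonal (``numpy.ndarray``), the in-memory form produced by
:mod:`covnet.network`.  The conventions follow the unweighted formulas of
Rubinov & Sporns as used by graph-analysis toolboxes for structural
covariance work:

* nodes of degree < 2 contribute 0 to the clustering coefficient and to
  local efficiency (they are retained in the average, not excluded);
* characteristic path length is defined only on connected graphs and
  raises on fragmented input;
* global efficiency treats unreachable pairs as contributing 0;
* betweenness is the unnormalized Brandes sum of geodesic fractions over
  unordered node pairs, endpoints excluded;
* small-worldness sigma = gamma / lambda against degree-preserving
  (Maslov-Sneppen double-edge-swap) null networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "clustering_coefficient",
    "transitivity",
    "local_efficiency",
    "characteristic_path_length",
    "path_length_reachable",
    "path_length_penalized",
    "global_efficiency",
    "distance_matrix",
    "is_connected",
    "degrees",
    "node_betweenness",
    "modularity_louvain",
    "null_network",
    "small_worldness",
    "identify_hubs",
    "MetricSet",
    "compute_metric_set",
    "GLOBAL_METRICS",
]


def _as_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    return (a != 0).astype(float)


def degrees(adj: np.ndarray) -> np.ndarray:
    """Node degree vector k_i."""
    return _as_adjacency(adj).sum(axis=1)


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean clustering coefficient C.

    Per node: existing edges among its neighbors divided by the
    k_i*(k_i-1)/2 possible ones; degree < 2 contributes 0.
    """
    a = _as_adjacency(adj)
    k = a.sum(axis=1)
    # 2 * triangles at each node = diag(A^3)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, tri2 / (k * (k - 1)), 0.0)
    return float(c.mean()) if c.size else 0.0


def transitivity(adj: np.ndarray) -> float:
    """Transitivity T = 3 * triangles / connected triples (0 when no triples)."""
    a = _as_adjacency(adj)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * triangles per node
    triples2 = (k * (k - 1)).sum()  # 2 * number of connected triples
    if triples2 == 0:
        return 0.0
    return float(tri2.sum() / triples2)


def distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths (hop counts) via BFS; inf if unreachable."""
    a = _as_adjacency(adj)
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def is_connected(adj: np.ndarray) -> bool:
    a = _as_adjacency(adj)
    if a.shape[0] <= 1:
        return True
    n_comp, _ = connected_components(csr_matrix(a), directed=False)
    return n_comp == 1


def n_components(adj: np.ndarray) -> int:
    a = _as_adjacency(adj)
    if a.shape[0] == 0:
        return 0
    n_comp, _ = connected_components(csr_matrix(a), directed=False)
    return int(n_comp)


def characteristic_path_length(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean geodesic distance L over unordered node pairs.

    Raises :class:`ValueError` on fragmented graphs — the average is
    undefined when some pairs are unreachable.  ``dist`` may carry a
    precomputed distance matrix to avoid repeated BFS sweeps.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    d = distance_matrix(a) if dist is None else dist
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    if not np.all(np.isfinite(vals)):
        raise ValueError("graph is fragmented; characteristic path length undefined")
    return float(vals.mean())


def path_length_reachable(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean geodesic distance over *reachable* node pairs.

    Equals :func:`characteristic_path_length` on connected graphs; on a
    fragmented graph unreachable pairs are dropped from the average.  Used
    for degree-preserving null graphs, which can rarely fragment.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length needs >= 2 nodes")
    d = distance_matrix(a) if dist is None else dist
    vals = d[np.triu_indices(n, k=1)]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def path_length_penalized(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean geodesic distance with unreachable pairs set to n (nodes).

    Equals :func:`characteristic_path_length` exactly on connected graphs.
    On fragmented graphs each unreachable pair contributes the maximum
    possible distance plus one (= n), so fragmentation — the extreme form of
    poor integration — lengthens the measure instead of silently shortening
    it.  This is the convention used for metric curves along a density grid,
    where the sparsest densities can fragment a graph.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length needs >= 2 nodes")
    d = distance_matrix(a) if dist is None else dist
    vals = d[np.triu_indices(n, k=1)].copy()
    vals[~np.isfinite(vals)] = n
    return float(vals.mean())


def global_efficiency(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean inverse geodesic distance over pairs; unreachable pairs contribute 0."""
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = distance_matrix(a) if dist is None else dist
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighborhood subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def node_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness centrality b_v = sum over pairs of geodesic fractions."""
    a = _as_adjacency(adj)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])])


def modularity_louvain(
    adj: np.ndarray, seed: int = 0, restarts: int = 20, resolution: float = 1.0
) -> tuple[float, np.ndarray]:
    """Best Louvain partition over ``restarts`` seeded runs, by maximum Q.

    Returns ``(Q, labels)`` where ``labels[i]`` is the module id of node i.
    Module ids are renumbered 0..K-1 by descending module size (ties by
    smallest member index) so the output is deterministic.
    """
    a = _as_adjacency(adj)
    if a.sum() == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    g = nx.from_numpy_array(a)
    best_q, best_parts = -np.inf, None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(restarts):
        s = int(child.generate_state(1)[0] % (2**31))
        parts = nx.community.louvain_communities(g, seed=s, resolution=resolution)
        q = nx.community.modularity(g, parts, resolution=resolution)
        if q > best_q:
            best_q, best_parts = q, parts
    order = sorted(best_parts, key=lambda c: (-len(c), min(c)))
    labels = np.empty(a.shape[0], dtype=int)
    for mod_id, comm in enumerate(order):
        for v in comm:
            labels[v] = mod_id
    return float(best_q), labels


def null_network(adj: np.ndarray, seed: int = 0, swap_factor: int = 10) -> np.ndarray:
    """Degree-preserving random graph via Maslov-Sneppen double-edge swaps.

    Attempts ``swap_factor * m`` successful swaps (m = edge count), rejecting
    moves that would create self-loops or multi-edges.  If no legal swap
    exists the input is returned unchanged with a warning.
    """
    a = _as_adjacency(adj)
    m = int(a.sum() // 2)
    if m < 2:
        raise ValueError("degree-preserving rewiring needs >= 2 edges")
    g = nx.from_numpy_array(a)
    try:
        nx.double_edge_swap(g, nswap=swap_factor * m, max_tries=100 * swap_factor * m, seed=seed)
    except nx.NetworkXException:
        # dense or rigid graphs (e.g. complete graphs) admit few or no legal
        # swaps; whatever swaps succeeded before the limit are kept
        if g.number_of_edges() != m or sorted(d for _, d in g.degree()) != sorted(
            int(k) for k in degrees(a)
        ):
            warnings.warn("no legal degree-preserving swap found; returning input graph")
            return a.copy()
    return nx.to_numpy_array(g, nodelist=range(a.shape[0]))


def small_worldness(
    adj: np.ndarray, n_null: int = 20, seed: int = 0, swap_factor: int = 10
) -> tuple[float, float, float]:
    """Small-world sigma with normalized clustering gamma and path-length lambda.

    gamma = C / <C_null>, lam = L / <L_null> over ``n_null`` degree-preserving
    nulls; sigma = gamma / lam.  Requires a connected graph.  Returns
    ``(sigma, gamma, lam)``; sigma is nan when the null clustering averages 0.
    """
    a = _as_adjacency(adj)
    if not is_connected(a):
        raise ValueError("small-worldness requires a connected graph")
    c_obs = clustering_coefficient(a)
    l_obs = characteristic_path_length(a)
    ss = np.random.SeedSequence(seed)
    c_null, l_null = [], []
    for child in ss.spawn(n_null):
        s = int(child.generate_state(1)[0] % (2**31))
        null = null_network(a, seed=s, swap_factor=swap_factor)
        c_null.append(clustering_coefficient(null))
        # rewired graphs can in principle fragment; the reachable-pairs
        # convention covers that rare case (identical when connected)
        l_null.append(path_length_reachable(null))
    gamma_den = float(np.mean(c_null))
    lam = l_obs / float(np.mean(l_null))
    if gamma_den == 0:
        warnings.warn("null networks have zero clustering; sigma undefined")
        return float("nan"), float("nan"), lam
    gamma = c_obs / gamma_den
    return gamma / lam, gamma, lam


def identify_hubs(stat: np.ndarray, sd_multiplier: float = 2.0) -> np.ndarray:
    """Indices of hub nodes: stat >= mean + sd_multiplier * sample SD.

    A constant statistic has SD 0 and yields no hubs.
    """
    s = np.asarray(stat, dtype=float)
    if s.size < 2:
        raise ValueError("hub detection needs >= 2 nodes")
    sd = s.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(s >= s.mean() + sd_multiplier * sd)


@dataclass
class MetricSet:
    """All global metrics of one binary graph, plus nodal degree/betweenness."""

    clustering: float
    transitivity: float
    local_efficiency: float
    global_efficiency: float
    path_length: float
    modularity: float
    partition: np.ndarray = field(repr=False)
    sigma: float = float("nan")
    gamma: float = float("nan")
    lam: float = float("nan")
    degree: np.ndarray = field(default=None, repr=False)
    betweenness: np.ndarray = field(default=None, repr=False)


def compute_metric_set(
    adj: np.ndarray,
    seed: int = 0,
    n_null: int = 20,
    louvain_restarts: int = 20,
    small_world: bool = True,
) -> MetricSet:
    """Evaluate the full metric panel on one binary graph.

    Path length uses the penalized convention (identical to the strict
    characteristic path length on connected graphs); small-worldness is
    reported as NaN on fragmented graphs.
    """
    a = _as_adjacency(adj)
    d = distance_matrix(a)
    q, part = modularity_louvain(a, seed=seed, restarts=louvain_restarts)
    if small_world and is_connected(a):
        sig, gam, lam = small_worldness(a, n_null=n_null, seed=seed)
    else:
        # sigma is only defined against connected comparisons
        sig = gam = lam = float("nan")
    return MetricSet(
        clustering=clustering_coefficient(a),
        transitivity=transitivity(a),
        local_efficiency=local_efficiency(a),
        global_efficiency=global_efficiency(a, dist=d),
        path_length=path_length_penalized(a, dist=d),
        modularity=q,
        partition=part,
        sigma=sig,
        gamma=gam,
        lam=lam,
        degree=degrees(a),
        betweenness=node_betweenness(a),
    )


def _curve_clustering(a, d):
    return clustering_coefficient(a)


def _curve_transitivity(a, d):
    return transitivity(a)


def _curve_local_eff(a, d):
    return local_efficiency(a)


def _curve_global_eff(a, d):
    return global_efficiency(a, dist=d)


def _curve_path_length(a, d):
    return path_length_penalized(a, dist=d)


#: Global metrics evaluable along a density grid; each callable takes
#: (adjacency, distance_matrix_or_None).  Metrics needing distances declare it.
GLOBAL_METRICS = {
    "clustering": (_curve_clustering, False),
    "transitivity": (_curve_transitivity, False),
    "local_efficiency": (_curve_local_eff, False),
    "global_efficiency": (_curve_global_eff, True),
    "path_length": (_curve_path_length, True),
}
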