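"""Shared fixtures and independent brute-force graph oracles.

The oracles deliberately avoid the package's own code paths (and networkx):
distances by hand-rolled BFS, triangles and triples by exhaustive
enumeration, betweenness by explicit shortest-path enumeration.  They are
slow and only meant for graphs with at most ~12 nodes.
"""

from collections import deque
from itertools import combinations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# toy graphs


def adjacency(n, edges):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return a


@pytest.fixture
def triangle():
    return adjacency(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return adjacency(3, [(0, 1), (1, 2)])


@pytest.fixture
def path4():
    return adjacency(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star4():
    """K1,3: node 0 is the center."""
    return adjacency(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def chorded_cycle():
    """4-cycle 0-1-2-3-0 plus chord 0-2."""
    return adjacency(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])


@pytest.fixture
def double_triangle():
    """Two triangles joined by a single bridge edge (2-3)."""
    return adjacency(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


def random_graph(n, p, rng):
    a = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if rng.uniform() < p:
            a[i, j] = a[j, i] = 1.0
    return a


# ---------------------------------------------------------------------------
# brute-force oracles


def bfs_distances(a):
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if a[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


def oracle_clustering(a):
    n = a.shape[0]
    total = 0.0
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(a[i, j] for i, j in combinations(nbrs, 2))
        total += 2.0 * links / (k * (k - 1))
    return total / n


def oracle_transitivity(a):
    n = a.shape[0]
    triangles = sum(
        a[i, j] and a[j, k] and a[i, k] for i, j, k in combinations(range(n), 3)
    )
    triples = 0
    for v in range(n):
        k = int(a[v].sum())
        triples += k * (k - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def oracle_global_efficiency(a):
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = bfs_distances(a)
    total = sum(
        (1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0)
        for i, j in combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def oracle_local_efficiency(a):
    n = a.shape[0]
    total = 0.0
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += oracle_global_efficiency(sub)
    return total / n


def oracle_path_length(a):
    n = a.shape[0]
    d = bfs_distances(a)
    vals = [d[i, j] for i, j in combinations(range(n), 2)]
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("fragmented")
    return float(np.mean(vals))


def oracle_betweenness(a):
    """Exhaustive shortest-path enumeration (endpoints excluded)."""
    n = a.shape[0]
    d = bfs_distances(a)
    b = np.zeros(n)

    def all_shortest_paths(s, t):
        if not np.isfinite(d[s, t]):
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in range(n):
                if a[u, v] and d[s, v] == d[s, u] + 1 and d[v, t] == d[s, t] - d[s, v]:
                    extend(path + [v])

        extend([s])
        return paths

    for s, t in combinations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                b[v] += 1.0 / len(paths)
    return b
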