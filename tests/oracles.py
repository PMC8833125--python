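"""Independent brute-force oracles for the graph metrics and statistics.

Everything here is deliberately naive (pure-Python BFS, exhaustive
shortest-path enumeration, from-definition Pearson) and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj) -> list[list[float]]:
    """Per-source BFS; math.inf for unreachable."""
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    out = []
    for s in range(n):
        dist = [math.inf] * n
        dist[s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if a[u][v] and dist[v] == math.inf:
                    dist[v] = dist[u] + 1
                    q.append(v)
        out.append(dist)
    return out


def oracle_lp(adj) -> float:
    d = bfs_distances(adj)
    n = len(d)
    vals = [d[i][j] for i in range(n) for j in range(i + 1, n)
            if math.isfinite(d[i][j])]
    return sum(vals) / len(vals) if vals else math.nan


def oracle_eglob(adj) -> float:
    d = bfs_distances(adj)
    n = len(d)
    if n < 2:
        return 0.0
    tot = sum(1.0 / d[i][j] if math.isfinite(d[i][j]) and d[i][j] > 0 else 0.0
              for i in range(n) for j in range(i + 1, n))
    return tot / (n * (n - 1) / 2)


def oracle_enod(adj) -> list[float]:
    d = bfs_distances(adj)
    n = len(d)
    return [sum(1.0 / d[i][j] if math.isfinite(d[i][j]) else 0.0
                for j in range(n) if j != i) / (n - 1) for i in range(n)]


def oracle_degree(adj) -> list[int]:
    a = np.asarray(adj, dtype=bool)
    return [int(a[i].sum()) for i in range(a.shape[0])]


def oracle_clustering(adj):
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    per = []
    for i in range(n):
        nb = [j for j in range(n) if a[i][j]]
        k = len(nb)
        if k < 2:
            per.append(0.0)
            continue
        e = sum(1 for x, y in combinations(nb, 2) if a[x][y])
        per.append(e / (k * (k - 1) / 2))
    return per, sum(per) / n if n else 0.0


def oracle_eloc(adj):
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    per = []
    for i in range(n):
        nb = [j for j in range(n) if a[i][j]]
        if len(nb) < 2:
            per.append(0.0)
            continue
        sub = a[np.ix_(nb, nb)]
        per.append(oracle_eglob(sub))
    return per, sum(per) / n if n else 0.0


def _all_shortest_paths(adj, s, t, dist):
    """Exhaustively enumerate all shortest s-t paths by DFS along the BFS
    distance gradient."""
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if a[u][v] and dist[s][v] == dist[s][u] + 1 and dist[v][t] == dist[u][t] - 1:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def oracle_betweenness(adj) -> list[float]:
    """Unnormalized undirected betweenness by exhaustive shortest-path
    enumeration (each unordered pair counted once)."""
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = bfs_distances(a)
    bc = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(d[s][t]):
                continue
            paths = _all_shortest_paths(a, s, t, d)
            total = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / total
    return bc


def oracle_pearson(x, y) -> float:
    """Two-pass from-definition Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def oracle_bh_mask(p, q):
    """Benjamini-Hochberg step-up by literal definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kstar = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            kstar = rank
    mask = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= kstar:
            mask[i] = True
    return mask


def oracle_min_density_k(weights) -> int:
    """Smallest k such that the top-k edges (by descending weight) connect
    the graph: linear scan with connectivity checked from scratch each time
    via label propagation."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    order = np.argsort(-w[iu, ju], kind="stable")
    edges = list(zip(iu[order], ju[order]))
    for k in range(1, len(edges) + 1):
        a = np.zeros((n, n), dtype=bool)
        for i, j in edges[:k]:
            a[i, j] = a[j, i] = True
        # label propagation connectivity check
        labels = list(range(n))
        changed = True
        while changed:
            changed = False
            for i in range(n):
                for j in range(n):
                    if a[i][j] and labels[j] < labels[i]:
                        labels[i] = labels[j]
                        changed = True
        if len(set(labels)) == 1:
            return k
    return len(edges)


def random_graph(rng, n, p=None) -> np.ndarray:
    """Random symmetric zero-diagonal binary adjacency."""
    if p is None:
        p = rng.uniform(0.15, 0.8)
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T
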