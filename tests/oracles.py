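"""Independent brute-force oracles for graph metrics and arithmetic checks.

These deliberately use different algorithms from the package: Floyd-Warshall
for distances, exhaustive triple enumeration for clustering, exhaustive
shortest-path enumeration for betweenness, and direct formula evaluation for
Pearson r/p.  They are only feasible on tiny graphs, which is the point.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(np.asarray(adj) > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_by_triples(adj: np.ndarray) -> tuple[float, np.ndarray]:
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        c[i] = closed / (k * (k - 1) / 2)
    return float(c.mean()), c


def path_length_mean(dist: np.ndarray) -> float:
    n = dist.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n)
            if i != j and math.isfinite(dist[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def efficiency_from_dist(dist: np.ndarray) -> tuple[float, np.ndarray]:
    n = dist.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    e = np.zeros(n)
    for i in range(n):
        e[i] = sum(
            1.0 / dist[i, j]
            for j in range(n)
            if j != i and math.isfinite(dist[i, j]) and dist[i, j] > 0
        ) / (n - 1)
    return float(e.mean()), e


def local_efficiency_oracle(adj: np.ndarray) -> tuple[float, np.ndarray]:
    n = adj.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        e[i] = efficiency_from_dist(floyd_warshall(sub))[0]
    return float(e.mean()), e


def _all_shortest_paths(adj: np.ndarray, s: int, t: int, d_st: float) -> list[tuple]:
    """Enumerate every shortest s-t path by depth-limited DFS."""
    if not math.isfinite(d_st):
        return []
    n = adj.shape[0]
    paths = []

    def extend(path: tuple) -> None:
        u = path[-1]
        if u == t:
            if len(path) - 1 == d_st:
                paths.append(path)
            return
        if len(path) - 1 >= d_st:
            return
        for v in range(n):
            if adj[u, v] and v not in path:
                extend(path + (v,))

    extend((s,))
    return paths


def betweenness_by_enumeration(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t, dist[s, t])
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def pearson_arithmetic(x, y) -> tuple[float, float]:
    """Pearson r and two-tailed p from the textbook covariance/SD and
    t = r sqrt((n-2)/(1-r^2)) formulas, via the t survival function."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, float(p)


def trapezoid(ys, xs) -> float:
    return float(sum((ys[k] + ys[k + 1]) * (xs[k + 1] - xs[k]) / 2.0
                     for k in range(len(ys) - 1)))


def random_adjacency(rng: np.random.Generator, n: int, p: float | None = None) -> np.ndarray:
    p = rng.uniform(0.15, 0.8) if p is None else p
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(np.int8)
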