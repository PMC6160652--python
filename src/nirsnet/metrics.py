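"""Global and nodal topology metrics of binary undirected graphs.

Implements the standard small-world battery on unweighted graphs: nodal
degree K, all-pairs shortest paths, clustering coefficient C_p, characteristic
path length L_p, global and nodal efficiency E_glob / E_nodal, local
efficiency E_loc, and shortest-path betweenness N_bc.

Conventions (chosen where the textbook formulas are 0/0 or divide by
infinity, and stated here because they matter at low sparsity):

* L_p averages min|L_ij| over *reachable* ordered pairs only; it is nan for
  an edgeless graph, where no pair is reachable.
* A node of degree < 2 has clustering coefficient 0 and local efficiency 0.
* Efficiencies treat unreachable pairs as contributing 0 (1/inf).
* Betweenness is unnormalized (raw pair-dependency sums); only relative
  comparisons between nodes of the same graph are used downstream.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .core import BinaryGraph, GraphMetrics


def _as_adjacency(g: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return np.asarray(g.adjacency, dtype=np.int8)
    return np.asarray(g, dtype=np.int8)


def shortest_paths(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by level-synchronous breadth-first
    search, run for every source at once via boolean matrix products.

    Returns an N x N float matrix with hop counts, 0 on the diagonal and
    inf for unreachable pairs.  Exact for unweighted graphs; the frontier
    expansion terminates after diameter-many rounds.
    """
    adj = _as_adjacency(g) > 0
    n = adj.shape[0]
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = adj | np.eye(n, dtype=bool)
    frontier = adj
    adj_num = adj.astype(np.int16)
    d = 1
    while True:
        expanded = (frontier @ adj_num) > 0
        new = expanded & ~reached
        if not new.any():
            break
        d += 1
        dist[new] = d
        reached |= new
        frontier = new
    return dist


def clustering_coefficient(g: BinaryGraph | np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering coefficient.

    C_i = (edges among i's neighbors) / (K_i (K_i - 1) / 2); 0 when K_i < 2.
    """
    adj = _as_adjacency(g).astype(np.int64)
    k = adj.sum(axis=1)
    # (A @ A) * A counts, per node, twice the edges among its neighbors
    e_i = ((adj @ adj) * adj).sum(axis=1) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(k >= 2, e_i / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c_i.mean()) if len(c_i) else 0.0, c_i


def characteristic_path_length(dist: np.ndarray) -> float:
    """Mean shortest-path length over reachable ordered pairs (i != j).

    Returns nan (undefined) when no off-diagonal pair is reachable.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(dist)
    if not finite.any():
        return float("nan")
    return float(dist[finite].mean())


def nodal_and_global_efficiency(dist: np.ndarray) -> tuple[float, np.ndarray]:
    """Global efficiency and per-node efficiency from a distance matrix.

    E_nodal(i) = (1/(N-1)) sum_{j != i} 1/min|L_ij|, with 1/inf = 0;
    E_glob is the mean over nodes.  Single-node graphs score 0.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    e_nodal = inv.sum(axis=1) / (n - 1)
    return float(e_nodal.mean()), e_nodal


def local_efficiency(g: BinaryGraph | np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-node local efficiency.

    E_loc_nodal(i) is the global efficiency of the subgraph induced on i's
    neighbors (i itself excluded); neighbor sets smaller than 2 score 0.
    """
    adj = _as_adjacency(g)
    n = adj.shape[0]
    e_loc_nodal = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        e_glob_sub, _ = nodal_and_global_efficiency(shortest_paths(sub))
        e_loc_nodal[i] = e_glob_sub
    return float(e_loc_nodal.mean()) if n else 0.0, e_loc_nodal


def betweenness(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness centrality (Brandes accumulation).

    Counts each unordered source-target pair once.
    """
    adj = _as_adjacency(g)
    n = adj.shape[0]
    neighbors = [np.flatnonzero(adj[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1.0)
        dist[s] = 0.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return bc / 2.0


def all_metrics(g: BinaryGraph | np.ndarray, include_nodal: bool = True) -> GraphMetrics:
    """Assemble every metric of one graph into a :class:`GraphMetrics` record.

    ``include_nodal=False`` computes the four global metrics only (the mode
    used for null ensembles, where nodal vectors are never consumed).
    """
    adj = _as_adjacency(g)
    dist = shortest_paths(adj)
    c_p, c_nodal = clustering_coefficient(adj)
    l_p = characteristic_path_length(dist)
    e_glob, e_nodal = nodal_and_global_efficiency(dist)
    e_loc, e_loc_nodal = local_efficiency(adj)
    if not include_nodal:
        return GraphMetrics(c_p=c_p, l_p=l_p, e_glob=e_glob, e_loc=e_loc)
    return GraphMetrics(
        c_p=c_p,
        l_p=l_p,
        e_glob=e_glob,
        e_loc=e_loc,
        k_nodal=adj.sum(axis=1).astype(float),
        e_nodal=e_nodal,
        e_loc_nodal=e_loc_nodal,
        n_bc=betweenness(adj),
        c_nodal=c_nodal,
    )
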