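"""Degree-matched random-network nulls and normalized small-world indicators.

Each null is produced by Maslov-Sneppen double-edge swaps: repeatedly pick
two edges (a,b), (c,d) and replace them with (a,d), (c,b) unless that would
create a self-loop or a duplicate edge.  Swaps preserve every node's degree
exactly, so the ensemble matches the real graph's node count, edge count and
degree sequence while destroying its specific topology.

The normalized indicators divide the real metric by the null-ensemble mean:
gamma = C_p / <C_p_rand>, lambda = L_p / <L_p_rand>, sigma = gamma / lambda,
and the efficiency analogues gamma_E, lambda_E, sigma_E.  A small-world
graph has gamma > 1, lambda ~ 1, hence sigma > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryGraph, GraphMetrics
from .metrics import all_metrics

DEFAULT_N_NULLS = 100
DEFAULT_SWAPS_PER_EDGE = 10
Z_CRITICAL = 1.96  # two-tailed 0.05 threshold, as conventionally printed


def critical_z(alpha: float = 0.05) -> float:
    """Two-tailed critical z for significance level ``alpha`` (0.05 -> 1.96)."""
    from scipy.stats import norm

    return float(norm.ppf(1.0 - alpha / 2.0))


def rewire_degree_preserving(
    g: BinaryGraph,
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.SeedSequence | None = None,
) -> BinaryGraph:
    """Randomize a graph by double-edge swaps, preserving all degrees.

    Attempts ``n_swaps_per_edge * n_edges`` swaps, rejecting any that would
    create a self-loop or parallel edge.  Graphs admitting no valid swap
    (e.g. a triangle, or fewer than 2 edges) come back unchanged.
    """
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    edges = np.array(np.triu_indices(n, k=1)).T
    edges = edges[g.adjacency[edges[:, 0], edges[:, 1]] == 1]
    m = len(edges)
    if m < 2:
        return BinaryGraph(adjacency=g.adjacency.copy(), sparsity=g.sparsity)
    adj = g.adjacency.copy()
    n_attempts = n_swaps_per_edge * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:  # swap orientation of the second edge
            c, d = d, c
        # proposed replacements: (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


@dataclass
class NullEnsemble:
    """Metrics of n degree-matched rewired copies of one graph."""

    metrics: list[GraphMetrics]
    seed: int | None = None

    def values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.mean(self.values(name)))

    def sd(self, name: str) -> float:
        return float(np.std(self.values(name), ddof=1))

    @property
    def n_nulls(self) -> int:
        return len(self.metrics)

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: (self.mean(name), self.sd(name))
            for name in GraphMetrics.GLOBAL_NAMES
        }


def null_ensemble(
    g: BinaryGraph,
    n_nulls: int = DEFAULT_N_NULLS,
    seed: int | np.random.SeedSequence | None = None,
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    include_nodal: bool = False,
) -> NullEnsemble:
    """Build and measure ``n_nulls`` independent degree-matched nulls.

    Per-null seeds are spawned deterministically from the master seed, so a
    fixed seed reproduces the ensemble bit for bit.
    """
    if n_nulls < 2:
        raise ValueError("need at least 2 nulls for ensemble statistics")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_nulls)
    mets = []
    for child in children:
        null = rewire_degree_preserving(g, n_swaps_per_edge, child)
        mets.append(all_metrics(null, include_nodal=include_nodal))
    return NullEnsemble(metrics=mets)


@dataclass(frozen=True)
class NormalizedMetrics:
    """Real-to-null metric ratios; nan where L_p is undefined."""

    gamma: float
    lambda_: float
    sigma: float
    gamma_e: float
    lambda_e: float
    sigma_e: float

    def as_dict(self) -> dict[str, float]:
        return {
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "gamma_e": self.gamma_e,
            "lambda_e": self.lambda_e,
            "sigma_e": self.sigma_e,
        }


def _ratio(real: float, rand: float) -> float:
    if not np.isfinite(real) or not np.isfinite(rand) or rand == 0:
        return float("nan")
    return real / rand


def normalized_metrics(real: GraphMetrics, nulls: NullEnsemble) -> NormalizedMetrics:
    """Normalized small-world indicators of a graph against its null ensemble."""
    gamma = _ratio(real.c_p, nulls.mean("c_p"))
    lam = _ratio(real.l_p, nulls.mean("l_p"))
    gamma_e = _ratio(real.e_glob, nulls.mean("e_glob"))
    lambda_e = _ratio(real.e_loc, nulls.mean("e_loc"))
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else float("nan")
    sigma_e = (
        gamma_e / lambda_e
        if np.isfinite(gamma_e) and np.isfinite(lambda_e) and lambda_e != 0
        else float("nan")
    )
    return NormalizedMetrics(gamma, lam, sigma, gamma_e, lambda_e, sigma_e)


@dataclass(frozen=True)
class ZScoreResult:
    """z of a real metric against its null distribution (sample SD, n-1)."""

    metric: str
    x_real: float
    null_mean: float
    null_sd: float
    z: float
    significant: bool
    undefined: bool = False


def zscore(
    x_real: float, null_values: np.ndarray | list[float], metric: str = ""
) -> ZScoreResult:
    """z = (x_real - mean(nulls)) / sd(nulls); |z| > 1.96 flags significance.

    Zero null SD, or an undefined real/null value, yields an undefined
    result (z = nan) rather than an exception.
    """
    vals = np.asarray(null_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 null values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if not np.isfinite(x_real) or not np.isfinite(mean) or not np.isfinite(sd) or sd == 0:
        return ZScoreResult(metric, float(x_real), mean, sd, float("nan"), False, True)
    z = (x_real - mean) / sd
    return ZScoreResult(metric, float(x_real), mean, sd, z, bool(abs(z) > Z_CRITICAL))
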