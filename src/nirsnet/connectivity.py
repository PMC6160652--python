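"""Functional connectivity: Pearson correlation matrix and sparsity binarization.

The sparsity S of a graph is the fraction of realized edges out of the
N(N-1)/2 possible channel pairs.  Binarization keeps the K = round(S * M)
pairs with the largest |r| (absolute correlation ranks edges, so strong
negative couplings also become edges) and records the smallest admitted |r|
as the realized threshold T.
"""

from __future__ import annotations

import math

import numpy as np

from .core import BinaryGraph, CorrelationMatrix, DegenerateChannelError, Recording


def correlation_matrix(rec: Recording) -> CorrelationMatrix:
    """Channel-pairwise Pearson correlation of a recording.

    Raises :class:`DegenerateChannelError` naming the first zero-variance
    channel, for which Pearson correlation is undefined.
    """
    data = rec.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples per channel")
    dead = np.flatnonzero(np.ptp(data, axis=1) == 0)
    if dead.size:
        raise DegenerateChannelError(
            f"channel {rec.channel_ids[dead[0]]} has zero variance"
        )
    r = np.corrcoef(data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, channel_ids=rec.channel_ids)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def edge_ranking(corr: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by (|r| desc, then row asc, then col asc).

    Returns (rows, cols, |r|) arrays; the deterministic tie rule makes
    binarization reproducible across platforms.
    """
    r = corr.values
    iu, ju = np.triu_indices(r.shape[0], k=1)
    absr = np.abs(r[iu, ju])
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -absr))
    return iu[order], ju[order], absr[order]


def binarize_at_sparsity(corr: CorrelationMatrix, sparsity: float) -> BinaryGraph:
    """Binary undirected graph keeping the top-|r| edges at a given sparsity.

    Edge count is round-half-away-from-zero of S * N(N-1)/2; S=0 yields the
    edgeless graph and S=1 the complete graph.
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError(f"sparsity must be in [0, 1], got {sparsity}")
    n = corr.n_channels
    m = n * (n - 1) // 2
    k = _round_half_away(sparsity * m)
    rows, cols, absr = edge_ranking(corr)
    adj = np.zeros((n, n), dtype=np.int8)
    if k > 0:
        adj[rows[:k], cols[:k]] = 1
        adj |= adj.T
    threshold = float(absr[k - 1]) if k > 0 else float("nan")
    return BinaryGraph(adjacency=adj, sparsity=float(sparsity), threshold=threshold)
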