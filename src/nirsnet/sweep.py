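"""Sparsity sweep: metric curves, AUC summaries, significance ranges, hubs.

Because any single binarization threshold is arbitrary, every metric is
computed across the full sparsity grid (default 0:0.01:1) and summarized by
the trapezoidal area under the curve,

    Y_AUC = sum_k (Y(S_k) + Y(S_k+1)) * dS / 2,

a threshold-independent scalar.  Per sparsity point, the real graph is
compared to a degree-matched null ensemble via z-scores and the normalized
indicators gamma/lambda/sigma; contiguous runs of |z| > 1.96 form the
significant sparsity ranges.  Hubs are nodes whose nodal AUC (degree, nodal
efficiency or betweenness, over the full grid) exceeds the node average by
more than one standard deviation on any criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryGraph, CorrelationMatrix, GraphMetrics, SparsityGrid, TraitScores
from .connectivity import _round_half_away, edge_ranking
from .metrics import all_metrics
from .nulls import (
    NormalizedMetrics,
    Z_CRITICAL,
    ZScoreResult,
    normalized_metrics,
    null_ensemble,
    zscore,
)

#: nodal criteria entering hub identification
HUB_CRITERIA = ("k_nodal", "e_nodal", "n_bc")


@dataclass
class MetricCurve:
    """One metric as a function of sparsity; masked points are undefined."""

    metric: str
    grid: np.ndarray
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.grid) == len(self.values) == len(self.mask)):
            raise ValueError("grid, values and mask must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass(frozen=True)
class AUCSummary:
    """Trapezoidal integral of a metric curve over a sparsity window."""

    metric: str
    window: tuple[float, float]
    value: float
    defined: bool = True
    reason: str = ""


@dataclass
class SweepResult:
    """Everything one correlation matrix yields across the sparsity grid."""

    grid: np.ndarray
    curves: dict[str, MetricCurve]
    nodal_curves: dict[str, np.ndarray]  # criterion -> (n_points, n_nodes)
    zscores: dict[str, list[ZScoreResult]] = field(default_factory=dict)
    normalized: list[NormalizedMetrics] = field(default_factory=list)

    def z_array(self, metric: str) -> np.ndarray:
        return np.array([r.z for r in self.zscores[metric]], dtype=float)


@dataclass
class SubjectNetworkProfile:
    """Per-subject AUC summaries plus trait scores: the association unit."""

    subject_id: str
    global_aucs: dict[str, float]
    nodal_aucs: dict[str, np.ndarray]
    traits: TraitScores | None = None


@dataclass
class HubReport:
    """Hub flags per nodal criterion and their union."""

    flags: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    union: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        stacked = np.column_stack([self.flags[c] for c in self.flags])
        self.union = stacked.any(axis=1)

    def hub_nodes(self) -> list[int]:
        return list(np.flatnonzero(self.union))


def metric_curves(
    corr: CorrelationMatrix,
    grid: SparsityGrid | None = None,
    n_nulls: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    include_nodal: bool = True,
    n_swaps_per_edge: int = 10,
) -> SweepResult:
    """Binarize at every grid sparsity and measure real (and null) networks.

    With ``n_nulls = 0`` the null ensembles, z-scores and normalized
    indicators are skipped — the fast path when only raw metric AUCs are
    needed.  Edge sets are nested across the grid (same ranking, growing
    edge count), so the sweep sorts |r| once.
    """
    grid = grid or SparsityGrid()
    s_values = grid.values
    n = corr.n_channels
    m = n * (n - 1) // 2
    rows, cols, _ = edge_ranking(corr)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    point_seeds = ss.spawn(len(s_values)) if n_nulls else [None] * len(s_values)

    global_vals: dict[str, list[float]] = {k: [] for k in GraphMetrics.GLOBAL_NAMES}
    nodal_vals: dict[str, list[np.ndarray]] = (
        {k: [] for k in HUB_CRITERIA} if include_nodal else {}
    )
    zsc: dict[str, list[ZScoreResult]] = (
        {k: [] for k in GraphMetrics.GLOBAL_NAMES} if n_nulls else {}
    )
    normalized: list[NormalizedMetrics] = []

    adj = np.zeros((n, n), dtype=np.int8)
    prev_k = 0
    for s, child in zip(s_values, point_seeds):
        k = _round_half_away(float(s) * m)
        if k > prev_k:
            adj[rows[prev_k:k], cols[prev_k:k]] = 1
            adj[cols[prev_k:k], rows[prev_k:k]] = 1
            prev_k = k
        g = BinaryGraph(adjacency=adj.copy(), sparsity=float(s))
        real = all_metrics(g, include_nodal=include_nodal)
        for name in GraphMetrics.GLOBAL_NAMES:
            global_vals[name].append(getattr(real, name))
        if include_nodal:
            for name in HUB_CRITERIA:
                nodal_vals[name].append(getattr(real, name))
        if n_nulls:
            ens = null_ensemble(
                g, n_nulls=n_nulls, seed=child, n_swaps_per_edge=n_swaps_per_edge
            )
            for name in GraphMetrics.GLOBAL_NAMES:
                zsc[name].append(
                    zscore(getattr(real, name), ens.values(name), metric=name)
                )
            normalized.append(normalized_metrics(real, ens))

    curves = {
        name: MetricCurve(metric=name, grid=s_values, values=np.array(vals))
        for name, vals in global_vals.items()
    }
    nodal_curves = {
        name: np.vstack(vals) for name, vals in nodal_vals.items()
    } if include_nodal else {}
    return SweepResult(
        grid=s_values,
        curves=curves,
        nodal_curves=nodal_curves,
        zscores=zsc,
        normalized=normalized,
    )


def _window_indices(grid: np.ndarray, window: tuple[float, float]) -> tuple[int, int]:
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy S_a < S_b")
    i = np.flatnonzero(np.isclose(grid, lo, atol=1e-9))
    j = np.flatnonzero(np.isclose(grid, hi, atol=1e-9))
    if not len(i) or not len(j):
        raise ValueError(f"window endpoints {window} must lie on the grid")
    return int(i[0]), int(j[0])


def auc(curve: MetricCurve, window: tuple[float, float] | None = None) -> AUCSummary:
    """Trapezoidal AUC of a curve over ``window`` (default: the full grid).

    A masked (undefined) point inside the window makes the AUC undefined,
    returned flagged rather than raised.
    """
    if window is None:
        window = (float(curve.grid[0]), float(curve.grid[-1]))
    i, j = _window_indices(curve.grid, window)
    if curve.mask[i : j + 1].any():
        bad = curve.grid[i : j + 1][curve.mask[i : j + 1]]
        return AUCSummary(
            metric=curve.metric,
            window=window,
            value=float("nan"),
            defined=False,
            reason=f"undefined curve points at S={np.round(bad, 4).tolist()}",
        )
    y = curve.values[i : j + 1]
    s = curve.grid[i : j + 1]
    value = float(np.sum((y[:-1] + y[1:]) * np.diff(s) / 2.0))
    return AUCSummary(metric=curve.metric, window=window, value=value)


def significant_range(
    zscores: list[ZScoreResult] | np.ndarray,
    grid: np.ndarray,
    z_critical: float = Z_CRITICAL,
) -> list[dict]:
    """Maximal contiguous grid runs where |z| > z_critical.

    Each run is reported with its endpoints and the mean +/- SD of z over
    the run (sample SD; nan for single-point runs).
    """
    z = (
        np.array([r.z for r in zscores], dtype=float)
        if not isinstance(zscores, np.ndarray)
        else np.asarray(zscores, dtype=float)
    )
    grid = np.asarray(grid, dtype=float)
    sig = np.isfinite(z) & (np.abs(z) > z_critical)
    runs: list[dict] = []
    start = None
    for idx in range(len(sig) + 1):
        if idx < len(sig) and sig[idx]:
            if start is None:
                start = idx
        elif start is not None:
            zz = z[start:idx]
            runs.append(
                {
                    "s_start": float(grid[start]),
                    "s_end": float(grid[idx - 1]),
                    "mean_z": float(zz.mean()),
                    "sd_z": float(np.std(zz, ddof=1)) if len(zz) > 1 else float("nan"),
                    "n_points": int(idx - start),
                }
            )
            start = None
    return runs


def identify_hubs(nodal_aucs: dict[str, np.ndarray]) -> HubReport:
    """Flag hub nodes: nodal AUC > mean + 1 SD on any criterion.

    Expects the per-node AUCs of degree, nodal efficiency and betweenness
    over the full sparsity grid (cohort means, or one subject's).  SD uses
    the sample convention across nodes.
    """
    flags: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for crit, values in nodal_aucs.items():
        values = np.asarray(values, dtype=float)
        if values.size < 3:
            raise ValueError("hub analysis requires at least 3 nodes")
        mu = float(values.mean())
        sd = float(np.std(values, ddof=1))
        flags[crit] = values > mu + sd
        means[crit] = mu
        sds[crit] = sd
    return HubReport(flags=flags, means=means, sds=sds)


def nodal_auc_vector(
    nodal_curve: np.ndarray, grid: np.ndarray, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Per-node trapezoidal AUC of a (n_points x n_nodes) nodal curve."""
    grid = np.asarray(grid, dtype=float)
    if window is None:
        i, j = 0, len(grid) - 1
    else:
        i, j = _window_indices(grid, window)
    y = nodal_curve[i : j + 1]
    ds = np.diff(grid[i : j + 1])[:, None]
    return np.sum((y[:-1] + y[1:]) * ds / 2.0, axis=0)


def common_defined_window(
    curve_sets: list[dict[str, MetricCurve]], grid: np.ndarray
) -> tuple[float, float]:
    """Largest contiguous sparsity range where every subject's global
    metrics are all defined — the default integration window for the
    association stage."""
    grid = np.asarray(grid, dtype=float)
    ok = np.ones(len(grid), dtype=bool)
    for curves in curve_sets:
        for curve in curves.values():
            ok &= ~curve.mask
    best = (0, -1)
    start = None
    for idx in range(len(ok) + 1):
        if idx < len(ok) and ok[idx]:
            if start is None:
                start = idx
        elif start is not None:
            if idx - start > best[1] - best[0] + 1:
                best = (start, idx - 1)
            start = None
    if best[1] < best[0] or best[1] == best[0]:
        raise ValueError("no contiguous window with all metrics defined")
    return float(grid[best[0]]), float(grid[best[1]])


def subject_profile(
    subject_id: str,
    sweep: SweepResult,
    traits: TraitScores | None = None,
    window: tuple[float, float] | None = None,
) -> SubjectNetworkProfile:
    """Integrate a subject's sweep into AUC summaries.

    Global metrics integrate over ``window`` (default full grid); nodal hub
    criteria always integrate over the full grid.
    """
    global_aucs = {
        name: auc(curve, window).value for name, curve in sweep.curves.items()
    }
    nodal_aucs = {
        name: nodal_auc_vector(curve, sweep.grid)
        for name, curve in sweep.nodal_curves.items()
    }
    return SubjectNetworkProfile(
        subject_id=subject_id,
        global_aucs=global_aucs,
        nodal_aucs=nodal_aucs,
        traits=traits,
    )
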