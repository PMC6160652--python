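"""Shared data containers for the fNIRS network-analysis pipeline.

A *Recording* is one subject's multichannel hemodynamic concentration time
series (channels x samples).  Downstream stages reduce it to a channel-wise
Pearson :class:`CorrelationMatrix`, binarize that at a sparsity threshold
into a :class:`BinaryGraph`, and summarize graph metrics over the sparsity
grid.  Trait scores ride along per subject for the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SIGNAL_TYPES = ("HbO", "HbR", "HbT")

#: Five-factor model dimensions in the O,C,E,A,N order used throughout.
TRAIT_FACTORS = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)

#: Attainable range of a 12-item, 1-5 Likert factor total.
TRAIT_SCORE_MIN = 12.0
TRAIT_SCORE_MAX = 60.0


class DegenerateChannelError(ValueError):
    """A channel has zero variance, so Pearson correlation is undefined."""


class SegmentError(ValueError):
    """The recording is too short for the requested analysis segment."""


class InvalidSpecError(ValueError):
    """A generator or analysis specification violates its invariants."""


@dataclass
class Recording:
    """One subject's channels x samples concentration matrix."""

    data: np.ndarray
    sampling_rate_hz: float
    signal_type: str = "HbO"
    channel_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise InvalidSpecError("sampling_rate_hz must be positive")
        if self.signal_type not in SIGNAL_TYPES:
            raise InvalidSpecError(
                f"signal_type must be one of {SIGNAL_TYPES}, got {self.signal_type!r}"
            )
        if self.channel_ids is None:
            self.channel_ids = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise InvalidSpecError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class TraitScores:
    """NEO five-factor totals, each a 12-item sum in [12, 60]."""

    openness: float
    conscientiousness: float
    extraversion: float
    agreeableness: float
    neuroticism: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in TRAIT_FACTORS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "TraitScores":
        return cls(**dict(zip(TRAIT_FACTORS, map(float, values))))


@dataclass
class CorrelationMatrix:
    """Symmetric channel x channel Pearson matrix with unit diagonal."""

    values: np.ndarray
    channel_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidSpecError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidSpecError("correlation matrix must be symmetric")
        self.values = v
        if self.channel_ids is None:
            self.channel_ids = [f"CH{i + 1:02d}" for i in range(v.shape[0])]
        self.channel_ids = list(self.channel_ids)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected, unweighted adjacency at one sparsity level.

    ``sparsity`` is the fraction of realized edges out of N(N-1)/2 possible;
    ``threshold`` is the smallest |r| admitted as an edge (nan when edgeless).
    """

    adjacency: np.ndarray
    sparsity: float = np.nan
    threshold: float = np.nan

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidSpecError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise InvalidSpecError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise InvalidSpecError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise InvalidSpecError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class SparsityGrid:
    """Inclusive sparsity grid S_1..S_n; default 0:0.01:1 (101 points)."""

    start: float = 0.0
    stop: float = 1.0
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.stop <= 1.0):
            raise InvalidSpecError("grid requires 0 <= start < stop <= 1")
        if self.step <= 0:
            raise InvalidSpecError("grid step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step))
        grid = self.start + self.step * np.arange(n + 1)
        # guard against float drift past the stop value
        return np.round(np.minimum(grid, self.stop), 12)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GraphMetrics:
    """All global and nodal topology metrics of one binary graph.

    ``l_p`` is nan for edgeless graphs (no reachable pair; the mean over
    reachable pairs is undefined).  Nodal vectors are None when the graph
    was measured in global-only mode (used for null ensembles).
    """

    c_p: float
    l_p: float
    e_glob: float
    e_loc: float
    k_nodal: np.ndarray | None = None
    e_nodal: np.ndarray | None = None
    e_loc_nodal: np.ndarray | None = None
    n_bc: np.ndarray | None = None
    c_nodal: np.ndarray | None = None

    #: metric names measured on null ensembles and z-scored in the sweep
    GLOBAL_NAMES = ("c_p", "l_p", "e_glob", "e_loc")

    def global_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.GLOBAL_NAMES}
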