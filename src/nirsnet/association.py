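"""NEO-FFI scoring and trait - network-metric association.

The five-factor inventory has 60 items, 12 per factor, each rated 1-5;
reverse-keyed items contribute (6 - raw).  Factor totals therefore span
[12, 60].  The published item-to-factor keying is licensed test content, so
the default map here is a documented placeholder (items assigned cyclically
N, E, O, A, C with no reverse keying); studies with the real instrument
supply their own map.

Association correlates each trait with each global network AUC (C_p, L_p,
E_glob, E_loc) across subjects: Pearson r with the two-tailed p from the
t transform, t = r * sqrt((n-2)/(1-r^2)), flagged at 0.05 (*) and 0.01 (**).
Raw (uncorrected) p-values are the default across the 20 cells; an optional
Benjamini-Hochberg column is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TRAIT_FACTORS, TraitScores
from .sweep import SubjectNetworkProfile

#: global metrics entering the association table, in report order
ASSOCIATION_METRICS = ("c_p", "l_p", "e_glob", "e_loc")

N_ITEMS = 60
ITEMS_PER_FACTOR = 12
LIKERT_MIN, LIKERT_MAX = 1, 5

#: placeholder keying: item i (1-based) -> factor, cycling N,E,O,A,C.
#: The real instrument's map (and its reverse-keyed items) is licensed
#: content and must be supplied by the user.
_CYCLE = ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness")
DEFAULT_ITEM_MAP = {i: _CYCLE[(i - 1) % 5] for i in range(1, N_ITEMS + 1)}
DEFAULT_REVERSE_KEYED: frozenset[int] = frozenset()


class ScoringError(ValueError):
    """An item response is missing or outside the 1-5 scale."""


def score_neoffi(
    responses: dict[int, int] | list[int],
    item_map: dict[int, str] | None = None,
    reverse_keyed: frozenset[int] | set[int] | None = None,
) -> TraitScores:
    """Score a 60-item response sheet into five factor totals.

    ``responses`` is a list of 60 ratings (item order 1..60) or a mapping
    item -> rating.  Raises :class:`ScoringError` naming the first missing
    or out-of-range item.
    """
    item_map = item_map or DEFAULT_ITEM_MAP
    reverse_keyed = DEFAULT_REVERSE_KEYED if reverse_keyed is None else frozenset(reverse_keyed)
    if not isinstance(responses, dict):
        responses = {i + 1: r for i, r in enumerate(responses)}
    counts = {f: 0 for f in TRAIT_FACTORS}
    for factor in item_map.values():
        counts[factor] += 1
    if any(c != ITEMS_PER_FACTOR for c in counts.values()):
        raise ScoringError(f"item map must assign 12 items per factor, got {counts}")
    totals = {f: 0.0 for f in TRAIT_FACTORS}
    for item, factor in item_map.items():
        if item not in responses or responses[item] is None:
            raise ScoringError(f"item {item} has no response")
        raw = responses[item]
        if not (LIKERT_MIN <= raw <= LIKERT_MAX) or raw != int(raw):
            raise ScoringError(f"item {item} response {raw!r} outside 1-5 scale")
        totals[factor] += (LIKERT_MAX + 1 - raw) if item in reverse_keyed else raw
    return TraitScores(**totals)


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r, two-tailed p (t transform, n-2 df) and the sample size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AssociationTable:
    """5 traits x 4 metrics of Pearson (r, p) across subjects."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def starred(self) -> pd.DataFrame:
        """Publication-style display: r with significance stars."""
        out = self.r.round(2).astype(str)
        for trait in self.r.index:
            for metric in self.r.columns:
                out.loc[trait, metric] += _stars(self.p.loc[trait, metric])
        return out

    def long_format(self, fdr: bool = False) -> pd.DataFrame:
        rows = []
        for trait in self.r.index:
            for metric in self.r.columns:
                rows.append(
                    {
                        "trait": trait,
                        "metric": metric,
                        "r": self.r.loc[trait, metric],
                        "p": self.p.loc[trait, metric],
                        "n": self.n,
                        "stars": _stars(self.p.loc[trait, metric]),
                    }
                )
        table = pd.DataFrame(rows)
        if fdr:
            table["p_fdr"] = _benjamini_hochberg(table["p"].to_numpy())
        return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank, idx in enumerate(order[::-1]):
        k = m - rank
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj


def trait_metric_table(profiles: list[SubjectNetworkProfile]) -> AssociationTable:
    """Correlate each trait with each global metric AUC across subjects.

    Subjects with an undefined AUC on a metric are excluded from that
    metric's column (a warning-worthy event surfaced by the pipeline log).
    """
    complete = [p for p in profiles if p.traits is not None]
    if len(complete) < 3:
        raise ValueError("need at least 3 profiles with trait scores")
    traits = np.array([p.traits.as_array() for p in complete])
    r = pd.DataFrame(index=list(TRAIT_FACTORS), columns=list(ASSOCIATION_METRICS),
                     dtype=float)
    pv = r.copy()
    n_used = len(complete)
    for j, metric in enumerate(ASSOCIATION_METRICS):
        y = np.array([p.global_aucs.get(metric, np.nan) for p in complete])
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        n_used = min(n_used, int(ok.sum()))
        for i, trait in enumerate(TRAIT_FACTORS):
            rr, pp, _ = pearson_with_p(traits[ok, i], y[ok])
            r.loc[trait, metric] = rr
            pv.loc[trait, metric] = pp
    return AssociationTable(r=r, p=pv, n=n_used)
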