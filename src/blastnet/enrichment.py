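"""Gene-set statistics: preranked GSEA, overrepresentation, and 2x2 tests.

The preranked gene set enrichment analysis is the classic weighted
Kolmogorov--Smirnov running sum: walking down the ranked list, hits
increment the sum proportionally to |stat|^weight (normalized over the
set), misses decrement it by 1/(N - n_set); the enrichment score is the
signed extremum.  Significance comes from gene-label permutation, and the
normalized score divides by the mean permuted |ES| of the same sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "GseaResult",
    "read_gmt",
    "preranked_gsea",
    "hypergeometric_overrepresentation",
    "fisher_exact_2x2",
    "yates_chi2",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    leading_edge: list[str]
    n_hits: int


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (name, description, members...; tab-separated)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], members=frozenset(filter(None, parts[2:]))))
    return sets


def _running_es(hit_mask: np.ndarray, weights: np.ndarray, n_total: int) -> tuple[float, int]:
    """Signed extremum of the running sum; returns (ES, extremum position)."""
    n_hits = int(hit_mask.sum())
    steps = np.where(hit_mask, weights / weights[hit_mask].sum(), -1.0 / (n_total - n_hits))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def preranked_gsea(
    ranked_stats: Mapping[str, float] | pd.Series,
    gene_set: GeneSet | Sequence[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> GseaResult:
    """Weighted KS enrichment of a gene set in a ranked statistic.

    ``ranked_stats`` maps gene -> ranking statistic (e.g. the moderated t);
    genes are sorted by the statistic in decreasing order internally.  The
    null is permutation of gene labels, i.e. random same-size member sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    series = pd.Series(ranked_stats, dtype=float).sort_values(ascending=False)
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    name = gene_set.name if isinstance(gene_set, GeneSet) else "gene_set"
    hit_mask = series.index.isin(members)
    n_hits = int(hit_mask.sum())
    n_total = series.size
    if n_hits == 0:
        raise ValueError(f"gene set {name!r} does not intersect the ranking")
    if n_hits == n_total:
        raise ValueError(f"gene set {name!r} covers the entire ranking")
    w = np.abs(series.to_numpy()) ** weight

    es, extremum = _running_es(hit_mask, w, n_total)
    if es >= 0:
        leading = list(series.index[: extremum + 1][hit_mask[: extremum + 1]])
    else:
        leading = list(series.index[extremum:][hit_mask[extremum:]])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    mask = np.zeros(n_total, dtype=bool)
    for b in range(n_perm):
        mask[:] = False
        mask[rng.choice(n_total, size=n_hits, replace=False)] = True
        perm_es[b], _ = _running_es(mask, w, n_total)

    same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
    n_sign = int(same_sign.sum())
    more_extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
    p = (more_extreme + 1) / (n_sign + 1)
    mean_abs = float(np.abs(perm_es[same_sign]).mean()) if n_sign else np.nan
    nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
    return GseaResult(name=name, es=es, nes=nes, p=p, leading_edge=leading, n_hits=n_hits)


def hypergeometric_overrepresentation(
    selected: Sequence[str] | set[str],
    gene_set: Sequence[str] | set[str] | GeneSet,
    universe: Sequence[str] | set[str],
) -> float:
    """Upper-tail hypergeometric p for the selected/set overlap."""
    universe = set(universe)
    selected = set(selected) & universe
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    outside = members - universe
    if outside:
        warnings.warn(f"{len(outside)} set members outside the universe were trimmed",
                      stacklevel=2)
        members = members & universe
    k = len(selected & members)
    if not selected or not members:
        return 1.0
    # P(overlap >= k) for drawing |selected| genes from the universe
    return float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(selected)))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Conditional odds ratio and two-sided Fisher exact p for a 2x2 table.

    Two-sidedness follows the point-probability convention (summing all
    tables with fixed margins whose probability does not exceed the
    observed one).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2) or np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("expected a non-negative integer 2x2 table")
    odds_ratio = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return odds_ratio, float(p)


def yates_chi2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Chi-square statistic with Yates' continuity correction on a 2x2 table.

    The correction is clamped so |O - E| - 1/2 never goes negative; p is
    the upper tail of the chi-square distribution with one degree of
    freedom.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    statistic, p, _, expected = stats.chi2_contingency(arr, correction=True)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(statistic), float(p)
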