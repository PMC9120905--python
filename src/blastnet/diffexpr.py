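"""Two-group differential expression with empirical-Bayes variance shrinkage.

The moderated t statistic shrinks each gene's pooled variance toward a prior
variance carrying ``prior_df`` pseudo-observations:

    s2_post = (prior_df * s2_prior + df * s2_g) / (prior_df + df)

with the statistic referred to a t distribution on df + prior_df degrees of
freedom.  The prior variance defaults to the mean of the per-gene pooled
variances; at prior_df = 0 the statistic reduces to the ordinary pooled
two-sample t.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "moderated_t_test",
    "bh_adjust",
    "select_seed_genes",
    "direction_counts",
]

#: |log2FC| at or below this value is called direction-neutral
NEUTRAL_LOG2FC = 0.1


def _group_masks(labels: Sequence[str] | pd.Series) -> tuple[np.ndarray, np.ndarray, str, str]:
    lab = pd.Series(list(labels))
    groups = sorted(pd.unique(lab))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    a, b = groups[0], groups[1]
    return (lab == a).to_numpy(), (lab == b).to_numpy(), str(a), str(b)


def moderated_t_test(
    matrix: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t test between the two label groups.

    Parameters
    ----------
    matrix
        log2 expression, genes in rows, samples in columns.
    labels
        One group label per sample column; the lexicographically smaller
        label is "group A" and log2FC is mean(A) - mean(B).
    prior_df
        Pseudo-observations behind the prior variance; 0 disables shrinkage.
    prior_var
        Prior variance; defaults to the mean of the per-gene pooled variances.

    Returns
    -------
    DataFrame indexed by gene with columns mean_a, mean_b, log2fc, t, p, q,
    direction.
    """
    if matrix.shape[1] != len(labels):
        raise ValueError("label length does not match sample count")
    if not np.all(np.isfinite(matrix.to_numpy())):
        raise ValueError("expression matrix contains non-finite values")
    if prior_df < 0:
        raise ValueError("prior_df must be non-negative")
    mask_a, mask_b, _, _ = _group_masks(labels)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 samples per group")

    x = matrix.to_numpy(dtype=float)
    xa, xb = x[:, mask_a], x[:, mask_b]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    df = n_a + n_b - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    s2_prior = float(np.mean(s2)) if prior_var is None else float(prior_var)
    denom_df = prior_df + df
    s2_post = (prior_df * s2_prior + df * s2) / denom_df

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    log2fc = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    degenerate = se == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with zero variance and zero prior; p set to 1",
            stacklevel=2,
        )
    p = 2.0 * stats.t.sf(np.abs(t), denom_df)
    p = np.where(degenerate, 1.0, p)

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t": t,
            "p": p,
        },
        index=matrix.index,
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.select(
        [out["log2fc"] > NEUTRAL_LOG2FC, out["log2fc"] < -NEUTRAL_LOG2FC],
        ["up-in-A", "up-in-B"],
        default="neutral",
    )
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_seed_genes(de: pd.DataFrame, q_cutoff: float = 0.05) -> list[str]:
    """Genes below the q cutoff, ordered by q then |log2FC| descending."""
    hits = de[de["q"] < q_cutoff].copy()
    hits["_abs_fc"] = hits["log2fc"].abs()
    hits = hits.sort_values(["q", "_abs_fc"], ascending=[True, False])
    return list(hits.index)


def direction_counts(
    de: pd.DataFrame, gene_set: Sequence[str] | set[str]
) -> tuple[int, int]:
    """Counts of set members up-regulated in group A and in group B.

    Membership is judged against the |log2FC| > 0.1 threshold; genes within
    the neutral band count in neither direction.  Genes absent from the DE
    table are dropped with a warning.
    """
    genes = list(gene_set)
    present = [g for g in genes if g in de.index]
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} genes not in the DE table were dropped",
            stacklevel=2,
        )
    fc = de.loc[present, "log2fc"]
    return int((fc > NEUTRAL_LOG2FC).sum()), int((fc < -NEUTRAL_LOG2FC).sum())
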