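"""Three-strategy consensus caller for Ph-like gene expression.

Ph-like (Philadelphia-chromosome-like) B-cell precursor ALL is defined by
its expression profile rather than a single lesion.  Cases are flagged by
three independent strategies built on a signed probe-level signature
(nearest-shrunken-centroid "PAM" factors):

1. a mock PAM score — the sum of expression values weighted by the per-gene
   signature factor — flagging the top 5% of samples;
2. hierarchical clustering on all signature genes, flagging the cluster
   whose mean mock-PAM score is highest;
3. hierarchical clustering on the 25 signature genes most significant in an
   independent labelled reference cohort, flagged the same way.

Samples selected by at least two strategies receive the consensus call.
Genes measured by multiple probes resolve to the mean of their factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .diffexpr import moderated_t_test

__all__ = [
    "PhLikeCall",
    "resolve_signature",
    "mock_pam_score",
    "cluster_call",
    "derive_top25",
    "consensus_call",
    "call_phlike",
]


@dataclass
class PhLikeCall:
    sample: str
    flag_pam: bool
    flag_cluster_full: bool
    flag_cluster_top25: bool

    @property
    def strategy_count(self) -> int:
        return int(self.flag_pam) + int(self.flag_cluster_full) + int(self.flag_cluster_top25)

    @property
    def consensus(self) -> bool:
        return self.strategy_count >= 2


def resolve_signature(signature: pd.DataFrame) -> pd.Series:
    """Per-gene signed factor; genes with several probes get the mean factor."""
    required = {"gene", "factor"}
    if not required <= set(signature.columns):
        raise ValueError(f"signature table needs columns {sorted(required)}")
    return signature.groupby("gene")["factor"].mean().rename("factor")


def mock_pam_score(
    matrix: pd.DataFrame, signature: pd.DataFrame, top_fraction: float = 0.05
) -> tuple[pd.Series, pd.Series]:
    """Signature-weighted expression sum per sample, and the top-5% flag.

    The flag covers the ceil(top_fraction * n_samples) highest scores;
    samples tied with the boundary score are all included, so the flagged
    count can exceed the nominal one only under exact ties.
    """
    factors = resolve_signature(signature)
    measured = factors.index.intersection(matrix.index)
    if measured.empty:
        raise ValueError("no signature gene is measured in the expression matrix")
    if len(measured) < len(factors):
        warnings.warn(
            f"{len(factors) - len(measured)} signature genes not measured; dropped",
            stacklevel=2,
        )
    scores = matrix.loc[measured].T @ factors.loc[measured]
    scores.name = "pam_score"
    k = math.ceil(top_fraction * matrix.shape[1])
    cutoff = scores.sort_values(ascending=False).iloc[k - 1]
    flags = (scores >= cutoff).rename("flag_pam")
    return scores, flags


def cluster_call(
    matrix: pd.DataFrame,
    feature_genes: Sequence[str],
    signature: pd.DataFrame,
    k: int = 2,
    method: str = "average",
    metric: str = "correlation",
) -> pd.Series:
    """Flag the hierarchical cluster most compatible with the signature.

    Samples are clustered on the feature-gene submatrix (average linkage on
    correlation distance by default) and cut into ``k`` clusters; the
    cluster with the highest mean mock-PAM score is flagged.  If the cut
    yields a single effective cluster, no sample is flagged and a warning
    is raised.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds the sample count {matrix.shape[1]}")
    features = [g for g in feature_genes if g in matrix.index]
    if not features:
        raise ValueError("no feature gene is measured in the expression matrix")
    sub = matrix.loc[features].T.to_numpy(dtype=float)
    dist = pdist(sub, metric=metric)
    if not np.all(np.isfinite(dist)):
        # zero-variance samples make correlation distance undefined
        warnings.warn("degenerate distances (constant samples); treated as identical",
                      stacklevel=2)
        dist = np.nan_to_num(dist, nan=0.0)
    assignment = fcluster(linkage(dist, method=method), t=k, criterion="maxclust")
    labels = pd.Series(assignment, index=matrix.columns)
    if labels.nunique() < 2:
        warnings.warn("clustering produced a single cluster; flagging no sample",
                      stacklevel=2)
        return pd.Series(False, index=matrix.columns, name="flag_cluster")
    scores, _ = mock_pam_score(matrix, signature)
    best = scores.groupby(labels).mean().idxmax()
    return (labels == best).rename("flag_cluster")


def derive_top25(
    reference_matrix: pd.DataFrame,
    reference_labels: Sequence[bool] | pd.Series,
    candidate_genes: Sequence[str],
    n_top: int = 25,
) -> list[str]:
    """Most significant signature genes in a labelled reference cohort.

    Moderated-t p-values are computed between the reference classes over
    the candidate pool; the ``n_top`` smallest-p genes are returned, ties
    broken by |log2FC| (descending) then gene symbol.
    """
    labels = pd.Series(list(reference_labels), index=reference_matrix.columns)
    if labels.nunique() != 2:
        raise ValueError("reference labels must contain both classes")
    pool = [g for g in candidate_genes if g in reference_matrix.index]
    if not pool:
        raise ValueError("no candidate gene is measured in the reference")
    if len(pool) < n_top:
        warnings.warn(
            f"candidate pool ({len(pool)}) smaller than {n_top}; returning all",
            stacklevel=2,
        )
    de = moderated_t_test(reference_matrix.loc[pool], labels.map({True: "pos", False: "neg"}))
    de = de.assign(_abs_fc=de["log2fc"].abs(), _gene=de.index)
    de = de.sort_values(["p", "_abs_fc", "_gene"], ascending=[True, False, True])
    return list(de.index[:n_top])


def consensus_call(
    flags_pam: Sequence[bool] | pd.Series,
    flags_full: Sequence[bool] | pd.Series,
    flags_top25: Sequence[bool] | pd.Series,
    sample_ids: Sequence[str] | None = None,
) -> list[PhLikeCall]:
    """Combine the three strategy flags under the at-least-two rule."""
    f1, f2, f3 = (pd.Series(list(f)) for f in (flags_pam, flags_full, flags_top25))
    if not (len(f1) == len(f2) == len(f3)):
        raise ValueError("strategy flag vectors differ in length")
    if sample_ids is None:
        for f in (flags_pam, flags_full, flags_top25):
            if isinstance(f, pd.Series):
                sample_ids = list(f.index)
                break
        else:
            sample_ids = [str(i) for i in range(len(f1))]
    return [
        PhLikeCall(sample=s, flag_pam=bool(a), flag_cluster_full=bool(b),
                   flag_cluster_top25=bool(c))
        for s, a, b, c in zip(sample_ids, f1, f2, f3)
    ]


def call_phlike(
    matrix: pd.DataFrame,
    signature: pd.DataFrame,
    reference_matrix: pd.DataFrame | None = None,
    reference_labels: Sequence[bool] | pd.Series | None = None,
    k: int = 2,
) -> pd.DataFrame:
    """Run all three strategies and the consensus on one cohort.

    Without a labelled reference the top-25 strategy cannot run; the
    consensus then requires both remaining strategies.
    """
    factors = resolve_signature(signature)
    _, flags_pam = mock_pam_score(matrix, signature)
    flags_full = cluster_call(matrix, list(factors.index), signature, k=k)
    if reference_matrix is not None:
        if reference_labels is None:
            raise ValueError("reference_labels required with a reference matrix")
        top25 = derive_top25(reference_matrix, reference_labels, list(factors.index))
        flags_top25 = cluster_call(matrix, top25, signature, k=k)
    else:
        warnings.warn("no reference cohort; consensus uses two strategies only",
                      stacklevel=2)
        flags_top25 = pd.Series(False, index=matrix.columns)
    calls = consensus_call(flags_pam, flags_full, flags_top25, list(matrix.columns))
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "flag_pam": [c.flag_pam for c in calls],
            "flag_cluster_full": [c.flag_cluster_full for c in calls],
            "flag_cluster_top25": [c.flag_cluster_top25 for c in calls],
            "strategy_count": [c.strategy_count for c in calls],
            "consensus": [c.consensus for c in calls],
        }
    ).set_index("sample")
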