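"""End-of-induction MRD outcome models for immunophenotype covariates.

MRD is a proportion on [10^-5, 1] after censoring (assay results below the
limit of detection are set to 10^-5).  Associations are modelled by
ordinary least squares on log10 MRD, so an exponentiated coefficient 10^b
is the fold change in MRD level relative to the covariate's reference
level — the scale on which marker effects are reported.  Variable
selection combines forward and backward stepwise search on AIC, keeping
the union of selections that remain below p = 0.05.  Predictive value of
binary phenotypes uses the ROC AUC with MRD >= 0.001 as the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import BELOW_LOD

__all__ = [
    "ModelFit",
    "censor_mrd",
    "fit_log_mrd_model",
    "select_model_aic",
    "roc_auc",
    "spearman",
]

MRD_FLOOR = 1e-5
HIGH_MRD_CUTOFF = 1e-3


class SingularDesignError(ValueError):
    pass


@dataclass
class ModelFit:
    """OLS fit on log10 MRD with fold-scale effect estimates."""

    covariates: list[str]
    effects: pd.DataFrame  # term, beta, fold, fold_lo, fold_hi, p, p_bonferroni
    aic: float
    n: int
    results: object = field(repr=False, default=None)


def censor_mrd(values: Sequence, lod: float = MRD_FLOOR) -> np.ndarray:
    """Apply the below-LOD rule: sentinel and sub-LOD values become 10^-5."""
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if isinstance(v, str):
            if v == BELOW_LOD:
                out[i] = MRD_FLOOR
                continue
            try:
                v = float(v)  # TSV round-trips read the mixed column as text
            except ValueError:
                raise ValueError(f"unrecognized MRD value {v!r}") from None
        else:
            v = float(v)
        if v > 1.0:
            raise ValueError(f"MRD {v} exceeds 1 (must be a proportion)")
        out[i] = MRD_FLOOR if v < lod else v
    return out


def _design_matrix(
    records: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-code categorical covariates against their reference levels.

    Quantitative ``age`` enters as age/10 so its effect reads per 10-year
    increase; other numeric columns enter untransformed.
    """
    reference_levels = dict(reference_levels or {})
    parts = []
    for cov in covariates:
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col):
            values = col.astype(float) / 10.0 if cov == "age" else col.astype(float)
            parts.append(values.rename(cov))
        else:
            levels = sorted(col.unique())
            ref = reference_levels.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"{cov}: reference level {ref!r} not observed")
            for level in levels:
                if level == ref:
                    continue
                parts.append((col == level).astype(float).rename(f"{cov}[{level}]"))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=records.index)
    X.insert(0, "Intercept", 1.0)
    return X


def fit_log_mrd_model(
    records: pd.DataFrame,
    covariates: Sequence[str],
    mrd_col: str = "mrd",
    reference_levels: Mapping[str, str] | None = None,
    bonferroni_family: int | None = None,
) -> ModelFit:
    """OLS of log10(censored MRD) on the given covariates.

    Effects are reported as fold changes 10^b with Wald 95% confidence
    intervals; a Bonferroni-adjusted p column is included, with the family
    size defaulting to the number of covariates.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 patient records")
    y = np.log10(censor_mrd(list(records[mrd_col])))
    X = _design_matrix(records, covariates, reference_levels)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise SingularDesignError(f"singular design; aliased terms: {aliased}")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    family = bonferroni_family if bonferroni_family is not None else max(1, len(covariates))
    effects = pd.DataFrame(
        {
            "beta": res.params,
            "fold": 10.0**res.params,
            "fold_lo": 10.0 ** ci[0],
            "fold_hi": 10.0 ** ci[1],
            "p": res.pvalues,
            "p_bonferroni": np.minimum(1.0, res.pvalues * family),
        }
    )
    return ModelFit(
        covariates=list(covariates),
        effects=effects,
        aic=float(res.aic),
        n=int(res.nobs),
        results=res,
    )


def _aic_of(records: pd.DataFrame, covs: list[str], mrd_col: str,
            reference_levels: Mapping[str, str] | None) -> float:
    y = np.log10(censor_mrd(list(records[mrd_col])))
    X = _design_matrix(records, covs, reference_levels)
    return float(sm.OLS(y, X).fit().aic)


def select_model_aic(
    records: pd.DataFrame,
    candidates: Sequence[str],
    mrd_col: str = "mrd",
    reference_levels: Mapping[str, str] | None = None,
    p_cutoff: float = 0.05,
) -> ModelFit:
    """Forward and backward stepwise AIC selection with a p-value filter.

    The final model is the union of the covariates chosen by the two
    searches, restricted to those whose terms stay below ``p_cutoff`` in
    the union fit, then refitted.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate covariates")

    # forward
    selected: list[str] = []
    current = _aic_of(records, selected, mrd_col, reference_levels)
    improved = True
    while improved:
        improved = False
        best_aic, best_cov = current, None
        for cov in candidates:
            if cov in selected:
                continue
            aic = _aic_of(records, selected + [cov], mrd_col, reference_levels)
            if aic < best_aic - 1e-9:
                best_aic, best_cov = aic, cov
        if best_cov is not None:
            selected.append(best_cov)
            current = best_aic
            improved = True
    forward = set(selected)

    # backward
    selected = list(candidates)
    current = _aic_of(records, selected, mrd_col, reference_levels)
    improved = True
    while improved and selected:
        improved = False
        best_aic, best_cov = current, None
        for cov in selected:
            rest = [c for c in selected if c != cov]
            aic = _aic_of(records, rest, mrd_col, reference_levels)
            if aic < best_aic - 1e-9:
                best_aic, best_cov = aic, cov
        if best_cov is not None:
            selected.remove(best_cov)
            current = best_aic
            improved = True
    backward = set(selected)

    union = [c for c in candidates if c in forward | backward]
    if not union:
        warnings.warn("no covariate survived stepwise selection; intercept-only model",
                      stacklevel=2)
        fit = fit_log_mrd_model(records, [], mrd_col, reference_levels)
        fit.covariates = []
        return fit
    union_fit = fit_log_mrd_model(records, union, mrd_col, reference_levels)
    keep = []
    for cov in union:
        terms = [t for t in union_fit.effects.index
                 if t == cov or t.startswith(f"{cov}[")]
        if any(union_fit.effects.loc[t, "p"] < p_cutoff for t in terms):
            keep.append(cov)
    return fit_log_mrd_model(records, keep, mrd_col, reference_levels) if keep else union_fit


def roc_auc(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC by pairwise concordance (ties score 1/2) with a bootstrap CI.

    The point estimate is the Mann--Whitney form: the mean rank of the
    positive class determines the probability a random positive outscores
    a random negative.  The CI is a stratified percentile bootstrap.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.size != y.size:
        raise ValueError("scores and outcomes differ in length")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")

    def _auc(sv: np.ndarray, yv: np.ndarray) -> float:
        ranks = stats.rankdata(sv)
        u = ranks[yv].sum() - yv.sum() * (yv.sum() + 1) / 2.0
        return float(u / (yv.sum() * (~yv).sum()))

    estimate = _auc(s, y)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, n1, replace=True), rng.choice(neg_idx, n0, replace=True)]
        )
        boots[b] = _auc(s[idx], y[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return estimate, (float(lo), float(hi))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; p by t approximation."""
    xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y differ in length")
    if xv.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)
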