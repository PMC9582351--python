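"""Single-sample gene-set scoring and preranked GSEA.

``ssgsea_scores`` implements the rank-weighted single-sample enrichment
statistic: within each sample, genes are ranked by expression (average
ranks for ties) and the enrichment score integrates the difference
between the weighted in-set empirical CDF (weights ``|rank|**alpha``)
and the unweighted out-of-set ECDF over the descending-rank gene list.
Because it is rank-based, any within-sample monotone transform of
expression leaves the scores unchanged.

``estimate_scores`` builds ESTIMATE-style stromal/immune summaries from
two signature sets, with the combined score defined as their sum.

``preranked_gsea`` is the classical weighted Kolmogorov-Smirnov running
sum on a user-supplied ranking with a gene-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ssgsea_scores", "estimate_scores", "preranked_gsea", "GseaResult"]


def _sample_es(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA enrichment score for one sample.

    ``ranks``: per-gene expression ranks (ties averaged); ``in_set``:
    boolean membership mask.  Genes are walked in descending rank order;
    at each step the weighted in-set ECDF minus the uniform out-set ECDF
    is accumulated.
    """
    order = np.argsort(-ranks, kind="stable")
    member = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(member, w, 0.0)
    denom_in = w_in.sum()
    n_out = (~member).sum()
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum(~member) / n_out
    return float((cdf_in - cdf_out).sum())


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: dict[str, set[str] | list[str]],
    alpha: float = 0.25,
    min_set: int = 3,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA enrichment matrix (gene set x sample).

    Sets with fewer than ``min_set`` genes present in ``expr`` are
    dropped with a warning.  With ``normalize=True`` the whole matrix is
    divided by its range (max - min), the usual normalized-score
    convention.
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    genes = expr.index
    masks = {}
    for name, members in sets.items():
        mask = np.asarray(genes.isin(set(members)))
        if mask.sum() < min_set:
            warnings.warn(
                f"gene set {name!r}: only {int(mask.sum())} gene(s) present "
                f"(< {min_set}); dropped"
            )
            continue
        if mask.all():
            warnings.warn(f"gene set {name!r} covers every gene; dropped")
            continue
        masks[name] = mask
    if not masks:
        raise ValueError("no gene set has enough genes in the expression matrix")

    X = expr.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=0)  # average ranks within each sample
    # pre-sort once per sample; every set reuses the descending order
    orders = np.argsort(-ranks, axis=0, kind="stable")
    ranks_sorted = np.take_along_axis(ranks, orders, axis=0)
    weights_sorted = np.abs(ranks_sorted) ** alpha
    out = np.empty((len(masks), X.shape[1]))
    for i, mask in enumerate(masks.values()):
        member = mask[orders]  # genes x samples, in sorted order
        w_in = np.where(member, weights_sorted, 0.0)
        cdf_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0)
        cdf_out = np.cumsum(~member, axis=0) / (~member).sum(axis=0)
        out[i] = (cdf_in - cdf_out).sum(axis=0)
    scores = pd.DataFrame(out, index=list(masks), columns=expr.columns)
    scores.attrs["method"] = "ssgsea"
    scores.attrs["normalization"] = "range" if normalize else "none"
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            scores /= rng
    return scores


def estimate_scores(
    expr: pd.DataFrame,
    stromal_set: set[str] | list[str],
    immune_set: set[str] | list[str],
) -> pd.DataFrame:
    """Stromal, immune and combined (stromal + immune) scores per sample."""
    mat = ssgsea_scores(
        expr, {"stromal": stromal_set, "immune": immune_set}, normalize=False
    )
    out = mat.T.rename(columns={"stromal": "stromal_score", "immune": "immune_score"})
    out["estimate_score"] = out["stromal_score"] + out["immune_score"]
    return out


@dataclass
class GseaResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_perm: int


def _running_es(stat_sorted: np.ndarray, member: np.ndarray, weight: float
                ) -> tuple[float, int]:
    """Signed maximal deviation of the weighted KS running sum and the
    index at which it is attained."""
    w = np.abs(stat_sorted) ** weight
    w_in = np.where(member, w, 0.0)
    denom = w_in.sum()
    if denom == 0:
        denom = 1.0
    n_out = (~member).sum()
    run = np.cumsum(w_in / denom - (~member) / n_out)
    i_max = int(np.argmax(run))
    i_min = int(np.argmin(run))
    if abs(run[i_max]) >= abs(run[i_min]):
        return float(run[i_max]), i_max
    return float(run[i_min]), i_min


def preranked_gsea(
    ranking: pd.Series,
    gene_set: set[str] | list[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA for one gene set.

    The null is gene-label permutation: random sets of the same size
    drawn from the ranking.  The permutation p-value is two-sided on
    |ES| with a +1 pseudocount, hence never below ``1/(n_perm + 1)``;
    NES divides ES by the mean |null ES| of matching sign.
    """
    if ranking.isna().any():
        raise ValueError("ranking contains missing values")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    members = set(gene_set) & set(ranking.index)
    if len(members) < 3:
        raise ValueError("gene set shares < 3 genes with the ranking")

    order = np.argsort(-ranking.to_numpy(), kind="stable")
    genes_sorted = ranking.index.to_numpy()[order]
    stat_sorted = ranking.to_numpy()[order]
    member = np.isin(genes_sorted, list(members))
    es, i_star = _running_es(stat_sorted, member, weight)

    if es >= 0:
        leading = [g for g, m in zip(genes_sorted[: i_star + 1], member[: i_star + 1]) if m]
    else:
        leading = [g for g, m in zip(genes_sorted[i_star:], member[i_star:]) if m]

    rng = np.random.default_rng(seed)
    n = len(genes_sorted)
    s = len(members)
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=s, replace=False)] = True
        null_es[b], _ = _running_es(stat_sorted, mask, weight)

    p = (1 + int((np.abs(null_es) >= abs(es)).sum())) / (n_perm + 1)
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null_es).mean()
    nes = es / denom if denom > 0 else 0.0
    name = getattr(gene_set, "name", None) or "gene_set"
    return GseaResult(name, es, float(nes), float(p), leading, n_perm)
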