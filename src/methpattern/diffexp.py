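"""Phenotype-related genes: moderated F-test, BH adjustment, Cox screen.

Differential expression across the modification patterns uses a one-way
linear model per gene with empirical-Bayes variance moderation: residual
variances are shrunk toward a common prior whose degrees of freedom and
scale are moment-matched on ``log s_g^2`` (digamma/trigamma equations),
and the F statistic uses the posterior variance on inflated denominator
degrees of freedom.  Prognostic screening fits a univariate Cox
proportional-hazards model per gene (Newton-Raphson on the Efron-tie
partial likelihood, vectorized across genes).  The signature is the
intersection of both filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "moderated_f_test",
    "bh_adjust",
    "univariate_cox_screen",
    "derive_signature",
    "GeneSignature",
    "trigamma_inverse",
]


def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to the gene-wise variances.

    Returns ``(d0, s0^2)``: prior degrees of freedom (may be ``inf``) and
    prior scale, estimated from ``log s2`` via the digamma/trigamma
    moments of the log chi-square distribution.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1)
    evar -= special.polygamma(1, df / 2)
    if evar > 0:
        d0 = 2 * trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        # no excess spread beyond sampling noise: infinite prior df; the
        # common variance is the plain average of the gene variances
        d0 = np.inf
        s0_2 = s2[ok].mean()
    return float(d0), float(s0_2)


def moderated_f_test(expr: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Empirical-Bayes moderated one-way F-test per gene.

    Parameters
    ----------
    expr
        genes x samples matrix.
    groups
        group label per sample (>= 2 groups, each with >= 2 samples).

    Returns a DataFrame with per-group means, the moderated F, raw p and
    BH-adjusted p; all-constant genes get ``p = 1`` and ``flagged=True``.
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("moderated_f_test needs >= 2 groups")
    masks = {g: (groups == g).to_numpy() for g in levels}
    for g, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples")

    X = expr.to_numpy(dtype=float)
    n = X.shape[1]
    k = len(levels)
    d_resid = n - k

    group_means = np.column_stack([X[:, masks[g]].mean(axis=1) for g in levels])
    sizes = np.array([masks[g].sum() for g in levels])
    grand = (group_means * sizes).sum(axis=1) / n
    ss_between = (sizes * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ms_between = ss_between / (k - 1)

    fitted = np.empty_like(X)
    for j, g in enumerate(levels):
        fitted[:, masks[g]] = group_means[:, [j]]
    ss_resid = ((X - fitted) ** 2).sum(axis=1)
    s2 = ss_resid / d_resid

    d0, s0_2 = _fit_f_dist(s2, d_resid)
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + d_resid * s2) / (d0 + d_resid)
    else:
        s2_post = np.full_like(s2, s0_2)

    # genes constant across every sample: no information, F undefined
    flagged = (ss_between + ss_resid) <= 0
    s2_safe = np.where(s2_post <= 0, 1.0, s2_post)
    F = ms_between / s2_safe
    if np.isfinite(d0):
        p = stats.f.sf(F, k - 1, d_resid + d0)
    else:
        p = stats.chi2.sf(F * (k - 1), k - 1)
    p = np.where(flagged, 1.0, p)

    out = pd.DataFrame(
        {f"mean_{g}": group_means[:, j] for j, g in enumerate(levels)},
        index=expr.index,
    )
    out["F_statistic"] = np.where(flagged, np.nan, F)
    out["p_value"] = p
    out["adj_p"] = bh_adjust(p)
    out["flagged"] = flagged
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["s2_post"] = s2_post
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# fast univariate Cox screen (Efron ties), vectorized across genes
# ---------------------------------------------------------------------------


def _efron_terms(time: np.ndarray, event: np.ndarray):
    """Precompute sorting and tie bookkeeping shared by all genes."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    ev_pos = np.nonzero(e)[0]
    if ev_pos.size == 0:
        raise ValueError("no events; Cox model cannot be fit")
    # group events by tied time; risk set starts at the first index with
    # the same time value (censored at t remain at risk for events at t)
    first_at_time = np.searchsorted(t, t[ev_pos], side="left")
    ev_times = t[ev_pos]
    _, group_idx, group_counts = np.unique(
        ev_times, return_inverse=True, return_counts=True
    )
    # l within group, fraction l/d per event term
    l_within = np.zeros(ev_pos.size, dtype=int)
    seen: dict[float, int] = {}
    for i, gt in enumerate(ev_times):
        l_within[i] = seen.get(gt, 0)
        seen[gt] = l_within[i] + 1
    frac = l_within / group_counts[group_idx]
    return order, t, e, ev_pos, first_at_time, group_idx, group_counts, frac


def _cox_pass(X, beta, prep):
    """Log-likelihood, score and information for every gene at ``beta``."""
    order, t, e, ev_pos, first_at_time, group_idx, group_counts, frac = prep
    Xs = X[:, order]
    z = np.clip(beta[:, None] * Xs, -700, 700)
    w = np.exp(z)
    wx = w * Xs
    wx2 = wx * Xs
    r0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    r1 = np.cumsum(wx[:, ::-1], axis=1)[:, ::-1]
    r2 = np.cumsum(wx2[:, ::-1], axis=1)[:, ::-1]

    n_groups = group_counts.size
    D0 = np.zeros((X.shape[0], n_groups))
    D1 = np.zeros_like(D0)
    D2 = np.zeros_like(D0)
    np.add.at(D0.T, group_idx, w[:, ev_pos].T)
    np.add.at(D1.T, group_idx, wx[:, ev_pos].T)
    np.add.at(D2.T, group_idx, wx2[:, ev_pos].T)

    R0 = r0[:, first_at_time]
    R1 = r1[:, first_at_time]
    R2 = r2[:, first_at_time]
    phi0 = R0 - frac * D0[:, group_idx]
    phi1 = R1 - frac * D1[:, group_idx]
    phi2 = R2 - frac * D2[:, group_idx]
    phi0 = np.maximum(phi0, np.finfo(float).tiny)

    x_events = Xs[:, ev_pos]
    loglik = (beta[:, None] * x_events).sum(axis=1) - np.log(phi0).sum(axis=1)
    score = x_events.sum(axis=1) - (phi1 / phi0).sum(axis=1)
    info = (phi2 / phi0 - (phi1 / phi0) ** 2).sum(axis=1)
    return loglik, score, info


def _cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 50, tol: float = 1e-8):
    """Univariate Efron Cox fits for every row of ``X`` simultaneously."""
    prep = _efron_terms(time, event)
    G = X.shape[0]
    beta = np.zeros(G)
    loglik, score, info = _cox_pass(X, beta, prep)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_pass(X, new_beta, prep)
        # step-halving where the likelihood worsened
        for _h in range(10):
            worse = (new_ll < loglik - 1e-12) & ~converged
            if not worse.any():
                break
            step = np.where(worse, step / 2, step)
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_pass(X, new_beta, prep)
        moved = ~converged
        beta = np.where(moved, new_beta, beta)
        loglik = np.where(moved, new_ll, loglik)
        score = np.where(moved, new_score, score)
        info = np.where(moved, new_info, info)
        converged |= np.abs(score) < tol
        if converged.all():
            break
    diverged = np.abs(beta) > 15
    se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    return beta, se, converged & ~diverged, loglik


def univariate_cox_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: list[str] | None = None,
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Per-gene univariate Cox PH screen on continuous expression.

    Returns a table of log hazard ratios with Wald tests and 95% CIs;
    constant or non-converged genes are flagged and excluded.
    """
    if genes is None:
        genes = list(expr.index)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    common = expr.columns.intersection(clinical.index)
    if len(common) < 3:
        raise ValueError("too few samples shared between expression and clinical")
    clin = clinical.loc[common]
    time = clin[time_col].to_numpy(dtype=float)
    event = clin[event_col].to_numpy(dtype=float)
    if np.nansum(event) == 0:
        raise ValueError("zero events; Cox screen impossible")
    keep = ~(np.isnan(time) | np.isnan(event))
    time, event = time[keep], event[keep]
    X = expr.loc[genes, common].to_numpy(dtype=float)[:, keep]

    constant = X.std(axis=1) == 0
    beta = np.full(len(genes), np.nan)
    se = np.full(len(genes), np.nan)
    conv = np.zeros(len(genes), dtype=bool)
    if (~constant).any():
        b, s, c, _ = _cox_newton(X[~constant], time, event)
        beta[~constant], se[~constant], conv[~constant] = b, s, c

    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "beta": beta,
            "HR": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "se": se,
            "p_value": p,
        },
        index=pd.Index(genes, name="gene"),
    )
    usable = conv & ~constant & np.isfinite(p)
    out.attrs["n_flagged"] = int((~usable).sum())
    return out[usable]


@dataclass
class GeneSignature:
    """Prognostic differential-expression signature."""

    genes: list[str]
    directions: dict[str, int]  # sign of the Cox log hazard ratio
    deg_threshold: float
    cox_threshold: float

    def __len__(self) -> int:
        return len(self.genes)


def derive_signature(
    deg_table: pd.DataFrame,
    cox_table: pd.DataFrame,
    deg_threshold: float = 0.01,
    cox_threshold: float = 0.01,
) -> GeneSignature:
    """Intersect the DEG filter (``adj_p < deg_threshold``) with the
    prognostic filter (``Cox p < cox_threshold``).

    Genes are ordered by DEG adjusted p, then symbol, so the signature is
    deterministic.
    """
    deg_pass = deg_table.loc[deg_table["adj_p"] < deg_threshold]
    cox_pass = cox_table.loc[cox_table["p_value"] < cox_threshold]
    shared = deg_pass.index.intersection(cox_pass.index)
    if len(shared) == 0:
        raise ValueError(
            "empty signature: no gene passes both the DEG and Cox filters"
        )
    ordered = (
        deg_pass.loc[shared]
        .assign(_sym=lambda d: d.index)
        .sort_values(["adj_p", "_sym"])
        .index.tolist()
    )
    directions = {g: int(np.sign(cox_table.loc[g, "beta"])) for g in ordered}
    return GeneSignature(ordered, directions, deg_threshold, cox_threshold)
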