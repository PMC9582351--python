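"""Parametric empirical-Bayes batch correction (ComBat).

Per-gene expression is standardized against a batch-size-weighted grand
model; batch location effects get a normal prior and batch scale effects
an inverse-gamma prior, with hyperparameters moment-matched across genes
and the conditional posterior means solved iteratively; the adjusted data
are back-transformed to the original scale.  Only the intercept model is
supported (no covariates) and only parametric priors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["combat_adjust"]

log = logging.getLogger(__name__)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _posterior_solve(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior means of (gamma*, delta2*) for one
    batch; ``z`` is the standardized data restricted to the batch."""
    n = z.shape[1]
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + delta_star * gamma_bar) / (
            n * tau2 + delta_star
        )
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - gamma_star).max(initial=0.0),
            np.abs(d_new - delta_star).max(initial=0.0),
        )
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


def combat_adjust(expr: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Remove additive/multiplicative batch effects from ``expr``.

    Parameters
    ----------
    expr
        genes x samples log-scale expression.
    batch
        batch label per sample (index must cover ``expr.columns``).

    Zero-variance genes cannot be standardized; they are passed through
    unchanged and logged.
    """
    batch = batch.reindex(expr.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = batch.unique()
    if len(levels) < 2:
        raise ValueError("combat_adjust needs >= 2 batches")
    masks = {b: (batch == b).to_numpy() for b in levels}
    for b, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"batch {b!r} has < 2 samples")

    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    n_b = {b: m.sum() for b, m in masks.items()}

    # batch-wise gene means and the size-weighted grand mean
    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([n_b[b] / n_samples for b in levels])
    grand_mean = batch_means @ weights
    resid = X.copy()
    for j, b in enumerate(levels):
        resid[:, masks[b]] = X[:, masks[b]] - batch_means[:, [j]]
    pooled_var = (resid**2).mean(axis=1)

    constant = pooled_var <= 0
    if constant.any():
        log.warning(
            "combat_adjust: %d zero-variance gene(s) passed through unadjusted",
            int(constant.sum()),
        )
    pooled_sd = np.sqrt(np.where(constant, 1.0, pooled_var))

    Z = (X - grand_mean[:, None]) / pooled_sd[:, None]

    adjusted = Z.copy()
    for j, b in enumerate(levels):
        m = masks[b]
        zb = Z[:, m]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        a, bb = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star, delta_star = _posterior_solve(
            zb, gamma_hat, delta_hat, gamma_bar, tau2, a, bb
        )
        adjusted[:, m] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * pooled_sd[:, None] + grand_mean[:, None]
    out[constant] = X[constant]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
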