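"""The DNA methylation score (DMS).

The DMS summarizes a sample's position along the prognostic signature:
signature-gene expression is centered (and by default unit-variance
scaled), the first two principal axes are extracted, and each sample's
score is the **sum of its PC1 and PC2 projections**.  Each axis is
sign-oriented so that a higher score carries a higher hazard (positive
univariate Cox log-HR for overall survival); high DMS therefore means
worse prognosis.  Patients are stratified at the cutpoint maximizing the
standardized two-group log-rank statistic (maximally selected rank
statistics) subject to a minimum group-proportion constraint.

``DMSModel(expr, clinical, genes).fit()`` returns a :class:`DMSResults`
carrying the loadings, orientation diagnostics, training scores, the
cutpoint and group labels; ``DMSResults.score`` applies the frozen model
(training means/SDs/loadings) to new cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import _cox_newton

__all__ = ["DMSModel", "DMSResults", "fit_dms", "score_dms", "optimal_cutpoint"]


class DMSModel:
    """PCA-based prognostic score model over the signature genes.

    Parameters
    ----------
    expr
        genes x samples log2 expression containing the signature genes.
    clinical
        table indexed by sample ID with ``os_time``/``os_event`` (used
        only to orient the principal axes).
    genes
        signature gene list (>= 2 usable genes required).
    scale
        divide each gene by its SD before PCA (default True).
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        clinical: pd.DataFrame,
        genes: list[str],
        scale: bool = True,
    ):
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"signature genes absent from expression: {missing[:5]}")
        self.expr = expr
        self.clinical = clinical
        self.genes = list(genes)
        self.scale = scale

    def fit(self, minprop: float = 0.1, orient: bool = True,
            time_col: str = "os_time", event_col: str = "os_event") -> "DMSResults":
        X = self.expr.loc[self.genes].to_numpy(dtype=float).T  # samples x genes
        if X.shape[0] < 3:
            raise ValueError("DMS fit needs >= 3 samples")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        usable = sds > 0
        if (~usable).any():
            warnings.warn(
                f"dropping {int((~usable).sum())} zero-variance signature gene(s)"
            )
        genes = [g for g, u in zip(self.genes, usable) if u]
        if len(genes) < 2:
            raise ValueError("fewer than 2 usable (non-constant) signature genes")
        X = X[:, usable]
        means, sds = means[usable], sds[usable]
        Z = (X - means) / (sds if self.scale else 1.0)
        if not self.scale:
            sds = np.ones_like(sds)

        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        v1, v2 = Vt[0], Vt[1]
        # deterministic pre-orientation sign convention (backend independent)
        for v in (v1, v2):
            i = np.argmax(np.abs(v))
            if v[i] < 0:
                v *= -1

        samples = list(map(str, self.expr.columns))
        clin = self.clinical.reindex(samples)
        time = clin[time_col].to_numpy(dtype=float)
        event = clin[event_col].to_numpy(dtype=float)
        ok = ~(np.isnan(time) | np.isnan(event))
        flips = [1, 1]
        hrs = [np.nan, np.nan]
        if orient:
            if np.nansum(event[ok]) == 0:
                raise ValueError("orientation requires >= 1 observed event")
            for j, v in enumerate((v1, v2)):
                pc = Z @ v
                beta, _, _, _ = _cox_newton(pc[None, ok], time[ok], event[ok])
                if beta[0] < 0:
                    flips[j] = -1
                hrs[j] = float(np.exp(abs(beta[0])))
        v1 = v1 * flips[0]
        v2 = v2 * flips[1]

        scores = pd.Series(Z @ v1 + Z @ v2, index=samples, name="DMS")
        cutpoint, groups, zstat = optimal_cutpoint(
            scores, clin, minprop=minprop, time_col=time_col, event_col=event_col
        )
        return DMSResults(
            genes=genes,
            means=means,
            sds=sds,
            v1=v1,
            v2=v2,
            scaled=self.scale,
            pc_hr=hrs,
            minprop=minprop,
            cutpoint_=cutpoint,
            cut_statistic_=zstat,
            scores_=scores,
            groups_=groups,
        )


@dataclass
class DMSResults:
    """Fitted DMS model: frozen loadings plus training diagnostics."""

    genes: list[str]
    means: np.ndarray
    sds: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    scaled: bool
    pc_hr: list[float]  # per-axis univariate HR magnitude used to orient
    minprop: float
    cutpoint_: float
    cut_statistic_: float
    scores_: pd.Series = field(repr=False)
    groups_: pd.Series = field(repr=False)

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Score a cohort with the frozen model (training means/SDs)."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise KeyError(f"expression lacks model genes: {missing[:5]}")
        X = expr.loc[self.genes].to_numpy(dtype=float).T
        Z = (X - self.means) / self.sds
        return pd.Series(Z @ self.v1 + Z @ self.v2,
                         index=list(map(str, expr.columns)), name="DMS")

    def assign_groups(self, scores: pd.Series) -> pd.Series:
        return pd.Series(
            np.where(scores.to_numpy() <= self.cutpoint_, "low", "high"),
            index=scores.index, name="dms_group",
        )

    def summary(self) -> str:
        lines = ["DNA methylation score (DMS) model", "=" * 34]
        lines.append(f"signature genes: {len(self.genes)}   scaled: {self.scaled}")
        lines.append(
            f"orientation HR per axis: PC1 {self.pc_hr[0]:.3f}, PC2 {self.pc_hr[1]:.3f}"
        )
        lines.append(
            f"training cutpoint: {self.cutpoint_:.4f} "
            f"(|standardized log-rank| = {self.cut_statistic_:.3f}, "
            f"minprop = {self.minprop})"
        )
        counts = self.groups_.value_counts()
        lines.append(
            "training groups: "
            + ", ".join(f"{g}={counts.get(g, 0)}" for g in ("low", "high"))
        )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "genes": self.genes,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "v1": self.v1.tolist(),
            "v2": self.v2.tolist(),
            "scaled": self.scaled,
            "cutpoint": self.cutpoint_,
            "minprop": self.minprop,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "DMSResults":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            v1=np.asarray(d["v1"]),
            v2=np.asarray(d["v2"]),
            scaled=d["scaled"],
            pc_hr=[np.nan, np.nan],
            minprop=d["minprop"],
            cutpoint_=d["cutpoint"],
            cut_statistic_=np.nan,
            scores_=pd.Series(dtype=float),
            groups_=pd.Series(dtype=object),
        )


def _logrank_z(scores: np.ndarray, time: np.ndarray, event: np.ndarray,
               cut: float) -> float:
    """Standardized two-group log-rank statistic for the split at ``cut``."""
    g = scores > cut
    order = np.argsort(time, kind="stable")
    t, e, gg = time[order], event[order].astype(bool), g[order]
    n = len(t)
    # walk the pooled event times
    O_minus_E = 0.0
    V = 0.0
    i = 0
    at_risk_total = n
    at_risk_high = int(gg.sum())
    while i < n:
        j = i
        d = 0
        d_high = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                d_high += int(gg[j])
            j += 1
        if d > 0 and 0 < at_risk_high < at_risk_total:
            exp_high = d * at_risk_high / at_risk_total
            if at_risk_total > 1:
                V += (
                    d
                    * (at_risk_high / at_risk_total)
                    * (1 - at_risk_high / at_risk_total)
                    * (at_risk_total - d)
                    / (at_risk_total - 1)
                )
            O_minus_E += d_high - exp_high
        at_risk_total -= j - i
        at_risk_high -= int(gg[i:j].sum())
        i = j
    if V <= 0:
        return 0.0
    return O_minus_E / np.sqrt(V)


def admissible_cutpoints(scores: np.ndarray, minprop: float) -> list[float]:
    """Candidate cut values leaving >= ``minprop`` of samples per side."""
    s = np.asarray(scores, dtype=float)
    n = s.size
    lo = int(np.ceil(minprop * n))
    uniq = np.unique(s)
    return [float(c) for c in uniq[:-1] if lo <= (s <= c).sum() <= n - lo]


def optimal_cutpoint(
    scores: pd.Series,
    clinical: pd.DataFrame,
    minprop: float = 0.1,
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> tuple[float, pd.Series, float]:
    """Maximally selected rank-statistics cutpoint.

    Evaluates every observed score value leaving at least ``minprop`` of
    the samples on each side of the split and returns the cut maximizing
    the absolute standardized log-rank statistic (ties -> smallest cut),
    together with low/high labels and the winning statistic.  The
    statistic is exploratory: its null distribution is inflated by the
    maximal selection and it must not be read as a log-rank test.
    """
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must lie in (0, 0.5)")
    clin = clinical.reindex(scores.index)
    time = clin[time_col].to_numpy(dtype=float)
    event = clin[event_col].to_numpy(dtype=float)
    ok = ~(np.isnan(time) | np.isnan(event))
    s = scores.to_numpy(dtype=float)
    if np.nansum(event[ok]) < 2:
        raise ValueError("optimal_cutpoint needs >= 2 events")
    if np.unique(s[ok]).size < 2:
        raise ValueError("all scores tied; no cutpoint exists")
    candidates = admissible_cutpoints(s[ok], minprop)
    if len(candidates) < 2:
        raise ValueError("fewer than 2 admissible cutpoints under minprop")
    best_c, best_z = None, -np.inf
    for c in candidates:
        z = abs(_logrank_z(s[ok], time[ok], event[ok], c))
        if z > best_z + 1e-12:
            best_z, best_c = z, c
    groups = pd.Series(
        np.where(s <= best_c, "low", "high"), index=scores.index, name="dms_group"
    )
    return float(best_c), groups, float(best_z)


def fit_dms(expr: pd.DataFrame, clinical: pd.DataFrame, genes: list[str],
            scale: bool = True, minprop: float = 0.1) -> DMSResults:
    """Functional wrapper: fit the DMS model and cutpoint in one call."""
    return DMSModel(expr, clinical, genes, scale=scale).fit(minprop=minprop)


def score_dms(model: DMSResults, expr: pd.DataFrame) -> pd.Series:
    """Functional wrapper for :meth:`DMSResults.score`."""
    return model.score(expr)
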