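"""Survival estimation and the cohort association statistics.

Kaplan-Meier curves, log-rank tests and multivariate Cox models are
delegated to lifelines; time-dependent ROC/AUC to scikit-survival's
IPCW cumulative/dynamic estimator; rank, contingency and correlation
tests to scipy.  Mutation and copy-number summaries (frequencies, TMB,
co-occurrence) are computed here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "SurvivalCurve",
    "CoxModel",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "time_dependent_auc",
    "rank_tests",
    "contingency_tests",
    "spearman_corr",
    "mutation_summaries",
    "cnv_frequencies",
    "NONSILENT_CLASSES",
]


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with Greenwood 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("km_estimate needs >= 1 subject")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not set(np.unique(events)) <= {0.0, 1.0}:
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    t = kmf.survival_function_.index.to_numpy()
    s = kmf.survival_function_.iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_
    ev = kmf.event_table["at_risk"].reindex(t).to_numpy()
    return SurvivalCurve(t, s, ev, ci.iloc[:, 0].to_numpy(), ci.iloc[:, 1].to_numpy())


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi-squared statistic, df, p)."""
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts == 0).any():
        raise ValueError("logrank_test needs >= 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxModel:
    """Multivariate Cox proportional-hazards fit."""

    covariates: list[str]
    beta: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_value: pd.Series
    ties: str
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_value,
            }
        )


def cox_fit(design: pd.DataFrame, times, events, ties: str = "efron") -> CoxModel:
    """Multivariate Cox PH regression (lifelines backend).

    ``design`` holds the numeric covariates; rank-deficient designs are
    rejected before fitting.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if ties not in {"efron", "breslow"}:
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = design.astype(float)
    if X.isna().any().any():
        raise ValueError("missing covariate values")
    centered = X - X.mean()
    if np.linalg.matrix_rank(centered.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    events = np.asarray(events, dtype=float)
    if events.sum() < 1:
        raise ValueError("cox_fit needs >= 1 event")
    df = X.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        converged = False
        raise ValueError("Cox model failed to converge (possible separation)")
    s = cph.summary
    return CoxModel(
        covariates=list(X.columns),
        beta=s["coef"],
        hr=s["exp(coef)"],
        ci_low=s["exp(coef) lower 95%"],
        ci_high=s["exp(coef) upper 95%"],
        p_value=s["p"],
        ties="efron",
        converged=converged,
    )


def time_dependent_auc(marker, times, events, horizon: float) -> float:
    """Cumulative/dynamic AUC(t) at ``horizon`` with IPCW weights from
    the censoring Kaplan-Meier curve (scikit-survival backend)."""
    from sksurv.metrics import cumulative_dynamic_auc

    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not (times.min() < horizon < times.max()):
        raise ValueError("horizon outside the observed follow-up range")
    cases = events & (times <= horizon)
    controls = times > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("no cases or no controls at the requested horizon")
    y = np.empty(len(times), dtype=[("event", bool), ("time", float)])
    y["event"] = events
    y["time"] = times
    auc, _ = cumulative_dynamic_auc(y, y, marker, [horizon])
    return float(auc[0])


def rank_tests(values, groups) -> tuple[float, float]:
    """Wilcoxon rank-sum for 2 groups, Kruskal-Wallis for >= 3."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("rank_tests needs >= 2 non-empty groups")
    if len(samples) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def contingency_tests(table, yates: bool = False) -> dict[str, float]:
    """Pearson chi-squared (no continuity correction by default) plus,
    for 2x2 tables, the Fisher exact p and odds ratio (Haldane 0.5
    correction when a zero cell occurs)."""
    T = np.asarray(table, dtype=float)
    if (T < 0).any() or not np.allclose(T, np.round(T)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    out: dict[str, float] = {}
    if T.min() == 0 and T.shape == (2, 2):
        chi2 = np.nan
        p_chi2 = np.nan
        try:
            chi2, p_chi2, _, _ = stats.chi2_contingency(T, correction=yates)
        except ValueError:
            pass
    else:
        chi2, p_chi2, _, _ = stats.chi2_contingency(T, correction=yates)
    out["chi2"] = float(chi2)
    out["chi2_p"] = float(p_chi2)
    if T.shape == (2, 2):
        _, p_fisher = stats.fisher_exact(T.astype(int), alternative="two-sided")
        out["fisher_p"] = float(p_fisher)
        a, b, c, d = T.ravel()
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        out["odds_ratio"] = float((a * d) / (b * c))
    return out


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_corr needs equal-length vectors of >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
        "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
        "Splice_Site", "Translation_Start_Site",
    }
)
SILENT_CLASSES = frozenset({"Silent", "Synonymous", "3'UTR", "5'UTR", "Intron", "IGR"})


def mutation_summaries(
    mutations: pd.DataFrame,
    samples: list[str],
    genes: list[str],
    include_unknown_classes: bool = False,
    tmb_scale: float = 1.0,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Per-gene mutated-sample frequency, per-sample TMB and pairwise
    co-occurrence Fisher tests over non-silent calls.

    ``samples`` is the denominator universe (samples without calls count
    as wild-type).  TMB = non-silent calls per sample times
    ``tmb_scale`` (identity by default; set to 1/Mb-covered for per-Mb
    burden).
    """
    mut = mutations.copy()
    known = mut["Variant_Classification"].isin(NONSILENT_CLASSES | SILENT_CLASSES)
    if (~known).any():
        warnings.warn(
            f"{int((~known).sum())} call(s) with unknown variant class "
            f"{'included' if include_unknown_classes else 'excluded'}"
        )
    nonsilent = mut["Variant_Classification"].isin(NONSILENT_CLASSES)
    if include_unknown_classes:
        nonsilent |= ~known
    calls = mut[nonsilent & mut["Tumor_Sample_Barcode"].isin(samples)]

    n = len(samples)
    mutated = {
        g: set(calls.loc[calls["Hugo_Symbol"] == g, "Tumor_Sample_Barcode"])
        for g in genes
    }
    freq = pd.Series({g: len(mutated[g]) / n for g in genes}, name="frequency")

    tmb = (
        calls.groupby("Tumor_Sample_Barcode").size().reindex(samples).fillna(0)
        * tmb_scale
    )
    tmb.name = "TMB"

    pairs = []
    glist = [g for g in genes]
    for i in range(len(glist)):
        for j in range(i + 1, len(glist)):
            gi, gj = glist[i], glist[j]
            a = len(mutated[gi] & mutated[gj])
            b = len(mutated[gi] - mutated[gj])
            c = len(mutated[gj] - mutated[gi])
            d = n - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            odds = np.inf if b * c == 0 and a * d > 0 else (
                (a * d) / (b * c) if b * c else np.nan
            )
            pairs.append((gi, gj, a, b, c, d, odds, p))
    cooc = pd.DataFrame(
        pairs,
        columns=["gene_a", "gene_b", "both", "a_only", "b_only", "neither",
                 "odds_ratio", "p_value"],
    )
    if len(cooc):
        cooc["adj_p"] = bh_adjust(cooc["p_value"].to_numpy())
        cooc["co_occurrent"] = (cooc["adj_p"] < 0.05) & (cooc["odds_ratio"] > 1)
    return {"frequency": freq, "tmb": tmb, "co_occurrence": cooc}


def cnv_frequencies(
    cnv: pd.DataFrame,
    gain_threshold: int = 0,
    loss_threshold: int = 0,
) -> pd.DataFrame:
    """Per-gene gain/loss frequencies from sample x gene calls in
    {-2, -1, 0, 1, 2}; gain = fraction of calls > ``gain_threshold``,
    loss = fraction < ``-loss_threshold`` (thresholds on magnitude)."""
    vals = cnv.to_numpy()
    if not np.isin(vals, (-2, -1, 0, 1, 2)).all():
        raise ValueError("CNV calls must lie in {-2, -1, 0, 1, 2}")
    gain = (cnv > gain_threshold).mean(axis=0)
    loss = (cnv < -loss_threshold).mean(axis=0)
    return pd.DataFrame({"gain_frequency": gain, "loss_frequency": loss})
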