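"""Consensus nonnegative matrix factorization for pattern discovery.

Samples are clustered on the regulator sub-matrix by NMF with
Kullback-Leibler multiplicative updates (the Brunet variant), repeated
from many random restarts per candidate rank.  Run-to-run co-clustering
frequencies form a consensus matrix; the cophenetic correlation of its
average-linkage dendrogram quantifies stability and selects the rank.

The model-style entry point is :class:`ConsensusNMF`, whose ``fit``
returns a :class:`ConsensusNMFResults` with the consensus evidence, the
selected rank and the final pattern labels (A, B, C, ... by descending
cluster size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "NMFResult",
    "ConsensusResult",
    "nmf_factorize",
    "consensus_cluster",
    "select_rank",
    "assign_patterns",
    "ConsensusNMF",
    "ConsensusNMFResults",
]

_EPS = np.finfo(float).tiny


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    return float(
        (V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum()
    )


@dataclass
class NMFResult:
    """One NMF factorization ``X ~ W @ H`` (KL objective)."""

    W: np.ndarray  # genes x k
    H: np.ndarray  # k x samples, rows sum to 1 scale-free
    objective_trace: list[float]
    seed: int
    converged: bool

    @property
    def labels(self) -> np.ndarray:
        """Hard sample labels: argmax over the rows of H."""
        return self.H.argmax(axis=0)


def nmf_factorize(
    X: np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFResult:
    """Factorize a nonnegative matrix by KL multiplicative updates.

    Stops when the relative drop of the generalized KL divergence falls
    below ``tol`` (checked every iteration) or at ``max_iter``.  H rows
    are rescaled to sum to 1 (compensated in W) so that argmax labels are
    scale-free.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError(
            "NMF input has negative entries; shift the matrix to a minimum "
            "of zero before factorizing"
        )
    if not (2 <= k <= min(X.shape)) and k != 1:
        raise ValueError(f"rank k={k} out of range for matrix of shape {X.shape}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / max(k, 1)) or 1.0
    W = rng.uniform(_EPS, scale, size=(X.shape[0], k))
    H = rng.uniform(_EPS, scale, size=(k, X.shape[1]))

    trace: list[float] = [_kl_divergence(X, W @ H)]
    converged = False
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = _kl_divergence(X, W @ H)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / max(prev, _EPS) < tol:
            converged = True
            break

    # make H rows sum to one; absorb the scale into W
    row_sums = np.maximum(H.sum(axis=1), _EPS)
    H = H / row_sums[:, None]
    W = W * row_sums[None, :]
    return NMFResult(W=W, H=H, objective_trace=trace, seed=seed, converged=converged)


@dataclass
class ConsensusResult:
    """Consensus evidence over a range of candidate ranks."""

    consensus: dict[int, np.ndarray]  # k -> samples x samples in [0, 1]
    cophenetic: dict[int, float]
    dispersion: dict[int, float]
    sample_ids: list[str]
    n_runs: int
    degenerate: dict[int, bool] = field(default_factory=dict)


def _consensus_for_k(
    X: np.ndarray,
    k: int,
    n_runs: int,
    seeds: np.ndarray,
    max_iter: int,
    tol: float,
    subsample: float,
) -> tuple[np.ndarray, bool]:
    n = X.shape[1]
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    any_full_rank = False
    for s in seeds:
        rng = np.random.default_rng(int(s))
        if subsample < 1.0:
            m = max(k + 1, int(round(subsample * n)))
            idx = np.sort(rng.choice(n, size=m, replace=False))
        else:
            idx = np.arange(n)
        res = nmf_factorize(X[:, idx], k, max_iter=max_iter, tol=tol, seed=int(s))
        lab = res.labels
        if len(np.unique(lab)) == k:
            any_full_rank = True
        sampled[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += lab[:, None] == lab[None, :]
    with np.errstate(invalid="ignore"):
        C = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2
    return C, not any_full_rank


def _cophenetic_coefficient(C: np.ndarray) -> float:
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        # all pairwise distances equal (e.g. perfect consensus): the
        # correlation is undefined; perfect-stability convention = 1
        return 1.0 if np.allclose(condensed, 0.0) else np.nan
    Z = average(condensed)
    coeff, _ = cophenet(Z, condensed)
    return float(coeff)


def consensus_cluster(
    X: np.ndarray,
    k_range: range | list[int],
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    subsample: float = 0.8,
    sample_ids: list[str] | None = None,
) -> ConsensusResult:
    """Multi-restart NMF consensus over candidate ranks.

    ``consensus[k][i, j]`` is the fraction of runs in which samples i and
    j received the same argmax-H label.
    """
    if n_runs < 10:
        raise ValueError("consensus clustering needs n_runs >= 10")
    X = np.asarray(X, dtype=float)
    ss = np.random.SeedSequence(seed)
    consensus, cophenetic, dispersion, degenerate = {}, {}, {}, {}
    for k in k_range:
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(k,))
        seeds = child.generate_state(n_runs) % (2**31 - 1)
        C, degen = _consensus_for_k(X, k, n_runs, seeds, max_iter, tol, subsample)
        consensus[k] = C
        degenerate[k] = degen
        cophenetic[k] = np.nan if degen else _cophenetic_coefficient(C)
        dispersion[k] = float((4 * (C - 0.5) ** 2).mean())
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(X.shape[1])]
    return ConsensusResult(consensus, cophenetic, dispersion, ids, n_runs, degenerate)


def select_rank(result: ConsensusResult) -> int:
    """Rank with the largest cophenetic coefficient; ties -> smallest k."""
    finite = {k: v for k, v in result.cophenetic.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no candidate rank has a finite cophenetic coefficient")
    best = max(finite.values())
    return min(k for k, v in finite.items() if v == best)


def _rename_by_size(labels: np.ndarray) -> np.ndarray:
    """Map integer labels to letters A, B, ... by descending cluster size,
    ties broken by first occurrence."""
    uniq = list(dict.fromkeys(labels))  # first-occurrence order
    sizes = {u: (labels == u).sum() for u in uniq}
    ordered = sorted(uniq, key=lambda u: (-sizes[u], uniq.index(u)))
    letter = {u: chr(ord("A") + i) for i, u in enumerate(ordered)}
    return np.array([letter[u] for u in labels])


def assign_patterns(
    result: NMFResult | ConsensusResult,
    k: int | None = None,
    strict: bool = True,
) -> pd.Series:
    """Hard pattern labels, renamed A, B, C, ... by descending size.

    A single factorization is labeled by argmax over H; a consensus
    result (the default pipeline path) by cutting the average-linkage
    dendrogram of the consensus distances at ``k`` clusters.
    """
    if isinstance(result, NMFResult):
        labels = result.labels
        ids = [str(i) for i in range(len(labels))]
        k_eff = result.H.shape[0]
    else:
        if k is None:
            k = select_rank(result)
        C = result.consensus[k]
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        Z = average(squareform(D, checks=False))
        labels = fcluster(Z, t=k, criterion="maxclust")
        ids = result.sample_ids
        k_eff = k
    if len(np.unique(labels)) < k_eff:
        msg = f"degenerate solution: only {len(np.unique(labels))} of {k_eff} clusters populated"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg)
    return pd.Series(_rename_by_size(labels), index=ids, name="pattern")


class ConsensusNMF:
    """Consensus-NMF clustering model over a genes x samples matrix.

    Parameters
    ----------
    X
        genes x samples DataFrame of log2 expression (typically the
        regulator sub-matrix of the batch-adjusted meta-cohort).
    k_range
        Candidate ranks (default 2..5).
    n_runs
        Random restarts per rank (default 30).
    fold_change
        When True (default), factorize the per-gene linear-scale fold
        change ``2**(x - rowmean(x))``: gene-specific baselines carry no
        cluster information but dominate the KL objective and leave the
        coefficient matrix degenerate (argmax labels then depend on the
        restart); relative expression removes them while preserving the
        multiplicative structure NMF models.  When False the matrix is
        used as-is except for a global shift to a minimum of zero
        (recorded in ``shift_``), since NMF requires nonnegativity.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        k_range: range | list[int] = range(2, 6),
        n_runs: int = 30,
        max_iter: int = 300,
        tol: float = 1e-6,
        subsample: float = 0.8,
        fold_change: bool = True,
    ):
        self.data = X
        self.fold_change = fold_change
        self.k_range = list(k_range)
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.subsample = subsample
        self.shift_ = float(max(0.0, -np.asarray(X, dtype=float).min()))

    def fit(self, seed: int = 0, k: int | None = None) -> "ConsensusNMFResults":
        """Run the consensus; ``k`` fixes the rank instead of selecting it."""
        X = np.asarray(self.data, dtype=float)
        if self.fold_change:
            Xs = np.exp2(X - X.mean(axis=1, keepdims=True))
        else:
            Xs = X + self.shift_
        res = consensus_cluster(
            Xs,
            self.k_range if k is None else [k],
            n_runs=self.n_runs,
            seed=seed,
            max_iter=self.max_iter,
            tol=self.tol,
            subsample=self.subsample,
            sample_ids=list(map(str, self.data.columns)),
        )
        best_k = k if k is not None else select_rank(res)
        labels = assign_patterns(res, k=best_k, strict=False)
        return ConsensusNMFResults(self, res, best_k, labels, seed)


@dataclass
class ConsensusNMFResults:
    model: ConsensusNMF
    consensus: ConsensusResult
    k_: int
    labels_: pd.Series
    seed: int

    @property
    def cophenetic_(self) -> pd.Series:
        return pd.Series(self.consensus.cophenetic, name="cophenetic").sort_index()

    def summary(self) -> str:
        lines = ["Consensus NMF clustering", "=" * 26]
        lines.append(f"samples: {len(self.labels_)}   runs/rank: {self.consensus.n_runs}")
        lines.append("rank   cophenetic   dispersion")
        for k in sorted(self.consensus.cophenetic):
            mark = " *" if k == self.k_ else ""
            lines.append(
                f"  {k}     {self.consensus.cophenetic[k]:8.4f}   "
                f"{self.consensus.dispersion[k]:8.4f}{mark}"
            )
        sizes = self.labels_.value_counts().sort_index()
        lines.append("pattern sizes: " + ", ".join(f"{a}={b}" for a, b in sizes.items()))
        return "\n".join(lines)
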