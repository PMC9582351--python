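"""Synthetic colon-cancer-like cohorts with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in real meta-cohorts: a small panel of regulator genes whose
expression defines ``k`` latent sample patterns (mean shifts on disjoint
gene blocks), a larger block of pattern-tracking genes (the differential
expression truth), immune- and stromal-signature co-expression that is
correlated with pattern, additive per-cohort batch effects,
pattern-dependent proportional-hazards survival with independent
censoring, and pattern-dependent somatic mutation counts.

Everything is reproducible from a single integer seed.  Ground truth
(pattern labels, differential genes, batch offsets, hazards) is carried
alongside the data so downstream stages can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .regulators import REGULATOR_SYMBOLS

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_batched_cohorts",
    "generate_immunotherapy_labels",
    "TME_CELL_TYPES",
    "ADAPTIVE_CELL_TYPES",
    "INNATE_CELL_TYPES",
]

# ---------------------------------------------------------------------------
# fixed gene-row layout (row indices in the expression matrix)
#
# rows 0..23            the 24 regulators (real symbols), 8 per pattern
# rows 24..303          28 TME cell-type signatures, 10 genes each
# rows 304..313         stromal signature
# rows 314..323         immune signature
# rows n-n_sig..n-1     planted differential block, k contiguous chunks
# everything else       null genes
# ---------------------------------------------------------------------------

N_REGULATORS = 24
TME_GENES_PER_SET = 10
TME_BLOCK_START = N_REGULATORS

ADAPTIVE_CELL_TYPES = (
    "Activated CD8 T cell", "Central memory CD8 T cell",
    "Effector memory CD8 T cell", "Activated CD4 T cell",
    "Central memory CD4 T cell", "Effector memory CD4 T cell",
    "T follicular helper cell", "Gamma delta T cell",
    "Type 1 T helper cell", "Type 2 T helper cell",
    "Type 17 T helper cell", "Regulatory T cell",
    "Activated B cell", "Memory B cell",
)
INNATE_CELL_TYPES = (
    "Natural killer cell", "CD56bright natural killer cell",
    "CD56dim natural killer cell", "Natural killer T cell",
    "Activated dendritic cell", "Plasmacytoid dendritic cell",
    "Immature dendritic cell", "Macrophage",
    "Eosinophil", "Mast cell", "Monocyte", "Neutrophil",
    "MDSC", "Immature B cell",
)
TME_CELL_TYPES = ADAPTIVE_CELL_TYPES + INNATE_CELL_TYPES

STROMAL_BLOCK_START = TME_BLOCK_START + len(TME_CELL_TYPES) * TME_GENES_PER_SET
IMMUNE_BLOCK_START = STROMAL_BLOCK_START + TME_GENES_PER_SET
SIGNATURE_BLOCK_MIN_START = IMMUNE_BLOCK_START + TME_GENES_PER_SET

VARIANT_CLASSES = (
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "Splice_Site", "Silent",
)


def gene_name(row: int) -> str:
    """Synthetic symbol for a gene row; the first 24 rows carry the real
    regulator symbols so the shipped regulator catalogue is exercised."""
    if row < N_REGULATORS:
        return REGULATOR_SYMBOLS[row]
    return f"G{row:06d}"


def tme_set_rows(cell_type: str) -> range:
    j = TME_CELL_TYPES.index(cell_type)
    start = TME_BLOCK_START + j * TME_GENES_PER_SET
    return range(start, start + TME_GENES_PER_SET)


class ConfigurationError(ValueError):
    """Raised when a :class:`SyntheticConfig` violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions the pipeline is validated under:
    600 samples, 3 latent patterns with moderately unbalanced
    proportions (0.41/0.30/0.29), a log2 mean shift of 1.0 on each
    pattern-defining gene block against residual noise of SD 0.5, exponential survival with per-pattern monthly
    hazards (pattern B most favorable), and ~150 planted differential
    genes.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_regulators: int = N_REGULATORS
    k_patterns: int = 3
    pattern_props: tuple[float, ...] = (0.41, 0.30, 0.29)
    effect_size: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    n_batches: int = 3
    batch_shift_sd: float = 2.0
    batch_sizes: tuple[int, ...] | None = None
    surv_hazards: tuple[float, ...] = (0.055, 0.010, 0.065)
    censor_rate: float = 0.010
    n_sig_genes: int = 150
    mut_rates: tuple[float, ...] = (20.0, 45.0, 10.0)
    risk_gene_betas: Mapping[str, float] = field(default_factory=dict)
    plant_tme: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.k_patterns < 1:
            raise ConfigurationError("k_patterns must be >= 1")
        if len(self.pattern_props) != self.k_patterns:
            raise ConfigurationError("pattern_props length must equal k_patterns")
        if abs(sum(self.pattern_props) - 1.0) > 1e-12:
            raise ConfigurationError("pattern_props must sum to 1 (simplex)")
        if any(p < 0 for p in self.pattern_props):
            raise ConfigurationError("pattern_props must be nonnegative")
        if len(self.surv_hazards) != self.k_patterns:
            raise ConfigurationError("surv_hazards length must equal k_patterns")
        if any(h <= 0 for h in self.surv_hazards):
            raise ConfigurationError("all survival hazards must be > 0")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be >= 0")
        if len(self.mut_rates) != self.k_patterns:
            raise ConfigurationError("mut_rates length must equal k_patterns")
        if self.n_sig_genes > self.n_genes:
            raise ConfigurationError("n_sig_genes must be <= n_genes")
        if self.n_regulators != N_REGULATORS:
            raise ConfigurationError("the regulator panel is fixed at 24 genes")
        if self.n_genes < N_REGULATORS + self.n_sig_genes:
            raise ConfigurationError(
                "n_genes too small for regulator panel plus signature block"
            )
        if self.plant_tme and self.n_genes - self.n_sig_genes < SIGNATURE_BLOCK_MIN_START:
            raise ConfigurationError(
                "n_genes too small to host the TME blocks; enlarge n_genes "
                "or set plant_tme=False"
            )
        if self.batch_sizes is not None:
            if len(self.batch_sizes) != self.n_batches:
                raise ConfigurationError("batch_sizes length must equal n_batches")
            if sum(self.batch_sizes) != self.n_samples:
                raise ConfigurationError("batch_sizes must sum to n_samples")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one cohort."""

    pattern: pd.Series  # sample_id -> 0..k-1
    deg_genes: list[str]  # every gene with a pattern-dependent planted mean
    signature_genes: list[str]  # the dedicated n_sig_genes differential block
    regulator_blocks: dict[int, list[str]]  # pattern -> defining regulators
    surv_hazards: list[float]
    mut_rates: list[float]
    risk_gene_betas: dict[str, float]
    batch: pd.Series  # sample_id -> batch label
    batch_offsets: pd.DataFrame | None = None  # gene x batch additive offsets

    def to_json(self) -> str:
        payload = {
            "pattern": self.pattern.astype(int).to_dict(),
            "deg_genes": self.deg_genes,
            "signature_genes": self.signature_genes,
            "regulator_blocks": {str(k): v for k, v in self.regulator_blocks.items()},
            "surv_hazards": self.surv_hazards,
            "mut_rates": self.mut_rates,
            "risk_gene_betas": self.risk_gene_betas,
            "batch": self.batch.astype(str).to_dict(),
            "batch_offsets": (
                None if self.batch_offsets is None
                else self.batch_offsets.to_dict(orient="index")
            ),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """Expression + clinical + mutation data with its planted truth."""

    expression: pd.DataFrame  # genes x samples, log2 scale
    clinical: pd.DataFrame  # indexed by sample_id
    mutations: pd.DataFrame  # MAF-like long table
    truth: SyntheticTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> None:
        """Write expression/clinical TSV, MAF-like TSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        self.mutations.to_csv(outdir / "mutations.maf.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(self.truth.to_json())


def _planted_shift_matrix(config: SyntheticConfig) -> tuple[np.ndarray, dict]:
    """Per-(gene, pattern) additive mean-shift matrix and block bookkeeping."""
    k = config.k_patterns
    shifts = np.zeros((config.n_genes, k))
    regulator_blocks: dict[int, list[str]] = {}
    per_block = N_REGULATORS // k
    for p in range(k):
        rows = range(p * per_block, (p + 1) * per_block if p < k - 1 else N_REGULATORS)
        shifts[list(rows), p] += config.effect_size
        regulator_blocks[p] = [gene_name(r) for r in rows]

    sig_start = config.n_genes - config.n_sig_genes
    bounds = np.linspace(0, config.n_sig_genes, k + 1).astype(int)
    signature_rows = list(range(sig_start, config.n_genes))
    for p in range(k):
        rows = range(sig_start + bounds[p], sig_start + bounds[p + 1])
        shifts[list(rows), p] += config.effect_size

    if config.plant_tme:
        # adaptive immune sets and the immune signature co-express with the
        # favorable pattern (index 1); innate sets and the stromal signature
        # with pattern 0; pattern 2 stays immune-poor.
        p_adaptive = 1 % k
        p_innate = 0
        for ct in ADAPTIVE_CELL_TYPES:
            shifts[list(tme_set_rows(ct)), p_adaptive] += config.effect_size
        for ct in INNATE_CELL_TYPES:
            shifts[list(tme_set_rows(ct)), p_innate] += config.effect_size
        shifts[STROMAL_BLOCK_START:STROMAL_BLOCK_START + TME_GENES_PER_SET,
               p_innate] += config.effect_size
        shifts[IMMUNE_BLOCK_START:IMMUNE_BLOCK_START + TME_GENES_PER_SET,
               p_adaptive] += config.effect_size

    deg_rows = sorted(set(np.nonzero(shifts.any(axis=1))[0]))
    info = {
        "regulator_blocks": regulator_blocks,
        "signature_rows": signature_rows,
        "deg_rows": deg_rows,
    }
    return shifts, info


def _simulate_survival(
    rng: np.random.Generator,
    hazards: np.ndarray,
    censor_rate: float,
    relative_risk: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    rate = hazards * relative_risk
    event_t = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=rate.shape)
    else:
        censor_t = np.full(rate.shape, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return time, event


def generate_cohort(
    config: SyntheticConfig | None = None,
    *,
    sample_prefix: str = "S",
    batch_label: str = "B0",
    batch_offset: np.ndarray | None = None,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    baseline: np.ndarray | None = None,
) -> SyntheticCohort:
    """Generate one cohort per the configured study conditions.

    Expression is ``baseline + pattern shift + batch offset + N(0, noise_sd)``
    on the log2 scale; survival is exponential in the sample's pattern
    hazard (optionally tilted by planted per-gene log-hazard betas) with
    independent exponential censoring; mutation counts are Poisson with
    the pattern's rate.
    """
    config = config or SyntheticConfig()
    config.validate()
    n = n_samples if n_samples is not None else config.n_samples
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    genes = [gene_name(r) for r in range(config.n_genes)]
    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]

    pattern = rng.choice(config.k_patterns, size=n, p=np.asarray(config.pattern_props))
    shifts, info = _planted_shift_matrix(config)

    if baseline is None:
        baseline = rng.normal(
            config.baseline_mean, config.baseline_sd, size=config.n_genes
        )
    expr = (
        baseline[:, None]
        + shifts[:, pattern]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    )
    if batch_offset is not None:
        expr = expr + batch_offset[:, None]
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    expression.index.name = "gene"

    # survival ---------------------------------------------------------------
    hazards = np.asarray(config.surv_hazards)[pattern]
    log_rr = np.zeros(n)
    betas: dict[str, float] = dict(config.risk_gene_betas)
    for g, beta in betas.items():
        x = expression.loc[g].to_numpy()
        log_rr += beta * (x - x.mean())
    os_time, os_event = _simulate_survival(rng, hazards, config.censor_rate,
                                           np.exp(log_rr))
    rfs_time, rfs_event = _simulate_survival(rng, hazards * 1.5,
                                             config.censor_rate, np.exp(log_rr))

    # clinical covariates loosely tied to pattern ----------------------------
    stage_probs = {
        0: (0.15, 0.35, 0.35, 0.15),
        1: (0.30, 0.40, 0.20, 0.10),
        2: (0.10, 0.25, 0.40, 0.25),
    }
    stages = np.array([
        rng.choice(("I", "II", "III", "IV"),
                   p=stage_probs[min(p, 2)])
        for p in pattern
    ])
    msi = rng.random(n) < np.where(pattern == (1 % config.k_patterns), 0.25, 0.10)

    clinical = pd.DataFrame(
        {
            "os_time": np.round(os_time, 3),
            "os_event": os_event,
            "rfs_time": np.round(rfs_time, 3),
            "rfs_event": rfs_event,
            "stage": stages,
            "msi": np.where(msi, "MSI", "MSS"),
            "batch": batch_label,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # mutations --------------------------------------------------------------
    counts = rng.poisson(np.asarray(config.mut_rates)[pattern])
    rows = []
    for s, c in zip(samples, counts):
        if c == 0:
            continue
        mut_genes = rng.choice(config.n_genes, size=c, replace=True)
        classes = rng.choice(len(VARIANT_CLASSES), size=c)
        rows.extend(
            (genes[g], s, VARIANT_CLASSES[v]) for g, v in zip(mut_genes, classes)
        )
    mutations = pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    )

    truth = SyntheticTruth(
        pattern=pd.Series(pattern, index=samples, name="pattern"),
        deg_genes=[genes[r] for r in info["deg_rows"]],
        signature_genes=[genes[r] for r in info["signature_rows"]],
        regulator_blocks=info["regulator_blocks"],
        surv_hazards=list(config.surv_hazards),
        mut_rates=list(config.mut_rates),
        risk_gene_betas=betas,
        batch=pd.Series(batch_label, index=samples, name="batch"),
    )
    return SyntheticCohort(expression, clinical, mutations, truth, config)


def generate_batched_cohorts(config: SyntheticConfig | None = None) -> list[SyntheticCohort]:
    """Generate ``n_batches`` cohorts sharing pattern composition.

    Each cohort receives an independent per-gene additive offset drawn
    from ``N(0, batch_shift_sd**2)``, recorded in its truth.
    """
    config = config or SyntheticConfig()
    config.validate()
    if config.n_batches < 2:
        raise ConfigurationError("generate_batched_cohorts requires n_batches >= 2")
    rng = np.random.default_rng(config.seed)
    if config.batch_sizes is not None:
        sizes = list(config.batch_sizes)
    else:
        base = config.n_samples // config.n_batches
        sizes = [base] * config.n_batches
        sizes[0] += config.n_samples - base * config.n_batches

    genes = [gene_name(r) for r in range(config.n_genes)]
    # one shared per-gene baseline: cohorts differ only by their additive
    # batch offsets (plus sampling noise), emulating same-platform batches
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    cohorts = []
    for b, size in enumerate(sizes):
        offset = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
        cohort = generate_cohort(
            config,
            sample_prefix=f"B{b}_S",
            batch_label=f"B{b}",
            batch_offset=offset,
            n_samples=size,
            rng=rng,
            baseline=baseline,
        )
        cohort.truth.batch_offsets = pd.DataFrame(
            {f"B{b}": offset}, index=genes
        )
        cohorts.append(cohort)
    return cohorts


def generate_immunotherapy_labels(
    cohort: SyntheticCohort,
    response_logit_slope: float,
    *,
    base_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Append a CR/PR vs SD/PD therapy-response column to the clinical table.

    The response probability is logistic in the planted prognostic score
    (the log hazard of the sample's pattern, standardized); a positive
    slope makes low-risk samples more likely to respond.
    """
    rng = np.random.default_rng(seed)
    pattern = cohort.truth.pattern.to_numpy()
    log_h = np.log(np.asarray(cohort.truth.surv_hazards))[pattern]
    score = log_h - log_h.mean()
    sd = score.std()
    if sd > 0:
        score = score / sd
    logit0 = math.log(base_rate / (1 - base_rate))
    p_resp = 1.0 / (1.0 + np.exp(-(logit0 - response_logit_slope * score)))
    responder = rng.random(len(p_resp)) < p_resp
    fine = np.where(
        responder,
        rng.choice(("CR", "PR"), size=len(p_resp)),
        rng.choice(("SD", "PD"), size=len(p_resp)),
    )
    clinical = cohort.clinical.copy()
    clinical["response"] = fine
    clinical["responder"] = responder.astype(int)
    return clinical
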