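"""End-to-end orchestration: merge -> batch adjust -> pattern NMF ->
DEG/Cox -> gene clusters -> DMS -> cutpoint -> enrichment -> reports.

``run_analysis`` drives the whole analysis on in-memory objects and
returns a :class:`ReportBundle`; ``run_pipeline`` wraps it for a YAML
config of file paths and writes every intermediate to the output
directory.  One root seed fans out deterministically to per-stage seeds
through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genesets
from .combat import combat_adjust
from .diffexp import derive_signature, moderated_f_test, univariate_cox_screen
from .dms import DMSModel, DMSResults
from .enrichment import estimate_scores, ssgsea_scores
from .io import merge_cohorts, read_clinical, read_expression, read_gene_sets, read_mutations
from .nmf import ConsensusNMF, ConsensusNMFResults
from .regulators import REGULATOR_SYMBOLS
from .survival import logrank_test, mutation_summaries, rank_tests

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_analysis", "run_pipeline"]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(df.to_csv().encode())
    return h.hexdigest()[:16]


@dataclass
class PipelineConfig:
    """Validated file-path configuration for a pipeline run."""

    expression_paths: list[str]
    clinical_path: str
    output_dir: str
    mutation_path: str | None = None
    gene_set_paths: dict[str, str] = field(default_factory=dict)
    regulators: list[str] = field(default_factory=lambda: list(REGULATOR_SYMBOLS))
    k_range: tuple[int, int] = (2, 5)
    n_runs: int = 30
    fixed_k: int | None = None
    deg_threshold: float = 0.01
    cox_threshold: float = 0.01
    dms_scale: bool = True
    minprop: float = 0.1
    seed: int = 0
    skip_combat: bool = False

    def validate(self) -> None:
        for p in [*self.expression_paths, self.clinical_path,
                  *(([self.mutation_path] if self.mutation_path else [])),
                  *self.gene_set_paths.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for t in (self.deg_threshold, self.cox_threshold):
            if not 0 < t <= 1:
                raise ValueError("thresholds must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """All pipeline outputs plus a manifest sufficient to reproduce them."""

    merged: pd.DataFrame
    batch: pd.Series
    adjusted: pd.DataFrame
    patterns: ConsensusNMFResults
    deg_table: pd.DataFrame
    cox_table: pd.DataFrame
    signature: object
    gene_clusters: ConsensusNMFResults
    dms: DMSResults
    enrichment: dict[str, pd.DataFrame]
    group_tests: pd.DataFrame
    survival_tests: pd.DataFrame
    mutation_reports: dict | None
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.adjusted.to_csv(out / "expression_adjusted.tsv", sep="\t")
        self.patterns.labels_.to_frame().to_csv(out / "patterns.tsv", sep="\t")
        self.patterns.cophenetic_.to_frame().to_csv(out / "cophenetic.tsv", sep="\t")
        self.deg_table.to_csv(out / "deg_table.tsv", sep="\t")
        self.cox_table.to_csv(out / "cox_table.tsv", sep="\t")
        (out / "signature_genes.txt").write_text("\n".join(self.signature.genes) + "\n")
        self.gene_clusters.labels_.rename("gene_cluster").to_frame().to_csv(
            out / "gene_clusters.tsv", sep="\t"
        )
        self.dms.to_json(out / "dms_model.json")
        pd.DataFrame(
            {"DMS": self.dms.scores_, "dms_group": self.dms.groups_}
        ).to_csv(out / "dms_scores.tsv", sep="\t")
        for name, mat in self.enrichment.items():
            mat.to_csv(out / f"enrichment_{name}.tsv", sep="\t")
        self.group_tests.to_csv(out / "group_tests.tsv", sep="\t")
        self.survival_tests.to_csv(out / "survival_tests.tsv", sep="\t")
        if self.mutation_reports is not None:
            self.mutation_reports["frequency"].to_frame().to_csv(
                out / "mutation_frequency.tsv", sep="\t"
            )
            self.mutation_reports["tmb"].to_frame().to_csv(out / "tmb.tsv", sep="\t")
            self.mutation_reports["co_occurrence"].to_csv(
                out / "mutation_cooccurrence.tsv", sep="\t", index=False
            )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def run_analysis(
    cohorts: list[pd.DataFrame],
    clinical: pd.DataFrame,
    mutations: pd.DataFrame | None = None,
    gene_sets: dict[str, dict[str, set[str]]] | None = None,
    regulators: list[str] | None = None,
    k_range: range | list[int] = range(2, 6),
    n_runs: int = 30,
    fixed_k: int | None = None,
    deg_threshold: float = 0.01,
    cox_threshold: float = 0.01,
    dms_scale: bool = True,
    minprop: float = 0.1,
    seed: int = 0,
    skip_combat: bool = False,
) -> ReportBundle:
    """Run the full analysis on in-memory cohorts.

    ``gene_sets`` maps collection names to GMT-style dicts; defaults to
    the bundled synthetic fixtures.
    """
    seeds = _stage_seeds(seed)
    regulators = list(regulators or REGULATOR_SYMBOLS)
    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 2)
            log.info("stage %s finished in %.2fs", name, timings[name])

        return done

    # 1. merge + batch adjustment ------------------------------------------
    d = _stage("merge_combat")
    if len(cohorts) > 1:
        merged, batch = merge_cohorts(cohorts)
        adjusted = merged if skip_combat else combat_adjust(merged, batch)
    else:
        merged = cohorts[0]
        batch = pd.Series(0, index=merged.columns, name="batch")
        adjusted = merged
    d()

    # 2. pattern discovery on the regulator panel --------------------------
    d = _stage("patterns")
    reg_present = [g for g in regulators if g in adjusted.index]
    if len(reg_present) < 2:
        raise ValueError("regulator panel absent from expression matrix")
    patterns = ConsensusNMF(
        adjusted.loc[reg_present], k_range=k_range, n_runs=n_runs
    ).fit(seed=seeds[0], k=fixed_k)
    d()

    # 3. DEGs across patterns + prognostic screen --------------------------
    d = _stage("signature")
    deg = moderated_f_test(adjusted, patterns.labels_)
    deg_pass = deg.index[deg["adj_p"] < deg_threshold].tolist()
    if not deg_pass:
        raise ValueError("no differentially expressed genes at the threshold")
    cox = univariate_cox_screen(adjusted, clinical, deg_pass)
    signature = derive_signature(deg, cox, deg_threshold, cox_threshold)
    d()

    # 4. second clustering on the signature genes --------------------------
    d = _stage("gene_clusters")
    gene_clusters = ConsensusNMF(
        adjusted.loc[signature.genes], k_range=k_range, n_runs=n_runs
    ).fit(seed=seeds[1], k=fixed_k)
    d()

    # 5. DMS + cutpoint -----------------------------------------------------
    d = _stage("dms")
    dms = DMSModel(adjusted, clinical, signature.genes, scale=dms_scale).fit(
        minprop=minprop
    )
    d()

    # 6. enrichment ---------------------------------------------------------
    d = _stage("enrichment")
    if gene_sets is None:
        gene_sets = {
            "tme28": genesets.synthetic_tme_sets(),
            "hallmark": genesets.synthetic_hallmark_sets(),
            "processes18": genesets.synthetic_process_sets(),
        }
    enrichment = {
        name: ssgsea_scores(adjusted, sets) for name, sets in gene_sets.items()
    }
    est_sets = genesets.synthetic_estimate_sets()
    try:
        enrichment["estimate"] = estimate_scores(
            adjusted,
            est_sets["STROMAL_SIGNATURE"],
            est_sets["IMMUNE_SIGNATURE"],
        ).T
    except ValueError:
        log.warning("estimate signatures absent from the matrix; skipped")

    # per-set Kruskal-Wallis across patterns, BH-adjusted
    rows = []
    for name, mat in enrichment.items():
        if name == "estimate":
            continue
        for gs in mat.index:
            stat, p = rank_tests(
                mat.loc[gs, patterns.labels_.index].to_numpy(),
                patterns.labels_.to_numpy(),
            )
            rows.append((name, gs, stat, p))
    group_tests = pd.DataFrame(
        rows, columns=["collection", "gene_set", "statistic", "p_value"]
    )
    if len(group_tests):
        from .diffexp import bh_adjust

        group_tests["adj_p"] = bh_adjust(group_tests["p_value"].to_numpy())
    d()

    # 7. survival contrasts -------------------------------------------------
    d = _stage("survival")
    clin = clinical.reindex(patterns.labels_.index)
    surv_rows = []
    for label_name, labels in (
        ("pattern", patterns.labels_),
        ("gene_cluster", gene_clusters.labels_),
        ("dms_group", dms.groups_),
    ):
        ok = clin["os_time"].notna() & clin["os_event"].notna()
        stat, df_, p = logrank_test(
            clin.loc[ok, "os_time"], clin.loc[ok, "os_event"], labels[ok]
        )
        surv_rows.append((label_name, "os", stat, df_, p))
    survival_tests = pd.DataFrame(
        surv_rows, columns=["grouping", "endpoint", "chi2", "df", "p_value"]
    )
    d()

    # 8. mutation summaries -------------------------------------------------
    d = _stage("mutations")
    mutation_reports = None
    if mutations is not None and len(mutations):
        mutation_reports = mutation_summaries(
            mutations,
            samples=list(adjusted.columns),
            genes=reg_present,
        )
    d()

    manifest = {
        "seed": seed,
        "stage_seeds": seeds,
        "n_samples": int(adjusted.shape[1]),
        "n_genes": int(adjusted.shape[0]),
        "k_selected": patterns.k_,
        "n_signature_genes": len(signature.genes),
        "dms_cutpoint": dms.cutpoint_,
        "input_hashes": [_hash_frame(c) for c in cohorts],
        "timings_s": timings,
    }
    return ReportBundle(
        merged=merged,
        batch=batch,
        adjusted=adjusted,
        patterns=patterns,
        deg_table=deg,
        cox_table=cox,
        signature=signature,
        gene_clusters=gene_clusters,
        dms=dms,
        enrichment=enrichment,
        group_tests=group_tests,
        survival_tests=survival_tests,
        mutation_reports=mutation_reports,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """File-based pipeline entry point: read inputs, run, write bundle."""
    config.validate()
    cohorts = [read_expression(p) for p in config.expression_paths]
    if len(cohorts) == 1:
        cohorts = cohorts  # single-cohort mode skips merging/combat
    clinical = read_clinical(config.clinical_path)
    mutations = read_mutations(config.mutation_path) if config.mutation_path else None
    gene_sets = (
        {name: read_gene_sets(p) for name, p in config.gene_set_paths.items()}
        or None
    )
    bundle = run_analysis(
        cohorts,
        clinical,
        mutations=mutations,
        gene_sets=gene_sets,
        regulators=config.regulators,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        n_runs=config.n_runs,
        fixed_k=config.fixed_k,
        deg_threshold=config.deg_threshold,
        cox_threshold=config.cox_threshold,
        dms_scale=config.dms_scale,
        minprop=config.minprop,
        seed=config.seed,
        skip_combat=config.skip_combat,
    )
    bundle.write(config.output_dir)
    return bundle
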