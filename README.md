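# methpattern

Colon tumors differ in how the DNA methylation machinery is wired:
*writers* (DNMT1, DNMT3A, DNMT3B) deposit 5-methylcytosine, *erasers*
(TET1-3) remove it, and eighteen *reader* proteins (MBDs, ZBTBs, UHRFs,
glycosylases, ...) interpret the mark.  The combined expression of these
24 regulator genes stratifies bulk transcriptomic cohorts into
modification **patterns** with distinct prognosis and distinct tumor
microenvironments — from immune-inflamed to immune-desert.
`methpattern` implements that analysis as a reusable, tested pipeline
for anyone who wants to apply it to their own expression cohorts or
interrogate its statistical behavior:

1. **Meta-cohort assembly** — merge cohorts on shared genes and remove
   per-cohort batch effects with parametric empirical-Bayes
   location/scale adjustment (the ComBat algorithm).
2. **Pattern discovery** — consensus nonnegative matrix factorization
   (KL multiplicative updates) of the 24-regulator sub-matrix, with
   subsampled restarts, cophenetic-correlation rank selection and
   size-ordered labels A, B, C, ...
3. **Prognostic signature** — an empirical-Bayes moderated F-test
   (limma-style variance shrinkage) finds genes differential across
   patterns at BH-adjusted p < 0.01; a per-gene univariate Cox screen
   (Newton-Raphson on the Efron partial likelihood) keeps those related
   to overall survival at p < 0.01.
4. **DNA methylation score (DMS)** — PCA over the signature genes; each
   sample's score is the sum of its first two principal-component
   projections, DMS = Σᵢ (PC1ᵢ + PC2ᵢ), with each axis oriented so that
   a higher score carries a higher hazard.  Patients split at the
   maximally selected rank-statistics cutpoint (survminer-style).
5. **Characterization** — ssGSEA single-sample enrichment for 28 immune
   cell types, pathway and treatment-biology signatures, ESTIMATE-style
   stromal/immune scores, preranked GSEA, Kaplan-Meier/log-rank,
   uni/multivariate Cox, time-dependent ROC/AUC, mutation frequencies,
   TMB and co-occurrence, and CNV gain/loss summaries.

A synthetic-cohort generator with planted ground truth (patterns,
differential genes, hazards, batch offsets, mutation burdens) makes the
whole pipeline testable end to end; the bundled gene-set fixtures are
synthetic stand-ins aligned with the generator and should be replaced
with real GMTs (e.g. MSigDB) for real data.

## Worked example

```python
import pandas as pd
from methpattern import (SyntheticConfig, generate_batched_cohorts,
                         merge_cohorts, combat_adjust, ConsensusNMF,
                         REGULATOR_SYMBOLS, moderated_f_test,
                         univariate_cox_screen, derive_signature,
                         DMSModel, logrank_test)

cfg = SyntheticConfig(n_samples=600, seed=7)          # 3 planted patterns
cohorts = generate_batched_cohorts(cfg)               # 3 batches w/ offsets
clinical = pd.concat([c.clinical for c in cohorts])
merged, batch = merge_cohorts([c.expression for c in cohorts])
expr = combat_adjust(merged, batch)

patterns = ConsensusNMF(expr.loc[list(REGULATOR_SYMBOLS)],
                        k_range=range(2, 6), n_runs=12).fit(seed=1)
print(patterns.summary())
```

```
Consensus NMF clustering
==========================
samples: 600   runs/rank: 12
rank   cophenetic   dispersion
  2       0.9208     0.5786
  3       0.9988     0.9920 *
  4       0.9813     0.7987
  5       0.9595     0.7595
pattern sizes: A=269, B=179, C=152
```

Rank 3 wins on consensus stability (cophenetic 0.999) and the sample
split mirrors the planted proportions.  Continuing:

```python
deg = moderated_f_test(expr, patterns.labels_)
hits = deg.index[deg["adj_p"] < 0.01].tolist()
cox = univariate_cox_screen(expr, clinical, hits)
sig = derive_signature(deg, cox)          # 478 DEGs -> 472 prognostic genes
dms = DMSModel(expr, clinical, sig.genes).fit()
print(dms.summary())
```

```
DNA methylation score (DMS) model
==================================
signature genes: 472   scaled: True
orientation HR per axis: PC1 1.043, PC2 1.050
training cutpoint: 6.7266 (|standardized log-rank| = 13.472, minprop = 0.1)
training groups: low=180, high=420
```

The low-DMS group (n = 180) is essentially the favorable pattern B; the
split separates survival sharply:

```python
chi2, df, p = logrank_test(clinical["os_time"], clinical["os_event"],
                           dms.groups_)
# chi2 = 181.5, p = 2.3e-41  (exploratory: the cutpoint was selected
# to maximize exactly this statistic)
```

`DMSResults.score(new_expr)` applies the frozen model (training means,
SDs and loadings) to validation cohorts; `run_analysis` /
`methpattern run --config config.yaml` drive all stages at once,
including the second NMF clustering on the signature genes and the
enrichment, survival and mutation reports.

## Command line

```bash
methpattern simulate --outdir sim --seed 3 --samples 600 --batches 3
methpattern merge --out merged.tsv sim/batch*/expression.tsv
methpattern combat --batch merged.batches.tsv --out adjusted.tsv merged.tsv
methpattern cluster --k-range 2:5 --runs 30 --seed 1 adjusted.tsv
methpattern dms fit --clinical clinical.tsv --genes signature_genes.txt \
    --out dms.json adjusted.tsv
```

## Documentation

`docs/methods.md` describes the statistical model of every stage, the
generator's design and its limits, and the numerical choices
(tolerances, tie-breaks, degenerate-input handling).
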