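# Methods

This note documents the statistical machinery of `methpattern`: what
each stage assumes, the parameters that matter, the numerical choices,
and what the synthetic-data validation does and does not establish.

## Data model

Expression is a genes × samples matrix of log2-scale, already-normalized
intensities (microarray or log-transformed RNA-seq).  Clinical tables
are indexed by sample ID and carry censored overall-survival
(`os_time` in months, `os_event` ∈ {0,1}) and optionally recurrence-free
survival, stage and molecular-subtype annotations.  Gene sets travel as
GMT; mutation calls as MAF-like rows (gene, sample, variant class).

## Cohort merging and batch correction

`merge_cohorts` intersects gene lists (sorted order, so the result is
independent of cohort order up to column permutation) and concatenates
samples; the source cohort index becomes the batch label.

`combat_adjust` is parametric empirical-Bayes ComBat: per gene, the data
are standardized against the batch-size-weighted grand mean and pooled
variance; per batch, location (γ) and scale (δ²) effects get a normal
and an inverse-gamma prior whose hyperparameters are moment-matched
across genes; the conditional posterior means are iterated to
convergence (tolerance 1e-6, ≤200 iterations) and the standardized data
are adjusted and back-transformed.  Only the intercept model is
implemented (no covariates) and only parametric priors — the common
configuration for merging same-platform expression cohorts.  Zero-
variance genes cannot be standardized; they pass through unchanged and
are logged.  Two properties worth knowing:

* The pooled per-gene mean is preserved (drift < 0.01 on the validation
  conditions) and a planted +5 log2 shift is removed to a residual
  batch-mean difference < 0.07.
* The adjustment is *not* exactly idempotent.  EB shrinkage deliberately
  leaves a small residual batch effect, and a second pass shrinks that
  residual again: on the validation conditions the second pass moves
  entries by about 1% of the first pass.  (Our implementation matches
  scanpy's ComBat to ~1e-6 absolute, so this is a property of the
  algorithm, not of the code.)

## Pattern discovery (consensus NMF)

The regulator panel is the fixed 24-gene catalogue (3 writers, 3
erasers, 18 readers).  Sample patterns are found by nonnegative matrix
factorization with Kullback-Leibler multiplicative updates (the Brunet
variant): W and H stay nonnegative by construction and the generalized
KL divergence is non-increasing per iteration; the per-iteration
objective trace is kept on the result.  H rows are rescaled to sum to
one so argmax labels are scale-invariant.

**Input transform.**  By default `ConsensusNMF` factorizes the per-gene
linear fold change `2**(x − rowmean(x))` rather than the raw log2
matrix.  The reason is identifiability, and it is the one place where
this implementation deliberately departs from feeding expression
straight into NMF: on log-scale data every gene carries a large additive
baseline, and that baseline mass can be distributed across metagenes in
infinitely many ways without changing the KL objective.  Restarts then
converge to equal-objective factorizations whose argmax labels disagree,
consensus stability stops discriminating the rank, and a two-cluster
solution looks perfectly stable on any data.  Dividing each gene by its
geometric-mean level (equivalently, exponentiating the centered log
values) removes the baseline while preserving the multiplicative
structure that KL-NMF models; cluster recovery and rank selection are
then sharp.  The raw path (global shift to a minimum of zero, recorded
in `shift_`) remains available via `fold_change=False`.

**Consensus.**  For each candidate rank k, `n_runs` factorizations are
run from distinct seeds, each on a random 80% subsample of the samples
(Monti-style).  The consensus entry C[i,j] is the fraction of co-sampled
runs in which i and j received the same argmax label.  Subsampling
matters: with restarts alone, a wrong rank that merges clusters the same
way on the full data looks perfectly stable; perturbing the sample set
makes such merges data-sensitive while the true rank stays stable.
Stability is summarized by the cophenetic correlation between the
consensus dissimilarity (1 − C) and the cophenetic distances of its
average-linkage dendrogram; a perfectly blocky consensus gets 1.0 by
convention.  `select_rank` takes the argmax (ties → smallest k).  Final
labels cut the average-linkage tree at k and are renamed A, B, C, … by
descending cluster size (ties by first occurrence), so outputs are
deterministic given seeds.  Ranks where every restart left a cluster
empty are flagged degenerate and excluded (cophenetic = NaN).

Defaults: `k_range` 2–5, `n_runs` 30, `max_iter` 300, relative KL
tolerance 1e-6, subsample 0.8.  On the validation conditions the
objective plateaus well before 300 iterations and labels are insensitive
to tightening the tolerance further.

## Differential expression and the prognostic screen

`moderated_f_test` fits a one-way group-mean model per gene and shrinks
the residual variances s²_g toward a common prior: the prior degrees of
freedom d0 and scale s0² are moment-matched on log s²_g via the digamma/
trigamma moments of the log-χ² distribution (Newton inversion of the
trigamma function), the posterior variance is
s̃² = (d0·s0² + d·s²)/(d0 + d), and the moderated F = MS_between / s̃²
is referred to an F distribution on (k−1, d + d0) degrees of freedom.
When the observed spread of log-variances is no larger than sampling
noise, d0 → ∞ and the common variance is the plain average of the
gene variances; the statistic then reduces to a pooled-variance F
(χ² reference).  The implementation agrees with limma's `eBayes`
moderated F to ~1e-6 relative on identical input.  Genes constant across
all samples carry no information and are flagged with p = 1.  Adjustment
is Benjamini-Hochberg step-up.

`univariate_cox_screen` fits one Cox proportional-hazards model per gene
on continuous expression, all genes simultaneously: Newton-Raphson on
the Efron-tie partial likelihood, vectorized across genes, with
step-halving, tolerance 1e-8 on the score and ≤50 iterations.  Constant
genes and diverging fits (|β| > 15, the monotone-likelihood signature of
separation) are flagged and excluded rather than reported.  Wald tests
and 95% CIs come from the observed information.  Against lifelines on
the same data the estimates agree to ~1e-6.

The signature is the intersection: BH-adjusted moderated-F p < 0.01 and
Cox Wald p < 0.01 (both thresholds configurable), ordered by adjusted p
then symbol.  An empty intersection is an explicit error, since the
score below cannot be built without genes.

## The DNA methylation score

`DMSModel.fit` centers (and by default unit-variance scales) the
signature genes, takes the top two right singular vectors of the
samples × genes matrix, and scores each sample as the **sum of its PC1
and PC2 projections**.  Interpretation note: the score formula
Σᵢ (PC1ᵢ + PC2ᵢ) is read as the per-sample sum of its two
principal-component scores — the convention of the signature-scoring
literature this design follows; a per-gene loading-sum variant would be
a different statistic and is intentionally not the default.

Sign conventions: each singular vector is first given a deterministic
orientation (largest-magnitude loading positive) so results do not
depend on the SVD backend, then flipped, if necessary, so that its
sample scores have a positive univariate Cox log-HR for overall
survival.  High DMS therefore always means higher hazard; without this
step the PCA sign is arbitrary and "high score = poor prognosis" would
be unidentifiable.  Unscaled PCA is available (`scale=False`); note that
scaling changes the numeric range of the score, so cutpoints are only
meaningful relative to the scaling under which they were fitted — the
score is unitless either way and absolute cutoff values do not transfer
between differently preprocessed data sets.

Scoring a new cohort applies the frozen training means, SDs and
loadings; nothing is refit.  Validation cohorts from other platforms
usually need their own cutpoint even so.

`optimal_cutpoint` is maximally selected rank statistics: every observed
score value leaving at least `minprop` (default 0.1) of samples on each
side is a candidate; the two-group standardized log-rank statistic is
computed for each split; the cut maximizing |z| wins (ties → smallest
cut).  The winning statistic is reported but must not be read as a
log-rank test — maximal selection inflates it far beyond the nominal
null (the test suite demonstrates rejection rates an order of magnitude
above 5% under independence).  Downstream log-rank p-values on the
chosen split are exploratory for the same reason.

## Single-sample enrichment and GSEA

`ssgsea_scores` ranks genes within each sample (average ranks on ties),
walks the list in descending rank order, and accumulates the difference
between the weighted in-set ECDF (weights |rank|^α, α = 0.25) and the
unweighted out-of-set ECDF.  Being rank-based, scores are invariant to
any within-sample monotone transform and to gene or sample order.  The
matrix is range-normalized (divided by max − min over all scores) by
default.  Sets with fewer than `min_set` (3) genes present are dropped
with a warning.  This scorer stands in for kernel-density GSVA wherever
single-sample pathway activity is needed; the method tag on the output
records that.

ESTIMATE-style summaries are ssGSEA scores of a stromal and an immune
signature, with the combined score defined as their sum.

`preranked_gsea` is the classical weighted Kolmogorov-Smirnov running
sum on a user-supplied ranking (the ranking metric is an explicit input,
not chosen internally).  The null is gene-label permutation: random
same-size sets drawn from the ranking.  The p-value is two-sided on |ES|
with a +1 pseudocount (hence never below 1/(n_perm+1)); NES divides ES
by the mean |null ES| of matching sign.  Gene-label permutation tests a
competitive null and is the only permutation scheme implemented.

## Survival and association statistics

Kaplan-Meier curves (Greenwood CIs), multi-group log-rank tests and
multivariate Cox models delegate to lifelines (Efron ties; rank-
deficient designs are rejected before fitting).  Time-dependent ROC/AUC
is the cumulative/dynamic estimator with inverse-probability-of-
censoring weights from the censoring Kaplan-Meier curve
(scikit-survival); other estimator families (e.g. the incident/dynamic
family) would give different values at the same horizon.  Rank tests are
Wilcoxon rank-sum (2 groups) or Kruskal-Wallis (≥3), with average-rank
tie handling; contingency tests are Pearson χ² without continuity
correction by default (Yates by flag) plus Fisher exact and a
Haldane-corrected odds ratio for 2×2 tables; correlation is Spearman.
All reported p-values are two-sided.

Mutation summaries count non-silent calls (the variant-class vocabulary
is the standard MAF set; unknown classes are excluded with a warning, or
included by flag): per-gene mutated-sample frequency over a caller-
supplied sample universe, per-sample TMB as the raw non-silent count
(an optional multiplicative constant converts to per-Mb), and pairwise
co-occurrence by Fisher exact tests on mutated/wild-type 2×2 tables,
BH-adjusted across pairs.  CNV gain/loss frequencies are the fractions
of calls above/below zero (thresholds configurable).

## The synthetic cohort generator

The generator produces the statistical structure the pipeline assumes,
with ground truth attached.  Layout (fixed gene rows, so the bundled
gene-set fixtures stay aligned): rows 0–23 the regulator panel (real
symbols, 8 defining genes per pattern); rows 24–303 the 28 cell-type
signature blocks (10 genes each); rows 304–323 stromal and immune
signatures; the last `n_sig_genes` rows the dedicated differential
block (k contiguous chunks); everything else null.

Expression = per-gene baseline N(6, 1) + pattern shift (`effect_size`
log2 units on the defining blocks) + optional per-batch offset
N(0, `batch_shift_sd`²) + residual N(0, `noise_sd`).  Batched cohorts
share one baseline vector so batch offsets are the only systematic
between-cohort difference.  Survival is exponential with the pattern's
monthly hazard (proportional hazards holds by construction), optionally
tilted by planted per-gene log-hazard coefficients, censored by an
independent exponential.  Mutation counts are per-sample Poisson with
the pattern's rate; variant classes are drawn uniformly from the MAF
vocabulary (so the non-silent TMB filter is exercised) with no
positional realism.  Therapy response is Bernoulli with a logit linear
in the planted prognostic score.

Default study conditions: n = 600 samples, 2000 genes, three patterns
with proportions (0.41, 0.30, 0.29), the kind of moderately unbalanced
split real colon-cancer meta-cohorts show, effect size 1.0, noise SD 0.5, three batches with offset SD 2,
censoring hazard 0.01/month, 150 dedicated differential genes, Poisson
mutation means (20, 45, 10).

**Hazard design.**  Per-pattern hazards are (0.055, 0.010, 0.065)/month:
the favorable pattern (index 1, the "B" analog — immune-inflamed, most
mutated) is the sole outlier, while the other two are close.  This is
deliberate.  A low/mid/high ladder looks natural but makes the middle
pattern's genes *marginally* non-prognostic — a gene elevated only in a
group whose hazard equals the risk-set average of the others has log-HR
near zero — so a univariate screen can never recover them, regardless of
sample size.  With one outlier pattern every planted block carries a
detectable marginal log-HR, and matches the clinical picture the
patterns represent (one distinctly favorable, immune-inflamed pattern;
two poor ones).  Median
survivals are ~13, 69 and 11 months.

Truth bookkeeping: `deg_genes` lists *every* gene with a planted
pattern-dependent mean — regulator blocks, TME/stromal/immune blocks and
the dedicated differential chunks — because all of them are genuinely
differential; recall and precision of the derived signature are measured
against this full list.

**What passing tests do and do not show.**  The generator's patterns are
spherical Gaussian blobs on disjoint gene blocks; real cohorts have
correlated genes, heavier tails, platform effects that are not purely
additive, informative censoring, and patterns that overlap.  Recovery at
ARI ≈ 1 here demonstrates correctness of the machinery at a favorable
signal-to-noise ratio (between-pattern separation ≈ 8 SD across a
block), not expected performance on real data; applying the pipeline to
real cohorts requires externally obtained expression, clinical and
mutation tables, which are outside the test loop.

## Numerical choices

* KL-NMF: tiny-float flooring (≈5e-324) prevents division by zero in the
  multiplicative updates; the objective uses the x·log(x/y) − x + y form
  with 0·log0 = 0.
* Trigamma inversion: Newton iterations from y = 0.5 + 1/x with
  closed-form limits for x < 1e-6 and x > 1e7.
* Cox screens clip the linear predictor at ±700 before exponentiation;
  step-halving (≤10 halvings) guards the Newton step.
* Cutpoint search is exact enumeration over admissible candidate values;
  no approximation is involved, so it matches any brute-force scan.
* Consensus seeds fan out from one root through `SeedSequence` spawn
  keys, so adding ranks does not perturb other ranks' runs; all seeds
  are reduced below 2³¹.
* Degenerate inputs are errors, not warnings, wherever a silently wrong
  number could result: empty signatures, all-tied scores, zero events,
  constant vectors in correlations, rank-deficient Cox designs.

## Known limitations

* ComBat supports no covariates and no non-parametric priors.
* Only gene-label permutation GSEA; no phenotype permutation.
* The ssGSEA scorer replaces kernel-density GSVA for single-sample
  pathway activity; scores correlate strongly but are not numerically
  interchangeable with GSVA's.
* TMB is a raw count by default; per-Mb conversion is the caller's
  constant.
* The bundled GMT fixtures are synthetic, matched to the generator's
  layout; conclusions about real immune biology require real gene sets
  and real cohorts.
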