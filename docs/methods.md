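# Methods

## Synthetic cohort model

The generator produces the joint structure the analysis assumes — genotype,
expression, race, and survival — from one seed.

**Genotypes.** Each SNP has a per-population alt-allele frequency *f*;
dosages are drawn Binomial(2, *f*) per sample, i.e. Hardy–Weinberg
equilibrium within population, with no linkage disequilibrium or admixture.
Background (non-driver) SNPs share one frequency across populations, so
they carry no between-race signal and serve as negatives for the
consistency stage.

**Expression.** Counts for gene *g* in sample *i* are negative binomial
with mean

&nbsp;&nbsp;μ<sub>gi</sub> = μ₀ · s<sub>i</sub> · 2^(β<sub>g</sub>·dos<sub>i</sub> + δ<sub>g,race(i)</sub>)

and variance μ + α·μ². Defaults: baseline mean μ₀ = 500 (a
moderately expressed gene at bulk RNA-seq depth), shared dispersion
α = 0.2 (typical biological overdispersion for bulk tumor cohorts),
lognormal library-size factors s<sub>i</sub> with σ = 0.3 and mean one.
β<sub>g</sub> is the planted additive cis-eQTL log2 effect per alt allele
(0 for non-driver genes); δ the planted race-specific log2 shift for
genes differentially expressed without genotype mediation. Under this
model a driver's group-mean expression ordering across populations
mechanically equals the allele-frequency ordering times sign(β), which is
exactly the structure the consistency test is designed to detect.

**Survival.** Times are exponential with hazard
λ₀·exp(Σ<sub>g</sub> θ<sub>g</sub>·z<sub>g</sub>(i)), where z is the
per-gene standardized log2(count+1) and λ₀ = 0.05 by default. Each sample
is censored independently with probability `censor_rate` (default 0.3); a
censored sample's recorded time is uniform on (0, t) so censoring always
precedes the latent event, and `censor_rate = 1` yields an all-censored
table. This is the minimal proportional-hazards generator adequate for
validating median-split log-rank behaviour; it does not model competing
risks, time-varying effects, or informative censoring.

**Cohort matching.** Ratio matching (e.g. AS:AA:CA = 1:1:4) downsamples the
surplus groups without replacement to exactly k·ratio with k maximal,
deterministically per seed, preserving original row order. Oversampling is
never used.

**What the generator does not emulate.** Real tumor cohorts have batch
effects, cancer-type-specific baselines, gene–gene correlation, LD between
SNPs, and ancestry admixture; none are modelled. Passing the planted-driver
recovery suites therefore demonstrates that the pipeline's logic and
statistics are correct under its stated assumptions, not that the same
power or error rates hold on real TCGA-like data.

## Differential expression

Counts are normalized per sample to a 40-million-read target library and
transformed log2(x·L/colsum + 1); the +1 pseudocount keeps zeros at zero
and the scaling makes proportional columns identical. Per gene, group vs
reference is tested with a two-sided Welch unequal-variance t-test on the
normalized values, log2FC defined as the difference of group means (so the
antisymmetry log2FC(A,B) = −log2FC(B,A) holds exactly), and BH adjustment
applied within each comparison. Genes constant in both groups get p = 1
rather than NaN. The Welch test is a deliberate self-contained stand-in
for moderated-variance NB model fits: it is seedable, dependency-light,
and its log2FC semantics match the fold-change thresholding downstream.
DEG thresholds default to |log2FC| ≥ 0.585 (1.5-fold) with padj ≤ 0.05;
a 2-fold criterion (≥ 1.0) is the convention for single-cancer analyses
and both are exposed in config.

## Survival stratification

Expression is median-split with ties assigned to the low group, so "high"
is strictly above the median (constant genes are an error, as the split is
undefined). Curves are Kaplan–Meier product-limit estimates and the
two-group comparison is the standard log-rank chi-square with 1 df, both
delegated to lifelines; a degenerate comparison with no comparable risk
sets returns p = 1 with a warning instead of NaN. The screen reports a
direction of effect: the sign of S_high − S_low at the last common event
time. By default the split is computed globally across the cohort; users
can subset by cancer type and rerun if a per-cancer split is wanted.

## eQTL fitting and orientation

Association is ordinary least squares of normalized expression on additive
alt-allele dosage with a two-sided t-test on the slope; missing genotypes
are dropped pairwise, and monomorphic SNPs are flagged untestable and
excluded downstream. BH adjustment runs across all tested SNP–gene pairs,
and a significance gate (padj ≤ 0.05) is applied before a pair enters the
consistency stage. The expression-increasing allele is alt iff slope > 0;
its per-population frequency is derived from the stored alt-allele
frequency at use time (complemented when the increasing allele is ref),
which makes every downstream verdict invariant to ref/alt relabelling.
No covariate correction or cis-window restriction is applied; pairs are
supplied explicitly.

## Consistency calls and ranking

Per comparison (A vs B) with DE direction d ≠ 0, the call is consistent
iff sign(f_A − f_B) = d and |f_A − f_B| ≥ `min_gap`; NDE comparisons are
skipped, as are sub-gap frequency differences. `min_gap` defaults to 0.02:
population frequency estimates from reference panels carry sampling noise
of roughly this order, and calling a direction on a smaller gap would be
spurious precision. The verdict demands unanimity over evaluated
comparisons — partially consistent pairs are reported with their counts
but never promoted. Candidate ranking (consistent verdict + survival
padj ≤ α, ordered by n_consistent, then survival p, then max |log2FC|,
then gene id) is deliberately a total order so runs are reproducible;
pairs that are consistent but survival-null are kept in a secondary
listing rather than discarded.

Recurrent gene-family selection operationalizes "similar differential
expression patterns" as same-direction DEG status in the same comparison:
a family passes when one (cancer, comparison) cell holds ≥ 2 members with
a shared direction and members are DE with a shared direction in ≥ 2
distinct cancers.

## Bayesian network module

Feature selection is two-stage: mRNA variables with |Pearson r| to the
seed gene above the mRNA threshold (default 0.38), then microRNA,
methylation, and protein variables with |r| above their layer thresholds
(0.45 / 0.40 / 0.30) to any selected transcript. Pearson correlation is
the default; the choice is exposed in config.

Structure learning maximizes a linear-Gaussian BIC — per node, the OLS
Gaussian log-likelihood given its parents minus (k/2)·log n — treating all
layers as continuous. The search is greedy hill climbing over add, delete,
and reverse moves, accepting the best improving move until a local
optimum, restarted from seeded random DAGs (default 20 restarts, first
restart from the empty graph), with acyclicity checked at every move, ties
broken lexicographically, and in-degree capped at 3 to bound overfitting
at the small n typical after feature selection. Within each restart the
score trajectory is non-decreasing by construction, and the learned score
is never below the empty graph's. Orientation of individual edges is
identifiable only up to Markov equivalence, so the test suite asserts
skeleton recovery, not edge directions. No layer-based edge constraints
(e.g. methylation → mRNA only) are imposed by default.

## Numerical choices and degenerate inputs

- p-values are clipped into (0, 1]: a perfect-fit regression reports the
  smallest positive float rather than 0.
- Zero-variance genes: p = 1 in DE; an error in median split.
- Multi-allelic VCF records are rejected, not split — the consistency
  calculus is biallelic.
- All coordinates keep the 1-based VCF convention; floats are written at
  six significant digits, and TSV round-trips are exact modulo that
  formatting.
- Randomness flows only through explicit seeds (`numpy.random.default_rng`);
  an identical config and seed reproduce every output byte for byte.
- Ward clustering for heatmap ordering uses the squared-Euclidean (Ward.D2)
  update via scipy.

## Problem sizes in the benchmark suites

The validation suites run at sizes chosen to give stable statistics from a
single CPU: DE recovery at 300 samples per group with 200 genes over 10
seeds (the per-seed standard error of a recovered log2FC is ≈ 0.05, so
the 10-seed mean is estimated to ≈ 0.017); allele-frequency recovery on
panels of 5000 (binomial SE ≈ 0.005 at f = 0.5); consistency sensitivity
and specificity at 100/100/400 samples over 20 seeds; network skeleton
recovery at n = 1000 over 20 seeds.

## Known limitations

- The Welch stand-in loses power relative to NB GLMs at very small group
  sizes and low counts; effect-size estimates are attenuated when one gene
  dominates the library (composition effect of column-sum normalization).
- The hill-climbing learner is a generic score-based method; it makes no
  claim to reproduce any specific published network-learning algorithm.
- Pathway enrichment, literature validation, and coding-variant impact
  prediction are out of scope.
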