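# Methods

This note records the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical and design decisions a maintainer would want
spelled out.

## Harmonization

Two summary-statistics tables are inner-joined on rsID and study B is
re-expressed on study A's effect allele. A record aligns if its allele pair
matches directly, after one effect/other swap (negating β_B and setting
`flipped`), after a strand complement, or after both. Everything else is
dropped and counted by reason, as are records whose chromosome/position
disagree between studies (no reconciliation is attempted — disagreement
usually signals a build mismatch the user must resolve). Palindromic (A/T,
C/G) SNPs are dropped by default because strand cannot be resolved without
allele-frequency data; `drop_palindromic=False` retains them under a
same-strand assumption. Coordinates are 1-based inclusive throughout;
position-based joining and liftover are out of scope.

## Synthetic data

The generator supplies ground-truth inputs in three layers.

**Reference panel.** Haplotypes arise by thresholding a latent AR(1)
Gaussian (per-block correlation ρ, default 0.9) at the per-SNP MAF
quantile; dosage is the sum of two independent haplotypes. LD is therefore
block-diagonal with geometrically decaying r² inside blocks and exactly 0
across blocks — simple, controllable, and sufficient for exercising greedy
pruning and windowed covariance. MAFs are uniform on (0.05, 0.5) by
default. Simulated allele pairs are drawn from the eight
non-strand-ambiguous combinations so a simulated pair harmonizes
losslessly; palindromic handling is exercised by hand-built tables in the
tests instead.

**Summary statistics.** Rather than simulating genotype-to-GWAS for
millions of observations, marginal z-scores follow the standard
summary-statistics model z ~ MVN(R·λ, R) per block, where R is the panel's
(ridge-stabilized) dosage correlation matrix and λ_j = β_j/SE_j is the
per-SNP non-centrality. SE_j = 1/√(2 f_j (1−f_j) n_eff) with
n_eff = 4/(1/n_cases + 1/n_controls), the usual large-sample SE of a
per-allele log-OR. β = z·SE and p is the two-sided normal tail (clamped at
10⁻³⁰⁰ to stay in (0,1]). The two traits' noise is independent, matching
non-overlapping study designs; sharing enters only through the planted
architecture. `shared_architecture` places causal SNPs at block centres
with effects sized so the causal SNP's expected z equals a requested
non-centrality, and assigns trait-B signs so that a chosen fraction of
shared loci is direction-concordant.

**Cohorts.** For the score stage, individual dosages are drawn from the
same block model and a liability L_i = Σ_j (d_ij − 2f_j) β_j + ε_i,
ε ~ N(0,1) is thresholded at the *empirical* (1 − prevalence) quantile, so
the case count is deterministic given the seed. Sex and a study-of-origin
label (up to 6 levels, mirroring multi-cohort consortium data) are uniform
and independent of genotype.

What this does **not** emulate: realistic demography or coalescent LD,
imputation uncertainty, allele-frequency differences between studies,
cryptic relatedness or stratification, or the X chromosome. Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean, known architecture — not robustness to the confounders of real
consortium data.

## Overlap enrichment

Greedy pruning follows the classic p-ordered rule: repeatedly keep the best
remaining SNP (smallest ordering-trait p; ties broken by chromosome and
position so the output is deterministic) and remove every remaining SNP
with r² above the threshold (default 0.05) to it. r² is the squared Pearson
correlation of panel dosages within a block (cross-block r² is 0), or a
user-supplied long-format r² table with unlisted pairs counting as 0. SNPs
missing from the LD source are dropped with a warning by default.

The Fisher exact test is implemented in-package with the
minimum-likelihood two-sided convention (sum of hypergeometric
probabilities ≤ the observed table's). For table totals up to 5,000 the
tail is accumulated in exact integer arithmetic, which removes any
tie-breaking ambiguity at symmetric tables; larger totals use log-gamma
probabilities with a 10⁻⁷ relative tie tolerance (the convention of the
standard library implementations, which serve as an independent
cross-check in the tests). The same minimum-likelihood convention is used
for the exact binomial test — it is what reproduces p = 0.0768 ≈ 0.08 for
12 successes in 16 trials at p₀ = ½.

The scan's five default cutoffs are 10⁻², 10⁻³, 10⁻⁴, 10⁻⁵, 10⁻⁶,
BH-adjusted together as one family (the number of cutoffs is
configurable), with corrected p < 0.01 flagged as excess overlap.
Degenerate margins (e.g. cutoff 1) produce a valid table with p = 1. The
permutation p uses the add-one estimator (1 + #{null ≤ observed})/(n+1),
which can never return 0. Direction concordance among doubly significant
pruned SNPs returns a flagged undefined result (not 0/0) when no SNP
qualifies. Subtype analyses (e.g. migraine without/with aura vs the other
trait) are the same scan run on subtype summary statistics; there is no
special code path.

## Polygenic risk score

Risk sets are all source SNPs with p ≤ tier threshold (defaults
5×10⁻⁸ / 10⁻⁴ / 10⁻², labelled strong/moderate/weak), deliberately not
LD-pruned — correlated SNPs up-weight well-supported loci and maximize
sensitivity. Scores reconcile cohort dosages to each risk SNP's effect
allele (2 − d when the cohort counts the other allele, directly or on the
complementary strand); risk SNPs absent from the cohort are skipped and
counted, missing dosages are skipped per individual rather than
mean-imputed, and a flag is raised when over half the risk set is
unusable. The logistic model is phenotype ~ standardized score + sex +
reference-coded cohort dummies; standardizing the score gives the odds
ratio a defined per-SD scale. Intervals are Wald at 95% — adequate at the
simulated sample sizes and much cheaper than profile likelihood. Constant
covariates are dropped with a warning; non-convergence or separation is
reported via a `converged=False` result rather than an exception.

## Cross-Phenotype Spatial Mapping

The region scan asks where the two traits' association profiles covary.
Profiles are −log₁₀(p) (floored at a configurable 10⁻³⁰ to absorb
underflow) and then Blom rank-normalized within chromosome. The rank step
is what makes the window statistic comparable between traits with very
different p-value distributions, and it makes the whole scan invariant to
any strictly monotone transform of either trait's p-values. The statistic
is the sample covariance (ddof = 1) of the two profiles in sliding windows
(defaults: 100 SNPs wide, step 50, minimum 10 SNPs, never spanning a
chromosome; a trailing partial window is kept when it holds enough SNPs).

The null circularly rotates one trait's profile by a random offset within
each chromosome, preserving that trait's local autocorrelation from LD
while breaking only the cross-trait alignment; a full-shuffle mode exists
for comparison. The significance threshold is the 99.95th percentile of
the null window statistics pooled across permutations (default 1,000).
Windows above threshold that overlap or lie within 50 kb merge into
regions; each region reports its per-trait lead SNP (smallest p inside the
interval) and whether the two leads' harmonized betas share a sign.

Two practical notes. First, because observed windows overlap (step <
window) and each seed shares one estimated threshold, pooled null
exceedance counts are slightly overdispersed relative to binomial.
Second, the rotation null retains each trait's signal peaks, so rotations
that happen to re-align two true peaks contaminate the extreme null tail;
the contamination fraction scales with (locus width)/(genome size), so the
scan needs the genome to be large relative to any single locus — with the
default window and a 50-SNP locus, a few thousand SNPs suffice, and the
test suite sizes its panels accordingly.

Subtype annotation looks up each region's trait-A lead SNP in two subtype
GWAS tables, counts leads with a strictly lower p in the first subtype
(ties conservatively count as "not lower"), and tests that count against
Binomial(n, ½) two-tailed; leads missing from either table are excluded
from the denominator and noted.

## Known-locus cross-query

Each trait's established lead SNPs are looked up in the other trait's
table. Leads absent from the table (or with irreconcilable alleles) are
excluded and shrink the Bonferroni denominator — no proxy substitution.
The two directions (A-leads in B, B-leads in A) are corrected as separate
families of their actually-testable sizes; the family α defaults to 0.05.
Direction agreement compares the lead's discovery-trait sign with the
other-trait beta after aligning it to the lead's effect allele.

## Pipeline and reproducibility

`run_pipeline` validates every enabled stage's parameters before anything
runs, executes harmonize → overlap → prs → cpsm → knownloci, echoes the
config into the output directory, and writes a manifest with the seed,
package/library versions and input SHA-256 checksums. All stage randomness
derives from the single run seed through per-stage spawned substreams, so
toggling one stage never changes another's draws; two runs with the same
config and seed produce byte-identical tables.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at desk scale: 5,000-SNP genomes (100 blocks of
50) for calibration and region-detection runs, 500–1,000-SNP genomes for
score recovery, cohorts of n = 2,000, 1,000 permutations for the region
null, and 20–50 seeds per calibration claim. These sizes were chosen so
each Monte-Carlo estimate has tolerable binomial error while the whole
suite stays interactive; the statistics themselves are size-agnostic.

## Known limitations

* The region-scan statistic is a stated windowed-covariance realization of
  the spatial-mapping idea; other reasonable realizations (kernel
  smoothing, per-window permutation thresholds) exist and could rank loci
  slightly differently.
* The rotation null is conservative in small genomes (see above).
* The generator's AR(1) block LD has no long-range structure, so pruning
  behaviour on real panels with irregular LD will differ in detail.
* Wald intervals can misbehave near separation; such fits are flagged
  rather than refined.
* Allele-frequency-based strand inference for palindromic SNPs is
  deliberately not implemented.
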