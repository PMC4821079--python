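# crossgwas

Toolkit for asking whether two complex diseases share genetic risk, using
genome-wide association study (GWAS) results. It was built around the
migraine / coronary-artery-disease question — two disorders with suspected
vascular common ground — but every stage is generic over any pair of
case/control GWAS.

The package is aimed at statistical geneticists who have per-SNP summary
statistics for two traits (and, optionally, individual-level genotypes for
one of them) and want to quantify shared risk at four levels:

1. **Overlap enrichment** (`crossgwas.overlap`). Harmonized SNPs are
   greedily pruned to approximate linkage equilibrium (drop everything with
   LD r² > 0.05 to a better-ranked SNP, ranked by association p). For each
   p-value cutoff *t* the pruned SNPs are cross-tabulated into a 2×2 table
   by (p_A ≤ t) × (p_B ≤ t) and tested with a two-sided Fisher exact test;
   the scan is Benjamini–Hochberg corrected, with corrected p < 0.01 called
   an excess of overlapping signals. An empirical null that permutes the
   SNP↔p assignment within each trait backs the parametric test, and an
   exact binomial test measures effect-direction concordance of the doubly
   significant SNPs.
2. **Polygenic risk score** (`crossgwas.prs`). Tiered (strong/moderate/weak)
   risk-SNP sets from trait B's GWAS, per-individual scores
   `S_i = Σ_j d_ij β_j` (dosage × log-OR), and a logistic regression of
   trait-A status on the standardized score adjusted for sex and
   study-of-origin dummies. The reported odds ratio is per 1 SD of score.
3. **Cross-Phenotype Spatial Mapping** (`crossgwas.cpsm`). A region scan
   for *where* the sharing lives: both traits' p-values are transformed to
   rank-normalized −log₁₀(p) profiles, a sliding window computes their
   covariance, and windows above the 99.95th percentile of a
   circular-rotation permutation null (1,000 permutations by default) are
   merged into regions reported with per-trait lead SNPs and
   effect-direction agreement.
4. **Known-locus cross-query** (`crossgwas.knownloci`). Established lead
   SNPs of each trait looked up in the other trait's GWAS under a
   Bonferroni threshold of α divided by the number of testable SNPs.

A synthetic-data module (`crossgwas.simulate`) generates LD-structured
reference panels (block-diagonal AR(1) haplotype model), two-trait summary
statistics from the standard z ~ MVN(R·λ, R) model with plantable shared
loci of chosen effect-direction concordance, and individual-level
case/control cohorts under a liability-threshold model — so every stage can
be validated against known ground truth.

## Worked example

Simulate a 1,000-SNP genome with two shared causal loci whose effects point
in *opposite* directions for the two traits, then run the stages:

```
crossgwas simulate --out-prefix sim --n-blocks 40 --snps-per-block 25 \
    --n-individuals 200 --n-shared 2 --noncentrality 8 --concordance 0 --seed 7
crossgwas harmonize --sumstats-a sim.trait_a.tsv --sumstats-b sim.trait_b.tsv --out pair.tsv
crossgwas overlap --pair pair.tsv --ld sim --perms 1000 --seed 7 --out overlap.tsv
crossgwas cpsm    --pair pair.tsv --window 50 --step 25 --perms 1000 --seed 7 --out-prefix cpsm
crossgwas prs     --source sim.trait_b.tsv --cohort sim.cohort --out prs.tsv
```

`overlap.tsv` (abridged):

```
cutoff  n11  n10  n01  n00  fisher_p   fdr_p      flagged  perm_p     concordant  total
0.01    2    4    0    109  0.0022883  0.0022883  True     0.0029970  0           2
1e-05   2    0    0    113  0.0001526  0.0003814  True     0.0009990  0           2
```

Both planted loci survive pruning and are significant in both traits at
every cutoff, so the corrected Fisher p flags excess overlap (`flagged`),
confirmed by the permutation p; 0 of 2 shared signals agree in direction,
as planted. `cpsm.regions.tsv` localizes the sharing:

```
chrom  start    end      peak_stat  lead_snp_a  lead_p_a  lead_snp_b  lead_p_b  direction_agreement
1      4185000  4745000  1.113      rs513       1.7e-17   rs513       2.6e-20   False
```

— one region whose lead SNP for both traits is the planted causal variant
(rs513), with opposite effect signs. And `prs.tsv` shows the risk-score
view of the same architecture: trait-B risk alleles are *protective* for
trait A, so the odds ratio per SD of score is below 1:

```
tier      n_snps  odds_ratio  ci_low  ci_high  p
strong    5       0.872       0.794   0.957    0.0039
moderate  10      0.849       0.773   0.933    0.00068
weak      38      0.892       0.812   0.981    0.019
```

The whole pipeline can also be run from one YAML config with
`crossgwas run --config config.yaml`, which writes per-stage TSVs and a
reproducibility manifest (seed, versions, input checksums).

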