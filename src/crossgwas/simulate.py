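"""Synthetic GWAS data with controllable shared genetic architecture.

Three generators give every analysis stage ground-truth inputs:

* :func:`simulate_panel` — an LD reference panel of diploid dosages with
  block-diagonal AR(1) linkage disequilibrium, emulating the haplotype-block
  structure of a HapMap-style European reference panel.
* :func:`simulate_sumstats_pair` — marginal association z-scores for two
  case/control traits drawn from the standard summary-statistics model
  z ~ MVN(R·λ, R), where R is the block LD correlation matrix and λ the
  per-SNP non-centrality (true log-OR divided by its sampling SE). Shared
  causal loci with configurable effect-direction concordance plant a joint
  architecture.
* :func:`simulate_cohort` — individual-level case/control data under a
  liability-threshold model, for the polygenic-risk-score stage which needs
  genotypes rather than summaries.

All randomness flows from a single integer seed per call; identical seeds
give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats, validate_sumstats

logger = logging.getLogger(__name__)

# non-strand-ambiguous allele pairs only, so simulated pairs harmonize losslessly
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]

_SNP_SPACING_BP = 5_000
_BLOCK_GAP_BP = 100_000


@dataclass
class LDBlockSpec:
    """Layout of the simulated LD structure.

    Blocks are mutually independent; within a block, adjacent SNPs' latent
    haplotype liabilities follow an AR(1) process with correlation
    ``within_block_rho``, so r² decays geometrically with SNP distance.
    """

    n_blocks: int = 20
    snps_per_block: int = 50
    within_block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chroms: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise ValueError("n_blocks and snps_per_block must be >= 1")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (1 <= self.n_chroms <= 22 and self.n_chroms <= self.n_blocks):
            raise ValueError("n_chroms must be in [1, min(22, n_blocks)]")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class ReferencePanel:
    """Reference genotypes used as the LD source for pruning and simulation.

    ``dosages`` is individuals × SNPs with values in {0, 1, 2}; ``snps``
    carries id, chrom, pos, alleles, block index and the generative MAF.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    spec: LDBlockSpec
    seed: int

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def block_indices(self, block: int) -> np.ndarray:
        """Column indices of the SNPs in one LD block."""
        return np.flatnonzero(self.snps["block"].to_numpy() == block)

    def block_corr(self, block: int, ridge: float = 1e-6) -> np.ndarray:
        """Sample dosage correlation matrix of one block, ridge-regularized
        toward positive definiteness (monomorphic columns get r = 0)."""
        d = self.dosages[:, self.block_indices(block)].astype(float)
        sd = d.std(axis=0)
        keep = sd > 0
        r = np.eye(d.shape[1])
        if keep.sum() >= 2:
            sub = np.corrcoef(d[:, keep], rowvar=False)
            r[np.ix_(keep, keep)] = sub
        r = (r + ridge * np.eye(len(r))) / (1 + ridge)
        return r

    def r2_matrix(self, snp_ids) -> np.ndarray:
        """Pairwise r² for the requested SNPs (cross-block pairs are 0)."""
        idx = self.snps.set_index("snp_id").index.get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs absent from panel: {missing[:5]}")
        blocks = self.snps["block"].to_numpy()[idx]
        d = self.dosages[:, idx].astype(float)
        sd = d.std(axis=0)
        ok = sd > 0
        r2 = np.zeros((len(idx), len(idx)))
        if ok.sum() >= 2:
            c = np.corrcoef(d[:, ok], rowvar=False) ** 2
            r2[np.ix_(ok, ok)] = c
        r2[blocks[:, None] != blocks[None, :]] = 0.0
        np.fill_diagonal(r2, 1.0)
        return r2


def _block_latents(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n draws of an m-dimensional standard-normal AR(1) series."""
    eps = rng.standard_normal((n, m))
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        out[:, j] = rho * out[:, j - 1] + scale * eps[:, j]
    return out


def _draw_dosages(rng: np.random.Generator, n: int, spec: LDBlockSpec,
                  mafs: np.ndarray) -> np.ndarray:
    """Diploid dosages for ``n`` individuals under the block AR(1) model."""
    m = spec.snps_per_block
    cols = []
    for b in range(spec.n_blocks):
        thr = stats.norm.ppf(mafs[b * m:(b + 1) * m])
        h1 = _block_latents(rng, n, m, spec.within_block_rho) < thr
        h2 = _block_latents(rng, n, m, spec.within_block_rho) < thr
        cols.append((h1.astype(np.int8) + h2.astype(np.int8)))
    return np.concatenate(cols, axis=1)


def simulate_panel(spec: LDBlockSpec, n_individuals: int, seed: int) -> ReferencePanel:
    """Simulate a reference panel of ``n_individuals`` diploid genomes.

    Haplotype alleles arise by thresholding a latent AR(1) Gaussian at the
    per-SNP MAF quantile, so adjacent-SNP LD is governed by
    ``spec.within_block_rho`` and cross-block r² is 0 by construction.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    dosages = _draw_dosages(rng, n_individuals, spec, mafs)

    blocks = np.repeat(np.arange(spec.n_blocks), spec.snps_per_block)
    blocks_per_chrom = int(np.ceil(spec.n_blocks / spec.n_chroms))
    chroms = blocks // blocks_per_chrom + 1
    pos = np.empty(spec.n_snps, dtype=int)
    offset = {}
    for j in range(spec.n_snps):
        c = chroms[j]
        offset[c] = offset.get(c, 0) + (
            _BLOCK_GAP_BP if j > 0 and chroms[j - 1] == c and blocks[j] != blocks[j - 1]
            else _SNP_SPACING_BP
        )
        pos[j] = offset[c]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=spec.n_snps)
    snps = pd.DataFrame({
        "snp_id": [f"rs{j + 1}" for j in range(spec.n_snps)],
        "chrom": chroms.astype(int),
        "pos": pos,
        "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "block": blocks,
        "maf": mafs,
    })
    return ReferencePanel(dosages, snps, spec, seed)


# ---------------------------------------------------------------------------
# Genetic architecture


@dataclass
class Architecture:
    """Per-SNP true effects (log-OR scale) for two traits.

    ``shared_loci`` records (block, effect_a, effect_b) for loci causal to
    both traits; ``direction_concordance`` is the fraction of shared loci
    whose effects carry the same sign. Trait-specific causal SNPs appear in
    exactly one of the effect vectors.
    """

    beta_a: np.ndarray
    beta_b: np.ndarray
    shared_loci: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def direction_concordance(self) -> float:
        if not self.shared_loci:
            return float("nan")
        same = sum(1 for _, ea, eb in self.shared_loci if np.sign(ea) == np.sign(eb))
        return same / len(self.shared_loci)


def null_architecture(panel: ReferencePanel) -> Architecture:
    """No causal variants for either trait."""
    z = np.zeros(panel.n_snps)
    return Architecture(z, z.copy())


def effective_n(n_cases: int, n_controls: int) -> float:
    """Effective sample size 4/(1/n_cases + 1/n_controls) of a case/control GWAS."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def beta_se(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    """Large-sample SE of a per-allele log-OR: 1/sqrt(2·f(1−f)·n_eff)."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * effective_n(n_cases, n_controls))


def shared_architecture(
    panel: ReferencePanel,
    shared_blocks,
    noncentrality_a: float,
    noncentrality_b: float,
    n_a: tuple[int, int],
    n_b: tuple[int, int],
    *,
    direction_concordance: float = 1.0,
    seed: int = 0,
) -> Architecture:
    """Plant shared causal loci at the centre SNP of the given blocks.

    Effect sizes are chosen so the causal SNP's expected marginal z-score
    equals the requested non-centrality at the given study sizes. Trait A's
    effects are positive; a fraction ``direction_concordance`` of trait B's
    effects share the sign, the rest are opposite (assigned deterministically
    from ``seed``).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    beta_a = np.zeros(panel.n_snps)
    beta_b = np.zeros(panel.n_snps)
    se_a = beta_se(panel.snps["maf"].to_numpy(), *n_a)
    se_b = beta_se(panel.snps["maf"].to_numpy(), *n_b)
    shared = []
    blocks = list(shared_blocks)
    n_same = int(round(direction_concordance * len(blocks)))
    signs = np.array([1.0] * n_same + [-1.0] * (len(blocks) - n_same))
    rng.shuffle(signs)
    for block, sign in zip(blocks, signs):
        idx = panel.block_indices(block)
        causal = idx[len(idx) // 2]
        ea = noncentrality_a * se_a[causal]
        eb = sign * noncentrality_b * se_b[causal]
        beta_a[causal] = ea
        beta_b[causal] = eb
        shared.append((int(block), float(ea), float(eb)))
    return Architecture(beta_a, beta_b, shared)


# ---------------------------------------------------------------------------
# Summary-statistics simulation


def _simulate_z(panel, beta_true, se, rng) -> np.ndarray:
    """Draw marginal z-scores ~ MVN(R·λ, R) block by block."""
    lam = beta_true / se
    z = np.empty(panel.n_snps)
    for b in range(panel.spec.n_blocks):
        idx = panel.block_indices(b)
        r = panel.block_corr(b)
        try:
            chol = np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            logger.warning("block %d LD matrix singular; adding ridge", b)
            r = (r + 1e-3 * np.eye(len(r))) / (1 + 1e-3)
            chol = np.linalg.cholesky(r)
        mean = r @ lam[idx]
        z[idx] = mean + chol @ rng.standard_normal(len(idx))
    return z


def _sumstats_from_z(panel, z, se, n_cases, n_controls) -> SummaryStats:
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)
    df = panel.snps[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    df["beta"] = z * se
    df["se"] = se
    df["p"] = p
    df["n_cases"] = n_cases
    df["n_controls"] = n_controls
    return validate_sumstats(df, source="<simulated>")


def simulate_sumstats_pair(
    panel: ReferencePanel,
    arch: Architecture,
    n_a: tuple[int, int],
    n_b: tuple[int, int],
    seed: int,
) -> tuple[SummaryStats, SummaryStats]:
    """Simulate a pair of GWAS summary-statistics tables over the panel's SNPs.

    Per trait, z ~ MVN(R·λ, R) blockwise with λ = true log-OR / SE(log-OR);
    beta = z·SE and p the two-sided normal tail. The two traits' sampling
    noise is independent (non-overlapping studies); shared signal enters only
    through the architecture.
    """
    if len(arch.beta_a) != panel.n_snps:
        raise ValueError("architecture does not match panel SNP count")
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(2))
    maf = panel.snps["maf"].to_numpy()
    se_a = beta_se(maf, *n_a)
    se_b = beta_se(maf, *n_b)
    za = _simulate_z(panel, arch.beta_a, se_a, rng_a)
    zb = _simulate_z(panel, arch.beta_b, se_b, rng_b)
    return (
        _sumstats_from_z(panel, za, se_a, *n_a),
        _sumstats_from_z(panel, zb, se_b, *n_b),
    )


# ---------------------------------------------------------------------------
# Individual-level cohort simulation (liability threshold)


@dataclass
class Cohort:
    """Individual-level case/control data for polygenic-score analysis."""

    dosages: np.ndarray            # individuals x SNPs, effect-allele counts
    snps: pd.DataFrame             # snp_id, effect_allele, other_allele
    phenotype: np.ndarray          # 1 = case
    sex: np.ndarray                # 0/1
    cohort_label: np.ndarray       # integer study-of-origin label
    seed: int

    @property
    def n(self) -> int:
        return len(self.phenotype)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())


def simulate_cohort(
    panel: ReferencePanel,
    arch: Architecture,
    n: int,
    prevalence: float,
    n_cohorts: int,
    seed: int,
    *,
    trait: str = "a",
) -> Cohort:
    """Simulate ``n`` individuals under a liability-threshold model.

    Liability = centred dosages · true effects + standard-normal noise;
    individuals above the empirical (1 − prevalence) liability quantile are
    cases, so the case count is deterministic given the seed. Sex and the
    study-of-origin label are assigned uniformly and independently of
    genotype.
    """
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    beta = arch.beta_a if trait == "a" else arch.beta_b
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    d = _draw_dosages(rng, n, panel.spec, panel.snps["maf"].to_numpy()).astype(float)
    centred = d - 2.0 * panel.snps["maf"].to_numpy()
    liability = centred @ beta + rng.standard_normal(n)
    cut = np.quantile(liability, 1.0 - prevalence)
    phenotype = (liability > cut).astype(int)
    if phenotype.sum() == 0 or phenotype.sum() == n:
        raise ValueError("n too small to contain both a case and a control")
    sex = rng.integers(0, 2, size=n)
    cohort_label = rng.integers(0, n_cohorts, size=n)
    return Cohort(
        d,
        panel.snps[["snp_id", "effect_allele", "other_allele"]].copy(),
        phenotype,
        sex,
        cohort_label,
        seed,
    )


# ---------------------------------------------------------------------------
# Export / import


def write_panel(panel: ReferencePanel, prefix: str) -> None:
    """Write ``<prefix>.dosages.tsv`` (individuals × SNPs) and ``<prefix>.snps.tsv``."""
    pd.DataFrame(panel.dosages, columns=panel.snps["snp_id"]).to_csv(
        f"{prefix}.dosages.tsv", sep="\t", index=False)
    meta = panel.snps.copy()
    meta["rho"] = panel.spec.within_block_rho
    meta["snps_per_block"] = panel.spec.snps_per_block
    meta["seed"] = panel.seed
    meta.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def load_panel(prefix: str) -> ReferencePanel:
    """Load a panel written by :func:`write_panel`."""
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t")
    meta = pd.read_csv(f"{prefix}.snps.tsv", sep="\t")
    spec = LDBlockSpec(
        n_blocks=int(meta["block"].max()) + 1,
        snps_per_block=int(meta["snps_per_block"].iloc[0]),
        within_block_rho=float(meta["rho"].iloc[0]),
        maf_range=(float(meta["maf"].min()), float(max(meta["maf"].max(), 1e-9))),
        n_chroms=int(meta["chrom"].nunique()),
    )
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "block", "maf"]
    return ReferencePanel(
        dos[meta["snp_id"]].to_numpy(dtype=np.int8), meta[cols], spec,
        int(meta["seed"].iloc[0]),
    )


def write_panel_vcf(panel: ReferencePanel, path: str) -> None:
    """Export the panel as a minimal VCF with a per-sample DS (dosage) field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        samples = [f"IND{i + 1}" for i in range(panel.n_individuals)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in panel.snps.iterrows():
            ds = "\t".join(str(int(v)) for v in panel.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.other_allele}\t"
                     f"{row.effect_allele}\t.\tPASS\t.\tDS\t{ds}\n")


def write_cohort(cohort: Cohort, prefix: str) -> None:
    """Write ``<prefix>.dosages.tsv`` and ``<prefix>.pheno.tsv``."""
    pd.DataFrame(cohort.dosages, columns=cohort.snps["snp_id"]).to_csv(
        f"{prefix}.dosages.tsv", sep="\t", index=False)
    pheno = pd.DataFrame({
        "phenotype": cohort.phenotype,
        "sex": cohort.sex,
        "cohort_label": cohort.cohort_label,
    })
    pheno["seed"] = cohort.seed
    pheno.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)
    cohort.snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def load_cohort(prefix: str) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t")
    pheno = pd.read_csv(f"{prefix}.pheno.tsv", sep="\t")
    snps = pd.read_csv(f"{prefix}.snps.tsv", sep="\t")
    return Cohort(
        dos[snps["snp_id"]].to_numpy(dtype=float),
        snps,
        pheno["phenotype"].to_numpy(),
        pheno["sex"].to_numpy(),
        pheno["cohort_label"].to_numpy(),
        int(pheno["seed"].iloc[0]) if "seed" in pheno else 0,
    )
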