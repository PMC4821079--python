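import numpy as np
import pandas as pd
import pytest

from crossgwas import (
    LDBlockSpec, SummaryStats, simulate_panel, validate_sumstats,
)


def make_sumstats(rows) -> SummaryStats:
    """Build a validated SummaryStats from a list of row dicts."""
    defaults = dict(beta=0.1, se=0.05, p=0.5, n_cases=1000, n_controls=1000,
                    effect_allele="A", other_allele="G")
    full = [{**defaults, **r} for r in rows]
    return validate_sumstats(pd.DataFrame(full))


def toy_table(n, *, chrom=1, seed=0, p=None, beta=None):
    """n-SNP summary-statistics rows with controllable p and beta vectors."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.01, 1.0, n) if p is None else np.asarray(p, dtype=float)
    beta = rng.normal(0, 0.1, n) if beta is None else np.asarray(beta, dtype=float)
    return [
        dict(snp_id=f"rs{i + 1}", chrom=chrom, pos=1000 * (i + 1),
             p=p[i], beta=beta[i])
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_panel():
    """5 blocks x 20 SNPs, rho=0.9, 200 reference individuals."""
    spec = LDBlockSpec(n_blocks=5, snps_per_block=20, within_block_rho=0.9)
    return simulate_panel(spec, 200, seed=11)


@pytest.fixture(scope="session")
def genome_panel():
    """40 blocks x 25 SNPs: large enough that a single planted locus is a
    small fraction of the genome, as the region-scan null requires."""
    spec = LDBlockSpec(n_blocks=40, snps_per_block=25, within_block_rho=0.9)
    return simulate_panel(spec, 200, seed=13)
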