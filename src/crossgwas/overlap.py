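"""Excess sharing of association signals between two traits.

The stage asks whether more SNPs are nominally associated with *both* traits
than chance predicts. Pipeline: greedily prune the harmonized SNP set to
approximate linkage equilibrium (r² ≤ 0.05, ordered by one trait's p-value);
for each p-value cutoff, cross-tabulate below/above-cutoff status in the two
traits into a 2×2 table; test each table with a two-sided Fisher exact test;
adjust the scan with Benjamini–Hochberg FDR; optionally back the parametric
test with an empirical permutation null that shuffles the SNP↔p assignment
within each trait; and test effect-direction concordance of the doubly
significant SNPs with an exact binomial test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats, special
from statsmodels.stats.multitest import multipletests

from .simulate import ReferencePanel
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.05
DEFAULT_CUTOFFS = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
DEFAULT_FLAG_ALPHA = 0.01

# largest table total handled by exact integer enumeration; beyond this a
# log-gamma float path with a small relative tie tolerance takes over
_FISHER_EXACT_LIMIT = 5000


# ---------------------------------------------------------------------------
# LD pruning


@dataclass
class PrunedSet:
    """SNPs in approximate linkage equilibrium, in greedy selection order."""

    snp_ids: list[str]
    r2_threshold: float
    order_by: str

    def __len__(self) -> int:
        return len(self.snp_ids)


def ld_prune(
    pair: HarmonizedPair,
    panel: ReferencePanel | None = None,
    *,
    r2_table: pd.DataFrame | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    order_by: str = "a",
    missing: str = "drop",
) -> PrunedSet:
    """Greedy p-value-ordered LD pruning.

    Repeatedly take the remaining SNP with the smallest p-value in the
    ordering trait (ties broken by chrom, pos) and remove every remaining SNP
    with r² above ``r2_threshold`` to it, until no SNP remains unprocessed.

    r² comes either from ``panel`` dosages (squared Pearson correlation
    within an LD block; cross-block r² is 0) or from a long-format
    ``r2_table`` with columns snp_a, snp_b, r2 (unlisted pairs count as 0).
    SNPs absent from the LD source are dropped with a warning
    (``missing="drop"``) or raise (``missing="error"``).
    """
    if order_by not in ("a", "b"):
        raise ValueError("order_by must be 'a' or 'b'")
    if panel is None and r2_table is None:
        raise ValueError("supply a reference panel or an r² table")
    df = pair.table
    pcol = f"p_{order_by}"

    if panel is not None:
        panel_idx = pd.Series(
            np.arange(panel.n_snps), index=panel.snps["snp_id"]
        )
        present = df["snp_id"].isin(panel_idx.index)
        if not present.all():
            n_missing = int((~present).sum())
            if missing == "error":
                raise KeyError(f"{n_missing} SNPs absent from the LD panel")
            logger.warning("dropping %d SNPs absent from the LD panel", n_missing)
            df = df.loc[present]
        cols = panel_idx[df["snp_id"]].to_numpy()
        blocks = panel.snps["block"].to_numpy()[cols]
    else:
        blocks = None

    order = df.assign(_row=np.arange(len(df))).sort_values(
        [pcol, "chrom", "pos"], kind="mergesort")["_row"].to_numpy()
    removed = np.zeros(len(df), dtype=bool)
    snp_ids = df["snp_id"].to_numpy()
    kept: list[str] = []

    if panel is not None:
        dos = panel.dosages[:, cols].astype(float)
        dos_c = dos - dos.mean(axis=0)
        norms = np.sqrt((dos_c**2).sum(axis=0))
        norms[norms == 0] = np.inf
        for i in order:
            if removed[i]:
                continue
            kept.append(snp_ids[i])
            removed[i] = True
            mates = np.flatnonzero((blocks == blocks[i]) & ~removed)
            if len(mates):
                r = (dos_c[:, mates].T @ dos_c[:, i]) / (norms[mates] * norms[i])
                removed[mates[r**2 > r2_threshold]] = True
    else:
        lut: dict[tuple[str, str], float] = {}
        for row in r2_table.itertuples(index=False):
            lut[(row.snp_a, row.snp_b)] = row.r2
            lut[(row.snp_b, row.snp_a)] = row.r2
        listed = {s for k in lut for s in k}
        for i in order:
            if removed[i]:
                continue
            sid = snp_ids[i]
            if missing == "error" and sid not in listed:
                raise KeyError(f"SNP {sid} absent from the r² table")
            kept.append(sid)
            removed[i] = True
            for j in np.flatnonzero(~removed):
                if lut.get((sid, snp_ids[j]), 0.0) > r2_threshold:
                    removed[j] = True

    return PrunedSet(kept, r2_threshold, order_by)


# ---------------------------------------------------------------------------
# Exact tests


@dataclass
class FisherResult:
    p: float
    odds_ratio: float
    or_finite: bool


def fisher_two_sided(n11: int, n10: int, n01: int, n00: int) -> FisherResult:
    """Two-sided Fisher exact test on a 2×2 table.

    Two-sided by the minimum-likelihood convention: sum the probabilities of
    all tables (at fixed margins) whose hypergeometric probability does not
    exceed the observed table's. For totals up to a few thousand the tail is
    accumulated in exact integer arithmetic; larger tables use log-gamma
    probabilities with a 1e-7 relative tie tolerance.

    The sample odds ratio (n11·n00)/(n10·n01) is returned alongside;
    ``or_finite`` is False when a zero cell makes it infinite or undefined.
    """
    for v in (n11, n10, n01, n00):
        if v < 0 or v != int(v):
            raise ValueError("cell counts must be non-negative integers")
    n11, n10, n01, n00 = int(n11), int(n10), int(n01), int(n00)
    total = n11 + n10 + n01 + n00
    if total < 1:
        raise ValueError("table total must be >= 1")
    r1 = n11 + n10
    c1 = n11 + n01
    lo = max(0, r1 + c1 - total)
    hi = min(r1, c1)

    denom_or = n10 * n01
    num_or = n11 * n00
    if denom_or > 0:
        odds_ratio, finite = num_or / denom_or, True
    else:
        odds_ratio, finite = (math.nan if num_or == 0 else math.inf), False

    if total <= _FISHER_EXACT_LIMIT:
        weights = [math.comb(r1, k) * math.comb(total - r1, c1 - k)
                   for k in range(lo, hi + 1)]
        w_obs = weights[n11 - lo]
        num = sum(w for w in weights if w <= w_obs)
        p = float(Fraction(num, math.comb(total, c1)))
    else:
        k = np.arange(lo, hi + 1)
        logw = (special.gammaln(r1 + 1) - special.gammaln(k + 1)
                - special.gammaln(r1 - k + 1)
                + special.gammaln(total - r1 + 1) - special.gammaln(c1 - k + 1)
                - special.gammaln(total - r1 - c1 + k + 1))
        logw -= logw.max()
        w = np.exp(logw)
        w_obs = w[n11 - lo]
        p = float(w[w <= w_obs * (1 + 1e-7)].sum() / w.sum())
    return FisherResult(min(p, 1.0), odds_ratio, finite)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, order-preserving."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial test (minimum-likelihood convention).

    Sums the probabilities of all outcomes no more likely than the observed
    ``k`` under Binomial(n, p0); capped at 1. For k=12, n=16, p0=0.5 this is
    2·2517/65536 ≈ 0.0768.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    return float(min(1.0, stats.binomtest(k, n, p0).pvalue))


# ---------------------------------------------------------------------------
# Cutoff scan


def _below_masks(pair: HarmonizedPair, pruned: PrunedSet):
    sub = pair.table.set_index("snp_id").loc[pruned.snp_ids]
    return sub["p_a"].to_numpy(), sub["p_b"].to_numpy(), sub


def _crosstab(pa, pb, cutoff):
    below_a = pa <= cutoff
    below_b = pb <= cutoff
    n11 = int(np.sum(below_a & below_b))
    n10 = int(np.sum(below_a & ~below_b))
    n01 = int(np.sum(~below_a & below_b))
    n00 = int(np.sum(~below_a & ~below_b))
    return n11, n10, n01, n00


def overlap_scan(
    pair: HarmonizedPair,
    pruned: PrunedSet,
    cutoffs=DEFAULT_CUTOFFS,
    *,
    flag_alpha: float = DEFAULT_FLAG_ALPHA,
) -> pd.DataFrame:
    """One 2×2 overlap table and Fisher test per p-value cutoff.

    Returns a frame with one row per cutoff: the table counts, sample odds
    ratio, two-sided Fisher p, BH-adjusted p over the whole scan, and a
    ``flagged`` column marking cutoffs with adjusted p below ``flag_alpha``
    (default 0.01, the excess-overlap call threshold).
    """
    cutoffs = sorted(set(cutoffs), reverse=True)
    pa, pb, _ = _below_masks(pair, pruned)
    rows = []
    for cutoff in cutoffs:
        n11, n10, n01, n00 = _crosstab(pa, pb, cutoff)
        if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
            logger.info("cutoff %.1e: degenerate margin, Fisher p = 1", cutoff)
        res = fisher_two_sided(n11, n10, n01, n00)
        rows.append({
            "cutoff": cutoff, "n11": n11, "n10": n10, "n01": n01, "n00": n00,
            "fisher_or": res.odds_ratio, "or_finite": res.or_finite,
            "fisher_p": res.p,
        })
    out = pd.DataFrame(rows)
    out["fdr_p"] = bh_adjust(out["fisher_p"])
    out["flagged"] = out["fdr_p"] < flag_alpha
    return out


def permute_overlap(
    pair: HarmonizedPair,
    pruned: PrunedSet,
    cutoffs,
    n_perm: int,
    seed: int,
) -> pd.DataFrame:
    """Empirical overlap p-values from a permutation null.

    Each permutation independently shuffles the SNP↔p assignment within each
    trait's pruned vector and recomputes the Fisher p per cutoff. The
    empirical p is the add-one estimator
    (1 + #{null p ≤ observed p}) / (n_perm + 1), which can never be 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cutoffs = sorted(set(cutoffs), reverse=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pa, pb, _ = _below_masks(pair, pruned)
    observed = np.array([
        fisher_two_sided(*_crosstab(pa, pb, c)).p for c in cutoffs
    ])
    exceed = np.zeros(len(cutoffs), dtype=int)
    # Fisher p depends on the table only through n11 at fixed margins; cache
    fisher_cache: dict[tuple, float] = {}
    for _ in range(n_perm):
        pa_perm = rng.permutation(pa)
        pb_perm = rng.permutation(pb)
        for i, cutoff in enumerate(cutoffs):
            tab = _crosstab(pa_perm, pb_perm, cutoff)
            p_null = fisher_cache.get(tab)
            if p_null is None:
                p_null = fisher_two_sided(*tab).p
                fisher_cache[tab] = p_null
            if p_null <= observed[i]:
                exceed[i] += 1
    return pd.DataFrame({
        "cutoff": cutoffs,
        "fisher_p": observed,
        "perm_p": (1 + exceed) / (n_perm + 1),
        "n_perm": n_perm,
    })


@dataclass
class ConcordanceResult:
    """Effect-direction agreement among doubly significant pruned SNPs."""

    concordant: int
    total: int
    binomial_p: float
    defined: bool


def direction_concordance(
    pair: HarmonizedPair,
    pruned: PrunedSet,
    cutoff: float,
) -> ConcordanceResult:
    """Count same-sign effects among SNPs below ``cutoff`` in both traits.

    Tests the concordant count against Binomial(n, 1/2) two-tailed. With no
    qualifying SNP the result is flagged undefined (p = NaN) rather than 0/0.
    """
    pa, pb, sub = _below_masks(pair, pruned)
    both = (pa <= cutoff) & (pb <= cutoff)
    total = int(both.sum())
    if total == 0:
        return ConcordanceResult(0, 0, math.nan, False)
    sa = np.sign(sub["beta_a"].to_numpy()[both])
    sb = np.sign(sub["beta_b"].to_numpy()[both])
    concordant = int(np.sum(sa == sb))
    return ConcordanceResult(concordant, total,
                             binomial_two_tailed(concordant, total, 0.5), True)
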