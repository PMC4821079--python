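"""Cross-Phenotype Spatial Mapping (CPSM): shared-locus region scanning.

Where the overlap stage asks a genome-wide yes/no question, CPSM localizes
the sharing: it scans for contiguous genomic regions where the two traits'
association profiles covary. Concretely:

1. Each trait's p-values become −log10(p), then are rank-normalized within
   chromosome (rank → normal quantile), making the window statistic robust
   to the two traits' very different p-value distributions.
2. A sliding window (default 100 SNPs, step 50) computes the sample
   covariance of the two transformed profiles.
3. Significance is judged against a permutation null that circularly rotates
   one trait's profile within each chromosome — preserving each trait's
   local autocorrelation from LD while breaking the cross-trait alignment —
   and takes a high percentile (default 99.95%) of the pooled null window
   statistics as the threshold. A full-shuffle null is available for
   comparison.
4. Windows above threshold are merged (gap ≤ 50 kb by default) into regions,
   each reported with its per-trait lead SNP and whether the lead effects
   share a sign.

Regions can further be annotated with the association of the trait-A lead
SNP in two trait-A subtypes (for migraine: with/without aura), including an
exact binomial test of which subtype tends to carry the stronger signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import binomial_two_tailed
from .sumstats import HarmonizedPair, SummaryStats

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_STEP = 50
DEFAULT_MIN_SNPS = 10
DEFAULT_PERCENTILE = 0.9995
DEFAULT_MERGE_GAP = 50_000
DEFAULT_P_FLOOR = 1e-30


def transform_profiles(pair: HarmonizedPair, *,
                       p_floor: float = DEFAULT_P_FLOOR) -> pd.DataFrame:
    """Per-SNP transformed association profiles for both traits.

    −log10(p) (p clamped below at ``p_floor``), then Blom rank-normalized
    within chromosome. Any strictly monotone transform of the p-values leaves
    the result unchanged; fully tied p-values map to a constant profile.
    """
    df = pair.table[["snp_id", "chrom", "pos", "p_a", "p_b",
                     "beta_a", "beta_b"]].copy()
    for trait in ("a", "b"):
        p = df[f"p_{trait}"].to_numpy(dtype=float)
        if (p < p_floor).any():
            logger.info("clamping %d p-values at floor %.1e",
                        int((p < p_floor).sum()), p_floor)
        score = -np.log10(np.maximum(p, p_floor))
        out = np.empty(len(df))
        for _, idx in df.groupby("chrom").indices.items():
            r = stats.rankdata(score[idx], method="average")
            n = len(idx)
            out[idx] = stats.norm.ppf((r - 0.375) / (n + 0.25))
        df[f"t_{trait}"] = out
    return df


def _window_starts(n: int, window: int, step: int, min_snps: int) -> np.ndarray:
    if n < min_snps:
        return np.array([], dtype=int)
    if n <= window:
        return np.array([0])
    starts = np.arange(0, n - window + 1, step)
    # keep a trailing partial window when the tail holds enough SNPs
    tail = starts[-1] + step
    if tail < n and n - tail >= min_snps:
        starts = np.append(starts, tail)
    return starts


def _window_cov(x: np.ndarray, y: np.ndarray, starts: np.ndarray,
                window: int) -> np.ndarray:
    """Sample covariance (ddof=1) of x and y in each window, via prefix sums."""
    n = len(x)
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    ends = np.minimum(starts + window, n)
    m = (ends - starts).astype(float)
    sx = cx[ends] - cx[starts]
    sy = cy[ends] - cy[starts]
    sxy = cxy[ends] - cxy[starts]
    return (sxy - sx * sy / m) / (m - 1)


def scan_windows(profiles: pd.DataFrame, *, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP,
                 min_snps: int = DEFAULT_MIN_SNPS) -> pd.DataFrame:
    """Sliding-window covariance of the two transformed profiles.

    Windows are ``window`` SNPs wide, advanced by ``step`` SNPs, never span
    chromosomes, and require ``min_snps`` SNPs; chromosomes with fewer SNPs
    than ``min_snps`` are skipped with a log entry.
    """
    if not (window >= min_snps >= 2):
        raise ValueError("need window >= min_snps >= 2")
    rows = []
    for chrom, sub in profiles.groupby("chrom"):
        n = len(sub)
        starts = _window_starts(n, window, step, min_snps)
        if starts.size == 0:
            logger.info("chromosome %s has %d SNPs < min_snps=%d; skipped",
                        chrom, n, min_snps)
            continue
        x = sub["t_a"].to_numpy()
        y = sub["t_b"].to_numpy()
        cov = _window_cov(x, y, starts, window)
        ends = np.minimum(starts + window, n)
        pos = sub["pos"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        for w, (s, e) in enumerate(zip(starts, ends)):
            rows.append({
                "chrom": chrom, "window": w,
                "start_pos": int(pos[s]), "end_pos": int(pos[e - 1]),
                "start_snp": ids[s], "end_snp": ids[e - 1],
                "n_snps": int(e - s), "stat": float(cov[w]),
            })
    return pd.DataFrame(rows)


def permutation_threshold(
    profiles: pd.DataFrame,
    *,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
    n_perm: int = 1000,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
    mode: str = "rotate",
) -> float:
    """Null threshold for the window statistic.

    Per permutation, trait B's profile is circularly rotated by a random
    offset within each chromosome (``mode="rotate"``, the default, which
    keeps single-trait LD autocorrelation intact) or fully shuffled
    (``mode="shuffle"``); all window statistics are recomputed and pooled
    across permutations, and the requested percentile of the pooled null is
    returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 < percentile < 1):
        raise ValueError("percentile must be in (0, 1)")
    if mode not in ("rotate", "shuffle"):
        raise ValueError("mode must be 'rotate' or 'shuffle'")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    per_chrom = []
    for _, sub in profiles.groupby("chrom"):
        n = len(sub)
        starts = _window_starts(n, window, step, min_snps)
        if starts.size:
            per_chrom.append((sub["t_a"].to_numpy(), sub["t_b"].to_numpy(), starts))
    null_stats = []
    for _ in range(n_perm):
        for x, y, starts in per_chrom:
            if mode == "rotate":
                off = rng.integers(1, len(y)) if len(y) > 1 else 0
                y_null = np.roll(y, off)
            else:
                y_null = rng.permutation(y)
            null_stats.append(_window_cov(x, y_null, starts, window))
    pooled = np.concatenate(null_stats)
    return float(np.quantile(pooled, percentile))


@dataclass
class CPSMRegion:
    """A contiguous interval of shared association (1-based inclusive)."""

    chrom: int
    start: int
    end: int
    peak_stat: float
    lead_snp_a: str
    lead_p_a: float
    lead_beta_a: float
    lead_snp_b: str
    lead_p_b: float
    lead_beta_b: float
    direction_agreement: bool
    n_windows: int


def call_regions(
    window_stats: pd.DataFrame,
    threshold: float,
    pair: HarmonizedPair,
    *,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[CPSMRegion]:
    """Merge above-threshold windows into regions with per-trait lead SNPs.

    Windows with statistic strictly above ``threshold`` that overlap or lie
    within ``merge_gap`` bp on the same chromosome fuse into one region. Per
    region, each trait's lead SNP is its smallest-p SNP inside the interval;
    ``direction_agreement`` records whether the two leads' harmonized betas
    share a sign. An empty list is a valid outcome.
    """
    sig = window_stats.loc[window_stats["stat"] > threshold]
    regions: list[CPSMRegion] = []
    tab = pair.table
    for chrom, sub in sig.groupby("chrom"):
        sub = sub.sort_values("start_pos")
        cur: list[pd.Series] = []
        intervals = []
        for _, row in sub.iterrows():
            if cur and row["start_pos"] - cur[-1]["end_pos"] > merge_gap:
                intervals.append(cur)
                cur = []
            cur.append(row)
        if cur:
            intervals.append(cur)
        for group in intervals:
            start = int(min(r["start_pos"] for r in group))
            end = int(max(r["end_pos"] for r in group))
            peak = float(max(r["stat"] for r in group))
            inside = tab.loc[(tab["chrom"] == chrom)
                             & (tab["pos"] >= start) & (tab["pos"] <= end)]
            lead_a = inside.loc[inside["p_a"].idxmin()]
            lead_b = inside.loc[inside["p_b"].idxmin()]
            regions.append(CPSMRegion(
                chrom=int(chrom), start=start, end=end, peak_stat=peak,
                lead_snp_a=lead_a["snp_id"], lead_p_a=float(lead_a["p_a"]),
                lead_beta_a=float(lead_a["beta_a"]),
                lead_snp_b=lead_b["snp_id"], lead_p_b=float(lead_b["p_b"]),
                lead_beta_b=float(lead_b["beta_b"]),
                direction_agreement=bool(
                    np.sign(lead_a["beta_a"]) == np.sign(lead_b["beta_b"])),
                n_windows=len(group),
            ))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def regions_to_frame(regions: list[CPSMRegion]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "peak_stat", "lead_snp_a", "lead_p_a",
            "lead_beta_a", "lead_snp_b", "lead_p_b", "lead_beta_b",
            "direction_agreement", "n_windows"]
    return pd.DataFrame([vars(r) for r in regions], columns=cols)


def write_regions_bed(regions: list[CPSMRegion], path) -> None:
    """Write regions as BED (0-based half-open, converted from 1-based)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tcpsm_region_{i + 1}\t"
                     f"{r.peak_stat:.6g}\n")


def annotate_subtypes(
    regions: list[CPSMRegion],
    mo: SummaryStats,
    ma: SummaryStats,
) -> tuple[pd.DataFrame, dict]:
    """Look up each region's trait-A lead SNP in two subtype GWAS tables.

    Returns the region frame extended with subtype p-values/betas, and a
    summary: how many leads have a strictly lower p in the first subtype
    (ties count as "not lower"), the total testable, the two-tailed binomial
    p against 1/2, and how many leads have same-sign subtype betas. Leads
    absent from either table are excluded from the counts and noted.
    """
    mo_t = mo.table.set_index("snp_id")
    ma_t = ma.table.set_index("snp_id")
    df = regions_to_frame(regions)
    rows = []
    for r in regions:
        rec = {"lead_snp_a": r.lead_snp_a, "p_mo": np.nan, "p_ma": np.nan,
               "beta_mo": np.nan, "beta_ma": np.nan, "testable": False}
        if r.lead_snp_a in mo_t.index and r.lead_snp_a in ma_t.index:
            rec.update(
                p_mo=float(mo_t.at[r.lead_snp_a, "p"]),
                p_ma=float(ma_t.at[r.lead_snp_a, "p"]),
                beta_mo=float(mo_t.at[r.lead_snp_a, "beta"]),
                beta_ma=float(ma_t.at[r.lead_snp_a, "beta"]),
                testable=True,
            )
        else:
            logger.warning("lead SNP %s absent from a subtype table; excluded",
                           r.lead_snp_a)
        rows.append(rec)
    ann = pd.DataFrame(rows, columns=["lead_snp_a", "p_mo", "p_ma",
                                      "beta_mo", "beta_ma", "testable"])
    out = df.merge(ann.drop_duplicates("lead_snp_a"), on="lead_snp_a", how="left")
    testable = ann.loc[ann["testable"]]
    total = len(testable)
    lower = int((testable["p_mo"] < testable["p_ma"]).sum())
    same_sign = int((np.sign(testable["beta_mo"])
                     == np.sign(testable["beta_ma"])).sum())
    summary = {
        "n_lower_in_mo": lower,
        "n_testable": total,
        "binomial_p": binomial_two_tailed(lower, total, 0.5) if total else float("nan"),
        "n_same_sign_subtypes": same_sign,
        "n_untestable": len(ann) - total,
    }
    return out, summary
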