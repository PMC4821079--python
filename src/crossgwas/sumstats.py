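"""Reading, validation and cross-study harmonization of GWAS summary statistics.

Two summary-statistics tables (one per phenotype) are merged into a single
allele-aligned table in which effect signs are directly comparable. All
downstream stages — overlap enrichment, polygenic scoring, shared-locus
scanning and known-locus cross-query — consume the harmonized table.

Conventions
-----------
* Coordinates are 1-based, inclusive (GWAS summary-statistic convention).
* The join key is the SNP identifier (rsID); position-based joining is not
  attempted, and records whose chromosome/position disagree between the two
  studies are dropped and counted rather than reconciled.
* Palindromic SNPs (A/T or C/G) are dropped by default because strand cannot
  be resolved without allele-frequency information; pass
  ``drop_palindromic=False`` to retain them under a same-strand assumption.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of a summary-statistics table.
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "n_cases", "n_controls",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(allele: str) -> str:
    """Watson–Crick complement of a single-base allele."""
    return _COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass
class SummaryStats:
    """One GWAS's per-SNP association results.

    ``table`` holds one row per SNP with the canonical columns
    (:data:`SUMSTATS_COLUMNS`), sorted by (chrom, pos); ``drops`` counts rows
    rejected during validation, keyed by reason.
    """

    table: pd.DataFrame
    drops: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)


def validate_sumstats(df: pd.DataFrame, *, source: str = "<memory>") -> SummaryStats:
    """Validate a raw summary-statistics frame into a :class:`SummaryStats`.

    Row-level violations (p outside (0, 1], non-positive SE, invalid or equal
    alleles, chromosome outside 1–22, duplicate SNP id, non-finite beta) drop
    the row with a logged line number; the result is sorted by (chrom, pos).
    """
    df = df.copy()
    drops: Counter = Counter()
    # line numbers refer to the data rows of the source file (header = line 1)
    df["_line"] = np.arange(2, len(df) + 2)

    for col in ("chrom", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("beta", "se", "p"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("n_cases", "n_controls"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    def _reject(mask: pd.Series, reason: str) -> None:
        nonlocal df
        bad = df.loc[mask]
        if len(bad):
            drops[reason] += len(bad)
            for line in bad["_line"].head(10):
                logger.warning("%s line %d: dropped (%s)", source, line, reason)
            if len(bad) > 10:
                logger.warning("%s: %d further rows dropped (%s)", source, len(bad) - 10, reason)
            df = df.loc[~mask]

    _reject(~(df["p"] > 0) | ~(df["p"] <= 1) | df["p"].isna(), "p_out_of_range")
    _reject(~(df["se"] > 0) | df["se"].isna(), "se_not_positive")
    _reject(~df["beta"].apply(np.isfinite), "beta_not_finite")
    _reject(
        ~df["effect_allele"].isin(_VALID_ALLELES)
        | ~df["other_allele"].isin(_VALID_ALLELES),
        "invalid_allele",
    )
    _reject(df["effect_allele"] == df["other_allele"], "equal_alleles")
    _reject(
        df["chrom"].isna() | (df["chrom"] < 1) | (df["chrom"] > 22)
        | (df["chrom"] % 1 != 0),
        "invalid_chrom",
    )
    _reject(df["pos"].isna() | (df["pos"] < 1) | (df["pos"] % 1 != 0), "invalid_pos")
    _reject(df.duplicated(subset="snp_id", keep="first"), "duplicate_snp_id")

    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryStats(df[SUMSTATS_COLUMNS], drops)


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    *,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Optional mapping from canonical names (:data:`SUMSTATS_COLUMNS`) to
        the names used in the file, for files with nonstandard headers.

    Raises
    ------
    ValueError
        If a mandatory column is absent after applying ``column_map``.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    mandatory = [c for c in SUMSTATS_COLUMNS if c not in ("n_cases", "n_controls")]
    missing = [c for c in mandatory if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return validate_sumstats(raw, source=str(path))


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write a summary-statistics table as TSV with the canonical header."""
    stats.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele alignment


@dataclass
class HarmonizedPair:
    """Allele-aligned inner join of two studies' summary statistics.

    ``table`` carries, per SNP: the trait-A allele orientation
    (effect_allele/other_allele), ``beta_a``/``se_a``/``p_a``,
    ``beta_b``/``se_b``/``p_b`` re-expressed on trait A's effect allele, and
    ``flipped`` marking records whose trait-B effect sign was negated during
    alignment. ``drops`` counts study-B records excluded per reason.
    """

    table: pd.DataFrame
    drops: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.table)


PAIR_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b", "flipped",
]


def align_alleles(
    a: SummaryStats,
    b: SummaryStats,
    *,
    drop_palindromic: bool = True,
) -> HarmonizedPair:
    """Inner-join two studies on SNP id and align study B to study A's alleles.

    Matching allows at most one effect/other swap and/or one strand
    complement; a swap negates ``beta_b`` and sets ``flipped``. Unresolvable
    allele pairs, positionally discordant records and (optionally)
    palindromic SNPs are dropped and counted.

    Raises
    ------
    ValueError
        If no SNP overlaps between the two tables.
    """
    ta = a.table.add_suffix("_a").rename(columns={"snp_id_a": "snp_id"})
    tb = b.table.add_suffix("_b").rename(columns={"snp_id_b": "snp_id"})
    merged = ta.merge(tb, on="snp_id", how="inner")
    drops: Counter = Counter()
    drops["non_overlap"] = len(b.table) - len(merged)
    if merged.empty:
        raise ValueError("no overlapping SNPs between the two studies")

    ok_pos = (merged["chrom_a"] == merged["chrom_b"]) & (merged["pos_a"] == merged["pos_b"])
    drops["discordant_position"] = int((~ok_pos).sum())
    merged = merged.loc[ok_pos]

    ea_a = merged["effect_allele_a"].to_numpy()
    oa_a = merged["other_allele_a"].to_numpy()
    ea_b = merged["effect_allele_b"].to_numpy()
    oa_b = merged["other_allele_b"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)

    palindromic = comp(ea_a) == oa_a
    direct = (ea_b == ea_a) & (oa_b == oa_a)
    swap = (ea_b == oa_a) & (oa_b == ea_a)
    strand = (comp(ea_b) == ea_a) & (comp(oa_b) == oa_a)
    strand_swap = (comp(ea_b) == oa_a) & (comp(oa_b) == ea_a)

    if drop_palindromic:
        keep_mask = ~palindromic
        drops["palindromic"] = int(palindromic.sum())
    else:
        # same-strand assumption: for palindromic SNPs the strand-complement
        # interpretations coincide with direct/swap, so only those apply
        keep_mask = np.ones(len(merged), dtype=bool)

    flipped = np.where(direct | strand, False, np.where(swap | strand_swap, True, False))
    resolvable = direct | swap | strand | strand_swap
    drops["allele_mismatch"] = int((keep_mask & ~resolvable).sum())
    keep_mask &= resolvable

    out = merged.loc[keep_mask].copy()
    flip = flipped[keep_mask].astype(bool)
    out["beta_b"] = np.where(flip, -out["beta_b"], out["beta_b"])
    out["flipped"] = flip
    out = out.rename(columns={
        "chrom_a": "chrom", "pos_a": "pos",
        "effect_allele_a": "effect_allele", "other_allele_a": "other_allele",
    })
    out = out[PAIR_COLUMNS].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if out.empty:
        raise ValueError("no overlapping SNPs remain after allele alignment")
    return HarmonizedPair(out, drops)


def write_pair(pair: HarmonizedPair, path, drop_report_path=None) -> None:
    """Write the harmonized table as TSV, optionally with a drop report."""
    pair.table.to_csv(path, sep="\t", index=False)
    if drop_report_path is not None:
        with open(drop_report_path, "w") as fh:
            for reason, count in sorted(pair.drops.items()):
                fh.write(f"{reason}\t{count}\n")


def read_pair(path) -> HarmonizedPair:
    """Read a harmonized pair table written by :func:`write_pair`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing harmonized column(s) {missing}")
    df["flipped"] = df["flipped"].astype(bool)
    return HarmonizedPair(df[PAIR_COLUMNS])
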