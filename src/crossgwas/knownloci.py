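"""Cross-query of established lead SNPs against the other trait's GWAS.

Each trait's previously reported genome-wide-significant lead SNPs are
looked up in the other trait's summary statistics; the Bonferroni threshold
divides the family alpha by the number of SNPs actually testable (leads
missing from the target table are excluded from the denominator, not
substituted by proxies). Each trait's lead-SNP family is corrected
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, complement_allele

logger = logging.getLogger(__name__)

LEADS_COLUMNS = ["snp_id", "source_trait", "effect_allele", "beta"]


@dataclass
class CrossQueryResult:
    """Per-lead lookup results plus the family-level threshold."""

    table: pd.DataFrame          # one row per testable lead
    excluded: pd.DataFrame       # leads that could not be tested, with reasons
    bonferroni_alpha: float
    family_alpha: float
    n_supplied: int
    n_testable: int


def read_leads(path) -> pd.DataFrame:
    """Read a lead-SNP list TSV (snp_id, source_trait, effect_allele, beta)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LEADS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df[LEADS_COLUMNS]


def cross_query(
    leads: pd.DataFrame,
    other: SummaryStats,
    family_alpha: float = 0.05,
) -> CrossQueryResult:
    """Test each supplied lead SNP for association to the other phenotype.

    ``leads`` needs columns snp_id, source_trait, effect_allele, beta (the
    lead's effect in its discovery trait). Leads absent from ``other`` — or
    with irreconcilable alleles — are excluded and shrink the Bonferroni
    denominator; ``significant`` flags p ≤ family_alpha / n_testable.
    ``direction_agreement`` compares the lead's discovery sign with the
    other-trait beta after aligning the other study to the lead's effect
    allele.

    Raises
    ------
    ValueError
        If no supplied lead is testable.
    """
    if not (0 < family_alpha < 1):
        raise ValueError("family_alpha must be in (0, 1)")
    if leads.empty:
        raise ValueError("empty lead-SNP list")
    ot = other.table.set_index("snp_id")
    rows, dropped = [], []
    for lead in leads.itertuples(index=False):
        if lead.snp_id not in ot.index:
            dropped.append({"snp_id": lead.snp_id, "reason": "absent_from_other_study"})
            continue
        rec = ot.loc[lead.snp_id]
        beta_other = float(rec["beta"])
        ea, oa = rec["effect_allele"], rec["other_allele"]
        lead_ea = str(lead.effect_allele).upper()
        if lead_ea in (ea, complement_allele(ea)):
            pass
        elif lead_ea in (oa, complement_allele(oa)):
            beta_other = -beta_other
        else:
            dropped.append({"snp_id": lead.snp_id, "reason": "allele_mismatch"})
            continue
        rows.append({
            "snp_id": lead.snp_id,
            "source_trait": lead.source_trait,
            "beta_source": float(lead.beta),
            "p_other": float(rec["p"]),
            "beta_other": beta_other,
            "direction_agreement": bool(np.sign(lead.beta) == np.sign(beta_other)),
        })
    if not rows:
        raise ValueError("no supplied lead SNP is testable in the other study")
    table = pd.DataFrame(rows)
    n_testable = len(table)
    bonf = family_alpha / n_testable
    table["bonferroni_alpha"] = bonf
    table["significant"] = table["p_other"] <= bonf
    excluded = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    if len(excluded):
        logger.info("%d of %d leads untestable", len(excluded), len(leads))
    return CrossQueryResult(table, excluded, bonf, family_alpha,
                            len(leads), n_testable)
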