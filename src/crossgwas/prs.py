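"""Polygenic risk scoring across phenotypes.

Risk-SNP sets are tiered by discovery-GWAS p-value (strong 5e-8, moderate
1e-4, weak 1e-2 by default, deliberately *not* LD-pruned to keep
sensitivity); each individual in the target cohort is scored as the sum of
effect-allele dosages weighted by the discovery log odds ratios; and the
score–phenotype relation is tested with a logistic regression adjusted for
sex and study-of-origin dummies. The score is standardized to unit SD before
the fit, so the reported odds ratio is per 1 SD of polygenic score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import Cohort
from .sumstats import SummaryStats, complement_allele

logger = logging.getLogger(__name__)

DEFAULT_TIERS = {"strong": 5e-8, "moderate": 1e-4, "weak": 1e-2}


@dataclass
class RiskSNPSet:
    """Discovery-trait risk SNPs carrying log-OR weights for scoring."""

    tier: str
    threshold: float
    table: pd.DataFrame  # snp_id, effect_allele, other_allele, weight

    def __len__(self) -> int:
        return len(self.table)


def select_risk_snps(source: SummaryStats, threshold: float,
                     tier: str = "") -> RiskSNPSet:
    """All source SNPs with p ≤ threshold, weighted by their log odds ratio.

    No LD pruning is applied. An empty selection is returned with a warning;
    scoring refuses empty sets.
    """
    t = source.table
    sel = t.loc[t["p"] <= threshold,
                ["snp_id", "effect_allele", "other_allele", "beta"]]
    sel = sel.rename(columns={"beta": "weight"}).reset_index(drop=True)
    if sel.empty:
        logger.warning("no SNPs pass p <= %.3g; scoring will refuse this set",
                       threshold)
    return RiskSNPSet(tier or f"p<={threshold:g}", threshold, sel)


@dataclass
class ScoreReport:
    """Per-individual scores plus bookkeeping of SNP/dosage missingness."""

    scores: np.ndarray
    n_snps_used: int
    n_snps_missing: int
    missing_per_individual: np.ndarray
    high_missingness: bool


def score_cohort(cohort: Cohort, riskset: RiskSNPSet) -> ScoreReport:
    """Score each individual: Σ_j dosage_ij · weight_j over shared SNPs.

    Cohort dosages are reconciled to the risk set's effect alleles: when the
    cohort counts the opposite allele (directly or on the complementary
    strand) the dosage enters as 2 − d. Risk SNPs absent from the cohort are
    skipped and counted; missing dosage values (NaN) are skipped per
    individual, not imputed. ``high_missingness`` is set when over half the
    risk set is absent from the cohort.
    """
    if len(riskset) == 0:
        raise ValueError("refusing to score with an empty risk-SNP set")
    cs = cohort.snps.reset_index(drop=True)
    col_of = pd.Series(np.arange(len(cs)), index=cs["snp_id"])
    merged = riskset.table.merge(
        cs.rename(columns={"effect_allele": "cohort_ea", "other_allele": "cohort_oa"}),
        on="snp_id", how="inner")
    n_missing = len(riskset) - len(merged)

    cols, signs = [], []
    dropped_mismatch = 0
    for row in merged.itertuples(index=False):
        if row.cohort_ea == row.effect_allele or \
           complement_allele(row.cohort_ea) == row.effect_allele:
            flip = False
        elif row.cohort_oa == row.effect_allele or \
                complement_allele(row.cohort_oa) == row.effect_allele:
            flip = True
        else:
            dropped_mismatch += 1
            continue
        cols.append(col_of[row.snp_id])
        signs.append((row.weight, flip))
    n_missing += dropped_mismatch
    if dropped_mismatch:
        logger.warning("%d risk SNPs dropped: alleles irreconcilable", dropped_mismatch)
    if not cols:
        raise ValueError("no risk SNP could be matched to the cohort")

    d = cohort.dosages[:, cols].astype(float)
    w = np.array([wt for wt, _ in signs])
    flip_mask = np.array([fl for _, fl in signs])
    d[:, flip_mask] = 2.0 - d[:, flip_mask]
    nan_mask = np.isnan(d)
    d_filled = np.where(nan_mask, 0.0, d)
    scores = d_filled @ w
    missing_per_ind = nan_mask.sum(axis=1)
    high = n_missing > 0.5 * len(riskset)
    if high:
        logger.warning("over half of the risk set (%d/%d) is unusable in this cohort",
                       n_missing, len(riskset))
    return ScoreReport(scores, len(cols), n_missing, missing_per_ind, high)


@dataclass
class ScoreResult:
    """Logistic-regression summary of score vs case/control status."""

    tier: str
    n_snps: int
    odds_ratio: float       # per 1 SD of score
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_controls: int
    converged: bool


def fit_score_model(scores: np.ndarray, cohort: Cohort, *,
                    tier: str = "", n_snps: int = 0) -> ScoreResult:
    """Fit phenotype ~ standardized score + sex + study dummies (logistic).

    The score is standardized to mean 0, SD 1, so the odds ratio is per 1 SD
    of polygenic score; the interval is Wald at 95%. Constant covariates are
    dropped with a warning; non-convergence or perfect separation is flagged
    via ``converged`` with NaN estimates.
    """
    y = np.asarray(cohort.phenotype)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    sd = scores.std()
    if sd == 0:
        raise ValueError("score has zero variance")
    x = pd.DataFrame({"score": (scores - scores.mean()) / sd})
    if np.unique(cohort.sex).size > 1:
        x["sex"] = cohort.sex
    else:
        logger.warning("sex is constant; dropped from the model")
    labels = np.asarray(cohort.cohort_label)
    if np.unique(labels).size > 1:
        dummies = pd.get_dummies(pd.Categorical(labels), prefix="cohort",
                                 drop_first=True, dtype=float)
        x = pd.concat([x, dummies], axis=1)
    design = sm.add_constant(x, has_constant="add")

    converged = True
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        beta = fit.params["score"]
        se = fit.bse["score"]
        if not np.isfinite(se) or se > 1e3:
            converged = False
    except Exception as exc:  # perfect separation, singular design
        logger.warning("logistic fit failed: %s", exc)
        converged = False

    if not converged:
        nan = float("nan")
        return ScoreResult(tier, n_snps, nan, nan, nan, nan,
                           int(y.sum()), int(len(y) - y.sum()), False)
    zcrit = stats.norm.ppf(0.975)
    return ScoreResult(
        tier=tier, n_snps=n_snps,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        p=float(2 * stats.norm.sf(abs(beta / se))),
        n_cases=int(y.sum()), n_controls=int(len(y) - y.sum()),
        converged=True,
    )


def run_tiers(source: SummaryStats, cohort: Cohort,
              tiers: dict[str, float] | None = None) -> pd.DataFrame:
    """Score and fit every tier; one row per tier (empty tiers are skipped)."""
    tiers = tiers or DEFAULT_TIERS
    rows = []
    for tier, threshold in tiers.items():
        riskset = select_risk_snps(source, threshold, tier)
        if len(riskset) == 0:
            logger.warning("tier %s empty at p <= %.3g; skipped", tier, threshold)
            continue
        report = score_cohort(cohort, riskset)
        res = fit_score_model(report.scores, cohort, tier=tier,
                              n_snps=report.n_snps_used)
        rows.append(vars(res))
    return pd.DataFrame(rows)
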