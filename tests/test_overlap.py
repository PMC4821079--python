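"""Overlap enrichment: pruning, exact tests, cutoff scan, permutations."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossgwas import (
    align_alleles, bh_adjust, binomial_two_tailed, direction_concordance,
    fisher_two_sided, ld_prune, null_architecture, overlap_scan,
    permute_overlap, shared_architecture, simulate_sumstats_pair,
)
from conftest import make_sumstats, toy_table


# ---------------------------------------------------------------------------
# independent oracles


def fisher_oracle(n11, n10, n01, n00):
    """Exact-arithmetic enumeration of ALL 2x2 tables at the fixed margins,
    summing the probabilities of tables no more likely than the observed."""
    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    total = r1 + r2

    def prob(k):  # table (k, r1-k, c1-k, r2-c1+k)
        if k < 0 or r1 - k < 0 or c1 - k < 0 or r2 - c1 + k < 0:
            return None
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                        math.comb(total, c1))

    p_obs = prob(n11)
    acc = Fraction(0)
    for k in range(0, min(r1, c1) + 1):
        pk = prob(k)
        if pk is not None and pk <= p_obs:
            acc += pk
    return float(acc)


def binomial_oracle(k, n, p0):
    """Full enumeration of Binomial(n, p0), minimum-likelihood two-tailed."""
    probs = [Fraction(math.comb(n, i)) * Fraction(p0).limit_denominator(10**6) ** i
             * (1 - Fraction(p0).limit_denominator(10**6)) ** (n - i)
             for i in range(n + 1)]
    return float(min(1, sum(p for p in probs if p <= probs[k])))


def prune_oracle(pvals, order, r2, threshold):
    """Literal restatement of the greedy rule: sort by p, take the top,
    strike everything in LD above threshold, repeat on the remainder."""
    remaining = list(order)
    kept = []
    while remaining:
        best = min(remaining, key=lambda i: pvals[i])
        kept.append(best)
        remaining = [i for i in remaining
                     if i != best and r2[best][i] <= threshold]
    return kept


# ---------------------------------------------------------------------------


class TestLdPrune:
    def test_independent_snps_all_retained(self):
        ss = make_sumstats(toy_table(6, seed=1))
        pair = align_alleles(ss, ss)
        r2 = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
        pruned = ld_prune(pair, r2_table=r2, r2_threshold=0.05)
        assert set(pruned.snp_ids) == set(pair.table["snp_id"])

    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        ss = make_sumstats(toy_table(2, p=[0.4, 0.01]))
        pair = align_alleles(ss, ss)
        r2 = pd.DataFrame([{"snp_a": "rs1", "snp_b": "rs2", "r2": 1.0}])
        pruned = ld_prune(pair, r2_table=r2)
        assert pruned.snp_ids == ["rs2"]

    def test_six_snp_toy_matches_hand_application(self):
        # hand-derived: order by p: rs3(.01) keep, removes rs1 (r2 .6);
        # rs5(.02) keep, removes rs6 (r2 .2); rs2(.05) keep (r2 to rs3 is
        # .04 <= .05); rs4(.9) keep
        p = [0.5, 0.05, 0.01, 0.9, 0.02, 0.3]
        ss = make_sumstats(toy_table(6, p=p))
        pair = align_alleles(ss, ss)
        r2 = pd.DataFrame([
            {"snp_a": "rs3", "snp_b": "rs1", "r2": 0.6},
            {"snp_a": "rs3", "snp_b": "rs2", "r2": 0.04},
            {"snp_a": "rs5", "snp_b": "rs6", "r2": 0.2},
        ])
        pruned = ld_prune(pair, r2_table=r2, r2_threshold=0.05)
        assert pruned.snp_ids == ["rs3", "rs5", "rs2", "rs4"]

    def test_panel_based_prune_respects_r2_and_keeps_global_lead(self, small_panel):
        from crossgwas import simulate_sumstats_pair
        arch = null_architecture(small_panel)
        a, b = simulate_sumstats_pair(small_panel, arch, (2000, 6000),
                                      (2000, 6000), seed=3)
        pair = align_alleles(a, b)
        pruned = ld_prune(pair, small_panel, r2_threshold=0.05)
        r2 = small_panel.r2_matrix(pruned.snp_ids)
        off = r2[~np.eye(len(r2), dtype=bool)]
        assert off.max() <= 0.05
        lead = pair.table.loc[pair.table["p_a"].idxmin(), "snp_id"]
        assert lead in pruned.snp_ids

    def test_row_order_invariance(self):
        p = [0.5, 0.05, 0.01, 0.9, 0.02, 0.3]
        rows = toy_table(6, p=p)
        ss1 = make_sumstats(rows)
        ss2 = make_sumstats(rows[::-1])
        r2 = pd.DataFrame([{"snp_a": "rs3", "snp_b": "rs1", "r2": 0.6}])
        p1 = ld_prune(align_alleles(ss1, ss1), r2_table=r2)
        p2 = ld_prune(align_alleles(ss2, ss2), r2_table=r2)
        assert p1.snp_ids == p2.snp_ids

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_literal_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        p = rng.uniform(1e-4, 1, n)
        ss = make_sumstats(toy_table(n, p=p))
        pair = align_alleles(ss, ss)
        r2 = {i: {j: 0.0 for j in range(n)} for i in range(n)}
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    v = rng.uniform(0, 1)
                    r2[i][j] = r2[j][i] = v
                    rows.append({"snp_a": f"rs{i + 1}", "snp_b": f"rs{j + 1}", "r2": v})
        table = pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
        pruned = ld_prune(pair, r2_table=table, r2_threshold=0.05)
        expect = [f"rs{i + 1}" for i in prune_oracle(p, range(n), r2, 0.05)]
        assert pruned.snp_ids == expect


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_two_sided(5, 5, 5, 5).p == pytest.approx(1.0)

    def test_diagonal_table_by_enumeration(self):
        res = fisher_two_sided(10, 0, 0, 10)
        assert res.p == pytest.approx(fisher_oracle(10, 0, 0, 10), abs=1e-15)
        assert not res.or_finite

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_fraction_oracle(self, n11, n10, n01, n00):
        if n11 + n10 + n01 + n00 == 0:
            return
        assert fisher_two_sided(n11, n10, n01, n00).p == pytest.approx(
            fisher_oracle(n11, n10, n01, n00), abs=1e-13)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_cross_check_against_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n11, n10, n01, n00 = rng.integers(0, 30, 4)
        if n11 + n10 + n01 + n00 == 0:
            return
        ours = fisher_two_sided(n11, n10, n01, n00).p
        ref = stats.fisher_exact([[n11, n10], [n01, n00]])[1]
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_large_table_float_path_agrees_with_scipy(self):
        ours = fisher_two_sided(60, 5940, 40, 3960).p
        ref = stats.fisher_exact([[60, 5940], [40, 3960]])[1]
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_odds_ratio_and_flags(self):
        res = fisher_two_sided(4, 2, 1, 8)
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.or_finite
        assert math.isnan(fisher_two_sided(0, 2, 0, 8).odds_ratio)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        # p(i)*n/i = (.05,.05,.05,.05,.05); cumulative min from largest: all .05
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_empty_list(self):
        assert len(bh_adjust([])) == 0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_monotone_and_bounded(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1 + 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestBinomial:
    def test_twelve_of_sixteen_exact_tail(self):
        # exact tail enumeration: 2*2517/65536
        p = binomial_two_tailed(12, 16, 0.5)
        assert p == pytest.approx(2 * 2517 / 65536)
        assert f"{p:.2f}" == "0.08"

    @pytest.mark.parametrize("k,n,expected", [
        (8, 16, 1.0),           # symmetric centre
        (0, 1, 1.0),            # both tails included
        (10, 10, 2 * 0.5**10),  # all successes: both extreme tails
    ])
    def test_boundary_cases(self, k, n, expected):
        assert binomial_two_tailed(k, n, 0.5) == pytest.approx(expected)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 25), st.integers(1, 25))
    def test_symmetry_at_half(self, k, n):
        k = min(k, n)
        assert binomial_two_tailed(k, n, 0.5) == pytest.approx(
            binomial_two_tailed(n - k, n, 0.5), abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 15), st.integers(1, 15))
    def test_matches_enumeration_oracle_off_half(self, k, n):
        k = min(k, n)
        assert binomial_two_tailed(k, n, 0.25) == pytest.approx(
            binomial_oracle(k, n, 0.25), rel=1e-9)


def _null_pair(panel, seed):
    arch = null_architecture(panel)
    a, b = simulate_sumstats_pair(panel, arch, (2000, 6000), (2000, 6000),
                                  seed=seed)
    return align_alleles(a, b)


class TestOverlapScan:
    def test_cutoff_one_degenerates(self, small_panel):
        pair = _null_pair(small_panel, 1)
        pruned = ld_prune(pair, small_panel)
        scan = overlap_scan(pair, pruned, cutoffs=[1.0])
        row = scan.iloc[0]
        assert row["n10"] == row["n01"] == row["n00"] == 0
        assert row["fisher_p"] == pytest.approx(1.0)

    def test_counts_partition_pruned_set(self, small_panel):
        pair = _null_pair(small_panel, 2)
        pruned = ld_prune(pair, small_panel)
        scan = overlap_scan(pair, pruned)
        totals = scan[["n11", "n10", "n01", "n00"]].sum(axis=1)
        assert (totals == len(pruned)).all()
        assert (scan["fdr_p"] >= scan["fisher_p"] - 1e-12).all()

    def test_strong_shared_architecture_flags_smallest_cutoffs(self, small_panel):
        flagged = 0
        for seed in range(6):
            arch = shared_architecture(small_panel, [0, 2, 4], 7, 7,
                                       (2000, 6000), (2000, 6000),
                                       direction_concordance=1.0, seed=seed)
            a, b = simulate_sumstats_pair(small_panel, arch, (2000, 6000),
                                          (2000, 6000), seed=400 + seed)
            pair = align_alleles(a, b)
            pruned = ld_prune(pair, small_panel)
            scan = overlap_scan(pair, pruned)
            flagged += int(scan["flagged"].any())
        assert flagged >= 5


class TestPermuteOverlap:
    def test_nperm_one_estimator_bounds(self, small_panel):
        pair = _null_pair(small_panel, 3)
        pruned = ld_prune(pair, small_panel)
        res = permute_overlap(pair, pruned, [1e-2], 1, seed=0)
        assert res["perm_p"].iloc[0] in (0.5, 1.0)
        with pytest.raises(ValueError):
            permute_overlap(pair, pruned, [1e-2], 0, seed=0)

    def test_estimator_never_zero_and_floor(self, small_panel):
        arch = shared_architecture(small_panel, [0, 1, 2, 3, 4], 8, 8,
                                   (2000, 6000), (2000, 6000),
                                   direction_concordance=1.0, seed=0)
        a, b = simulate_sumstats_pair(small_panel, arch, (2000, 6000),
                                      (2000, 6000), seed=5)
        pair = align_alleles(a, b)
        pruned = ld_prune(pair, small_panel)
        res = permute_overlap(pair, pruned, [1e-3], 99, seed=1)
        assert res["perm_p"].iloc[0] >= 1 / 100  # add-one floor

    def test_null_empirical_p_roughly_uniform(self, small_panel):
        """Across seeds the null empirical p should not pile up near 0."""
        ps = []
        for seed in range(20):
            pair = _null_pair(small_panel, 600 + seed)
            pruned = ld_prune(pair, small_panel)
            res = permute_overlap(pair, pruned, [1e-2], 60, seed=seed)
            ps.append(res["perm_p"].iloc[0])
        ps = np.array(ps)
        assert (ps <= 0.1).mean() <= 0.25
        assert ps.mean() > 0.3


class TestDirectionConcordance:
    def test_all_concordant_exact_p(self):
        p = [1e-4] * 10
        beta = [0.2] * 10
        ss = make_sumstats(toy_table(10, p=p, beta=beta))
        pair = align_alleles(ss, ss)
        pruned = ld_prune(pair, r2_table=pd.DataFrame(columns=["snp_a", "snp_b", "r2"]))
        res = direction_concordance(pair, pruned, 1e-2)
        assert (res.concordant, res.total) == (10, 10)
        assert res.binomial_p == pytest.approx(2 * 0.5**10)

    def test_half_concordant_p_one(self, small_panel):
        pair = _null_pair(small_panel, 4)
        tab = pair.table.copy()
        tab["p_a"] = tab["p_b"] = 1e-4
        tab["beta_a"] = 0.1
        tab["beta_b"] = np.where(np.arange(len(tab)) % 2 == 0, 0.1, -0.1)
        pair.table = tab
        pruned = ld_prune(pair, small_panel, r2_threshold=1.01)
        res = direction_concordance(pair, pruned, 1e-2)
        assert res.concordant * 2 == res.total
        assert res.binomial_p == pytest.approx(1.0)

    def test_zero_qualifying_flagged_undefined(self, small_panel):
        pair = _null_pair(small_panel, 5)
        pruned = ld_prune(pair, small_panel)
        res = direction_concordance(pair, pruned, 1e-300)
        assert not res.defined and res.total == 0
        assert math.isnan(res.binomial_p)

    def test_opposite_architecture_yields_discordance(self, small_panel):
        below_half = 0
        for seed in range(6):
            arch = shared_architecture(small_panel, [0, 1, 2, 3, 4], 7, 7,
                                       (2000, 6000), (2000, 6000),
                                       direction_concordance=0.0, seed=seed)
            a, b = simulate_sumstats_pair(small_panel, arch, (2000, 6000),
                                          (2000, 6000), seed=700 + seed)
            pair = align_alleles(a, b)
            pruned = ld_prune(pair, small_panel)
            res = direction_concordance(pair, pruned, 1e-2)
            if res.defined and res.concordant / res.total < 0.5:
                below_half += 1
        assert below_half >= 5
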