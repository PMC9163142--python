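"""Rank-sum / Fisher / BH primitives and the cohort-level statistics."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from pisnv.caller import PiSNVCall
from pisnv.io import GenomicInterval, SiteSet, UTRAnnotation, Variant
from pisnv.stats import (
    bh_fdr,
    build_rbp_site_map,
    fisher_exact,
    gene_recurrence,
    gene_utr_lengths,
    rbp_enrichment,
    sample_profiles,
    sample_ratio,
    site_overlap,
    wilcoxon_rank_sum,
)


def _call(sample, chrom, pos, gene, is_pisnv, ref="A", alt="C"):
    return PiSNVCall(Variant(chrom, pos, ref, alt, sample), gene, is_pisnv,
                     [])


# ---------------------------------------------------------------------------
# sample ratio
# ---------------------------------------------------------------------------

def test_sample_ratio_extremes():
    calls = [_call("S", "c", i + 1, "G1", False) for i in range(10)]
    assert sample_ratio("S", calls).ratio == 0.0
    calls = [_call("S", "c", i + 1, "G1", True) for i in range(10)]
    p = sample_ratio("S", calls)
    assert p.ratio == 1.0 and p.n_utr3_snv == 10


def test_sample_ratio_zero_denominator_flagged():
    calls = [_call("S", "c", 5, "", False)]  # outside any 3'-UTR
    p = sample_ratio("S", calls)
    assert p.flagged and p.ratio == 0.0 and p.n_utr3_snv == 0


def test_sample_ratio_counts_distinct_variants():
    """A variant hitting two genes' UTRs counts once in both margins."""
    v = Variant("c", 7, "A", "C", "S")
    calls = [PiSNVCall(v, "G1", True, []), PiSNVCall(v, "G2", False, []),
             _call("S", "c", 9, "G1", False)]
    p = sample_ratio("S", calls)
    assert (p.n_utr3_snv, p.n_utr3_pisnv) == (2, 1)


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------

def test_wilcoxon_exact_small_case():
    """x={1,2}, y={3,4}: p = 2/6 by full rank enumeration."""
    w, p = wilcoxon_rank_sum([1, 2], [3, 4])
    assert w == 3.0
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_wilcoxon_symmetry_under_swap():
    x, y = [0.1, 0.7, 0.3], [0.5, 0.9, 0.2, 0.8]
    _, p1 = wilcoxon_rank_sum(x, y)
    _, p2 = wilcoxon_rank_sum(y, x)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_wilcoxon_identical_groups_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    _, p = wilcoxon_rank_sum(x, list(x))
    assert p == pytest.approx(1.0, abs=1e-9)


def test_wilcoxon_exact_matches_enumeration_oracle():
    """Independent subset enumeration for several no-tie sample sizes."""
    rng = np.random.default_rng(23)
    for n, m in [(2, 3), (4, 4), (5, 6), (3, 8)]:
        vals = rng.permutation(np.arange(1, n + m + 1) * 1.37)
        x, y = vals[:n], vals[n:]
        w, p = wilcoxon_rank_sum(x, y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n].sum()
        mean_w = n * (n + m + 1) / 2
        hits = total = 0
        for combo in combinations(range(1, n + m + 1), n):
            total += 1
            hits += abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-12
        assert p == pytest.approx(hits / total, abs=1e-12)


def test_wilcoxon_exact_matches_scipy():
    rng = np.random.default_rng(29)
    x = rng.normal(size=6)
    y = rng.normal(size=6) + 0.8
    _, p = wilcoxon_rank_sum(x, y)
    p_sp = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")[1]
    assert p == pytest.approx(p_sp, abs=1e-12)


def test_wilcoxon_large_sample_matches_scipy_asymptotic():
    rng = np.random.default_rng(31)
    x = rng.normal(size=25)
    y = rng.normal(size=30) + 0.4
    _, p = wilcoxon_rank_sum(x, y)
    p_sp = sps.mannwhitneyu(x, y, alternative="two-sided",
                            method="asymptotic")[1]
    assert p == pytest.approx(p_sp, rel=1e-9)


def test_wilcoxon_empty_group_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_fisher_odds_ratio_arithmetic():
    odds, _ = fisher_exact(10, 5, 2, 20)
    assert odds == pytest.approx(20.0)


def test_fisher_symmetric_table():
    odds, p = fisher_exact(5, 5, 5, 5)
    assert odds == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_fisher_infinite_odds():
    odds, _ = fisher_exact(4, 3, 0, 9)
    assert odds == math.inf


def test_fisher_degenerate_margin_errors():
    with pytest.raises(ValueError):
        fisher_exact(0, 0, 3, 4)


def test_fisher_matches_scipy():
    rng = np.random.default_rng(37)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 40, size=4)
        if (a + b) * (c + d) * (a + c) * (b + d) == 0:
            continue
        _, p = fisher_exact(int(a), int(b), int(c), int(d))
        _, p_sp = sps.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(p_sp, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def test_bh_single_and_equal_values():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    assert bh_fdr([0.04, 0.04, 0.04]) == pytest.approx([0.04] * 3)


def test_bh_hand_worked_vector():
    q = bh_fdr([0.01, 0.02, 0.04, 0.5])
    assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5], abs=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_fdr([1.2])


def test_bh_matches_statsmodels_and_is_monotone():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(41)
    for _ in range(20):
        p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
        q = bh_fdr(p)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_sm, atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_table_margins(default_result, default_caller):
    results = default_result.enrichment
    assert results, "no RBPs tested"
    totals = {(r.table[0] + r.table[1]) for r in results}
    assert len(totals) == 1  # a+b == total piSNV occurrences for every RBP
    grand = {sum(r.table) for r in results}
    assert len(grand) == 1  # the universe is shared


def test_enrichment_a_zero_never_significant():
    """OR <= 1 whenever no piSNV is in-site."""
    calls = ([_call("S", "c", i + 1, "G1", True) for i in range(5)]
             + [_call("S", "c", 100 + i, "G1", False) for i in range(20)])
    tree_map = {"R1": {}}
    # sites covering some non-piSNV positions only
    from intervaltree import IntervalTree
    t = IntervalTree()
    t.addi(99, 110)
    tree_map["R1"]["c"] = t
    (res,) = rbp_enrichment(calls, tree_map)
    assert res.table[0] == 0
    assert res.odds_ratio <= 1
    assert not res.significant


def test_enrichment_permutation_null(default_result):
    """Shuffling piSNV labels kills every enrichment in >=95% of permutations."""
    calls = default_result.calls_tumor
    in_utr = [c for c in calls if c.gene_id]
    labels = [c.is_pisnv for c in in_utr]
    rng = np.random.default_rng(43)
    empty = 0
    n_perm = 20
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        permuted = [PiSNVCall(c.variant, c.gene_id, bool(k), [])
                    for c, k in zip(in_utr, perm)]
        res = rbp_enrichment(permuted, _SITE_MAP_CACHE["map"])
        empty += not any(r.significant for r in res)
    assert empty >= int(0.95 * n_perm)


_SITE_MAP_CACHE: dict = {}


@pytest.fixture(autouse=True, scope="module")
def _prime_site_map(default_caller):
    _SITE_MAP_CACHE["map"] = build_rbp_site_map(default_caller)
    yield


# ---------------------------------------------------------------------------
# gene recurrence
# ---------------------------------------------------------------------------

def test_gene_recurrence_arithmetic_and_sorting():
    calls = [_call(f"S{i}", "c", 10 + i, "G1", True) for i in range(6)]
    res = gene_recurrence(calls, {"G1": 3000, "G2": 1000})
    assert res[0].gene_id == "G1"
    assert res[0].corrected_frequency == pytest.approx(2.0)  # 6 / 3 kb
    assert res[1].corrected_frequency == 0.0


def test_gene_recurrence_scaling_law():
    calls = [_call(f"S{i}", "c", 10 + i, "G1", True) for i in range(4)]
    res1 = gene_recurrence(calls, {"G1": 2000})
    res2 = gene_recurrence(calls, {"G1": 4000})
    assert res2[0].corrected_frequency == pytest.approx(
        res1[0].corrected_frequency / 2)


def test_gene_recurrence_zero_length_excluded():
    res = gene_recurrence([], {"G1": 0, "G2": 500})
    assert [g.gene_id for g in res] == ["G2"]


def test_gene_utr_lengths_unions_transcripts():
    utrs = [UTRAnnotation("T1", "G1", [GenomicInterval("c", 0, 100, "+")]),
            UTRAnnotation("T2", "G1", [GenomicInterval("c", 50, 150, "+")])]
    assert gene_utr_lengths(utrs) == {"G1": 150}


# ---------------------------------------------------------------------------
# site overlap
# ---------------------------------------------------------------------------

def test_site_overlap_extremes():
    calls = [_call("S", "c", i + 1, "G1", True) for i in range(10)]
    empty = SiteSet("m6A", [])
    full = SiteSet("APA", [GenomicInterval("c", 0, 1000, "+")])
    res = {s.class_name: s for s in site_overlap(calls, [empty, full])}
    assert res["m6A"].fraction == 0.0
    assert res["APA"].fraction == 1.0


def test_site_overlap_uniform_coverage_fraction():
    """Uniform piSNVs over [0, 10000) vs a set covering 10% of positions."""
    rng = np.random.default_rng(47)
    pos = rng.choice(10000, size=2000, replace=False)
    calls = [_call("S", "c", int(p) + 1, "G1", True) for p in pos]
    sites = SiteSet("m6A", [GenomicInterval("c", k * 1000, k * 1000 + 100, "+")
                            for k in range(10)])
    (res,) = site_overlap(calls, [sites])
    se = math.sqrt(0.1 * 0.9 / 2000)
    assert abs(res.fraction - 0.1) < 4 * se
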