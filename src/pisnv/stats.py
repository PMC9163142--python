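"""Cohort-level statistics over piSNV calls.

Per-sample piSNV ratio, tumor-vs-control rank-sum comparison, per-RBP
Fisher enrichment with Benjamini-Hochberg FDR control, 3'-UTR-length
corrected gene recurrence, and regulatory-site overlap fractions.

The elementary tests (Wilcoxon rank sum, two-sided Fisher exact,
BH step-up) are implemented here with scipy supplying only the
distributions; the test suite cross-checks them against scipy and
statsmodels and against brute-force enumeration oracles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .caller import (
    PiSNVCall,
    PiSNVCaller,
    pwm_log_odds_matrix,
)
from .io import GenomicInterval, SiteSet, UTRAnnotation, Variant

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class SampleProfile:
    """Per-sample 3'-UTR SNV and piSNV counts and their ratio."""

    sample_id: str
    n_utr3_snv: int
    n_utr3_pisnv: int
    ratio: float
    flagged: bool = False  # True when the denominator was zero

    def __post_init__(self) -> None:
        if self.n_utr3_pisnv > self.n_utr3_snv:
            raise ValueError(f"{self.sample_id}: piSNV count exceeds SNV count")


@dataclass
class EnrichmentResult:
    """One RBP's 2x2 Fisher test outcome with BH-adjusted FDR."""

    rbp_name: str
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p_value: float
    fdr: float
    significant: bool


@dataclass
class GeneRecurrence:
    """Per-gene piSNV recurrence, corrected by 3'-UTR length."""

    gene_id: str
    n_samples_with_pisnv: int
    n_pisnv: int
    utr3_length: int
    corrected_frequency: float  # samples with event per kb of 3'-UTR


@dataclass
class SiteOverlapSummary:
    """Fraction of distinct piSNVs falling inside one regulatory-site class."""

    class_name: str
    n_overlapping: int
    n_total_pisnv: int
    fraction: float


# ---------------------------------------------------------------------------
# per-sample ratio
# ---------------------------------------------------------------------------

def sample_ratio(sample_id: str, calls: Sequence[PiSNVCall]) -> SampleProfile:
    """Ratio of distinct 3'-UTR piSNVs to distinct 3'-UTR SNVs for one sample.

    ``calls`` are the caller's outputs for this sample's variants; variants
    outside every 3'-UTR (empty gene id) are excluded from both counts.
    """
    utr_keys = {c.variant.key for c in calls if c.gene_id}
    pisnv_keys = {c.variant.key for c in calls if c.gene_id and c.is_pisnv}
    n_snv, n_pi = len(utr_keys), len(pisnv_keys)
    if n_snv == 0:
        return SampleProfile(sample_id, 0, 0, 0.0, flagged=True)
    return SampleProfile(sample_id, n_snv, n_pi, n_pi / n_snv)


def sample_profiles(calls: Iterable[PiSNVCall]) -> list[SampleProfile]:
    """Group calls by sample and compute each sample's profile."""
    by_sample: dict[str, list[PiSNVCall]] = {}
    for c in calls:
        by_sample.setdefault(c.variant.sample_id, []).append(c)
    return [sample_ratio(sid, cs) for sid, cs in sorted(by_sample.items())]


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]
                      ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of ``x``.  The null distribution is enumerated
    exactly when ``len(x) + len(y) <= 16`` and there are no ties; larger or
    tied samples use the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < n + m

    if n + m <= 16 and not has_ties:
        # exact: enumerate all C(n+m, n) assignments of ranks to x
        all_ranks = range(1, n + m + 1)
        total = 0
        extreme = 0
        mean_w = n * (n + m + 1) / 2.0
        dev = abs(w - mean_w)
        for combo in combinations(all_ranks, n):
            total += 1
            if abs(sum(combo) - mean_w) >= dev - 1e-12:
                extreme += 1
        return w, extreme / total

    mean_w = n * (n + m + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_w = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)  # continuity correction
    z = max(z, 0.0)
    return w, float(min(1.0, 2.0 * sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# Fisher exact and BH-FDR
# ---------------------------------------------------------------------------

def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on [[a, b], [c, d]]; returns (OR, p).

    The two-sided p sums hypergeometric probabilities of all tables at the
    fixed margins whose probability does not exceed the observed table's
    (minimum-likelihood method).  Probabilities share the denominator
    C(n, c1), so numerators are compared as exact integers and ties are
    resolved exactly rather than through a floating-point slack.  OR is the
    sample odds ratio a*d / (b*c), +inf when b*c == 0 and a*d > 0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        raise ValueError("degenerate table: a margin is zero")
    n = r1 + r2
    odds = math.inf if (b * c == 0 and a * d > 0) else (
        0.0 if b * c == 0 else (a * d) / (b * c))
    # P(a = k) = C(r1, k) C(r2, c1-k) / C(n, c1): integer numerators
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num_k <= num_obs:
            total += num_k
    p = float(Fraction(total, math.comb(n, c1)))
    return odds, min(1.0, p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# RBP enrichment
# ---------------------------------------------------------------------------

def build_rbp_site_map(caller: PiSNVCaller) -> dict[str, dict[str, IntervalTree]]:
    """Per-RBP genomic binding loci: PWM motif matches union CLIP peaks.

    Motif matches are windows on any gene's 3'-UTR whose reference log-odds
    clears the caller's hit floor; peaks contribute their full interval.
    Returns rbp -> chrom -> IntervalTree.
    """
    p = caller.params
    site_map: dict[str, dict[str, IntervalTree]] = {}

    def _add(rbp: str, chrom: str, start: int, end: int) -> None:
        site_map.setdefault(rbp, {}).setdefault(chrom, IntervalTree()).addi(
            start, end)

    for gene in caller.genes.values():
        seq_idx = _encode(gene.sequence)
        for pwm in caller.pwms:
            lo = pwm_log_odds_matrix(pwm, p.background)
            floor = (p.motif_score_min if p.motif_score_min is not None
                     else p.motif_score_frac * float(lo.max(axis=1).sum()))
            L = pwm.length
            if L > gene.length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(seq_idx, L)
            scores = lo[np.arange(L)[None, :], windows].sum(axis=1)
            for w in np.nonzero(scores >= floor)[0]:
                gs = gene.genomic_pos0(int(w) if gene.strand == "+"
                                       else int(w) + L - 1)
                _add(pwm.rbp_name, gene.chrom, gs, gs + L)
    for tree in caller.peak_index.values():
        for hit in tree:
            pk = hit.data
            _add(pk.rbp_name, pk.interval.chrom, pk.interval.start,
                 pk.interval.end)
    return site_map


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(("ACGU".index(b) for b in seq), dtype=np.int64,
                       count=len(seq))


def rbp_enrichment(calls: Sequence[PiSNVCall],
                   site_map: Mapping[str, Mapping[str, IntervalTree]],
                   alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-RBP 2x2 Fisher enrichment of piSNVs inside RBP binding loci.

    Unit of analysis is the 3'-UTR SNV occurrence (sample x variant, pooled
    over the cohort; a variant hitting two genes' UTRs counts once); for
    each RBP the table is piSNV-status x in-site-status.  BH correction
    runs across all tested RBPs; an RBP is significant iff FDR < ``alpha``
    and OR > 1.
    """
    variants: dict[tuple[str, str], tuple[Variant, bool]] = {}
    for c in calls:
        if not c.gene_id:
            continue
        k = (c.variant.sample_id, c.variant.key)
        prev = variants.get(k)
        variants[k] = (c.variant, c.is_pisnv or (prev[1] if prev else False))
    if not variants:
        return []

    rows = []
    for rbp in sorted(site_map):
        trees = site_map[rbp]
        if not any(len(t) for t in trees.values()):
            logger.info("rbp_enrichment: %s has an empty site set, skipped", rbp)
            continue
        a = b = c_ = d = 0
        for v, is_pi in variants.values():
            tree = trees.get(v.chrom)
            in_site = bool(tree is not None and tree.at(v.pos0))
            if is_pi and in_site:
                a += 1
            elif is_pi:
                b += 1
            elif in_site:
                c_ += 1
            else:
                d += 1
        try:
            odds, p = fisher_exact(a, b, c_, d)
        except ValueError:
            logger.info("rbp_enrichment: %s has a degenerate table, skipped", rbp)
            continue
        rows.append((rbp, (a, b, c_, d), odds, p))

    if not rows:
        return []
    qs = bh_fdr([r[3] for r in rows])
    return [
        EnrichmentResult(rbp, table, odds, p, float(q),
                         significant=bool(q < alpha and odds > 1))
        for (rbp, table, odds, p), q in zip(rows, qs)
    ]


# ---------------------------------------------------------------------------
# gene recurrence
# ---------------------------------------------------------------------------

def gene_recurrence(calls: Sequence[PiSNVCall],
                    utr_lengths: Mapping[str, int]) -> list[GeneRecurrence]:
    """Per-gene piSNV recurrence corrected by 3'-UTR length (events per kb).

    The corrected frequency divides the number of distinct samples carrying
    a piSNV in the gene by the gene's 3'-UTR length in kb.  Sorted by
    decreasing corrected frequency, ties broken by gene id.
    """
    samples: dict[str, set[str]] = {}
    events: dict[str, set[str]] = {}
    for c in calls:
        if c.is_pisnv and c.gene_id:
            samples.setdefault(c.gene_id, set()).add(c.variant.sample_id)
            events.setdefault(c.gene_id, set()).add(c.variant.key)
    out = []
    for gene, length in utr_lengths.items():
        if length <= 0:
            logger.warning("gene_recurrence: %s has zero UTR length, excluded",
                           gene)
            continue
        n_s = len(samples.get(gene, ()))
        out.append(GeneRecurrence(gene, n_s, len(events.get(gene, ())),
                                  length, n_s / (length / 1000.0)))
    out.sort(key=lambda g: (-g.corrected_frequency, g.gene_id))
    return out


def gene_utr_lengths(utrs: Iterable[UTRAnnotation]) -> dict[str, int]:
    """Gene-level union 3'-UTR lengths from transcript annotations."""
    by_gene: dict[str, list[GenomicInterval]] = {}
    for a in utrs:
        by_gene.setdefault(a.gene_id, []).extend(a.utr3_intervals)
    lengths = {}
    for gene, ivs in by_gene.items():
        merged: list[list[int]] = []
        for iv in sorted(ivs, key=lambda i: i.start):
            if merged and iv.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        lengths[gene] = sum(e - s for s, e in merged)
    return lengths


# ---------------------------------------------------------------------------
# regulatory-site overlap
# ---------------------------------------------------------------------------

def site_overlap(calls: Sequence[PiSNVCall],
                 site_sets: Sequence[SiteSet]) -> list[SiteOverlapSummary]:
    """Fraction of distinct piSNVs lying inside each regulatory-site class."""
    pisnvs: dict[str, Variant] = {
        c.variant.key: c.variant for c in calls if c.is_pisnv and c.gene_id
    }
    out = []
    for ss in site_sets:
        trees: dict[str, IntervalTree] = {}
        for iv in ss.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        n_overlap = sum(
            1 for v in pisnvs.values()
            if v.chrom in trees and trees[v.chrom].at(v.pos0)
        )
        n_total = len(pisnvs)
        out.append(SiteOverlapSummary(ss.class_name, n_overlap, n_total,
                                      n_overlap / n_total if n_total else 0.0))
    return out


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def profiles_frame(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.sample_id, p.n_utr3_snv, p.n_utr3_pisnv, p.ratio, p.flagged)
         for p in profiles],
        columns=["sample_id", "n_utr3_snv", "n_utr3_pisnv", "ratio", "flagged"])


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.rbp_name, *r.table, r.odds_ratio, r.p_value, r.fdr, r.significant)
         for r in results],
        columns=["rbp_name", "a", "b", "c", "d", "odds_ratio", "p_value",
                 "fdr", "significant"])


def recurrence_frame(results: Sequence[GeneRecurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.n_samples_with_pisnv, g.n_pisnv, g.utr3_length,
          g.corrected_frequency) for g in results],
        columns=["gene_id", "n_samples_with_pisnv", "n_pisnv", "utr3_length",
                 "corrected_frequency"])


def site_overlap_frame(results: Sequence[SiteOverlapSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.class_name, s.n_overlapping, s.n_total_pisnv, s.fraction)
         for s in results],
        columns=["class_name", "n_overlapping", "n_total_pisnv", "fraction"])
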