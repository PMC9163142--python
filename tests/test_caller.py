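"""Motif scoring, structure distance, CLIP overlap and the piSNV decision."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pisnv.caller import (
    CallerParams,
    PiSNVCaller,
    build_peak_index,
    classify_region,
    clip_overlap,
    pwm_log_odds,
    pwm_max_score,
    scan_motifs,
    structure_distance,
)
from pisnv.io import ClipPeak, GenomicInterval, UTRAnnotation, Variant
from pisnv.pipeline import inputs_from_study, run_pipeline
from pisnv.simulate import SimulationConfig, make_pwm, simulate_study

from conftest import call_signature, call_truth_summary, mirror_study


def oracle_log_odds(window: str, matrix: np.ndarray) -> float:
    """Independent per-position sum against a uniform background."""
    total = 0.0
    for j, base in enumerate(window):
        total += math.log2(matrix[j]["ACGU".index(base)] / 0.25)
    return total


def test_uniform_pwm_scores_zero():
    from pisnv.io import PWMRecord
    pwm = PWMRecord("U", np.full((6, 4), 0.25))
    assert pwm_log_odds("ACGUAC", pwm) == pytest.approx(0.0, abs=1e-12)


def test_consensus_log_odds_matches_per_position_oracle():
    """0.97/0.01 CUCUCU PWM: consensus scores 6*log2(0.97/0.25) ~ 11.74."""
    pwm = make_pwm("PTBP1", "CUCUCU", 0.97)
    score = pwm_log_odds("CUCUCU", pwm)
    assert score == pytest.approx(oracle_log_odds("CUCUCU", pwm.matrix),
                                  abs=1e-10)
    assert score == pytest.approx(6 * math.log2(0.97 / 0.25), abs=1e-10)
    assert score == pytest.approx(11.74, abs=0.01)
    assert pwm_max_score(pwm) == pytest.approx(score, abs=1e-10)


def test_fifth_position_c_to_u_delta():
    """C->U at motif position 5 drops the score by log2(0.97/0.01) ~ 6.60."""
    pwm = make_pwm("PTBP1", "CUCUCU", 0.97)
    ref = pwm_log_odds("CUCUCU", pwm)
    alt = pwm_log_odds("CUCUUU", pwm)
    assert alt == pytest.approx(oracle_log_odds("CUCUUU", pwm.matrix),
                                abs=1e-10)
    assert alt - ref == pytest.approx(-6.60, abs=0.01)
    assert alt == pytest.approx(5.14, abs=0.01)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_scan_far_from_motif_is_empty():
    pwm = make_pwm("PTBP1", "CUCUCU", 0.97)
    seq = "A" * 20 + "CUCUCU" + "A" * 20
    hits = scan_motifs(seq, [pwm], 40, "G")
    assert hits == []


def test_scan_planted_instance_yields_single_negative_hit():
    pwm = make_pwm("PTBP1", "CUCUCU", 0.97)
    seq = "A" * 20 + "CUCUCU" + "A" * 20
    hits = scan_motifs(seq, [pwm], 24, "U")  # 5th motif base, C->U
    assert len(hits) == 1
    h = hits[0]
    assert h.utr_offset == 20 and h.delta < -6
    assert h.delta == pytest.approx(h.alt_score - h.ref_score)


def test_degenerate_column_gives_zero_delta():
    """Alt equal-probability with ref in a two-base column: delta == 0."""
    from pisnv.io import PWMRecord
    mat = np.full((4, 4), 0.01)
    for j, b in enumerate("CUCU"):
        mat[j, "ACGU".index(b)] = 0.97
    mat[1] = [0.01, 0.485, 0.01, 0.485]  # position 2 tolerates C or U
    mat = mat / mat.sum(axis=1, keepdims=True)
    pwm = PWMRecord("D", mat)
    seq = "A" * 10 + "CUCU" + "A" * 10
    hits = scan_motifs(seq, [pwm], 11, "C",
                       CallerParams(motif_score_frac=0.7))
    assert len(hits) == 1
    assert hits[0].delta == pytest.approx(0.0, abs=1e-12)


def test_scan_equals_brute_force_rescorer():
    """Window-by-window rescoring oracle on random UTRs <= 500 nt."""
    rng = np.random.default_rng(11)
    pwms = [make_pwm(f"R{i}", "".join(rng.choice(list("ACGU"), size=L)), 0.9)
            for i, L in enumerate([4, 6, 7])]
    params = CallerParams(motif_score_frac=0.6)
    for _ in range(20):
        n = int(rng.integers(30, 500))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        # ensure some real hits: splice a consensus in
        pw = pwms[int(rng.integers(3))]
        pos = int(rng.integers(0, n - pw.length))
        seq = seq[:pos] + pw.consensus + seq[pos + pw.length:]
        off = int(rng.integers(max(0, pos - 3), min(n, pos + pw.length + 3)))
        alt = str(rng.choice([b for b in "ACGU" if b != seq[off]]))
        got = {(h.rbp_name, h.utr_offset,
                round(h.ref_score, 9), round(h.alt_score, 9))
               for h in scan_motifs(seq, pwms, off, alt, params)}
        expected = set()
        for pwm in pwms:
            floor = params.motif_score_frac * pwm_max_score(pwm)
            for w in range(0, n - pwm.length + 1):
                if not (w <= off < w + pwm.length):
                    continue
                ref_win = seq[w:w + pwm.length]
                alt_win = (ref_win[:off - w] + alt + ref_win[off - w + 1:])
                rs = pwm_log_odds(ref_win, pwm)
                if rs >= floor:
                    expected.add((pwm.rbp_name, w, round(rs, 9),
                                  round(pwm_log_odds(alt_win, pwm), 9)))
        assert got == expected


def test_delta_depends_only_on_variant_column():
    """delta == log-odds difference at the variant column alone."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        L = int(rng.integers(4, 9))
        cons = "".join(rng.choice(list("ACGU"), size=L))
        pwm = make_pwm("R", cons, 0.9)
        seq = "".join(rng.choice(list("ACGU"), size=40))
        w = int(rng.integers(0, 40 - L))
        seq = seq[:w] + cons + seq[w + L:]
        j = int(rng.integers(L))
        off = w + j
        alt = str(rng.choice([b for b in "ACGU" if b != seq[off]]))
        (hit,) = [h for h in scan_motifs(seq, [pwm], off, alt,
                                         CallerParams(motif_score_frac=0.99))
                  if h.utr_offset == w]
        lo = np.log2(pwm.matrix / 0.25)
        col_delta = lo[j, "ACGU".index(alt)] - lo[j, "ACGU".index(seq[off])]
        assert hit.delta == pytest.approx(col_delta, abs=1e-10)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def test_structure_same_base_distance_zero():
    seq = "GCGCGCAAAAGCGCGC" * 4
    sa = structure_distance(seq, 30, seq[30], radius=20)
    assert sa.distance == 0.0 and sa.ref_structure == sa.alt_structure


def test_structure_poly_a_unpaired_distance_zero():
    seq = "A" * 101
    sa = structure_distance(seq, 50, "C", radius=50)
    assert set(sa.ref_structure) == {"."}
    assert sa.distance == 0.0


def test_structure_breaking_a_hairpin_stem():
    """Disrupting a perfect 12-bp stem must change the MFE pairing."""
    stem5, loop = "GGGGGGGGGGGG", "AAAA"
    seq = stem5 + loop + "CCCCCCCCCCCC"
    ref = structure_distance(seq, 0, seq[0], radius=30)
    assert "(" in ref.ref_structure  # the hairpin actually folds
    sa = structure_distance(seq, 5, "C", radius=30)  # G->C inside the stem
    assert sa.distance > 0.0


def test_structure_short_window_flagged():
    sa = structure_distance("ACGUACGUAC", 5, "A", radius=10)
    assert sa.short_window and sa.distance == 0.0


def test_structure_distance_is_symmetric():
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGU"), size=101))
    off = 50
    alt = "G" if seq[off] != "G" else "C"
    fwd = structure_distance(seq, off, alt, radius=50)
    mutated = seq[:off] + alt + seq[off + 1:]
    back = structure_distance(mutated, off, seq[off], radius=50)
    assert fwd.distance == pytest.approx(back.distance, abs=1e-12)


# ---------------------------------------------------------------------------
# CLIP overlap and region classes
# ---------------------------------------------------------------------------

def test_clip_overlap_membership_and_boundary():
    peaks = [ClipPeak(GenomicInterval("chr1", 100, 200, "+"), "PTBP1"),
             ClipPeak(GenomicInterval("chr1", 140, 260, "+"), "SRSF1")]
    index = build_peak_index(peaks)
    inside = Variant("chr1", 151, "A", "C")      # pos0=150
    assert clip_overlap(inside, index) == ["PTBP1", "SRSF1"]
    at_end = Variant("chr1", 201, "A", "C")      # pos0=200: half-open
    assert clip_overlap(at_end, index) == ["SRSF1"]
    assert clip_overlap(Variant("chr2", 150, "A", "C"), index) == []


def test_clip_overlap_is_strand_matched():
    peaks = [ClipPeak(GenomicInterval("chr1", 100, 200, "-"), "PTBP1")]
    index = build_peak_index(peaks)
    v = Variant("chr1", 151, "A", "C")
    assert clip_overlap(v, index, strand="+") == []
    assert clip_overlap(v, index, strand="-") == ["PTBP1"]


def test_classify_region_precedence():
    labelled = [(GenomicInterval("chr1", 100, 200, "+"), "utr3"),
                (GenomicInterval("chr1", 150, 400, "+"), "exon")]
    assert classify_region(Variant("chr1", 160, "A", "C"), labelled) == "utr3"
    assert classify_region(Variant("chr1", 300, "A", "C"), labelled) == "exon"
    assert classify_region(Variant("chr1", 900, "A", "C"), labelled) == "other"


# ---------------------------------------------------------------------------
# the full decision
# ---------------------------------------------------------------------------

def test_variant_outside_utr_never_called(default_caller):
    ref = default_caller.genome["chr1"][0]  # intergenic gap base
    v = Variant("chr1", 1, ref, "A" if ref != "A" else "C", "S")
    (call,) = default_caller.call_variant(v)
    assert not call.is_pisnv and call.gene_id == "" and not call.supporting_rbps


def test_planted_disruptor_is_called_with_its_rbp(default_study,
                                                  default_caller):
    truth = default_study.truth_variants
    planted = truth[truth.is_planted_disruptor].iloc[0]
    v = Variant(planted.chrom, int(planted.pos), planted.ref, planted.alt,
                planted.sample_id)
    calls = default_caller.call_variant(v)
    assert any(c.is_pisnv for c in calls)
    supporting = {ev.rbp_name for c in calls for ev in c.supporting_rbps}
    assert planted.target_rbp in supporting
    ev = next(ev for c in calls for ev in c.supporting_rbps
              if ev.rbp_name == planted.target_rbp)
    assert ev.motif_disrupted and ev.delta < -2


def test_ref_mismatch_raises(default_caller):
    gene = next(iter(default_caller.genes.values()))
    pos0 = gene.intervals[0].start + 5
    actual = default_caller.genome[gene.chrom][pos0]
    wrong = "A" if actual != "A" else "C"
    alt = "G" if wrong != "G" else "T"
    v = Variant(gene.chrom, pos0 + 1, wrong, alt, "S")
    with pytest.raises(ValueError, match="ref mismatch"):
        default_caller.call_variant(v)


def test_pisnv_counts_never_exceed_utr_snv_counts(default_result):
    for p in (default_result.profiles_tumor + default_result.profiles_control):
        assert p.n_utr3_pisnv <= p.n_utr3_snv
        assert p.ratio == pytest.approx(
            p.n_utr3_pisnv / p.n_utr3_snv if p.n_utr3_snv else 0.0)


def test_caller_recovers_planted_truth(default_study, default_result):
    sens, fcr = call_truth_summary(
        default_study,
        default_result.calls_tumor + default_result.calls_control)
    assert sens >= 0.9
    assert fcr <= 0.05


def test_strand_equivariance_on_small_study(small_study):
    """Mirrored genome + flipped strands => identical calls everywhere."""
    fwd = run_pipeline(inputs_from_study(small_study))
    mirrored = run_pipeline(mirror_study(small_study))
    lengths = {c: len(s) for c, s in small_study.genome.items()}
    sig_fwd = call_signature(fwd.calls_tumor + fwd.calls_control)
    sig_mir = call_signature(mirrored.calls_tumor + mirrored.calls_control,
                             lengths)
    assert sig_fwd == sig_mir


def test_require_clip_restricts_candidates(small_study):
    """With require_clip, motif-only loci lose binding evidence."""
    loose = run_pipeline(inputs_from_study(small_study))
    strict = run_pipeline(inputs_from_study(small_study),
                          CallerParams(require_clip=True))
    n_loose = sum(c.is_pisnv for c in loose.calls_tumor)
    n_strict = sum(c.is_pisnv for c in strict.calls_tumor)
    assert n_strict <= n_loose
    for c in strict.calls_tumor:
        for ev in c.supporting_rbps:
            assert ev.clip_overlap


def test_caller_params_validation():
    with pytest.raises(ValueError):
        CallerParams(delta_threshold=1.0)
    with pytest.raises(ValueError):
        CallerParams(structure_threshold=0.0)
    with pytest.raises(ValueError):
        CallerParams(fold_window_radius=5)
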