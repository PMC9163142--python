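"""The 3'-UTR piSNV caller.

A somatic SNV in a 3'-UTR is classified as posttranscriptional-impairment
related (a piSNV) for an RBP R when two kinds of evidence coincide at its
locus:

* binding evidence — a PWM motif match of R on the reference allele whose
  log-odds score clears the hit floor, and/or a CLIP peak of R covering the
  position (both required with ``require_clip``);
* impairment evidence — the variant drops the motif log-odds by at least
  ``delta_threshold`` bits, or it changes the local minimum-free-energy
  secondary structure by at least ``structure_threshold`` (fraction of
  positions in the folding window whose pairing partner changes).

Evidence is combined with OR across RBPs and OR across the two impairment
arms.  Folding uses ViennaRNA on a window of ``2*fold_window_radius + 1``
nucleotides centred on the variant; it is evaluated lazily, only when some
candidate RBP is not already resolved by the motif delta, because the MFE
computation dominates runtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import RNA
from intervaltree import IntervalTree

from .io import (
    PWM_ALPHABET,
    ClipPeak,
    GenomicInterval,
    PWMRecord,
    UTRAnnotation,
    Variant,
    extract_utr_sequence,
    reverse_complement,
    transcribe,
)

UNIFORM_BACKGROUND = np.full(4, 0.25)

_RNA_INDEX = {b: i for i, b in enumerate(PWM_ALPHABET)}
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CallerParams:
    """Tunable thresholds of the caller.

    delta_threshold : bits (< 0)
        Motif-arm cutoff on alt-minus-ref log-odds.
    structure_threshold : fraction in (0, 1]
        Structure-arm cutoff on the pairing-change distance.
    motif_score_min : bits or None
        Absolute hit floor on the reference-allele log-odds; when None the
        floor is ``motif_score_frac`` of each PWM's maximum attainable score.
    fold_window_radius : nt
        Half-width of the folding window.
    require_clip : bool
        Demand CLIP support in addition to a motif hit for binding evidence.
    """

    delta_threshold: float = -2.0
    structure_threshold: float = 0.1
    motif_score_min: float | None = None
    motif_score_frac: float = 0.8
    fold_window_radius: int = 50
    require_clip: bool = False
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        if self.delta_threshold >= 0:
            raise ValueError("delta_threshold must be < 0 bits")
        if not (0 < self.structure_threshold <= 1):
            raise ValueError("structure_threshold must be in (0, 1]")
        if self.fold_window_radius < 10:
            raise ValueError("fold_window_radius must be >= 10 nt")
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(self.background.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")


@dataclass(frozen=True)
class MotifHit:
    """One PWM window overlapping a variant, scored on both alleles."""

    rbp_name: str
    utr_offset: int  # window start on the sense 3'-UTR sequence, 0-based
    ref_score: float
    alt_score: float

    @property
    def delta(self) -> float:
        return self.alt_score - self.ref_score


@dataclass(frozen=True)
class StructureAssessment:
    """Local MFE structures of the two alleles and their pairing distance."""

    window_radius: int
    ref_structure: str
    alt_structure: str
    distance: float
    short_window: bool = False


@dataclass(frozen=True)
class RBPEvidence:
    """Per-RBP evidence at a called locus."""

    rbp_name: str
    motif_disrupted: bool
    clip_overlap: bool
    delta: float  # bits; NaN when no motif hit
    structure_distance: float  # NaN when folding was not needed


@dataclass
class PiSNVCall:
    """Classification of one variant within one gene's 3'-UTR."""

    variant: Variant
    gene_id: str
    is_pisnv: bool
    supporting_rbps: list[RBPEvidence]
    structure: StructureAssessment | None = None


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def encode_rna(seq: str) -> np.ndarray:
    """RNA string -> integer codes in PWM_ALPHABET order."""
    try:
        return np.fromiter((_RNA_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"base outside ACGU: {exc.args[0]!r}") from exc


def pwm_log_odds_matrix(pwm: PWMRecord, background: np.ndarray) -> np.ndarray:
    """(L, 4) log2 odds of the (pseudocounted) matrix against background."""
    return np.log2(pwm.matrix / np.asarray(background)[None, :])


def pwm_log_odds(window: str, pwm: PWMRecord,
                 background: np.ndarray | None = None) -> float:
    """Log-odds score in bits of one window under one PWM.

    Sum over positions of log2(p_matrix(base) / p_background(base)).
    """
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    lom = pwm_log_odds_matrix(pwm, bg)
    idx = encode_rna(window)
    return float(lom[np.arange(pwm.length), idx].sum())


def pwm_max_score(pwm: PWMRecord, background: np.ndarray | None = None) -> float:
    """Maximum attainable log-odds (consensus) in bits."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    return float(pwm_log_odds_matrix(pwm, bg).max(axis=1).sum())


def scan_motifs(utr_seq: str, pwms: Sequence[PWMRecord], variant_offset: int,
                alt_base: str, params: CallerParams | None = None) -> list[MotifHit]:
    """Score every PWM window overlapping a variant on ref and alt alleles.

    Returns hits whose reference-allele score clears the hit floor
    (``motif_score_min`` or ``motif_score_frac`` of the PWM maximum).
    """
    params = params or CallerParams()
    if not (0 <= variant_offset < len(utr_seq)):
        raise ValueError("variant_offset outside sequence")
    seq_idx = encode_rna(utr_seq)
    alt_idx = _RNA_INDEX[alt_base] if alt_base in _RNA_INDEX else None
    if alt_idx is None:
        raise ValueError(f"alt base outside ACGU: {alt_base!r}")
    hits: list[MotifHit] = []
    for pwm in pwms:
        L = pwm.length
        lo = pwm_log_odds_matrix(pwm, params.background)
        floor = (params.motif_score_min if params.motif_score_min is not None
                 else params.motif_score_frac * float(lo.max(axis=1).sum()))
        first = max(0, variant_offset - L + 1)
        last = min(variant_offset, len(utr_seq) - L)
        for w in range(first, last + 1):
            cols = np.arange(L)
            ref_score = float(lo[cols, seq_idx[w : w + L]].sum())
            if ref_score < floor:
                continue
            j = variant_offset - w
            alt_score = ref_score - float(lo[j, seq_idx[variant_offset]]) \
                + float(lo[j, alt_idx])
            hits.append(MotifHit(pwm.rbp_name, w, ref_score, alt_score))
    return hits


def _pair_table(structure: str) -> np.ndarray:
    # RNA.ptable is 1-based with length at index 0
    pt = RNA.ptable(structure)
    return np.array(pt[1:], dtype=np.int64)


def structure_distance(utr_seq: str, variant_offset: int, alt_base: str,
                       radius: int = 50) -> StructureAssessment:
    """Fold ref and alt windows around a variant and compare base pairing.

    The distance is the fraction of window positions whose pairing status or
    partner differs between the two MFE structures.  Windows shorter than
    20 nt after clipping at the sequence ends are not folded (distance 0,
    ``short_window`` flag set).
    """
    if radius < 10:
        raise ValueError("radius must be >= 10 nt")
    lo = max(0, variant_offset - radius)
    hi = min(len(utr_seq), variant_offset + radius + 1)
    ref_win = utr_seq[lo:hi]
    if len(ref_win) < 20:
        return StructureAssessment(radius, "", "", 0.0, short_window=True)
    j = variant_offset - lo
    alt_win = ref_win[:j] + alt_base + ref_win[j + 1 :]
    ref_db, _ = RNA.fold(ref_win)
    if alt_win == ref_win:
        return StructureAssessment(radius, ref_db, ref_db, 0.0)
    alt_db, _ = RNA.fold(alt_win)
    diff = int((_pair_table(ref_db) != _pair_table(alt_db)).sum())
    return StructureAssessment(radius, ref_db, alt_db, diff / len(ref_win))


# ---------------------------------------------------------------------------
# interval indexes
# ---------------------------------------------------------------------------

def build_peak_index(peaks: Iterable[ClipPeak]) -> dict[str, IntervalTree]:
    """chrom -> IntervalTree of ClipPeaks."""
    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.interval.chrom, IntervalTree()).addi(
            pk.interval.start, pk.interval.end, pk
        )
    return trees


def clip_overlap(variant: Variant, peak_index: dict[str, IntervalTree],
                 strand: str | None = None) -> list[str]:
    """RBP names of CLIP peaks containing the variant position.

    ``strand`` restricts hits to peaks on the host 3'-UTR's strand.
    """
    tree = peak_index.get(variant.chrom)
    if tree is None:
        return []
    names = {
        hit.data.rbp_name
        for hit in tree.at(variant.pos0)
        if strand is None or hit.data.interval.strand == strand
    }
    return sorted(names)


def classify_region(variant: Variant,
                    labelled: Iterable[tuple[GenomicInterval, str]]) -> str:
    """Assign a variant to utr3 > exon > other by interval membership."""
    found = {
        label
        for iv, label in labelled
        if iv.chrom == variant.chrom and iv.contains(variant.pos0)
    }
    for cls in ("utr3", "exon"):
        if cls in found:
            return cls
    return "other"


# ---------------------------------------------------------------------------
# gene-level UTR model
# ---------------------------------------------------------------------------

class GeneUTR:
    """Union 3'-UTR of one gene with genomic<->sense-offset mapping."""

    def __init__(self, gene_id: str, intervals: Sequence[GenomicInterval],
                 genome: Mapping[str, str]):
        ivs = sorted(_merge(intervals), key=lambda iv: iv.start)
        self.gene_id = gene_id
        self.intervals = ivs
        self.chrom = ivs[0].chrom
        self.strand = ivs[0].strand
        self.annotation = UTRAnnotation(gene_id, gene_id, list(ivs))
        self.sequence = extract_utr_sequence(genome, self.annotation)
        self.length = len(self.sequence)
        # cumulative genomic-order offsets of each interval
        self._cum = np.concatenate([[0], np.cumsum([len(iv) for iv in ivs])])

    def sense_offset(self, pos0: int) -> int | None:
        """Sense-strand 3'-UTR offset of a genomic 0-based position."""
        for k, iv in enumerate(self.intervals):
            if iv.contains(pos0):
                plus = int(self._cum[k]) + (pos0 - iv.start)
                return plus if self.strand == "+" else self.length - 1 - plus
        return None

    def genomic_pos0(self, offset: int) -> int:
        """Inverse of :meth:`sense_offset`."""
        if not (0 <= offset < self.length):
            raise ValueError("offset outside UTR")
        plus = offset if self.strand == "+" else self.length - 1 - offset
        k = int(np.searchsorted(self._cum, plus, side="right")) - 1
        return self.intervals[k].start + (plus - int(self._cum[k]))


def _merge(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(intervals, key=lambda iv: iv.start)
    if not ivs:
        raise ValueError("empty interval list")
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom != last.chrom or iv.strand != last.strand:
            raise ValueError("gene intervals span chroms/strands")
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def build_gene_utrs(utrs: Iterable[UTRAnnotation],
                    genome: Mapping[str, str]) -> dict[str, GeneUTR]:
    """Group transcript annotations by gene and take the interval union."""
    by_gene: dict[str, list[GenomicInterval]] = {}
    for annot in utrs:
        by_gene.setdefault(annot.gene_id, []).extend(annot.utr3_intervals)
    return {g: GeneUTR(g, ivs, genome) for g, ivs in by_gene.items()}


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------

class PiSNVCaller:
    """Classifies somatic SNVs against a fixed reference study.

    Builds the gene-level UTR sequences, PWM log-odds tables and peak index
    once, then scores any number of variants.
    """

    def __init__(self, genome: Mapping[str, str], utrs: Iterable[UTRAnnotation],
                 pwms: Sequence[PWMRecord], peaks: Iterable[ClipPeak],
                 params: CallerParams | None = None):
        self.genome = genome
        self.params = params or CallerParams()
        self.pwms = list(pwms)
        # per-PWM log-odds tables and hit floors, computed once
        self._tables = []
        for pwm in self.pwms:
            lo = pwm_log_odds_matrix(pwm, self.params.background)
            floor = (self.params.motif_score_min
                     if self.params.motif_score_min is not None
                     else self.params.motif_score_frac * float(lo.max(axis=1).sum()))
            self._tables.append((pwm.rbp_name, lo, floor))
        self.genes = build_gene_utrs(utrs, genome)
        self._seq_idx = {g: encode_rna(gene.sequence)
                         for g, gene in self.genes.items()}
        self.peak_index = build_peak_index(peaks)
        self._utr_tree: dict[str, IntervalTree] = {}
        for gene in self.genes.values():
            for iv in gene.intervals:
                self._utr_tree.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, gene.gene_id
                )

    # -- lookups ------------------------------------------------------------

    def genes_at(self, variant: Variant) -> list[str]:
        tree = self._utr_tree.get(variant.chrom)
        if tree is None:
            return []
        return sorted({hit.data for hit in tree.at(variant.pos0)})

    def in_utr3(self, variant: Variant) -> bool:
        return bool(self.genes_at(variant))

    # -- classification -----------------------------------------------------

    def call_variant(self, variant: Variant) -> list[PiSNVCall]:
        """One PiSNVCall per gene whose 3'-UTR hosts the variant.

        A variant outside every 3'-UTR yields a single negative call with an
        empty gene id.
        """
        gene_ids = self.genes_at(variant)
        if not gene_ids:
            return [PiSNVCall(variant, "", False, [])]
        return [self._call_in_gene(variant, self.genes[g]) for g in gene_ids]

    def call(self, variants: Iterable[Variant]) -> list[PiSNVCall]:
        out: list[PiSNVCall] = []
        for v in variants:
            out.extend(self.call_variant(v))
        return out

    def _call_in_gene(self, variant: Variant, gene: GeneUTR) -> PiSNVCall:
        p = self.params
        genome_base = self.genome[variant.chrom][variant.pos0]
        if genome_base != variant.ref:
            raise ValueError(
                f"ref mismatch for {variant.key} (sample {variant.sample_id!r}): "
                f"genome has {genome_base!r}"
            )
        offset = gene.sense_offset(variant.pos0)
        assert offset is not None
        if gene.strand == "+":
            alt_rna = transcribe(variant.alt)
        else:
            alt_rna = transcribe(_DNA_COMP[variant.alt])

        seq_idx = self._seq_idx[gene.gene_id]
        alt_idx = _RNA_INDEX[alt_rna]
        best_delta: dict[str, float] = {}
        ref_idx = int(seq_idx[offset])
        for rbp, lo, floor in self._tables:
            L = lo.shape[0]
            first = max(0, offset - L + 1)
            last = min(offset, gene.length - L)
            if last < first:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(
                seq_idx[first : last + L], L)
            scores = lo[np.arange(L)[None, :], windows].sum(axis=1)
            for k in np.nonzero(scores >= floor)[0]:
                j = offset - (first + int(k))
                delta = float(lo[j, alt_idx] - lo[j, ref_idx])
                d = best_delta.get(rbp)
                if d is None or delta < d:
                    best_delta[rbp] = delta
        clip_rbps = set(clip_overlap(variant, self.peak_index, gene.strand))

        if p.require_clip:
            candidates = set(best_delta) & clip_rbps
        else:
            candidates = set(best_delta) | clip_rbps
        if not candidates:
            return PiSNVCall(variant, gene.gene_id, False, [])

        motif_ok = {r for r in candidates
                    if best_delta.get(r, 0.0) <= p.delta_threshold}
        structure: StructureAssessment | None = None
        # the structure arm only matters for candidates the delta did not settle
        if candidates - motif_ok:
            structure = structure_distance(
                gene.sequence, offset, alt_rna, p.fold_window_radius
            )
        struct_ok = (structure is not None
                     and structure.distance >= p.structure_threshold)

        supporting = []
        for r in sorted(candidates):
            if r in motif_ok or struct_ok:
                supporting.append(RBPEvidence(
                    rbp_name=r,
                    motif_disrupted=r in motif_ok,
                    clip_overlap=r in clip_rbps,
                    delta=best_delta.get(r, math.nan),
                    structure_distance=(structure.distance if structure is not None
                                        else math.nan),
                ))
        return PiSNVCall(variant, gene.gene_id, bool(supporting), supporting,
                         structure)


def call_pisnvs(variants: Iterable[Variant], utrs: Iterable[UTRAnnotation],
                genome: Mapping[str, str], pwms: Sequence[PWMRecord],
                peaks: Iterable[ClipPeak],
                params: CallerParams | None = None) -> list[PiSNVCall]:
    """Functional entry point: build a :class:`PiSNVCaller` and classify."""
    return PiSNVCaller(genome, utrs, pwms, peaks, params).call(variants)
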