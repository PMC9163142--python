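"""Readers, writers and domain types for every external file format.

Coordinate conventions are fixed here and nowhere else:

* BED is 0-based half-open and is kept verbatim as the internal canonical
  form (:class:`GenomicInterval`).
* VCF positions are 1-based; :class:`Variant` stores the 1-based position
  (``pos``) and exposes the 0-based one as ``pos0``.  The conversion happens
  exactly once, at parse time.
* Sequences handed to downstream scoring are mature-sense RNA (5'->3',
  ``U`` not ``T``); minus-strand annotations are reverse-complemented by
  :func:`extract_utr_sequence`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

BASES = "ACGT"
RNA_BASES = "ACGU"
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

#: row order of every PWM matrix in the package
PWM_ALPHABET = RNA_BASES


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase A/C/G/T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (T becomes U)."""
    return seq.replace("T", "U")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class Variant:
    """A somatic single-nucleotide variant (1-based position, as in VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class UTRAnnotation:
    """Strand-aware 3'-UTR intervals of one transcript (or gene-level union)."""

    transcript_id: str
    gene_id: str
    utr3_intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        ivs = sorted(self.utr3_intervals, key=lambda iv: iv.start)
        strands = {iv.strand for iv in ivs}
        if len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: intervals on mixed strands")
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping intervals")
        self.utr3_intervals = ivs

    @property
    def strand(self) -> str:
        return self.utr3_intervals[0].strand

    @property
    def chrom(self) -> str:
        return self.utr3_intervals[0].chrom

    @property
    def utr3_length(self) -> int:
        return sum(len(iv) for iv in self.utr3_intervals)


@dataclass
class PWMRecord:
    """An RBP binding motif as a position probability matrix over A/C/G/U.

    ``matrix`` has shape (L, 4) with columns in :data:`PWM_ALPHABET` order and
    each row summing to one.
    """

    rbp_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.rbp_name}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"{self.rbp_name}: motif length must be >= 4")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.rbp_name}: negative probabilities")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"{self.rbp_name}: positions do not sum to 1: {sums}")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        """Most probable base at each position, as RNA."""
        return "".join(PWM_ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class ClipPeak:
    """One CLIP-seq binding interval of a named RBP."""

    interval: GenomicInterval
    rbp_name: str
    score: float = 0.0


@dataclass
class SiteSet:
    """A class of regulatory sites (m6A / APA / miRNA binding / other)."""

    class_name: str
    intervals: list[GenomicInterval]


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's overall-survival record with Cox covariates."""

    sample_id: str
    os_time: float
    os_event: int
    age: float
    sex: str
    stage: str

    def __post_init__(self) -> None:
        if self.os_time <= 0:
            raise ValueError(f"{self.sample_id}: os_time must be > 0")
        if self.os_event not in (0, 1):
            raise ValueError(f"{self.sample_id}: os_event must be 0/1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of uppercase DNA strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_utr_sequence(genome: Mapping[str, str], annot: UTRAnnotation) -> str:
    """Mature-sense RNA sequence (5'->3') of a 3'-UTR annotation.

    Intervals are concatenated in transcription order; minus-strand
    annotations are reverse-complemented before transcription.
    """
    contig = genome.get(annot.chrom)
    if contig is None:
        raise KeyError(f"contig {annot.chrom!r} not in genome")
    parts = []
    for iv in annot.utr3_intervals:
        if iv.end > len(contig):
            raise ValueError(
                f"{annot.transcript_id}: interval {iv.chrom}:{iv.start}-{iv.end} "
                f"beyond contig end {len(contig)}"
            )
        parts.append(contig[iv.start : iv.end])
    dna = "".join(parts)
    if annot.strand == "-":
        dna = reverse_complement(dna)
    return transcribe(dna)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample: str | None = None) -> list[Variant]:
    """Read biallelic SNVs from a VCF.

    Indels/MNVs are skipped (logged count); multi-allelic records are
    rejected.  ``sample`` overrides the genotype-column sample id; without it
    a single-sample VCF uses its one sample and a sample-less VCF yields
    variants with an empty ``sample_id``.
    """
    variants: list[Variant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if sample is None and len(header_samples) == 1:
            sample = header_samples[0]
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split upstream"
                )
            if not alts:
                n_skipped += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                n_skipped += 1
                continue
            variants.append(
                Variant(rec.chrom, rec.pos, ref, alt, sample_id=sample or "")
            )
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV records", path, n_skipped)
    return variants


def write_vcf(variants: Sequence[Variant], path: str | Path,
              contigs: Mapping[str, int], sample_id: str) -> None:
    """Write SNVs as a minimal single-sample VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t0/1\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_bed6(line: str, lineno: int, path: str) -> tuple[GenomicInterval, str, float]:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise ValueError(f"{path}:{lineno}: need >= 6 BED fields, got {len(fields)}")
    chrom, start, end, name, score, strand = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start_i >= end_i:
        raise ValueError(f"{path}:{lineno}: start >= end ({start_i} >= {end_i})")
    if strand not in ("+", "-"):
        raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
    try:
        score_f = float(score)
    except ValueError:
        score_f = 0.0
    return GenomicInterval(chrom, start_i, end_i, strand), name, score_f


def _iter_bed_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _expand_bed12(fields: list[str], lineno: int, path: str) -> list[GenomicInterval]:
    chrom, start = fields[0], int(fields[1])
    strand = fields[5]
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"{path}:{lineno}: blockCount mismatch")
    return [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(starts, sizes)
    ]


def read_utr_bed(path: str | Path,
                 gene_map: Mapping[str, str] | None = None) -> list[UTRAnnotation]:
    """Read per-transcript 3'-UTR intervals from BED6 (grouped by name) or BED12.

    ``gene_map`` maps transcript id -> gene id; without it the gene id
    defaults to the transcript id.
    """
    grouped: dict[str, list[GenomicInterval]] = {}
    for lineno, line in _iter_bed_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) >= 12:
            iv0, name, _ = _parse_bed6(line, lineno, str(path))
            ivs = _expand_bed12(fields, lineno, str(path))
        else:
            iv0, name, _ = _parse_bed6(line, lineno, str(path))
            ivs = [iv0]
        grouped.setdefault(name, []).extend(ivs)
    annots = []
    for tx, ivs in grouped.items():
        gene = gene_map.get(tx, tx) if gene_map else tx
        annots.append(UTRAnnotation(tx, gene, ivs))
    return annots


def read_peaks_bed(path: str | Path) -> list[ClipPeak]:
    """Read CLIP peaks from BED6; the name field carries the RBP name."""
    peaks = []
    for lineno, line in _iter_bed_lines(path):
        iv, name, score = _parse_bed6(line, lineno, str(path))
        peaks.append(ClipPeak(iv, name, score))
    return peaks


def read_sites_bed(path: str | Path, class_name: str) -> SiteSet:
    """Read one regulatory-site class (m6A / APA / miRNA / other) from BED6."""
    ivs = [_parse_bed6(line, lineno, str(path))[0]
           for lineno, line in _iter_bed_lines(path)]
    return SiteSet(class_name, ivs)


def read_bed(path: str | Path, kind: str, **kwargs):
    """Dispatch BED reading by payload kind: ``utr``, ``peak`` or ``sites``."""
    if kind == "utr":
        return read_utr_bed(path, kwargs.get("gene_map"))
    if kind == "peak":
        return read_peaks_bed(path)
    if kind == "sites":
        return read_sites_bed(path, kwargs.get("class_name", "other"))
    raise ValueError(f"unknown BED kind {kind!r}")


def write_bed(records: Iterable[tuple[GenomicInterval, str, float]],
              path: str | Path) -> None:
    """Write (interval, name, score) triples as canonical BED6."""
    with open(path, "w") as fh:
        for iv, name, score in records:
            score_s = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score_s}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# PWMs (MEME-motif-style text)
# ---------------------------------------------------------------------------

PWM_PSEUDOCOUNT = 1e-3


def read_pwms(path: str | Path, pseudocount: float = PWM_PSEUDOCOUNT) -> list[PWMRecord]:
    """Read MEME-motif-style letter-probability matrices.

    Zero probabilities are floored at ``pseudocount`` and each position is
    renormalized, so log-odds scores downstream are always finite.
    """
    pwms: list[PWMRecord] = []
    name: str | None = None
    rows: list[list[float]] = []
    in_matrix = False

    def _flush() -> None:
        nonlocal name, rows, in_matrix
        if name is None:
            return
        if not rows:
            raise ValueError(f"motif {name}: no probability rows")
        mat = np.array(rows, dtype=float)
        sums = mat.sum(axis=1)
        if (sums <= 0).any():
            bad = int(np.nonzero(sums <= 0)[0][0])
            raise ValueError(f"motif {name}: position {bad} sums to 0")
        mat = mat / sums[:, None]
        mat = np.maximum(mat, pseudocount)
        mat = mat / mat.sum(axis=1, keepdims=True)
        pwms.append(PWMRecord(name, mat))
        name, rows, in_matrix = None, [], False

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("MOTIF"):
                _flush()
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"MOTIF line without a name: {line!r}")
                name = parts[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line and name is not None:
                parts = line.split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                        continue
                    except ValueError:
                        pass
                in_matrix = False
        _flush()
    return pwms


def write_pwms(pwms: Sequence[PWMRecord], path: str | Path) -> None:
    """Write PWMs in minimal MEME-motif text (alphabet ACGU)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.rbp_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                "nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_gene_map(path: str | Path) -> dict[str, str]:
    """Transcript->gene TSV with columns ``transcript_id`` and ``gene_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("transcript_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"gene map {path}: missing column {col!r}")
    return dict(zip(df["transcript_id"], df["gene_id"]))


CLINICAL_COLUMNS = ["sample_id", "os_time", "os_event", "age", "sex", "stage"]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV -> validated DataFrame (one row per patient)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path}: missing columns {missing}")
    # row-wise validation through the dataclass invariants
    for row in df.itertuples(index=False):
        ClinicalRecord(str(row.sample_id), float(row.os_time), int(row.os_event),
                       float(row.age), str(row.sex), str(row.stage))
    return df
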