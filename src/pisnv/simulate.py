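"""Truth-labelled synthetic study generator.

Emulates the statistical structure of a pan-cancer 3'-UTR mutation study at
desk scale: a random reference with per-gene 3'-UTRs, consensus motif
instances of a panel of RBPs planted into the sequence, CLIP peaks covering
most instances (plus decoys), a tumor and a control cohort whose somatic
SNVs are a mixture of uniform background and consensus-breaking disruptors,
an exponential survival model with a planted hazard ratio for the
high-piSNV-ratio group, and regulatory site sets (m6A / APA / miRNA).

Disruption is planted at the sequence level — a consensus base of a planted
motif instance is mutated away — so the downstream caller is tested
end-to-end rather than against its own labels.  Background SNVs are placed
outside motif-instance footprints, which keeps the per-variant truth exact.
Everything is deterministic given ``SimulationConfig.seed``; per-stage
substreams are spawned from one master ``SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BASES,
    ClipPeak,
    GenomicInterval,
    PWMRecord,
    SiteSet,
    UTRAnnotation,
    Variant,
    reverse_complement,
    write_bed,
    write_fasta,
    write_pwms,
    write_vcf,
)

logger = logging.getLogger(__name__)

_DNA_OF_RNA = str.maketrans("ACGU", "ACGT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 20
    utr_len_mean: int = 1000          # bp, Poisson mean (truncated >= min)
    min_utr_len: int = 200
    n_tumor_samples: int = 50
    n_control_samples: int = 50
    background_mut_rate: float = 1.0  # SNVs per kb of 3'-UTR per sample
    disrupt_fraction_tumor: float = 0.3
    disrupt_fraction_control: float = 0.1
    n_rbps: int = 20
    motif_len_min: int = 6
    motif_len_max: int = 8
    consensus_prob: float = 0.97      # PWM weight on the consensus base
    max_instances_per_utr: int = 3
    peak_prob: float = 0.8            # CLIP peak emitted per instance
    peak_pad: int = 10                # peak extends this far beyond the motif
    decoy_peak_rate: float = 0.1      # decoy peaks per kb of 3'-UTR
    enriched_rbp: str = "PTBP1"
    enrichment_factor: float = 5.0
    min_enriched_instances: int = 3  # guarantees the planted effect exists
    hazard_ratio: float = 2.5         # high- vs low-ratio group
    baseline_hazard: float = 1 / 1500  # events per day
    censor_rate: float = 0.3
    site_coverage: float = 0.1        # fraction of UTR bases per site class
    site_len: int = 20
    genes_per_contig: int = 50
    intergenic_gap: int = 100

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_tumor_samples < 1 or self.n_control_samples < 0:
            raise ValueError("need n_tumor_samples >= 1 and "
                             "n_control_samples >= 0")
        for name in ("disrupt_fraction_tumor", "disrupt_fraction_control",
                     "peak_prob", "censor_rate", "site_coverage"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_mut_rate < 0 or self.decoy_peak_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be > 0")


@dataclass(frozen=True)
class MotifInstance:
    """A consensus motif occurrence planted into a gene's 3'-UTR."""

    gene_id: str
    rbp_name: str
    utr_offset: int          # sense-strand offset of the instance start
    consensus: str           # RNA
    interval: GenomicInterval  # genomic footprint


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes, in memory, plus the truth tables."""

    config: SimulationConfig
    genome: dict[str, str]
    utrs: list[UTRAnnotation]
    gene_map: dict[str, str]
    pwms: list[PWMRecord]
    clip_peaks: list[ClipPeak]
    motif_instances: list[MotifInstance]
    tumor_variants: dict[str, list[Variant]]
    control_variants: dict[str, list[Variant]]
    truth_variants: pd.DataFrame   # sample, cohort, key, is_planted, target_rbp
    truth_samples: pd.DataFrame    # sample, cohort, n_snv, n_planted, true_ratio
    clinical: pd.DataFrame
    site_sets: list[SiteSet]


# ---------------------------------------------------------------------------
# PWM panel
# ---------------------------------------------------------------------------

def make_pwm(rbp_name: str, consensus: str, consensus_prob: float = 0.97) -> PWMRecord:
    """PWM putting ``consensus_prob`` on the consensus base at each position."""
    off = (1.0 - consensus_prob) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        mat[i, "ACGU".index(b)] = consensus_prob
    return PWMRecord(rbp_name, mat)


def make_pwm_panel(cfg: SimulationConfig, rng: np.random.Generator) -> list[PWMRecord]:
    """A panel of ``n_rbps`` sharp consensus PWMs; PTBP1 (CUCUCU) is first."""
    pwms = [make_pwm("PTBP1", "CUCUCU", cfg.consensus_prob)]
    seen = {"CUCUCU"}
    while len(pwms) < cfg.n_rbps:
        L = int(rng.integers(cfg.motif_len_min, cfg.motif_len_max + 1))
        cons = "".join(rng.choice(list("ACGU"), size=L))
        if cons in seen:
            continue
        seen.add(cons)
        pwms.append(make_pwm(f"RBP{len(pwms):02d}", cons, cfg.consensus_prob))
    return pwms


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[dict[str, str], list[UTRAnnotation], dict[str, str]]:
    """Random genome with one single-interval 3'-UTR per gene."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(1)[0])
    lengths = np.maximum(cfg.min_utr_len,
                         rng.poisson(cfg.utr_len_mean, size=cfg.n_genes))
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genome: dict[str, str] = {}
    utrs: list[UTRAnnotation] = []
    gene_map: dict[str, str] = {}
    contig_parts: list[str] = []
    cursor = cfg.intergenic_gap
    contig_idx = 1
    base_choices = np.array(list(BASES))

    def _close_contig() -> None:
        nonlocal contig_parts, cursor, contig_idx
        if contig_parts:
            genome[f"chr{contig_idx}"] = "".join(contig_parts) + \
                "".join(rng.choice(base_choices, size=cfg.intergenic_gap))
            contig_idx += 1
        contig_parts, cursor = [], cfg.intergenic_gap

    contig_parts.append("".join(rng.choice(base_choices, size=cfg.intergenic_gap)))
    for i in range(cfg.n_genes):
        if i > 0 and i % cfg.genes_per_contig == 0:
            _close_contig()
            contig_parts.append(
                "".join(rng.choice(base_choices, size=cfg.intergenic_gap)))
        L = int(lengths[i])
        seq = "".join(rng.choice(base_choices, size=L))
        chrom = f"chr{contig_idx}"
        iv = GenomicInterval(chrom, cursor, cursor + L, str(strands[i]))
        tx, gene = f"TX{i + 1:04d}", f"G{i + 1:04d}"
        utrs.append(UTRAnnotation(tx, gene, [iv]))
        gene_map[tx] = gene
        contig_parts.append(seq)
        contig_parts.append("".join(rng.choice(base_choices, size=cfg.intergenic_gap)))
        cursor += L + cfg.intergenic_gap
    _close_contig()
    return genome, utrs, gene_map


def _utr_interval(annot: UTRAnnotation) -> GenomicInterval:
    assert len(annot.utr3_intervals) == 1
    return annot.utr3_intervals[0]


def _genomic_span(annot: UTRAnnotation, offset: int, length: int) -> tuple[int, int]:
    """Genomic [start, end) of sense-offset window [offset, offset+length)."""
    iv = _utr_interval(annot)
    if iv.strand == "+":
        return iv.start + offset, iv.start + offset + length
    return iv.end - offset - length, iv.end - offset


def _genomic_pos0(annot: UTRAnnotation, offset: int) -> int:
    s, _ = _genomic_span(annot, offset, 1)
    return s


# ---------------------------------------------------------------------------
# motif instances and CLIP peaks
# ---------------------------------------------------------------------------

def plant_motifs_and_peaks(genome: dict[str, str], utrs: Sequence[UTRAnnotation],
                           pwms: Sequence[PWMRecord], cfg: SimulationConfig,
                           rng: np.random.Generator
                           ) -> tuple[dict[str, str], list[ClipPeak], list[MotifInstance]]:
    """Write consensus instances into the genome; emit covering + decoy peaks."""
    editable = {c: list(s) for c, s in genome.items()}
    instances: list[MotifInstance] = []
    peaks: list[ClipPeak] = []

    for annot in utrs:
        iv = _utr_interval(annot)
        utr_len = len(iv)
        k = int(rng.integers(0, cfg.max_instances_per_utr + 1))
        taken: list[tuple[int, int]] = []
        for _ in range(k):
            pwm = pwms[int(rng.integers(len(pwms)))]
            L = pwm.length
            if L > utr_len:
                continue
            for _try in range(50):
                off = int(rng.integers(0, utr_len - L + 1))
                if all(off + L <= a or off >= b for a, b in taken):
                    break
            else:
                continue
            taken.append((off, off + L))
            cons = pwm.consensus
            dna = cons.translate(_DNA_OF_RNA)
            gs, ge = _genomic_span(annot, off, L)
            planted = dna if iv.strand == "+" else reverse_complement(dna)
            editable[iv.chrom][gs:ge] = list(planted)
            inst_iv = GenomicInterval(iv.chrom, gs, ge, iv.strand)
            instances.append(MotifInstance(annot.gene_id, pwm.rbp_name, off,
                                           cons, inst_iv))
            if rng.random() < cfg.peak_prob:
                ps = max(iv.start, gs - cfg.peak_pad)
                pe = min(iv.end, ge + cfg.peak_pad)
                peaks.append(ClipPeak(GenomicInterval(iv.chrom, ps, pe, iv.strand),
                                      pwm.rbp_name, 1.0))

    # the enriched RBP must actually occur for its planted effect to exist;
    # top up its instance count in randomly chosen UTRs if the uniform
    # draw left it under-represented
    enriched = [p for p in pwms if p.rbp_name == cfg.enriched_rbp]
    if enriched:
        pwm = enriched[0]
        n_have = sum(1 for i in instances if i.rbp_name == cfg.enriched_rbp)
        guard = 0
        while n_have < cfg.min_enriched_instances and guard < 200:
            guard += 1
            annot = utrs[int(rng.integers(len(utrs)))]
            iv = _utr_interval(annot)
            L = pwm.length
            if L > len(iv):
                continue
            occupied = [(i.utr_offset, i.utr_offset + len(i.consensus))
                        for i in instances if i.gene_id == annot.gene_id]
            off = int(rng.integers(0, len(iv) - L + 1))
            if any(off + L > a and off < b for a, b in occupied):
                continue
            cons = pwm.consensus
            gs, ge = _genomic_span(annot, off, L)
            planted = (cons.translate(_DNA_OF_RNA) if iv.strand == "+"
                       else reverse_complement(cons.translate(_DNA_OF_RNA)))
            editable[iv.chrom][gs:ge] = list(planted)
            instances.append(MotifInstance(annot.gene_id, pwm.rbp_name, off,
                                           cons,
                                           GenomicInterval(iv.chrom, gs, ge,
                                                           iv.strand)))
            n_have += 1
            if rng.random() < cfg.peak_prob:
                ps = max(iv.start, gs - cfg.peak_pad)
                pe = min(iv.end, ge + cfg.peak_pad)
                peaks.append(ClipPeak(GenomicInterval(iv.chrom, ps, pe,
                                                      iv.strand),
                                      pwm.rbp_name, 1.0))

    # decoy peaks at motif-free positions
    total_kb = sum(len(_utr_interval(a)) for a in utrs) / 1000.0
    n_decoys = int(rng.poisson(cfg.decoy_peak_rate * total_kb))
    weights = np.array([len(_utr_interval(a)) for a in utrs], dtype=float)
    weights /= weights.sum()
    footprint = {a.gene_id: [(i.interval.start, i.interval.end)
                             for i in instances if i.gene_id == a.gene_id]
                 for a in utrs}
    width = cfg.motif_len_min + 2 * cfg.peak_pad
    rbp_names = [p.rbp_name for p in pwms]
    for _ in range(n_decoys):
        annot = utrs[int(rng.choice(len(utrs), p=weights))]
        iv = _utr_interval(annot)
        if len(iv) <= width:
            continue
        for _try in range(50):
            gs = int(rng.integers(iv.start, iv.end - width))
            ge = gs + width
            if all(ge <= a or gs >= b for a, b in footprint[annot.gene_id]):
                peaks.append(ClipPeak(GenomicInterval(iv.chrom, gs, ge, iv.strand),
                                      rbp_names[int(rng.integers(len(rbp_names)))],
                                      0.5))
                break

    return {c: "".join(s) for c, s in editable.items()}, peaks, instances


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _disruptor_variant(inst: MotifInstance, strand: str,
                       rng: np.random.Generator, sample_id: str) -> Variant:
    """Mutate a consensus base of an instance away from consensus.

    Internal C -> U is preferred when the consensus allows it; otherwise a
    random position is mutated to a random non-consensus base.
    """
    cons = inst.consensus
    internal_c = [j for j in range(1, len(cons) - 1) if cons[j] == "C"]
    if internal_c:
        j = int(rng.choice(internal_c))
        alt_rna = "U"
    else:
        j = int(rng.integers(len(cons)))
        others = [b for b in "ACGU" if b != cons[j]]
        alt_rna = str(rng.choice(others))
    ref_dna = cons[j].translate(_DNA_OF_RNA)
    alt_dna = alt_rna.translate(_DNA_OF_RNA)
    if strand == "+":
        pos0 = inst.interval.start + j
    else:
        pos0 = inst.interval.end - 1 - j
        ref_dna, alt_dna = _COMP[ref_dna], _COMP[alt_dna]
    return Variant(inst.interval.chrom, pos0 + 1, ref_dna, alt_dna, sample_id)


def simulate_cohort(genome: dict[str, str], utrs: Sequence[UTRAnnotation],
                    instances: Sequence[MotifInstance], cfg: SimulationConfig,
                    cohort: str, rng: np.random.Generator
                    ) -> tuple[dict[str, list[Variant]], pd.DataFrame]:
    """Per-sample SNVs: uniform background plus planted consensus disruptors."""
    if cohort not in ("tumor", "control"):
        raise ValueError("cohort must be 'tumor' or 'control'")
    n_samples = cfg.n_tumor_samples if cohort == "tumor" else cfg.n_control_samples
    frac = (cfg.disrupt_fraction_tumor if cohort == "tumor"
            else cfg.disrupt_fraction_control)
    prefix = "TUMOR" if cohort == "tumor" else "CTRL"

    strand_of = {a.gene_id: _utr_interval(a).strand for a in utrs}
    # genomic background positions outside all instance footprints
    bg_pos: list[tuple[str, int]] = []
    for a in utrs:
        iv = _utr_interval(a)
        blocked = np.zeros(len(iv), dtype=bool)
        for inst in instances:
            if inst.gene_id == a.gene_id:
                blocked[inst.interval.start - iv.start:
                        inst.interval.end - iv.start] = True
        for off in np.nonzero(~blocked)[0]:
            bg_pos.append((iv.chrom, iv.start + int(off)))
    total_kb = sum(len(_utr_interval(a)) for a in utrs) / 1000.0

    weights = np.array(
        [cfg.enrichment_factor if (cohort == "tumor"
                                   and i.rbp_name == cfg.enriched_rbp) else 1.0
         for i in instances], dtype=float)
    weights = weights / weights.sum() if len(instances) else weights

    cohort_variants: dict[str, list[Variant]] = {}
    truth_rows = []
    sample_rows = []
    for s in range(n_samples):
        sid = f"{prefix}_{s + 1:03d}"
        n_total = int(rng.poisson(cfg.background_mut_rate * total_kb))
        n_disrupt = int(rng.binomial(n_total, frac)) if n_total else 0
        variants: list[Variant] = []
        used: set[tuple[str, int]] = set()

        placed = 0
        attempts = 0
        while placed < n_disrupt and len(instances) and attempts < 20 * n_disrupt + 50:
            attempts += 1
            inst = instances[int(rng.choice(len(instances), p=weights))]
            v = _disruptor_variant(inst, strand_of[inst.gene_id], rng, sid)
            if (v.chrom, v.pos) in used:
                continue
            used.add((v.chrom, v.pos))
            assert genome[v.chrom][v.pos0] == v.ref
            variants.append(v)
            truth_rows.append((sid, cohort, v.chrom, v.pos, v.ref, v.alt,
                               True, inst.rbp_name))
            placed += 1
        if placed < n_disrupt:
            logger.warning("%s: requested %d disruptors, placed %d (saturated)",
                           sid, n_disrupt, placed)

        n_bg = n_total - placed
        idx = rng.choice(len(bg_pos), size=min(n_bg, len(bg_pos)), replace=False)
        for i in idx:
            chrom, pos0 = bg_pos[int(i)]
            if (chrom, pos0 + 1) in used:
                continue
            used.add((chrom, pos0 + 1))
            ref = genome[chrom][pos0]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            v = Variant(chrom, pos0 + 1, ref, alt, sid)
            variants.append(v)
            truth_rows.append((sid, cohort, v.chrom, v.pos, v.ref, v.alt,
                               False, ""))
        cohort_variants[sid] = variants
        n_planted = sum(1 for r in truth_rows if r[0] == sid and r[6])
        n_snv = len(variants)
        sample_rows.append((sid, cohort, n_snv, n_planted,
                            n_planted / n_snv if n_snv else 0.0))

    truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "cohort", "chrom", "pos", "ref", "alt",
        "is_planted_disruptor", "target_rbp"])
    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "cohort", "n_snv", "n_planted", "true_ratio"])
    return cohort_variants, truth, samples


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def simulate_clinical(true_ratios: Mapping[str, float], cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential survival with a planted binary effect of the piSNV ratio.

    Hazard is ``baseline_hazard * hazard_ratio**1[ratio > median]``; an
    independent exponential censoring time is tuned so each subject is
    censored with probability ``censor_rate``.  Age/sex/stage are drawn
    independently of the ratio, so the planted effect survives multivariate
    adjustment.
    """
    sids = list(true_ratios)
    ratios = np.array([true_ratios[s] for s in sids], dtype=float)
    high = ratios > np.median(ratios)
    hazard = cfg.baseline_hazard * np.where(high, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        c_hazard = hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_censor = rng.exponential(1.0 / c_hazard)
    else:
        t_censor = np.full_like(t_event, np.inf)
    os_time = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)
    age = np.clip(rng.normal(62, 10, size=len(sids)), 30, 90)
    sex = rng.choice(["male", "female"], size=len(sids))
    stage = rng.choice(["I", "II", "III", "IV"], size=len(sids),
                       p=[0.2, 0.3, 0.3, 0.2])
    return pd.DataFrame({
        "sample_id": sids,
        "os_time": np.maximum(os_time, 1e-6),
        "os_event": os_event,
        "age": np.round(age, 1),
        "sex": sex,
        "stage": stage,
    })


# ---------------------------------------------------------------------------
# regulatory site sets
# ---------------------------------------------------------------------------

def simulate_site_sets(utrs: Sequence[UTRAnnotation], cfg: SimulationConfig,
                       rng: np.random.Generator) -> list[SiteSet]:
    """Random site intervals covering ~``site_coverage`` of UTR bases per class."""
    out = []
    for cls in ("m6A", "APA", "miRNA"):
        ivs: list[GenomicInterval] = []
        for a in utrs:
            iv = _utr_interval(a)
            n = int(rng.poisson(cfg.site_coverage * len(iv) / cfg.site_len))
            for _ in range(n):
                if len(iv) <= cfg.site_len:
                    continue
                s = int(rng.integers(iv.start, iv.end - cfg.site_len))
                ivs.append(GenomicInterval(iv.chrom, s, s + cfg.site_len, iv.strand))
        out.append(SiteSet(cls, sorted(ivs, key=lambda i: (i.chrom, i.start))))
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate the complete synthetic study for one seed."""
    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rngs = [np.random.default_rng(s) for s in streams]
    genome0, utrs, gene_map = simulate_reference(cfg, rngs[0])
    pwms = make_pwm_panel(cfg, rngs[1])
    genome, peaks, instances = plant_motifs_and_peaks(genome0, utrs, pwms, cfg,
                                                      rngs[2])
    tumor, truth_t, samples_t = simulate_cohort(genome, utrs, instances, cfg,
                                                "tumor", rngs[3])
    control, truth_c, samples_c = simulate_cohort(genome, utrs, instances, cfg,
                                                  "control", rngs[4])
    truth_variants = pd.concat([truth_t, truth_c], ignore_index=True)
    truth_samples = pd.concat([samples_t, samples_c], ignore_index=True)
    ratios = dict(zip(samples_t["sample_id"], samples_t["true_ratio"]))
    clinical = simulate_clinical(ratios, cfg, rngs[5])
    site_sets = simulate_site_sets(utrs, cfg, rngs[6])
    return SyntheticStudy(cfg, genome, utrs, gene_map, pwms, peaks, instances,
                          tumor, control, truth_variants, truth_samples,
                          clinical, site_sets)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write every file the pipeline consumes, plus truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, out / "genome.fa")
    write_bed(((a.utr3_intervals[0], a.transcript_id, 0.0) for a in study.utrs),
              out / "utr3.bed")
    pd.DataFrame(sorted(study.gene_map.items()),
                 columns=["transcript_id", "gene_id"]).to_csv(
        out / "gene_map.tsv", sep="\t", index=False)
    write_pwms(study.pwms, out / "pwms.meme")
    write_bed(((p.interval, p.rbp_name, p.score) for p in study.clip_peaks),
              out / "clip_peaks.bed")
    contigs = {c: len(s) for c, s in study.genome.items()}
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sid, variants in {**study.tumor_variants, **study.control_variants}.items():
        write_vcf(variants, vcf_dir / f"{sid}.vcf", contigs, sid)
    study.truth_variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    study.truth_samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    study.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    for ss in study.site_sets:
        write_bed(((iv, ss.class_name, 0.0) for iv in ss.intervals),
                  out / f"sites_{ss.class_name}.bed")
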