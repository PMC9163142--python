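"""End-to-end orchestration: call -> cohort stats -> survival.

Works on in-memory objects (a :class:`~pisnv.simulate.SyntheticStudy` or
anything shaped like one) so the CLI, the tests and the acceptance script
share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import stats as st
from . import survival as sv
from .caller import CallerParams, PiSNVCall, PiSNVCaller
from .io import (
    ClipPeak,
    PWMRecord,
    SiteSet,
    UTRAnnotation,
    Variant,
    read_clinical,
    read_fasta,
    read_gene_map,
    read_peaks_bed,
    read_pwms,
    read_sites_bed,
    read_utr_bed,
    read_vcf,
)


@dataclass
class StudyInputs:
    """Everything the pipeline consumes, already parsed."""

    genome: Mapping[str, str]
    utrs: list[UTRAnnotation]
    pwms: list[PWMRecord]
    peaks: list[ClipPeak]
    tumor_variants: Mapping[str, Sequence[Variant]]
    control_variants: Mapping[str, Sequence[Variant]] | None = None
    clinical: pd.DataFrame | None = None
    site_sets: list[SiteSet] = field(default_factory=list)


def load_study_dir(study_dir: str | Path) -> StudyInputs:
    """Load the file layout written by ``pisnv simulate`` / ``write_study``."""
    d = Path(study_dir)
    gene_map = read_gene_map(d / "gene_map.tsv")
    genome = read_fasta(d / "genome.fa")
    utrs = read_utr_bed(d / "utr3.bed", gene_map)
    pwms = read_pwms(d / "pwms.meme")
    peaks = read_peaks_bed(d / "clip_peaks.bed")
    tumor: dict[str, list[Variant]] = {}
    control: dict[str, list[Variant]] = {}
    for vcf in sorted((d / "vcf").glob("*.vcf")):
        sid = vcf.stem
        target = control if sid.startswith("CTRL") else tumor
        target[sid] = read_vcf(vcf, sample=sid)
    clinical = None
    if (d / "clinical.tsv").exists():
        clinical = read_clinical(d / "clinical.tsv")
    site_sets = [read_sites_bed(p, p.stem.replace("sites_", ""))
                 for p in sorted(d.glob("sites_*.bed"))]
    return StudyInputs(genome, utrs, pwms, peaks, tumor, control, clinical,
                       site_sets)


def inputs_from_study(study) -> StudyInputs:
    """Adapt an in-memory :class:`~pisnv.simulate.SyntheticStudy`."""
    return StudyInputs(study.genome, study.utrs, study.pwms, study.clip_peaks,
                       study.tumor_variants, study.control_variants,
                       study.clinical, study.site_sets)


@dataclass
class PipelineResult:
    """All tables the pipeline produces for one study."""

    calls_tumor: list[PiSNVCall]
    calls_control: list[PiSNVCall]
    profiles_tumor: list[st.SampleProfile]
    profiles_control: list[st.SampleProfile]
    ratio_test: tuple[float, float] | None  # (W, p) tumor vs control
    enrichment: list[st.EnrichmentResult]
    recurrence: list[st.GeneRecurrence]
    overlap: list[st.SiteOverlapSummary]
    cutpoint: sv.CutpointResult | None
    km_high: sv.KMCurve | None
    km_low: sv.KMCurve | None
    cox: sv.CoxResult | None


def run_pipeline(inputs: StudyInputs, params: CallerParams | None = None,
                 alpha: float = 0.05, minprop: float = 0.1,
                 continuous: bool = False) -> PipelineResult:
    """Run caller, cohort statistics and survival on parsed inputs."""
    params = params or CallerParams()
    caller = PiSNVCaller(inputs.genome, inputs.utrs, inputs.pwms, inputs.peaks,
                         params)
    calls_tumor: list[PiSNVCall] = []
    for sid in sorted(inputs.tumor_variants):
        calls_tumor.extend(caller.call(inputs.tumor_variants[sid]))
    calls_control: list[PiSNVCall] = []
    if inputs.control_variants:
        for sid in sorted(inputs.control_variants):
            calls_control.extend(caller.call(inputs.control_variants[sid]))

    profiles_t = st.sample_profiles(calls_tumor)
    profiles_c = st.sample_profiles(calls_control) if calls_control else []
    ratio_test = None
    rt = [p.ratio for p in profiles_t if not p.flagged]
    rc = [p.ratio for p in profiles_c if not p.flagged]
    if rt and rc:
        ratio_test = st.wilcoxon_rank_sum(rt, rc)

    site_map = st.build_rbp_site_map(caller)
    enrichment = st.rbp_enrichment(calls_tumor, site_map, alpha=alpha)
    recurrence = st.gene_recurrence(calls_tumor,
                                    st.gene_utr_lengths(inputs.utrs))
    overlap = st.site_overlap(calls_tumor, inputs.site_sets)

    cutpoint = km_high = km_low = cox = None
    if inputs.clinical is not None and len(profiles_t) >= 4:
        ratios = {p.sample_id: p.ratio for p in profiles_t}
        clin = inputs.clinical[inputs.clinical["sample_id"].isin(ratios)]
        vals = clin["sample_id"].map(ratios).to_numpy()
        times = clin["os_time"].to_numpy()
        events = clin["os_event"].to_numpy()
        try:
            cutpoint = sv.optimal_cutpoint(vals, times, events, minprop)
        except ValueError:
            cutpoint = None
        if cutpoint is not None:
            high = vals > cutpoint.cutpoint
            km_high = sv.km_estimate(times[high], events[high])
            km_low = sv.km_estimate(times[~high], events[~high])
            design = sv.clinical_design(clin, ratios,
                                        cutpoint=cutpoint.cutpoint,
                                        continuous=continuous)
            try:
                cox = sv.cox_fit(design, times, events)
            except ValueError:
                cox = None

    return PipelineResult(calls_tumor, calls_control, profiles_t, profiles_c,
                          ratio_test, enrichment, recurrence, overlap,
                          cutpoint, km_high, km_low, cox)


# ---------------------------------------------------------------------------
# tabular serialization of calls
# ---------------------------------------------------------------------------

def calls_frame(calls: Sequence[PiSNVCall]) -> pd.DataFrame:
    """Per-variant summary table (one row per variant x gene)."""
    rows = []
    for c in calls:
        best = min((ev.delta for ev in c.supporting_rbps), default=float("nan"))
        sd = next((ev.structure_distance for ev in c.supporting_rbps), float("nan"))
        rows.append((c.variant.sample_id, c.variant.chrom, c.variant.pos,
                     c.variant.ref, c.variant.alt, c.gene_id, c.is_pisnv,
                     ",".join(ev.rbp_name for ev in c.supporting_rbps),
                     best, sd))
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "gene_id", "is_pisnv",
        "supporting_rbps", "best_delta", "structure_distance"])


def evidence_frame(calls: Sequence[PiSNVCall]) -> pd.DataFrame:
    """One row per variant x supporting RBP."""
    rows = []
    for c in calls:
        for ev in c.supporting_rbps:
            rows.append((c.variant.sample_id, c.variant.chrom, c.variant.pos,
                         c.variant.ref, c.variant.alt, c.gene_id, ev.rbp_name,
                         ev.motif_disrupted, ev.clip_overlap, ev.delta,
                         ev.structure_distance))
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "gene_id", "rbp_name",
        "motif_disrupted", "clip_overlap", "delta_bits", "structure_distance"])
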