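"""Shared fixtures: one default synthetic study and its pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from pisnv.caller import PiSNVCaller
from pisnv.pipeline import StudyInputs, inputs_from_study, run_pipeline
from pisnv.simulate import SimulationConfig, SyntheticStudy, simulate_study


@pytest.fixture(scope="session")
def default_study() -> SyntheticStudy:
    """The default study conditions at a fixed seed."""
    return simulate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_caller(default_study) -> PiSNVCaller:
    return PiSNVCaller(default_study.genome, default_study.utrs,
                       default_study.pwms, default_study.clip_peaks)


@pytest.fixture(scope="session")
def default_result(default_study):
    return run_pipeline(inputs_from_study(default_study))


@pytest.fixture(scope="session")
def small_study() -> SyntheticStudy:
    """A lighter study for tests that rerun the caller several times."""
    cfg = SimulationConfig(seed=5, n_genes=8, n_tumor_samples=6,
                           n_control_samples=6, n_rbps=8)
    return simulate_study(cfg)


def call_truth_summary(study: SyntheticStudy, calls) -> tuple[float, float]:
    """(sensitivity on planted disruptors, false-call rate on background)."""
    called: dict[tuple[str, str, int], bool] = {}
    for c in calls:
        k = (c.variant.sample_id, c.variant.chrom, c.variant.pos)
        called[k] = called.get(k, False) or c.is_pisnv
    truth = study.truth_variants
    planted = truth[truth.is_planted_disruptor]
    background = truth[~truth.is_planted_disruptor]
    sens = np.mean([
        called.get((r.sample_id, r.chrom, r.pos), False)
        for r in planted.itertuples()
    ])
    fcr = np.mean([
        called.get((r.sample_id, r.chrom, r.pos), False)
        for r in background.itertuples()
    ])
    return float(sens), float(fcr)


def all_calls(result) -> list:
    return result.calls_tumor + result.calls_control


def mirror_study(study: SyntheticStudy) -> StudyInputs:
    """Reverse-complement every contig and flip all strands/coordinates.

    The mirrored study describes the identical biology, so the caller must
    produce identical calls (strand equivariance).
    """
    from pisnv.io import (ClipPeak, GenomicInterval, UTRAnnotation, Variant,
                          reverse_complement)

    lengths = {c: len(s) for c, s in study.genome.items()}
    genome = {c: reverse_complement(s) for c, s in study.genome.items()}

    def flip_iv(iv: GenomicInterval) -> GenomicInterval:
        L = lengths[iv.chrom]
        return GenomicInterval(iv.chrom, L - iv.end, L - iv.start,
                               "-" if iv.strand == "+" else "+")

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def flip_variant(v: Variant) -> Variant:
        L = lengths[v.chrom]
        return Variant(v.chrom, L - v.pos + 1, comp[v.ref], comp[v.alt],
                       v.sample_id)

    utrs = [UTRAnnotation(a.transcript_id, a.gene_id,
                          [flip_iv(iv) for iv in a.utr3_intervals])
            for a in study.utrs]
    peaks = [ClipPeak(flip_iv(p.interval), p.rbp_name, p.score)
             for p in study.clip_peaks]
    tumor = {sid: [flip_variant(v) for v in vs]
             for sid, vs in study.tumor_variants.items()}
    control = {sid: [flip_variant(v) for v in vs]
               for sid, vs in study.control_variants.items()}
    return StudyInputs(genome, utrs, study.pwms, peaks, tumor, control,
                       None, [])


def call_signature(calls, lengths=None):
    """Canonical, strand-agnostic summary of a call set for comparison.

    When ``lengths`` is given the variant position is mapped back through
    the mirror so signatures of original and mirrored runs align.
    """
    sig = set()
    for c in calls:
        pos = c.variant.pos
        if lengths is not None:
            pos = lengths[c.variant.chrom] - pos + 1
        sig.add((
            c.variant.sample_id, c.variant.chrom, pos, c.gene_id, c.is_pisnv,
            tuple(sorted(
                (ev.rbp_name, ev.motif_disrupted, ev.clip_overlap,
                 round(ev.delta, 9) if ev.delta == ev.delta else None,
                 round(ev.structure_distance, 9)
                 if ev.structure_distance == ev.structure_distance else None)
                for ev in c.supporting_rbps)),
        ))
    return sig
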