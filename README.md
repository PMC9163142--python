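# pisnv — 3′-UTR posttranscriptional-impairment SNV analysis

`pisnv` identifies somatic single-nucleotide variants in 3′ untranslated
regions that are predicted to impair posttranscriptional regulation
(**piSNVs**), and carries the calls through the cohort-level analyses a
cancer-genomics study needs: per-sample piSNV burden, tumor-vs-control
contrasts, RNA-binding-protein (RBP) enrichment, gene recurrence and
survival stratification.  It is written for computational biologists who
have per-sample somatic VCFs, a 3′-UTR annotation, RBP position weight
matrices (PWMs) and CLIP-seq peaks, and want a reproducible, testable
pipeline — plus a truth-labelled synthetic-cohort generator so every stage
can be validated without any external download.

## The method

A 3′-UTR SNV is called a piSNV for RBP *R* when **binding evidence** and
**impairment evidence** coincide at its locus:

- *Binding*: a PWM match of *R* on the reference allele with log-odds score
  `S(w) = Σ_j log2( p_R(w_j, j) / q(w_j) ) ≥ s_min` (background *q* uniform
  by default; `s_min` defaults to 80 % of the PWM's maximum score), and/or a
  CLIP peak of *R* covering the position (both required with
  `require_clip`).
- *Impairment*: the allele substitution drops the motif score by
  `Δ = S(alt) − S(ref) ≤ −2` bits, **or** the minimum-free-energy secondary
  structure of the 101-nt window centred on the variant (ViennaRNA) changes
  in ≥ 10 % of positions (pairing-partner distance).

Evidence combines as OR over RBPs and OR over the two impairment arms.
Downstream:

- **piSNV ratio** — per sample, piSNVs / SNVs within 3′-UTRs; tumor vs
  control cohorts compared by the two-sided Wilcoxon rank-sum test (exact
  enumeration for ≤ 16 untied observations).
- **RBP enrichment** — per RBP, a 2×2 Fisher exact test (minimum-likelihood
  two-sided p, exact integer tie handling) of piSNV status × membership in
  the RBP's binding sites (motif matches ∪ CLIP peaks), with
  Benjamini–Hochberg FDR across RBPs; significant iff FDR < 0.05 and
  OR > 1.
- **Gene recurrence** — samples-with-piSNV per gene divided by the gene's
  3′-UTR length in kb (union over transcripts).
- **Survival** — the maximally selected rank statistic picks the piSNV-ratio
  cutpoint maximizing the standardized log-rank statistic over admissible
  splits (`minprop = 0.1`); Kaplan–Meier curves, the log-rank test (labelled
  exploratory for the selected split) and a multivariate Cox proportional
  hazards model (Efron ties, Newton–Raphson) with age, sex and TNM stage.

## Worked example

Simulate a study (20 genes, 50 tumor + 50 control samples, 30 % / 10 % of
3′-UTR SNVs planted as motif-consensus disruptors, PTBP1 boosted 5×) and
run the whole pipeline:

```bash
pisnv simulate --seed 1 --out demo/study
pisnv run-all --study-dir demo/study --out demo/results
cat demo/results/report.md
```

```
# piSNV pipeline report

- provenance: `config_hash=9ac6af8d9464`
- tumor samples: 50, control samples: 50
- tumor vs control piSNV-ratio Wilcoxon p = 3.65e-11
- significant RBPs (BH-FDR < 0.05, OR > 1): PTBP1, RBP01, RBP02, ...
- piSNVs in APA sites: 7.5%
- piSNVs in m6A sites: 9.3%
- piSNVs in miRNA sites: 8.4%
- optimal ratio cutpoint 0.429, log-rank p = 0.000109 (exploratory; selected by scanning)
```

The tumor cohort's piSNV ratio separates cleanly from the control cohort
(planted fractions 0.3 vs 0.1; Wilcoxon p ≈ 4e-11), the boosted RBP tops
the enrichment table (`rbp_enrichment.tsv`: PTBP1 a=120 in-site piSNV
occurrences against 0 in-site non-piSNVs, FDR ≈ 2e-71 — other planted RBPs
are also genuinely enriched because disruptors sit inside their motifs),
the site-overlap fractions track the simulated ~10 % site coverage, and the
survival scan recovers a cutpoint near the planted median split.  Output
tables (`calls.tsv`, `evidence.tsv`, `sample_profiles.tsv`,
`rbp_enrichment.tsv`, `gene_recurrence.tsv`, `site_overlap.tsv`,
`km_curves.tsv`, `cutpoint.json`, `cox_results.tsv`) are TSV/JSON with a
provenance header comment; rerunning with the same seed reproduces every
file byte for byte.

The same stages are importable as a library:

```python
from pisnv import SimulationConfig, simulate_study, run_pipeline
from pisnv.pipeline import inputs_from_study

study = simulate_study(SimulationConfig(seed=1))
result = run_pipeline(inputs_from_study(study))
print(result.ratio_test)             # (W, p) tumor vs control
print(result.cox.summary())          # hazard ratios with 95% CIs
```

## Layout

- `pisnv.io` — VCF/BED/FASTA/MEME-motif/TSV readers and writers; coordinate
  conventions (BED 0-based half-open internally, VCF 1-based at the edge).
- `pisnv.simulate` — the truth-labelled synthetic study generator.
- `pisnv.caller` — PWM scanning, structure distance, CLIP overlap, the
  piSNV decision.
- `pisnv.stats` — ratios, Wilcoxon/Fisher/BH, enrichment, recurrence,
  site overlap.
- `pisnv.survival` — Kaplan–Meier, log-rank, cutpoint scan, Cox (Efron).
- `pisnv.cli` — `pisnv simulate | call | stats | survive | run-all`.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
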