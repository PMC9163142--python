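# Methods

## The piSNV decision

A somatic SNV inside a gene's 3′-UTR is assessed against every RBP in the
panel.  For RBP *R* the caller asks two independent questions:

1. **Does *R* bind here?**  Either a PWM match of *R* overlapping the
   variant whose reference-allele log-odds score reaches the hit floor, or
   a CLIP peak of *R* containing the position (strand-matched to the host
   UTR).  With `require_clip` both are demanded; by default either
   suffices, because CLIP assays cover a minority of RBPs and conditions
   while motif models cover the panel.
2. **Does the variant impair the interaction?**  Either the motif arm —
   the best (most negative) per-window log-odds change `Δ ≤ δ` — or the
   structure arm — the local MFE refold changes pairing in at least a
   fraction `σ` of window positions.

`piSNV(variant, R) = binding(R) AND (motif_disrupted(R) OR structure_changed)`,
and a variant is a piSNV if the conjunction holds for any RBP.  The OR
combination mirrors a workflow in which motif loss and structural
rearrangement are parallel routes to the same endpoint (loss of
protein–RNA contact); no published threshold set exists for this caller's
antecedents, so all four knobs are explicit, documented parameters rather
than constants.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `motif_score_frac` | 0.8 | fraction of each PWM's max score | scales the hit floor to motif information content; an absolute `motif_score_min` (bits) can override it |
| `delta_threshold` | −2 | bits | a four-fold likelihood drop; separates consensus-breaking substitutions (≈ −6.6 bits on a 0.97-consensus column) from tolerated ones (0 bits) with a wide margin |
| `structure_threshold` | 0.1 | fraction of window positions | ~10 nt of re-paired bases in a 101-nt window; below typical fold-to-fold noise for a true rearrangement, above the 0 of a silent substitution |
| `fold_window_radius` | 50 | nt | a point mutation perturbs structure locally; windowed folding bounds runtime at O(window³) per variant |
| `require_clip` | off | — | CLIP coverage is incomplete; the union rule is the default, the intersection a stricter option |

Folding is evaluated lazily: when the motif arm already resolves every
candidate RBP at a locus (or no candidate exists), the MFE computation is
skipped and the structure distance recorded as NaN.  The decision is
identical to eager evaluation — only folds that cannot change the outcome
are omitted — and it is what makes cohort-scale runs cheap, since the MFE
window dominates per-variant cost.

Per-gene 3′-UTRs are the union of transcript intervals (merged, strand
checked); a variant falling in two genes' UTRs is assessed once per gene.
The variant's reference allele is checked against the genome and a
mismatch is an error, which catches coordinate-convention bugs at the
boundary rather than deep in a result table.

## Cohort statistics

- **Ratio.** Per sample, distinct piSNVs over distinct 3′-UTR SNVs.  A
  zero denominator yields ratio 0 with a flag and the sample is excluded
  from rank tests.  The tumor–control contrast is the two-sided Wilcoxon
  rank-sum test: exact enumeration of rank assignments when n+m ≤ 16
  without ties, otherwise the normal approximation with tie and continuity
  corrections.
- **Enrichment.** The unit is the SNV occurrence (sample × variant),
  pooled over the tumor cohort.  For each RBP the 2×2 table crosses piSNV
  status with membership in the RBP's binding loci — PWM matches at the
  hit floor anywhere in the UTRs, union CLIP peaks.  Fisher's exact test
  uses the minimum-likelihood two-sided rule with integer-exact tie
  comparison; Benjamini–Hochberg step-up q-values run across all tested
  RBPs, and significance requires FDR < α (default 0.05) and OR > 1.
  RBPs with empty site sets or degenerate margins are skipped and logged.
- **Recurrence.** Genes ranked by distinct samples carrying a piSNV per kb
  of 3′-UTR; the raw piSNV count is also emitted.  Length correction
  removes the trivial advantage of long UTRs.
- **Site overlap.** Fraction of distinct piSNVs inside each user-supplied
  regulatory site class (m6A, APA, miRNA binding); a generic interval
  annotator, agnostic to where the site sets came from.

## Survival

The per-sample ratio is dichotomized at the value maximizing the
standardized two-group log-rank statistic `|O−E|/√V` over all splits
leaving at least `minprop = 0.1` of samples on each side (the maximally
selected rank statistic; 0.1 matches the referenced cutpoint tool's
default).  The selected split's own log-rank p is reported but labelled
exploratory: maximizing over correlated splits inflates it, and no
correction is applied — over null replicates the minimal scanned p is
below 0.05 far more often than 5 %, which the test suite demonstrates
rather than hides.  Kaplan–Meier curves use the product-limit form with
censoring decrementing the risk set without steps.  The Cox model
maximizes the Efron-tied partial likelihood by Newton–Raphson with step
halving to gradient norm < 1e-8 (≤ 50 iterations); Efron over Breslow
because the synthetic cohorts produce heavy ties, for which Efron's
correction is markedly less biased.  Covariates: the high/low indicator
(or the continuous ratio on request), age, sex and dummy-coded TNM stage
(ordinal scoring optional).  Non-convergence or a runaway coefficient
(|β| > 20, monotone likelihood under perfect separation) returns a flagged
result with no estimates.  Wald CIs and p-values; lifelines reproduces the
coefficients to 1e-5 in the cross-check tests.

## The synthetic study

The generator emulates the statistical structure of a pan-cancer 3′-UTR
mutation study at desk scale, with full truth labels:

- **Reference.** One contig per batch of 50 genes; each gene one 3′-UTR of
  length Poisson(1000 bp) truncated at ≥ 200 bp, half the genes on the
  minus strand, uniform base composition.
- **Motifs and peaks.** A panel of 20 sharp PWMs (0.97 consensus weight;
  PTBP1's CUCUCU first).  Each UTR receives 0–3 consensus instances of
  random RBPs written into the genomic sequence (reverse-complemented on
  minus-strand genes); each instance emits a covering CLIP peak (± 10 bp)
  with probability 0.8, plus decoy peaks at 0.1/kb at motif-free
  positions.  The enriched RBP is topped up to ≥ 3 instances: a planted
  enrichment effect must exist in every replicate to be recoverable at
  all.
- **Cohorts.** Per sample, SNV count ~ Poisson(1 SNV/kb of UTR); a
  fraction (tumor 0.3, control 0.1) are placed on consensus positions of
  motif instances with the consensus base mutated away — C→U at an
  internal position when the consensus allows, mirroring the canonical
  pyrimidine-tract disruption — and the enriched RBP's instances receive
  5× weight in tumor samples.  Background SNVs fall uniformly on 3′-UTR
  positions *outside* instance footprints, so the per-variant truth labels
  are exact (a background hit inside a consensus instance would be a true
  disruptor mislabelled as background).
- **Clinical.** Event times are exponential with hazard
  `h0 · HR^{1[ratio > median]}` (h0 = 1/1500 per day, HR = 2.5); an
  independent exponential censoring time is scaled so each subject is
  censored with probability 0.3.  Age, sex and stage are drawn
  independently of the ratio, so the planted effect must survive
  multivariate adjustment rather than being laundered through a
  confounder.
- **Site sets.** m6A/APA/miRNA intervals of 20 nt covering ~10 % of UTR
  bases, placed independently of motifs.

Everything derives from one master seed through spawned substreams; equal
seeds give byte-identical output files.

### What the generator does *not* emulate

Mutational signatures and their sequence context, copy number,
subclonality, transcript-level isoform choice, realistic PWM information
content (real motifs are softer than 0.97 consensus), correlated CLIP
occupancy, or covariate-linked survival confounding.  Passing tests
therefore demonstrate that the pipeline recovers effects *of the planted
kind at the planted magnitude* — they do not certify sensitivity on real
tumor genomes, where motif disruption is subtler and binding evidence far
noisier.

One structural consequence worth stating plainly: because disruptors are
planted inside consensus instances, piSNV status is genuinely coupled to
*every* planted RBP's site membership, not only the boosted one.  The
enrichment screen accordingly flags most planted RBPs even when no RBP is
differentially boosted — that is true signal under this generator, not a
failure of FDR control, as the label-permutation null (which empties the
significant set) shows.  Distinguishing "this RBP is more affected than
the others" from "piSNVs live in RBP sites" would need a contrast against
a control cohort's piSNVs rather than against non-piSNVs.

## Numerical choices

- PWM columns are floored at 1e-3 and renormalized at parse time, keeping
  log-odds finite for hard-zero matrices.
- Fisher two-sided p compares hypergeometric numerators as exact integers
  (shared denominator), so probability ties are handled exactly instead of
  through a floating-point slack.
- The structure distance compares ViennaRNA pair tables position by
  position (unpaired vs partner index) and normalizes by window length;
  windows clipped below 20 nt at sequence ends return distance 0 with a
  flag rather than folding unstable stubs.
- Cutpoint ties (identical standardized statistics) resolve to the first
  scanned value, i.e. the smallest ratio.
- Degenerate inputs fail loudly: empty survival input, one-group log-rank,
  constant Cox covariates and zero-margin Fisher tables are errors, not
  silent NaNs.

## Problem sizes

The default study is 20 genes (~20 kb of UTR), 50+50 samples, ~20 SNVs per
sample; replicate-based checks use 100 such studies for the cohort
contrasts and 50–100 clinical cohorts of n = 200–500 for the survival
recovery, sizes at which every planted effect is comfortably detectable
and a full replicate set runs in minutes on one CPU.

## Known limitations

- Thresholds for the caller are declared stand-ins; no published set
  exists to validate against, so they are exposed in configuration and
  their consequences measured on synthetic truth only.
- Expression evidence (whether an impaired site actually changes the
  host mRNA's abundance) is outside the caller by design; matched
  expression would enter downstream filtering, not the call.
- Windowed MFE folding ignores ensemble (partition-function) structure;
  a variant shifting base-pair probabilities without changing the single
  MFE structure scores 0 on the structure arm.
- The cutpoint-selected log-rank p is exploratory (see above); the Cox
  model on the same dichotomy inherits some of that selection optimism.
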