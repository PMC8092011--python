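# Methods

This note documents the models and procedures apexmir implements, the
parameters that matter, the synthetic study conditions the generator
emulates, and the numerical and design choices made where the design was
genuinely open.

## Target-site scoring

A miRNA/target duplex is scored by summed per-position penalties: 0 for a
Watson–Crick pair, 0.5 for a G:U wobble, 1.0 for a mismatch or a bulged
(unpaired) nucleotide, with every penalty doubled at miRNA positions 2–13
counted from the miRNA 5′ end. Sequences are normalised internally to the
DNA alphabet (U→T); the duplex is antiparallel, so miRNA position 1 pairs
the 3′-most nucleotide of the site. Position 1 is penalised by default; an
`exempt_position_one` flag removes its penalty for users who follow the
convention of tools that ignore terminal mismatches.

Two conventions are under-determined by the penalty scheme itself and are
fixed here explicitly:

* **Bulge placement weight.** A bulged *target* nucleotide falls between
  two miRNA positions; it inherits the weight of the next miRNA position 3′
  of the gap (a bulge between positions *i* and *i+1* is doubled iff
  *i+1* ≤ 13 and *i+1* ≥ 2). A bulged *miRNA* nucleotide uses its own
  position's weight.
* **Overlap resolution.** All candidate windows scoring within the
  threshold are enumerated; overlapping candidates resolve to the lowest
  score, remaining ties to the smallest start coordinate, then the shortest
  site. This makes the reported site set deterministic. One consequence:
  two alignments of the same locus can tie (e.g. a one-nt target bulge
  versus a one-nt miRNA bulge two positions away); the tie-break then picks
  one representation, and the predicted cleavage position — the quantity
  downstream stages consume — is the same in both.

The default search allows at most one bulged nucleotide per site
(`max_bulges=1`); larger budgets switch from the closed-form shifted-window
search to a per-window alignment DP (slower, exact for the configured
budget). In practice multi-bulge sites exceed penalty 5 anyway.

The cleavage position is read off the alignment path as the transcript
nucleotide paired with miRNA position 10; a site whose position 10 is
bulged out is flagged cleavage-ambiguous and excluded from PARE validation
rather than assigned an arbitrary coordinate.

## PARE dual-window validation

For a predicted cleavage position *c*, `W_s` is the sum of tag counts at
positions *c* ± 2 (5-nt window) and `W_L` the sum over *c* ± 15 (31 nt),
each averaged across biological replicates; a site passes when
`W_s/W_L ≥ 0.75` and `W_s ≥ 4`.

* **Sum, not per-position mean.** The companion threshold `W_s ≥ 4` reads
  as a tag count; a per-position mean of 4 over 5 nt would be an
  implausibly high bar. A `window_stat="mean"` switch provides the
  per-position variant.
* **Raw counts by default.** The ratio is invariant to library-size
  normalisation; only the `W_s ≥ 4` cut is affected. A tags-per-million
  mode (`normalized=True`) exists for cross-library work.
* **Edge clipping.** Windows are clipped at transcript ends and never
  rescaled — rescaling would inflate ratios for sites near termini.
* **Degenerate case.** `W_L = 0` defines ratio 0 and a failed call (never
  NaN): absence of signal cannot validate a site.

## Efficacy metrics

The **relative PARE frequency** of a validated target is its assigned `W_s`
divided by the target's RPM in the *miRNA precursor domain* — the atlas
domain maximising the family's summed precursor expression (ties break to
atlas domain order with a warning; an explicit family→domain table
overrides the rule). Only targets reaching ≥ 1 RPM in at least one domain
are scored; a zero denominator flags the record undefined and excludes it
from correlations. Units mix tags with RPM, so the value is dimensionless
up to a constant — valid for the rank-level comparisons it serves.

Signatures shared by several targets (identical 31-nt sequence context
within a family, the product of target-site conservation) are handled two
ways: **independent** (each target receives the full observed `W_s`; the
default) and **abundance-weighted** (the signature's `W_s` is split across
member targets proportionally to their expression in the precursor domain;
assignments sum exactly to the observed value). With no expression anywhere
in a sharing group the split is uniform.

The **miRNA-to-target ratio** is summed family precursor expression over
target expression in the precursor domain, per target or with all target
expressions summed ("combined"). The **miRNA level** covariate used in
correlations is summed precursor expression over the six mutually
non-overlapping atlas domains (meristem, internode, P1, P2, P3,
vasculature) — a proxy justified by the measured precursor–mature coupling,
since domain-resolved mature small RNA quantification is not available.
Correlations of the relative PARE frequency against complementarity score,
miRNA level and miRNA-to-target ratio are Pearson's r on defined records
(undefined records are dropped and counted; fewer than 3 points is an
error).

**Processing-efficiency comparison.** For each precursor,
`(mutant + pc) / (wildtype + pc)` is computed in two tissues
(pseudocount pc = 0.5 RPM to tame zero denominators) and the precursor is
classified relative to the equal-ratio line (above/equal/below, equality at
relative tolerance 1e-9). Precursors below 1 RPM in all four measurements
are excluded, mirroring the expressed-gene filter applied upstream of
differential-expression testing.

## Expression-atlas operations

Min–max normalisation rescales each gene row to [0, 1]; a constant row maps
to zeros (the formula's 0/0 case). Hierarchical clustering uses Euclidean
distance with complete linkage and the deterministic dendrogram leaf order
for fixed input order. The precursor–mature correlation is Spearman's rank
correlation of log10(x + 1)-transformed summed precursor expression against
log10(mature RPM + 1), over isoforms detected at raw read count ≥ 10; base
and pseudocount only matter for zeros, since ranks are otherwise invariant.

**Outlier flagging.** Isoforms with higher or lower mature accumulation
than their precursor expression predicts are flagged when their residual
from the least-squares fit of log mature on log precursor exceeds 2 median
absolute deviations. Residuals on the ranks themselves were evaluated first
and rejected: rank residuals compress exactly the tail information a fold
change carries (a fold-8 shift moves points only a few ranks in a 40-point
sample, leaving many strong outliers unflagged), while log-scale residuals with the same
robust threshold separate fold-8 outliers completely. The MAD threshold is
deliberately liberal (≈1.35σ for Gaussian residuals), matching the
exploratory role of the flag.

## Synthetic study conditions

The generator emulates, at desk scale, the statistical structure the
analysis assumes. Defaults (the shipped conditions): 20 miRNA families,
2 mature isoforms per family (single-nucleotide variants), 4 precursors per
family, 3 targets per family, 21-nt miRNAs, 300-nt transcripts.

* **Expression.** Each family follows one of three domain archetypes
  (meristem, primordia, vasculature — the three major expression clusters
  of the shoot apex), assigned round-robin. Isoform precursor totals over
  the six non-overlapping domains are exactly `10^N(2.0, 0.45)` RPM
  (per-domain rows carry log10 jitter σ = 0.2 and are rescaled to the
  total). Targets follow the family archetype with the vasculature damped
  by 50% for vascular families, emulating cleavage-driven anticorrelation
  in the tissue where precursor expression peaks.
* **Mature coupling.** Mature abundance multiplies the precursor total by
  `10^N(0, 0.18)`; sequencing depth is fixed at 10^6 tags so RPM equals raw
  count (tag counts quantise RPM at 10^6/depth resolution — exact-limit
  checks raise the depth to remove quantisation). Because log totals are
  normal by construction, the coupling's Spearman correlation has the
  closed form ρ_s = (6/π)·arcsin(ρ/2) with ρ = σ_x/√(σ_x² + σ_c²) ≈ 0.92
  at the defaults. A 10% fraction of isoforms is multiplied or divided
  (alternating) by fold 8, the regime in which the outlier flag must fire.
* **Sites.** Each target carries one planted site realised from a mutation
  spec (0–2 mutations drawn from mismatch/wobble/bulge, total penalty ≤ 5);
  the truth score is computed additively from the spec, independent of the
  scoring module. A 10% sharing rate copies a site's context into a sibling
  target, creating multi-mapped signatures.
* **PARE.** Background degradation is homogeneous Poisson at 0.02 tags/nt
  per replicate (2 replicates). Truly cleaved signatures (50%; the rest are
  background-only decoys) add a Poisson peak at the cleavage position with
  mean 30 × a site-strength multiplier (precursor-sum × target-expression,
  normalised to geometric mean 1 and clipped to [0.5, 2] to bound the
  dynamic range). Peak tags of a shared signature are drawn once and placed
  at every member locus, the way multi-mapping reads are counted. In this
  regime the dual-window filter separates cleaved sites from decoys
  essentially completely, which is what makes planted-truth recovery a
  meaningful end-to-end check.

What the generator does **not** model: 5′-bias and sequence-dependent
structure in degradome background, sequencing error, transcript-length
variation, secondary miRNA sites per transcript, and tissue-level
correlation structure beyond the three archetypes. Passing tests therefore
demonstrate correctness of the statistics and plumbing under the stated
assumptions, not performance on real degradome data, where the
signal-to-background regime must be assessed per library.

## Problem sizes and determinism

All stochastic checks run at fixed problem sizes chosen for quick
turnaround: 50×10 random transcript/miRNA pairs for scanner–oracle
equivalence, 1,000 random fixtures for the window statistic, 40–100
generator seeds for recovery and sensitivity rates, and 200 seeds for the
correlation interval. Every generator stream is derived from a single seed
via independent child sequences, so all outputs — FASTA, TSV, BED and the
full pipeline result set — are byte-identical across reruns with the same
seed and inputs; output floats are written with fixed formatting to keep
this property at the file level.
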