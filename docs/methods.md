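# Methods

This note documents the models and procedures implemented in `clipsplice`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Coordinates and gene models

All coordinates are 0-based, half-open (BED convention); GTF input is shifted
on read, and 1-based values appear only in human-readable reports. A gene
model is a transcript: ordered exons with introns derived as the gaps between
consecutive exons, stored in transcript order so that minus-strand logic
never leaks into downstream code. Splice-site positions are always the
first/last *intronic* base of an intron: the donor (5'ss) of a plus-strand
intron is its start, of a minus-strand intron its last base, and likewise for
acceptors. A cassette-exon context carries the four sites of the two flanking
introns labelled `up5ss`, `up3ss`, `down5ss`, `down3ss` in transcript
orientation.

Region classification assigns one label per interval using a single
representative position — the preferred crosslink for clusters, the midpoint
otherwise — so that labels over any cluster set form a partition. Priority is
exonic > intronic > intergenic; among overlapping genes, same-strand matches
win, then the smallest gene span. Overlapping transcripts of one gene are
collapsed to the longest transcript for classification only; splicing is
quantified per transcript exon.

## Binding clusters

Uniquely mapped reads are merged by transitive same-strand overlap
(half-open: abutting reads do not merge). PCR duplicates — identical
interval and conversion set — are collapsed by default. Clusters need at
least `min_reads = 2` reads and one converted read; both are configurable and
recorded in the run manifest, since no published filter exists for this step.
The preferred crosslink is the position with the most T→C conversions, ties
broken toward the smallest coordinate (deterministic and strand-agnostic).

Consensus clusters pair replicates by reciprocal crosslink containment. When
a cluster qualifies for several partners, pairs are resolved greedily by
ascending crosslink distance, each cluster used once; the resolution policy
is ours (multiplicity is unspecified in the underlying definition) and is
symmetric as a set under replicate swap. The consensus adopts replicate 1's
crosslink. The cluster score is log₂(1 + converted reads) — a stated
stand-in, monotone in conversion support, used only for ranking and display.

Boundary profiles anchor offset 0 on the intronic boundary base (donor for
exon–intron, acceptor for intron–exon), offsets signed along the transcript.
Clusters contribute their crosslink; reads contribute full coverage. Profiles
are normalized per boundary, so the profile sum times the boundary count
equals the item hits.

## Splicing quantification

PSI, PIR and RPKM are exact ratios of integer counts; 0/0 is undefined and
propagates as an exclusion, never as 0 or NaN arithmetic. Because mappability
exclusivity ("reads mappable only to…") requires the original aligner, each
read record carries its single piece of junction evidence and the counter
logic applies the ≥ 6 bp overlap rule to it. One read receives exactly one
*evidence class* (inclusion, skipping, intron junction, unassigned), but a
class feeds every counter it logically supports: an adjacent exon–exon
junction is inclusion evidence for both flanking exons *and* skipping
evidence for the intron between them; a junction skipping exons is exclusion
evidence for each skipped exon and skipping evidence for every intron it
spans. The cassette interval [0.02, 0.98] is closed on both ends. A
min-coverage floor of 10 informative reads per sample (configurable) gates
entry into differential testing; duplicate exon coordinates across
transcripts are collapsed by (chrom, start, end, strand).

## Differential statistics

Per paired replicate, Δ = case − control for PSI/PIR and a pseudocounted
log₂ ratio (c = 0.1) for expression. The local SD sorts features by their
per-replicate supporting-read total (case + control), computes the sample SD
of Δ in a centered window of max(25, 1% of features) — the window shifts
inward at the list edges rather than shrinking — then smooths the raw SDs by
loess (span 0.3) against coverage *rank*, which tames the skew of raw
coverage. Smoothed SDs are floored at 1e-6. Under homoscedastic noise this
recovers the global σ at every rank and yields Z with mean ≈ 0, SD ≈ 1
(verified in the acceptance suite).

Rank products are direction-specific: two one-sided analyses (up and down)
with rank 1 the most extreme Z in the requested direction and average ranks
on ties. The permutation FDR shuffles each replicate's observed rank list
independently; at a rank product RP, fdr = E[# null RP ≤ RP] / #{observed
RP' ≤ RP}, monotonized non-decreasing in RP by reverse cumulative minimum
(the step-up convention) and capped at 1. Both directions reuse one seed so
that swapping case and control labels swaps the up and down lists exactly.
Defaults: 200 permutations (FDR resolution ~0.005 per feature at n = 2000,
desk-scale runtime), fdr < 0.05 and |ΔPSI| ≥ 0.10 for calls, mean Δ across
replicates as the reported effect size.

## Integration

Binding proximity flags a splice site when a consensus crosslink lies within
the flanking intron and within 150 nt of the site. The intronic-side rule is
deliberate — the four-site classification concerns intronic splice-site
vicinity — and `include_exonic_side` relaxes it. The splicing map bins
crosslink offsets (default 5 nt bins, ±300 nt) around each of the four
anchors per exon group; density is hits per exon per bin, so the integral
times group size conserves hit counts. Group comparisons use two-sided
Mann–Whitney U against a background group (no test is canonical for CDF
shifts; U is assumption-light); groups under 5 members return a CDF but skip
the test.

Splice-site strength is a PWM log₂-odds score against genome-wide base
frequencies, with conventional windows: 9-mer donors (3 exonic + 6 intronic
nt) and 23-mer acceptors (20 intronic + 3 exonic nt), pseudocount 1. PWM
scoring is a declared stand-in for unnamed strength methods; scores are
comparable only within one trained model. Windows crossing a contig edge or
containing N are excluded.

## Synthetic data: what it emulates

The generator reproduces the study design the pipeline expects: multi-exon
genes (default 4–8 exons, 80–250 nt exons, 300–1200 nt introns, both
strands) with canonical GT…AG intron dinucleotides; binding sites placed on
the intronic side of splice sites at Normal(70, 10) nt from the anchor
(defaults favor acceptors 0.35 : 0.15 over donors, matching the observed
~70 nt upstream-of-3'ss enrichment), snapped to the nearest transcript-strand
T; two independent CLIP replicates of 30-nt reads with Poisson(20) coverage
per site, conversion probability 0.7 at the crosslink T and a small multiple
of it elsewhere, plus ~10% non-specific background reads; and junction count
tables for 2 overexpression and 4 knockdown replicates with paired controls,
depth Poisson(100) per feature and beta-binomial overdispersion ρ = 0.01.

Planted effects: 10% of cassette exons receive |ΔPSI| = 0.3, skipping upon
overexpression with probability 0.85 and the inverse sign under knockdown;
with probability 0.8 (`coupling`) a planted exon also carries binding at 1–4
of its four splice sites, and the effect grows by 0.1 per additional bound
site — emulating the observed dose dependence of skipping on bound-site
count. Recorded truth is always the *realized* change after clipping PSI to
[0, 1]. Introns flanking planted exons gain ΔPIR = ±0.1 opposite in sign to
the exon's ΔPSI.

Not emulated: sequencing error, alignment ambiguity and mappability (reads
arrive with their junction evidence resolved), expression-level regulatory
effects, alternative 5'/3' splice sites and mutually exclusive exons, and
genome-scale library sizes. Passing tests therefore demonstrate the
correctness and calibration of the statistics and the integration logic on
idealized alignments — not robustness to alignment artifacts.

## Problem sizes and reproducibility

Validation studies use 2000 internal exons (500 genes × 4 internal exons),
20 seeds for null calibration, 4 replicates for power, and 200–600 genes for
binding recovery and integration — sizes chosen so the full suite runs on a
laptop in well under a minute per study while keeping binomial tolerances
tight (±0.05 at n ≥ 400). Every stochastic step draws from a generator
seeded from a single config seed via per-stage seed sequences; the pipeline
fans one global seed into per-stage seeds by hashing the stage name, so
disabling a stage never reshuffles another's randomness. Two runs of one
config produce byte-identical outputs (SHA-256 digests in the manifest).

## Known limitations

- Consensus pairing is greedy; a globally optimal matching could differ in
  rare dense regions. The pairing predicate itself is exact.
- The permutation FDR is an expectation ratio, not a p-value; with very few
  features it is coarse (resolution 1/permutations) though unbiased.
- The local SD absorbs coverage-dependent noise but assumes exchangeability
  of features within a coverage window; strong biological heteroscedasticity
  within a window inflates the local SD and costs power rather than
  producing false positives.
- PWM splice-site scores ignore positional dependencies (no maximum-entropy
  or decision-tree models).
- Single-site crosslink recovery assumes sites are farther apart than a read
  length; sites closer than ~30 nt can merge into one cluster and count as a
  single recovered site.
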