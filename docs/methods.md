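# Methods

## Coordinate and distance conventions

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted at the parsing boundary (1-based closed → 0-based half-open)
and converted back on write, so no off-by-one can drift through the
pipeline. Distance between two intervals is the edge-to-edge gap in bp:
any ≥ 1 bp overlap gives distance 0, and a query on a chromosome with no
reference interval gets a `+inf` sentinel rather than being dropped.
"At least 2 kb from the nearest gene" is evaluated inclusively on this
gap, so a peak exactly 2000 bp from a gene edge is distal. Overlap tests
use a configurable minimum of shared bases (default 1 bp) computed on
the true intersection length. Unknown strand is stored explicitly as
`"."`; strandless operations ignore it. narrowPeak summit offsets are
retained as metadata but unused.

## Six-class enhancer classification

Distal H3K27ac peaks (≥ 2 kb edge-gap from genes) are classified on two
axes:

1. **H3K4me1 proximity** — H3K4me1 marks gene bodies in plants, so a
   distal H3K27ac peak with an H3K4me1 peak within 1 kb (edge gap,
   overlap included; the window absorbs the TSS-to-gene-body offset) is
   treated as a likely misannotated gene rather than an enhancer.
2. **Strand-resolved transcription** — per strand, the evidence is the
   coverage area over the peak divided by the library read length, i.e.
   an estimated read count. A strand is expressed when this reaches
   `min_reads` (default 5). Both strands → bidirectional; one →
   unidirectional; neither → none. The estimated-read parameterization
   is sequencing-depth-robust and directly testable against planted
   counts. Collapsing plus-only/minus-only to "unidirectional" is the
   only lossy step; the raw per-strand evidence stays on every record.

The cross gives six exhaustive, mutually exclusive classes. Raising
`min_reads` is monotone: the "none" classes can only grow and
"bidirectional" can only shrink.

Evidence layers per record: TFBS hit (≥ 1 bp overlap with the union of
TF binding-site sets); capped transcription by re-applying the strand
call to a capped-RNA (RAMPAGE-like) track at its own threshold (default
2 estimated reads — cap-selected libraries are shallower); reporter
activity summarized per record as max/mean/median of per-bp signal
(median by default), compared between classes by two-sided Welch t-tests
(scipy, unequal variances; identical degenerate distributions report
p = 1); chromatin loops ("in loop" = overlapping either anchor, with the
strictly-between-anchors count also reported since the phrase "in a
loop" is ambiguous between the two readings); and conserved-element
counts with per-class fractions at the ≥ 1 and ≥ 10 tiers. Fractions
over empty classes are NaN, never 0. Linked-gene expression
(log2(RPKM + 0.1)) is compared against (a) uniformly random genes and
(b) random genes overlapping any loop anchor — draw size equal to the
linked set, 100 seeded draws, medians reported, Welch test on the first
draw.

## Peak processing

The pseudo-replicate reproducibility rule keeps exactly the
merged-sample peaks that overlap (≥ 1 bp) at least one peak in *each* of
the two pseudo-replicates; read splitting and peak calling are upstream.
The rule is idempotent. Upset-style intersection tables operate on union
regions merged by single-linkage ≥ 1 bp overlap (book-ended intervals
stay separate under half-open coordinates); a sample is a member of a
region iff one of its peaks overlaps it. This merged-region semantics is
deterministic and order-invariant, unlike reciprocal pairwise overlap.
Feature annotation is by priority gene > TE family (largest overlap,
then lexicographic family name) > intergenic ≤ 2 kb > intergenic > 2 kb,
and distances are binned {genic, < 2 kb, 2–10 kb, 10–100 kb, > 100 kb}.

## Mappability and random controls

Aligner-based mappability is replaced by exact k-mer uniqueness: the
genome is tiled into non-overlapping k-bp bins (default k = 150; the
sub-k chromosome tail is dropped) and a bin is mappable iff it contains
no N and its sequence occurs exactly once genome-wide counting both
strands. This is deterministic and dependency-free; it differs from
aligner mappability in allowing no mismatches, so it is slightly more
permissive on near-duplicates. Adjacent mappable bins merge into runs.

Controls are drawn per input interval uniformly over every valid start
position (any run long enough, any offset), preserving the count and the
exact length multiset; placement is deterministic given the seed.
Controls may overlap each other and may change chromosome (matching the
defaults of the standard shuffling tool); both behaviors are flags, with
rejection sampling up to `max_attempts` when overlap is forbidden. An
interval longer than the longest run is an error naming the interval.

## Signal model and metaprofiles

Coverage is run-length encoded per chromosome and strand; integrals over
arbitrary (fractional) windows are computed exactly from a
piecewise-linear cumulative-area function, so bin means never resample
the signal. `scale_regions` metaprofiles rescale each interval body to
`body_bins` bins (fractional-overlap weighting, so sub-bin bodies are
handled without error) and append fixed `bin_bp` flanks;
`reference_point` centres fixed bins on the interval midpoint. Bins
extending beyond a chromosome end are missing values excluded from
column means — zero-filling would fabricate boundary dips. The per-bin
statistic is the mean, matching standard metaplot tools. Intervals are
not strand-oriented (the peaks profiled here are unstranded).

The boundary statistic divides the mean signal in the bins straddling
each boundary (`edge_bp` outside, in flank bins, plus the body bins
falling entirely within `edge_bp` inside, whose number depends on each
row's own length) by the mean over interior body bins; bins partially
covering the edge zone are excluded from both terms, so an exactly
planted step profile recovers its ratio exactly. A zero interior mean
reports `+inf` with a notice.

## Expression and conservation logic

A gene is tissue-specific (up or down) when it passes FDR < 0.05 (no
fold-change floor; both are flags) in the stated direction in *every*
pairwise comparison of that tissue versus each other tissue; a missing
pairing is an error naming it. The conservation flow assigns each
reference DEG, per target inbred, one of three exhaustive statuses:
conserved (any listed homolog is a DEG there — "any" matching because
compara-style orthology is one-to-many), homolog-not-DEG, or
no-homolog; summary percentages are computed over all reference DEGs
and sum to 100. Expression quintiles rank genes with RPKM > 0 ("expressed"
means strictly positive by default) into five near-equal bins with ties
broken by gene id for determinism.

## Small RNA and telomeres

Size distributions are CPM normalized by the total mapped-read library
size (not by the 18–28nt subset). Hairpin flagging is deliberately a
heuristic without RNA folding: a cluster is hairpin-like iff it spans
≥ 1 kb, its 20–24nt reads are ≥ 80% on one strand, and 22nt reads are
≥ 50% of its 20–24nt reads — the operational signature of kilobase
inverted-repeat ("proto-miRNA") loci; all thresholds are parameters,
and clusters with no 20–24nt reads get undefined sentinels. Telomere
repeats ("CCCTAAA", configurable) are counted greedily and
non-overlapping in the first window (default 10 kb) of each chromosome,
and the reverse complement in the last window; assembled telomere tracts
are incomplete, so the counts bound telomere length from below and are
reported per window, never as a length estimate.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions every acceptance property runs under: 600 distal peaks (100
per class) on 2 chromosomes, seed-deterministic to the byte; RNA
evidence planted at 15–25 estimated reads per expressed strand
(≥ 2× away from the calling threshold of 5, so class recovery is exact
by design); 40 telomere-repeat copies per chromosome end; 2,000
reference DEGs with conservation probability 0.6 and no-homolog
probability 0.1 across three target inbreds; 150 planted pollen-specific
up-regulated genes (with the other tissues mirroring, at one-tenth
scale, the strongly pollen-dominated counts such data show — ear 26/19,
coleoptilar node 0/21); 300 loops wiring enhancers to genes carrying a
+1.5 log2-unit expression shift (applied in every tissue, since the
loop comparison consumes one tissue's RPKM vector); 24nt signal at
background 1.0 with class-dependent boundary factors (3×/2×/1.5× for
bidirectional/unidirectional/none) in ±500 bp zones around each peak
edge; activity means 3/2/1 (sd 0.5) for the three expression classes;
and an exact 21:22:24 = 1:3:6 small-RNA length mixture with 10 planted
hairpin clusters (3 kb, 95% strand bias, 70% 22nt) among 50.

Layout: each chromosome is a row of 20 kb slots carrying, at fixed
offsets, one gene (every slot), and optionally one enhancer, one TE, one
sRNA cluster and background sRNA reads — which places every enhancer
≥ 7 kb from every gene, distal by construction, with H3K4me1 planted
within 100–900 bp only for the K4me1+ classes (gene bodies also carry
H3K4me1, as in real data). The genome background is i.i.d. uniform
A/C/G/T scrubbed of the telomere motif and its reverse complement, so
telomere counts and 150-mer uniqueness are fully controlled; coverage is
written as idealized uniform pileups (`count × read_length / length`)
because the pipeline consumes coverage, not reads. Planted marginals are
exact wherever the configuration states a count and sampled wherever it
states a probability. The bundle's mappable mask is constructed from the
layout (whole-genome bins minus telomere-touching bins); the k-mer
masking code itself is validated on separate small genomes with planted
duplications against a brute-force substring-count oracle.

What the generator does **not** emulate: nucleotide composition bias,
TE sequence models, read-level noise or mapping artifacts, dependence
structure between evidence layers beyond the planted class effects,
DNA-methylation or >30nt short-RNA tracks, or replicate variability.
Passing tests therefore demonstrate the correctness of the logic and
statistics on idealized inputs, not robustness to alignment noise or
annotation error in real data.

## Problem sizes and numerical choices

The bundled analyses run at desk scale: a ~16 Mb two-chromosome genome,
600 peaks, 2,000 reference DEGs, 10^4 single-interval shuffles, and 20
random 50 kb genomes for the mappability oracle — sizes chosen so every
stage recovers its planted truth with tight statistical bounds while the
whole suite completes in seconds. Welch tests use scipy with unequal
variances; binomial recovery checks use ±2 SE (rates) or ±3 σ (shuffle
uniformity); profile oracles agree to 10⁻⁹ absolute. Ties are broken
deterministically everywhere (lexicographic names, gene ids), and all
randomness flows through `numpy.random.default_rng` seeds supplied by
the caller.

## Known limitations

- k-mer uniqueness is a surrogate for aligner mappability (no
  mismatches, no quality model).
- Hairpin flagging does not fold RNA; it operationalizes the
  strand-bias/length/22nt signature only.
- The loop comparison's "random genes in loops" pool coincides with the
  linked genes themselves when loops only connect enhancers to genes, as
  in the synthetic bundle; on real data the pool also contains gene–gene
  loop anchors.
- Peak calling, differential-expression fitting, orthology inference,
  sRNA cluster calling and conservation-element discovery are consumed
  as inputs, never recomputed.
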