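# Methods

## Scope and design

`retroscope` re-implements, at desk scale, the computational skeleton of a
long-read retrotranscriptome study: structural LTR retrotransposon
annotation, long-read transcript assembly and mapping, origin
classification of retroelement-related transcript loci, a domestication
screen, copy-number assays and clade-enrichment statistics. External
heavyweight tools (structural annotators, long-read assemblers, spliced
aligners, domain databases) are replaced by small, deterministic,
parameterized equivalents so that every stage can be validated against
planted ground truth. The package is a library first; the CLI is a thin
wrapper over the same functions.

Coordinates are 0-based half-open everywhere in memory; GFF3 writers alone
convert to 1-based closed intervals. Every operation is a pure function of
its inputs and a seed.

## Synthetic data model (simkit)

The generator *defines the study conditions*; downstream accuracy claims
are claims about these conditions.

* **Background** is i.i.d. nucleotide sequence at configurable GC (default
  0.41, a typical plant genome value). An i.i.d. background is the
  simplest null that cannot spuriously contain LTR-length direct repeats
  at the detector's identity threshold.
* **Elements.** Default census per genome (30 loci): 8 autonomous
  full-length, 2 autonomous truncated, TR subtypes 6/1/1/1/1
  (TR-GAG/TR-RT/TR-RT-RH/TR-RH/TR-INT-RT), 10 gene-like nonLTR loci of
  which 3 are GAG-host fusions — the published 56-locus composition at
  roughly half scale. LTRs are 250–600 bp, start TG / end CA, pair
  identity 0.95 (substitutions only); each element is flanked by a 4–6 bp
  target-site duplication; ≥ 1 kb background separates elements.
* **Coding content.** Internal ORFs encode the bundled consensus peptides
  through uniformly random synonymous codons — silent variation that keeps
  domains detectable at the protein level while leaving only ~70–75% DNA
  identity between loci of the same category, below every nucleotide-level
  threshold in the pipeline. Autonomous full elements carry all five
  domains in Copia (GAG-AP-INT-RT-RH) or Gypsy (GAG-AP-RT-RH-INT) order,
  chosen per element. Truncated autonomous elements carry an incomplete
  domain set split across two ORFs, so they are detected as elements but
  are neither full-length nor single-ORF TR structures.
* **Transcripts.** Element transcripts run from mid-5'-LTR to mid-3'-LTR
  in a single exon (the R-region-to-R-region mRNA of a retroelement;
  introns inside the element's coding span would contradict the genomic
  ORF contiguity that element calling relies on). Gene-like loci have
  4–10 exons with GT…AG introns of 80–400 bp, 30 bp minimum exon length
  and short UTRs. Fusion genes encode a contiguous 45–60% slice of the
  GAG consensus fused to one host domain; plain gene loci encode
  full-length GAG.
* **Reads.** Per-(locus, sample) counts are Poisson around the configured
  expectation (so RPM tests can state honest tolerances); the default
  abundance design emulates a control plus three provocative treatments,
  with ~30% of loci silent in the control. Errors are per-base
  substitution/insertion/deletion (default 3/2/2%, ~7% total, long-read
  cDNA territory); 10% of reads are 5'-truncated uniformly up to half
  their length, mimicking cDNA length bias without modeling it. Reads are
  emitted in transcript orientation (the transcript stage declares
  stranded-library logic out of scope). No homopolymer-specific error
  model, no polyA tails, no depth bias — conclusions about real ONT data
  must allow for those gaps.
* **Accessions and short reads.** Extra copies carry 0–5% random
  substitutions (inside the 80/80 envelope, never byte-identical); copy
  count 0 deletes the planted locus. Short reads are uniform, error-free,
  both strands; read count is the closed form depth·G/L.

## Sequence core

Translation uses the standard code (N → X, stops as `*`). ORF finding
reports ATG-initiated, stop-terminated (or end-truncated) ORFs in all six
frames; nested ORFs sharing a stop collapse to the longest. The default
minimum of 80 aa is below the 139-aa GAG core, so no domain-bearing ORF is
lost, while bounding spurious ORF counts.

Local alignment is Smith–Waterman with affine gaps via biopython's
`PairwiseAligner` (nucleotide: +2/−3, gap −5/−2; protein: BLOSUM62,
−11/−1); the test suite checks it against an independent quadratic Gotoh
DP. Identity counts matching columns over all alignment columns (gaps
included); query coverage is the aligned query span over the query length.
Fast edit-distance steps (consensus voting, read assignment, LTR pair
identity, copy screening) use edlib.

Anchor chaining maximizes total anchor length minus a concave gap cost
(0.01·min(gq,gt) + 0.5·log₂(1+|gt−gq|)), allows target-side gaps up to
10 kb (introns), trims small anchor overlaps (seeds crossing exon
junctions) rather than rejecting the pair, and breaks ties toward the
leftmost target position. An exhaustive subset-enumeration oracle verifies
it on small instances.

## Structural annotation

One parameterized detector replaces the union of external annotators
(whose merge rule the original protocol leaves unstated): exact 20-mers
repeated at a compatible distance are clustered by diagonal (±32) and
position (gap ≤ 200 bp), extended without gaps under an X-drop of 12, and
kept when LTR length (100–3000 bp), element length (1–18 kb) and pair
identity (≥ 0.80, edit-distance based) pass. Overlapping candidates
resolve by identity, then length, then position. TSD and TG…CA are
recorded but never required — real genomes carry degenerate elements that
strict motif filters would discard.

Domain scanning aligns each bundled consensus peptide to the query; a hit
needs ≥ 30% of that consensus' BLOSUM62 self-score. The floor is
calibrated on random-peptide nulls (empirical false-positive rate < 1%,
asserted in the suite) and passes half-length fragments (~50% of
self-score), which the domestication screen depends on. The bundled
peptide set is **synthetic** — deterministic random peptides standing in
for curated domain profiles; since planted ORFs encode these peptides,
detection behaves as it would with real profiles against real elements.
Hit sets are independent of consensus load order.

Element calling aggregates domains across internal ORFs in transcription
order (strand from the best-scoring coding ORF). Completeness requires all
five domains; superfamily requires both INT and RT.

## Transcript models

Greedy centroid clustering on k-mer containment (k = 15, threshold 0.04):
same-locus reads at 7% error share ~11% of k-mers, protein-level homologs
~0.1% — the threshold sits an order of magnitude from both. Reads are
visited longest-first; singletons are dropped. One-round majority-vote
consensus against the longest member (ties to that member; insertions
need a strict majority) replaces iterative correction; at the simulated
error rates it reaches ≥ 99% identity with 20 members.

The spliced mapper indexes 15-mers, chains anchors per strand, polishes
exon junctions by ungapped extension, and derives MQ = min(60, 6·(best −
second-best chain score)), where the second-best chain must lie at a
different locus. The MQ formula is defined here because the original
pipeline relies on an external aligner's opaque MQ; the filter boundary
(keep MQ > 30) is preserved verbatim. Identical two-copy loci map at MQ 0
and are dropped with a logged reason.

Quantification assigns each read to the best-aligning model (identity
≥ 0.75 over ≥ 50% of the read; ties discard the read, so no double
counting). RPM divides by total mapped reads per sample — the denominator
the original per-sample comparisons imply; it defaults to assigned reads
and accepts an explicit per-sample total when models cover only part of
the transcriptome. Detection is strictly RPM > 2; a sample with zero
mapped reads is an error, not a silent zero. Reported heatmap input is
log₂(RPM+1): the +1 keeps zero-RPM cells finite and is config-exposed.

## Origin classification

Decision order: (1) if ≥ 80% of the locus lies within one annotated
element, the call is LTR_RTE with the element's completeness — unless the
element is a two-LTR structure with exactly one *domain-bearing* ORF
carrying a proper subset of the five domains, which makes it TR_RTE named
`TR-<domains in genomic order>`; (2) otherwise any detected LTR within a
1 kb flank makes the locus a truncated LTR_RTE (remnant); (3) otherwise
nonLTR_RTE. The 80% overlap and 1 kb flank operationalize an intersection
rule stated without thresholds in the source protocol; both are
config-exposed, and enlarging the flank can only move calls away from
nonLTR_RTE (tested monotonicity). "One ORF" counts domain-bearing ORFs
because random internal sequence yields spurious ≥ 80-aa ORFs at a
non-negligible rate (~e^(−3.75) per ATG), which would make the literal ORF
count unstable; the structural definition of a TR element refers to its
protein-coding ORF. Multi-coding-ORF two-LTR elements fall to LTR_RTE
truncated.

Domestication candidates are nonLTR loci with ≥ 4 exons, GAG consensus
coverage < 0.8 (the "partial GAG" operationalization; published examples
show clearly sub-full-length cores) and a host-class domain in the same
ORF as the GAG fragment. All three evidence values are reported.

## Mobilome assays

80/80 counting: k-mer candidate windows on both strands, local alignment
per window, acceptance strictly above 80% identity and 80% query coverage,
greedy non-overlapping acceptance by score (split alignments of one copy
cannot count twice; merged windows are recursively re-searched so adjacent
copies are not collapsed). Counts are normalized per element by the
minimum across assemblies (minimum 0 → 1, logged). Coverage CNV divides
mean per-base element depth (reads at ≥ 90% identity over ≥ 90% of their
length) by the accession's genome-wide mean depth — global mean depth is
the normalization choice where the original pipeline's is not restated.
The CNV evidence threshold of 2-fold is the smallest integer copy gain
distinguishable from coverage noise at the default 20× depth.

## Statistics

Yates-corrected chi-square: χ² = N·max(0, |ad−bc|−N/2)² /
((a+b)(c+d)(a+c)(b+d)), p from the χ²₁ upper tail (scipy); zero margins
are an error naming the degenerate margin. The clade table uses the four
published-style numbers directly as cells — (clade expressed, expressed
total, clade genomic, genome total) — the construction verified to
reproduce printed clade statistics exactly (an exact-rational oracle and
scipy's `chi2_contingency` cross-check the implementation). A
totals-minus-counts table does not reproduce them. Benjamini–Hochberg
adjusted p-values accompany raw ones when several clades are tested; raw
values are still emitted so printed statistics remain reproducible.

Expression clustering: average-linkage on 1 − Pearson correlation of
log₂(RPM+1) rows; zero-variance rows get distance 1 to everything; labels
are relabeled deterministically in row order. Note that correlation
distance is scale-free: profile groups must differ in shape, not just
level, to separate. Condition overlap enumerates occupied condition
subsets (counts sum to transcripts detected anywhere) and reports the
treatment-only class.

## Problem sizes and numerical choices

Default validation scenarios: 300 kb genomes for unit tests; ten ~1 Mb
genomes (30 elements each) for structure-recovery acceptance; ≤ 200 kb
accession assemblies for copy counting; 20× short-read depth; 3 seeds ×
32 rows for clustering accuracy. These sizes make the full validation
suite a few minutes of single-core compute while keeping every category
populated. Chain scores break ties leftmost; consensus ties go to the
representative read's base; domain-hit overlap resolution is
score-descending and greedy. Degenerate inputs (empty genomes, empty read
sets, empty matrices, zero margins, zero depth) raise explicit errors
rather than returning silent zeros.

## Limitations

The synthetic conditions omit nested insertions, solo LTRs as background
noise, segmental duplications, realistic repeat landscapes, ONT
homopolymer error structure and expression-level dynamic range beyond the
Poisson design. A solo LTR whose element partner was lost is only found
when some detected element's LTR falls within the flank window. Lineage-
level clade labels (Ale, Tekay, …) are accepted as input metadata for the
enrichment test, never computed — protein phylogeny is out of scope.
Accuracy numbers reported by the acceptance suite are properties of the
generator's conditions; on real genomes the detector's recall depends on
element degradation far beyond the 0.95 LTR identity simulated here.
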