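# Methods

## Problem setting

A contig-level assembly is to be organized into chromosomes using (a)
sequence homology to one or more chromosome-scale reference genomes of
related lines and (b) independent localization evidence: genetic
markers used during assembly, protein homology to annotated reference
proteomes, DArT-seq loci carrying genetic-map chromosome assignments,
and BAC clones localized cytogenetically by FISH via their
sequence-tagged connectors (STCs). No single track is complete or
error-free; the pipeline's job is to combine them transparently.

## Homology placement model

The placer treats the reference as a dictionary of *unique anchors*:
k-mers (canonical form, so a k-mer and its reverse complement are one
object; k odd so no k-mer is self-complementary) that occur exactly
once across all reference chromosomes. k-mers containing N are
excluded. A contig is scanned for anchors; each anchor votes for its
chromosome of origin.

Decision rule: a contig is **placed** when total votes ≥ `min_anchors`
(default 10), the top chromosome is a strict maximum, and its vote
fraction ≥ `min_confidence` (default 0.8). Fewer than `min_anchors`
votes → **unplaced**; enough votes but a tied or insufficiently
dominant top chromosome → **ambiguous**. Defaults: `k = 21` is the
common anchor size at which random 21-mers are effectively unique in a
sub-gigabase genome while tolerating ~1% sequence divergence between
line and reference (a 21-mer straddles a substitution with probability
≈ 1 − 0.99²¹ ≈ 0.19, leaving ~80% of anchors intact); the thresholds
make exact reference substrings place with confidence 1.0 and
half-and-half chimeras come out ambiguous. Orientation is the majority
strand agreement among supporting anchors (a tie warns and defaults to
'+'); contig position is the median supporting-anchor coordinate,
robust to a minority of spurious anchor hits.

Each reference is processed in a separate run. Merging divergent
references into a single placement is deliberately unsupported:
multi-reference merges of distant lines tend to destroy chromosome-level
assignment, and disagreements between references are instead resolved
downstream as separate evidence tracks.

Placements export to AGP v2.1. Gaps between ordered contigs are written
as component type `U`, length 100, `scaffold`/`yes`/`align_genus` — the
convention common reference-guided scaffolders emit; the true gap sizes
are unknown by construction. Unplaced and ambiguous contigs become
singleton AGP objects named after themselves, which is also how
ingested external-scaffolder AGP distinguishes placed from unplaced
components (a W line whose object equals its component is unplaced).

## Consensus model

Per contig, each source is first reduced to one claim by its internal
majority over loci (internal tie → the source abstains; this is what a
"highest number of matches" rule means applied per source). Sources
then vote with weight `w(s)` (unit by default — no published basis
exists for unequal weights). The consensus is the strict argmax;
support is winning weight over total weight; every source whose claim
differs from the consensus is listed as a `(source, chromosome)`
conflict. Ties produce status `ambiguous`, absence of evidence
`no_evidence`. Duplicated records (same contig, source, chromosome,
locus) are deduplicated before voting, so consensus is invariant to
record order and duplication.

Two consensi are computed: *bioinformatics-only*, excluding the
`bac_fish` source, and *all-evidence*. Cytogenetic probe localization
is the one track not derived from sequence comparison; keeping it out
of the primary consensus lets it serve as independent validation, and
the all-evidence consensus still flags it as a conflict when it
dissents (the ctg2607 pattern in the bundled worked example).

Chromosome labels are normalized by extracting the `Chr<n>` token
(configurable regex), so reference-suffixed labels like `Chr2_9930`
and bare `Chr2` vote together.

## Locus evidence

Locus-to-assembly BLASTN hits become claims by: discarding hits below
`min_identity` (default 90%, the customary floor for accepting a
marker match); keeping each locus's best remaining hit (minimal
e-value, ties to maximal identity, then smallest contig id — the locus
table has no bitscore column, otherwise the tie-break mirrors the
protein rule); and looking the locus up in the genetic map. Protein
evidence joins each query's best subject (minimal e-value, then maximal
bitscore, maximal identity, smallest subject id) to the subject's
annotated chromosome and claims it for the query's host contig.

## Assembly statistics

N50 follows the accumulate-sorted-lengths definition (shortest contig
at which the descending cumulative sum reaches half the assembly).
Base percentages use total assembly length as denominator — N bases
count in the denominator of all four base percentages and in none of
the numerators, which is why the four percentages of gap-containing
chromosome-scale assemblies sum to well under 100. Median length uses
the midpoint convention. Percentages are exact internally and rounded
to two decimals only at presentation.

## Composition partitioning

Contigs split into placed vs unplaced (ambiguous counts as unplaced —
it has not been assigned). A gene belongs to the partition of its host
contig, regardless of overlap with AGP objects or repeats; repeat
coverage is computed from merged (union) repeat intervals per contig so
overlapping annotations are not double-counted. Merging is the default;
the CLI exposes `--no-merge` raw totals for comparison. RepeatMasker
rows flagged `*` (lower-scoring overlaps) are kept by default — merging
makes them harmless — with a reader option to drop them.

## Synthetic study

The generator emulates, at toy scale, the study design the pipeline is
meant for: 7 chromosomes of 120–160 kb (~1 Mb total), each with a
pericentromeric tandem-repeat array occupying 10% of its length built
from one of three ~180 bp unit motifs (Type-III/Type-IV tandem-unit and
rDNA-like classes, reused across chromosomes so array k-mers are never
unique). Chromosomes are cut into segments of 2–50 kb with array
boundaries respected, so repeat segments are pure repeat; segments are
renamed in shuffled order, mutated (1% substitutions, 0.05% single-base
indels) and reverse-complemented with probability 1/2 to form the
assembly contigs. Genes (140; lncRNA proportion 23% on unique contigs,
74% on repeat contigs, echoing the enrichment real unplaced partitions
show) and interspersed repeat annotations (~25% of unique-contig bases,
disjoint, with some intervals deliberately written as two overlapping
rows to exercise merging) are planted in final contig coordinates, so
the truth bookkeeping is exact by construction. Evidence tracks sample
distinct unique contigs (markers 25, DArT 30, STC 12; at most one locus
per source and contig, so each corrupted claim surfaces as exactly one
consensus conflict); claims are corrupted at rate 5% by swapping to a
uniformly random other chromosome, and every corruption is recorded in
the truth object. Protein tables draw best-hit identities across all
bins (55% exactly 100.00) and carry no injected errors — corruption
lives in the locus tracks, keeping conflict precision/recall
well-defined at the claim level.

What the generator does **not** emulate: realistic sequence evolution
(no transition/transversion bias, no structural variation between line
and reference), repeat-family divergence (array copies are identical up
to the global mutation pass), assembly artifacts (chimeric or collapsed
contigs), or genome-scale data volumes. Passing recovery tests
therefore demonstrates the correctness of the machinery under the
stated noise model, not scaffolding accuracy on real divergent genomes.

## Numerical and procedural choices

- Intervals are 0-based half-open internally; every reader/writer
  converts at the boundary. AGP records mirror their on-disk 1-based
  columns verbatim to keep round-trips byte-stable.
- All tie-breaks are total orders (documented per operation), so every
  stage is deterministic given its inputs; reports are byte-identical
  across runs with timestamps disabled (the default).
- "Identity = 100" means the tabular `pident` field parsed to exactly
  100.00; no coverage filter is imposed on top.
- Queries with no hit at all are visible as the gap between query count
  and `total_found` rather than being silently dropped.
- Recovery tests run on the default ~1 Mb generated study; that size
  keeps the unique-anchor index exact (a plain dictionary) while giving
  ~50 contigs and a few hundred evidence claims per run.
- Published whole-assembly statistics for the three public cucumber
  genomes are frozen in `ctga.pipeline.REFERENCE_ASSEMBLY_STATS`;
  `verify_reference_statistics` checks a locally provided FASTA against
  them. The genomes themselves are large external downloads and are not
  bundled.

## Known limitations

- The anchor index holds every unique k-mer in memory; fine to tens of
  megabases, not engineered for gigabase references.
- No misassembly detection: a chimeric contig is surfaced as ambiguous,
  never broken.
- Gap lengths in exported AGP are nominal (100 bp), not estimated.
- Consensus weights are global per source; there is no per-claim
  quality weighting.
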