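# Methods

## Scope and model

The package analyses one relation: an isomerase gene (*kduI* or *dhuI*)
and a reductase gene (*kduD* or *dhuD*) on the same contig within a
bounded intergenic distance. Everything else — family detection, tandem
chains, possession matrices, abundance and habitat summaries — is built
on that relation. Transcription-unit membership is explicitly out of
scope: a call asserts proximity and orientation, not co-transcription.

## Gene model and coordinates

Coordinates are 1-based and inclusive on both ends (GFF3/GenBank
convention); all internal arithmetic keeps that convention. Genes are
stored by contig coordinates regardless of strand; transcription order is
derived on demand. Within a contig genes sort by start, with ties broken
by gene id so every downstream table is deterministic. Proteins are
uppercased on input and a terminal `*` stop is stripped.

## Intergenic distance

For two genes with the leftmost gene `u` and the other `v`, the distance
is `max(0, v.start − u.end − 1)`: the number of bases strictly between
the two features, clamped at zero for overlapping or abutting genes.
Distance definitions differ by one or two bases between reasonable
conventions (end-to-start, midpoint); this one was chosen because it
counts actual intergenic bases and is symmetric. The 500-bp pairing
cutoff is compared as ≤, so a pair at exactly 500 bp is a cluster and
501 bp is not; the off-by-one sensitivity at the boundary is a property
of any convention and is covered by an explicit boundary test.

## Typing

Parallel pairs (same strand) are labelled A–H by gene content and
transcription order, upstream gene first: A *kduI–kduD*, B *kduD–kduI*,
C *dhuI–dhuD*, D *dhuD–dhuI*, E *kduI–dhuD*, F *dhuD–kduI*,
G *dhuI–kduD*, H *kduD–dhuI*. On the minus strand "upstream" is the gene
with the larger coordinate, which makes every label invariant under
reverse-complementing the contig (a property test mirrors random genomes
and asserts nothing changes).

Antiparallel pairs take the superscript-c label of the content-matched
parallel letter: for a content pair whose parallel labels are X
(isomerase first) and Y (reductase first), the divergent arrangement
(adjacent 5′ ends, genes pointing apart) is X^c and the convergent
arrangement (adjacent 3′ ends) is Y^c. This convention is isolated in
`classify_pair` so it can be flipped in one place if an authoritative
pictorial definition is adopted; antiparallel clusters are rare in real
data, so downstream counts are insensitive to the choice. Brute force
over all 32 raw (content, side, strand, strand) configurations confirms
they collapse pairwise into exactly 16 labels under reverse-complement
equivalence.

Pairing deliberately ignores intervening genes (recorded on the call) and
relative strand; only the distance cutoff filters. One gene may serve in
several calls, and tandem chains (≥3 genes, consecutive same-direction
calls sharing genes) are reported in addition to — never instead of —
their constituent pair calls, so a tandem-positive strain counts toward
both constituent types. Antiparallel calls never join chains.

## Sequence search

Two engines share one hit contract (full-sequence E-value below the
configured threshold, default 10⁻⁵):

* **Pairwise** — Smith–Waterman / Needleman–Wunsch with BLOSUM62, gap
  open 11 / extend 1 (protein-BLAST defaults; a gap of length k costs
  11 + k). Percent identity is counted over all alignment columns
  including gaps — determinate and conservative. Because raw scores of
  this scorer carry no ready-made statistics, E-values come from a seeded
  Gumbel fit to the scores of residue-shuffled decoy pairs drawn from the
  target database (default 200 decoys): E(S) = K·m·N·exp(−λS). The fit is
  deterministic per seed and refuses degenerate (constant) score
  distributions. Residues outside the 20-letter alphabet map to X, which
  scores 0 against everything. Global identity is made symmetric by
  canonicalizing the argument order before aligning, since co-optimal
  alignments can differ in column count.
* **Profile** — profile HMMs compiled from the aligned query set
  (match states at columns with <50% gaps, pseudocount-smoothed log-odds
  emissions) and searched with full-sequence E-values against the
  protein database; the profile machinery is HMMER's, driven through
  pyhmmer, with the database size pinned to the number of target
  sequences and the serialized profile's timestamp pinned so outputs are
  byte-reproducible. The multiple alignment behind a profile is MAFFT
  (`--auto`), the standard choice for protein query sets of this size;
  a single-query set skips alignment.

## Iterative query selection

Each family starts from one seed protein. Per round, the current query is
searched against the remaining pool; candidates at ≥97% global identity
to *any* already-selected query are excluded (applying the redundancy
filter against all previous queries, not only the current one, prevents
near-duplicate accumulation); the surviving hit with the lowest E-value
(ties: higher score, then lexicographic id) becomes the next query and
leaves the pool. Twenty rounds yield up to 21 queries; exhaustion before
that is recorded, not an error. The candidate set is each round's own hit
list, not a cumulative pool across rounds — the simplest reading of a
single-query-per-round procedure; with a reasonably dense family ladder
the two readings select the same sequences. Selection is fully
deterministic given the inputs.

## Family assignment and possession

The two reductase families are homologous (both SDRs), so their profiles
cross-react; a best-hit rule keeps each gene in exactly one family:
minimum E-value, ties by higher score, then a fixed family priority
(kduI, dhuI, kduD, dhuD, ugl, ogl, yteR, kdgA, kdgK, kdgF). Genes whose
best E-value misses the threshold stay unassigned. Copy counts are kept
uncapped — real genomes show extreme duplications, and capping would hide
them. Co-occurrence ratios are reported with explicit numerator and
denominator, per strain by default and per cluster as a variant (the two
differ when strains carry several clusters); zero denominators give NaN,
never 0. Separate-loci accounting restricts to cluster-negative strains
and cross-tabulates the four core families.

## Abundance and habitat summaries

Per sample, the abundance of a cluster type is the summed relative
abundance of strains positive for that type; a strain with two types
contributes to both (deliberate double counting that mirrors per-type
reporting). The omnibus test across types is Kruskal–Wallis; the focal
type (highest median, or caller-specified) is compared to each other type
with a paired two-sided Wilcoxon signed-rank test, since the same samples
underlie every type. Both per-sample sums and cohort means are emitted.
Habitat scores are averaged per type over type-positive strains;
categories are kept when some type's mean exceeds 10, and each cell is
flagged above/below the per-category mean across types.

The representative 16S sequence is chosen by greedy centroid clustering
at 90% global nucleotide identity (match +1, mismatch −1, gap open 2,
extend 1, threshold compared as ≥): sequences are processed
longest-first (ties by id) — the standard centroid-clustering order —
each joining the first centroid it matches, else founding a cluster; the
centroid of the largest cluster wins, size ties going to the longer
centroid, then lexicographic id.

## Synthetic data

The generators emulate exactly what the pipeline consumes. Planted
proteins are seed copies mutated at uniformly chosen positions
(preferring substitutions with non-negative BLOSUM62 score) until the
ungapped identity hits the target ±1 point; decoys are residue-shuffled
seeds, preserving composition while destroying homology. Gene lengths
are drawn from 600–1500 bp (typical bacterial CDS); intervening
cupin-like genes from 270–360 bp. Planted cluster pairs are self-checked
at generation time: the emitted genes must classify to the requested
label with the requested gap. Cohorts draw per-strain phylum and
per-type presence (independent Bernoulli by default); the alternative
matched design plants an exact number of positive strains per type on
disjoint strains, which is the correct null for abundance comparisons —
with unequal positive-strain counts the per-type sums differ even
without any enrichment, so Bernoulli cohorts cannot calibrate the test.
Abundance tables are per-sample log-normal draws (σ = 1), scaled by the
enrichment fold for strains carrying an enriched type, and normalized to
sum to one per sample.

What the generators do **not** emulate: real sequence divergence (mutated
seeds lack indels, domain shuffling and composition drift, so synthetic
"40% identity" is easier to detect than natural 40% identity), nucleotide
sequence (proteins are the payload; no codon structure), pseudogenes,
assembly fragmentation, and annotation errors. Passing tests therefore
demonstrate the correctness of the algorithms and bookkeeping, not the
sensitivity of profile search on natural remote homologs. Relatedly,
because conservative-substitution mutants remain easy targets, the
query-broadening benefit is asserted as an E-value improvement of the
broadened profile over the seed-only profile on a remote family member,
rather than as a detect/miss dichotomy.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
instances — cohorts of 6–40 strains, 200 single-cluster genomes for
boundary recovery, 100 genomes for mirror invariance, 60-member families
for query selection, 50-sample abundance cohorts with 20 null
replicates — sizes at which every stage's expected output is exactly
enumerable from the planted truth. Every random draw flows through an
explicit integer seed (numpy Generators; derived sub-seeds stay below
2³¹), and repeated runs are byte-identical, including serialized
profiles.

## Known limitations

* The pairwise E-value calibration is a small-sample Gumbel fit; its
  absolute E-values are approximate (decoy-count-limited), which is
  acceptable because thresholding at 10⁻⁵ sits far from the fitted
  bulk.
* The antiparallel letter convention is a defined choice (see Typing).
* Full-genome-scale behaviour (thousands of genomes, cross-reacting
  natural paralogs, 146-copy duplications) is supported by the data
  structures but not exercised by the bundled synthetic scales.
* `profile_search` accepts a pairwise-style calibration argument for
  interface parity but uses the profile's own statistics.
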