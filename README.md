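# gagclust

Detection, typing and comparative analysis of bacterial gene clusters that
encode the two-step assimilation of 4-deoxy-L-*threo*-5-hexosulose uronate
(DHU), the common intermediate of glycosaminoglycan (GAG) and pectin
breakdown.

## The problem

Two unrelated protein families isomerize DHU — KduI (cupin-like) and DhuI
(RpiB-like) — making them *nonhomologous isofunctional* enzymes, and two
divergent short-chain dehydrogenase–reductases (KduD, DhuD; ~42% mutual
identity) reduce the product. In many genomes one isomerase gene and one
reductase gene sit next to each other. With two isomerases, two
reductases, two gene orders and two relative orientations there are 16
possible cluster configurations: types A–H when both genes point the same
way (A *kduI–kduD*, B *kduD–kduI*, C *dhuI–dhuD*, D *dhuD–dhuI*,
E *kduI–dhuD*, F *dhuD–kduI*, G *dhuI–kduD*, H *kduD–dhuI*, upstream gene
first) and A^c–H^c for antiparallel arrangements. Which configurations
exist, in which phyla, with what gene spacing, and alongside which
DHU-producing enzymes (UGL, OGL, YteR) and auxiliary genes (*kdgF*,
*kdgA*, *kdgK*) is the question this package answers for any collection
of annotated genomes.

## What the package does

* **Family detection** — for each of the ten gene families, an iterative
  query-selection loop (search with the current query, keep hits with
  full-sequence E < 10⁻⁵, take the lowest-E hit that is <97% identical to
  every query selected so far, repeat 20 rounds → up to 21 queries), then
  a profile HMM built from the aligned queries and searched against every
  annotated protein.
* **Cluster typing** — every isomerase–reductase pair on one contig with
  an intergenic distance ≤500 bp is a cluster call, classified into the 16
  types; intervening genes are recorded, not disqualifying (type H often
  carries a small cupin gene inside the gap). Overlapping calls that share
  a gene are additionally reported as tandem chains (e.g.
  *kduI–kduD–dhuI* = types A + H).
* **Inventories and summaries** — best-hit family assignment, strain ×
  family/type possession matrix, co-occurrence ratios with the auxiliary
  families, separate-loci accounting for cluster-negative strains,
  type × phylum tables, relative-abundance sums per type with
  Kruskal–Wallis/Wilcoxon rank tests, habitat-score means per type, and
  the greedy 90%-identity centroid rule for picking a representative 16S
  rRNA sequence.
* **Synthetic data** — generators for annotated genomes with planted
  clusters (any type, gap, intervening genes, decoy paralogs), strain
  cohorts with phylum labels and per-type frequencies, and abundance
  tables with a planted per-type enrichment — every pipeline stage is
  testable offline with exact ground truth.

## Worked example

```python
from gagclust import Config, find_pairs, merge_tandem
from gagclust.synthetic import ClusterPlan, synth_genome
from gagclust.cluster_typing import ClusterTypeLabel

# plant a type-A cluster (kduI 99 bp upstream of kduD) and recover it
plan = ClusterPlan(label=ClusterTypeLabel("A"), gap_bp=99)
ann, truth = synth_genome("demo", [plan], rng_seed=0)
calls = find_pairs(ann, truth.families, Config())
for c in calls:
    print(c.label.render(), c.gap_bp, c.iso_family, c.red_family)
```

prints

```
A 99 kduI kduD
```

one call of type A at the planted 99-bp spacing. The full pipeline over a
directory of genomes (GFF3 + protein FASTA, or a flat gene table) runs as

```bash
gagclust run-all --annotations genomes/ --seeds seeds.faa \
    --lineages lineages.tsv -o results/
```

writing per-stage TSVs (queries, profiles, hits, assignments, calls,
tandems, distance tables, possession matrix, co-occurrence ratios,
separate-loci counts, type × phylum tables) plus a `manifest.json` with
config and input checksums. `seeds.faa` holds one seed protein per family
(ids `kduI`, `kduD`, `dhuI`, `dhuD`, `ugl`, `ogl`, `yteR`, `kdgA`,
`kdgK`, `kdgF`), e.g. the published reference sequences for each family.

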