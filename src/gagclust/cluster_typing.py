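"""Pairing and typing of isomerase-reductase gene clusters.

A cluster is one DHU-isomerase gene (*kduI* or *dhuI*) and one DK-II
reductase gene (*kduD* or *dhuD*) on the same contig separated by at most
``Config.cluster_gap_bp`` (default 500 bp), regardless of intervening
genes or relative strand.  Every such pair is classified into one of 16
configurations:

* parallel pairs (both genes transcribed in the same direction) are
  labelled ``A``-``H`` by gene content and transcription order:
  A kduI-kduD, B kduD-kduI, C dhuI-dhuD, D dhuD-dhuI, E kduI-dhuD,
  F dhuD-kduI, G dhuI-kduD, H kduD-dhuI (upstream gene named first);
* antiparallel pairs get the ``c`` superscript of the content-matched
  parallel letter: for a content pair whose parallel labels are X
  (isomerase first) and Y (reductase first), the divergent arrangement
  (adjacent 5' ends, genes pointing away from each other) is X^c and the
  convergent arrangement (adjacent 3' ends) is Y^c.

Three-gene tandem arrangements (e.g. kduI-kduD-dhuI) arise when two pair
calls share a gene; they are reported in addition to the pair calls, so a
tandem-positive strain counts toward both constituent types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import Config, Gene, GenomeAnnotation

ISOMERASES = ("kduI", "dhuI")
REDUCTASES = ("kduD", "dhuD")
CORE_FAMILIES = ISOMERASES + REDUCTASES

# transcription order (upstream family, downstream family) -> letter
PARALLEL_ORDER: dict[tuple[str, str], str] = {
    ("kduI", "kduD"): "A",
    ("kduD", "kduI"): "B",
    ("dhuI", "dhuD"): "C",
    ("dhuD", "dhuI"): "D",
    ("kduI", "dhuD"): "E",
    ("dhuD", "kduI"): "F",
    ("dhuI", "kduD"): "G",
    ("kduD", "dhuI"): "H",
}
ORDER_FROM_LETTER = {v: k for k, v in PARALLEL_ORDER.items()}


class TypingError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ClusterTypeLabel:
    """One of the 16 cluster configurations, rendered 'A'..'H' / 'Ac'..'Hc'."""

    letter: str
    antiparallel: bool = False

    def __post_init__(self) -> None:
        if self.letter not in "ABCDEFGH" or len(self.letter) != 1:
            raise TypingError(f"letter must be A..H, got {self.letter!r}")

    def render(self) -> str:
        return self.letter + ("c" if self.antiparallel else "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "ClusterTypeLabel":
        text = text.strip()
        if len(text) == 2 and text[1] == "c":
            return cls(text[0], True)
        return cls(text, False)


ALL_LABELS: tuple[ClusterTypeLabel, ...] = tuple(
    ClusterTypeLabel(letter, anti)
    for anti in (False, True)
    for letter in "ABCDEFGH"
)


@dataclass(frozen=True)
class ClusterCall:
    """A typed isomerase-reductase pair."""

    genome_id: str
    contig_id: str
    iso_gene: Gene
    iso_family: str
    red_gene: Gene
    red_family: str
    label: ClusterTypeLabel
    gap_bp: int
    intervening_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.iso_gene.contig_id != self.red_gene.contig_id:
            raise TypingError("paired genes must share a contig")
        if self.gap_bp < 0:
            raise TypingError("gap must be >= 0")


@dataclass(frozen=True)
class TandemCluster:
    """A chain of >=3 genes forming overlapping pair calls."""

    genome_id: str
    contig_id: str
    gene_ids: tuple[str, ...]
    chain_string: str
    constituent_labels: tuple[ClusterTypeLabel, ...]


def intergenic_gap(g1: Gene, g2: Gene) -> int:
    """Distance in bp between two genes; overlapping or abutting genes -> 0."""
    if g1.contig_id != g2.contig_id:
        raise TypingError(
            f"genes {g1.gene_id} and {g2.gene_id} are on different contigs"
        )
    u, v = sorted((g1, g2), key=lambda g: (g.start, g.gene_id))
    return max(0, v.start - u.end - 1)


def classify_pair(
    iso: Gene, iso_family: str, red: Gene, red_family: str
) -> ClusterTypeLabel:
    """Classify an isomerase-reductase pair into one of the 16 labels."""
    if iso_family not in ISOMERASES:
        raise TypingError(f"{iso_family!r} is not an isomerase family")
    if red_family not in REDUCTASES:
        raise TypingError(f"{red_family!r} is not a reductase family")
    if iso.contig_id != red.contig_id:
        raise TypingError("paired genes must share a contig")

    left, right = sorted(
        ((iso, iso_family), (red, red_family)),
        key=lambda t: (t[0].start, t[0].gene_id),
    )
    if iso.strand == red.strand:
        # transcription order: left-to-right on '+', right-to-left on '-'
        if iso.strand == "+":
            order = (left[1], right[1])
        else:
            order = (right[1], left[1])
        return ClusterTypeLabel(PARALLEL_ORDER[order], antiparallel=False)
    # antiparallel: divergent (<- ->) takes the isomerase-first letter,
    # convergent (-> <-) the reductase-first letter
    divergent = left[0].strand == "-"
    order = (iso_family, red_family) if divergent else (red_family, iso_family)
    return ClusterTypeLabel(PARALLEL_ORDER[order], antiparallel=True)


def enumerate_configurations() -> list[ClusterTypeLabel]:
    """All 16 distinct labels, obtained by brute force over the 32 raw
    (isomerase, reductase, left/right, strand, strand) configurations."""
    labels = set()
    for iso_fam in ISOMERASES:
        for red_fam in REDUCTASES:
            for iso_left in (True, False):
                for iso_strand in "+-":
                    for red_strand in "+-":
                        a = Gene("iso", "c", 100, 1000, iso_strand)
                        b = Gene("red", "c", 1200, 2000, red_strand)
                        iso, red = (a, b) if iso_left else (b, a)
                        labels.add(classify_pair(iso, iso_fam, red, red_fam))
    return sorted(labels, key=lambda l: (l.antiparallel, l.letter))


def find_pairs(
    ann: GenomeAnnotation,
    families: Mapping[str, str],
    cfg: Config = Config(),
) -> list[ClusterCall]:
    """All isomerase-reductase pairs within the gap cutoff.

    ``families`` maps gene_id -> family name.  Pairing ignores relative
    strand and intervening genes (which are recorded on the call); a gene
    may take part in several calls.
    """
    by_contig: dict[str, list[Gene]] = {}
    for g in ann.genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    calls: list[ClusterCall] = []
    for contig_id, genes in sorted(by_contig.items()):
        isos = [g for g in genes if families.get(g.gene_id) in ISOMERASES]
        reds = [g for g in genes if families.get(g.gene_id) in REDUCTASES]
        for iso in isos:
            for red in reds:
                gap = intergenic_gap(iso, red)
                if gap > cfg.cluster_gap_bp:
                    continue
                label = classify_pair(
                    iso, families[iso.gene_id], red, families[red.gene_id]
                )
                u, v = sorted((iso, red), key=lambda g: (g.start, g.gene_id))
                intervening = tuple(
                    g.gene_id
                    for g in genes
                    if g.gene_id not in (iso.gene_id, red.gene_id)
                    and g.start > u.end
                    and g.end < v.start
                )
                calls.append(
                    ClusterCall(
                        genome_id=ann.genome_id,
                        contig_id=contig_id,
                        iso_gene=iso,
                        iso_family=families[iso.gene_id],
                        red_gene=red,
                        red_family=families[red.gene_id],
                        label=label,
                        gap_bp=gap,
                        intervening_gene_ids=intervening,
                    )
                )
    calls.sort(
        key=lambda c: (
            c.contig_id,
            min(c.iso_gene.start, c.red_gene.start),
            c.iso_gene.gene_id,
            c.red_gene.gene_id,
        )
    )
    return calls


def merge_tandem(calls: Sequence[ClusterCall]) -> list[TandemCluster]:
    """Maximal chains of same-direction calls sharing genes (length >= 3).

    Antiparallel calls never join a chain.  Pair calls are preserved; a
    tandem is reported in addition, carrying its constituent labels.
    """
    parallel = [c for c in calls if not c.label.antiparallel]
    groups: dict[tuple[str, str, str], list[ClusterCall]] = {}
    for c in parallel:
        groups.setdefault((c.genome_id, c.contig_id, c.iso_gene.strand), []).append(c)

    tandems: list[TandemCluster] = []
    for (genome_id, contig_id, strand), group in sorted(groups.items()):
        # union-find over gene ids through shared-call edges
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        genes_by_id: dict[str, tuple[Gene, str]] = {}
        for c in group:
            for g, fam in ((c.iso_gene, c.iso_family), (c.red_gene, c.red_family)):
                genes_by_id[g.gene_id] = (g, fam)
                parent.setdefault(g.gene_id, g.gene_id)
            ra, rb = find(c.iso_gene.gene_id), find(c.red_gene.gene_id)
            if ra != rb:
                parent[ra] = rb

        components: dict[str, list[str]] = {}
        for gid in parent:
            components.setdefault(find(gid), []).append(gid)

        for members in components.values():
            if len(members) < 3:
                continue
            genes = sorted(
                (genes_by_id[gid] for gid in members),
                key=lambda t: (t[0].start, t[0].gene_id),
            )
            if strand == "-":
                genes = genes[::-1]  # transcription order
            chain_ids = tuple(g.gene_id for g, _ in genes)
            chain_string = "-".join(fam for _, fam in genes)
            member_set = set(members)
            constituents = tuple(
                c.label
                for c in group
                if c.iso_gene.gene_id in member_set
                and c.red_gene.gene_id in member_set
            )
            tandems.append(
                TandemCluster(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    gene_ids=chain_ids,
                    chain_string=chain_string,
                    constituent_labels=constituents,
                )
            )
    tandems.sort(key=lambda t: (t.genome_id, t.contig_id, t.gene_ids))
    return tandems


@dataclass
class DistanceTable:
    """Per-label intergenic-distance summaries."""

    stats: pd.DataFrame  # index label; count, median, q1, q3
    histogram: pd.DataFrame  # index bin_start; one column per label


def distance_table(calls: Sequence[ClusterCall], cfg: Config = Config()) -> DistanceTable:
    """Count, quartiles (gaps <= cluster_gap_bp) and a 50-bp histogram
    (gaps <= plot_gap_bp) of intergenic distances per label."""
    if not calls:
        return DistanceTable(
            stats=pd.DataFrame(columns=["count", "median", "q1", "q3"]),
            histogram=pd.DataFrame(),
        )
    rows = [(c.label.render(), c.gap_bp) for c in calls]
    df = pd.DataFrame(rows, columns=["label", "gap_bp"])

    within = df[df.gap_bp <= cfg.cluster_gap_bp]
    stats = within.groupby("label")["gap_bp"].agg(
        count="size", median="median", q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    )

    bins = np.arange(0, cfg.plot_gap_bp + 50, 50)
    hist_src = df[df.gap_bp <= cfg.plot_gap_bp]
    hist = {}
    for label, sub in hist_src.groupby("label"):
        counts, _ = np.histogram(sub.gap_bp, bins=bins)
        hist[label] = counts
    histogram = pd.DataFrame(hist, index=pd.Index(bins[:-1], name="bin_start"))
    return DistanceTable(stats=stats, histogram=histogram)


def calls_to_frame(calls: Iterable[ClusterCall]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "contig_id": c.contig_id,
            "iso_gene": c.iso_gene.gene_id,
            "iso_family": c.iso_family,
            "red_gene": c.red_gene.gene_id,
            "red_family": c.red_family,
            "label": c.label.render(),
            "gap_bp": c.gap_bp,
            "intervening": ",".join(c.intervening_gene_ids),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "contig_id", "iso_gene", "iso_family",
            "red_gene", "red_family", "label", "gap_bp", "intervening",
        ],
    )


def tandems_to_frame(tandems: Iterable[TandemCluster]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": t.genome_id,
            "contig_id": t.contig_id,
            "genes": ",".join(t.gene_ids),
            "chain": t.chain_string,
            "constituent_labels": ",".join(l.render() for l in t.constituent_labels),
        }
        for t in tandems
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "genes", "chain", "constituent_labels"]
    )
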