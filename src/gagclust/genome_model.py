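"""Data model and I/O for annotated bacterial genomes.

The atom of every downstream analysis is the :class:`Gene`: an annotated
coding feature with 1-based inclusive contig coordinates, a strand, and the
protein it encodes.  A :class:`GenomeAnnotation` holds the genes of one
assembly sorted by ``(contig_id, start, gene_id)`` so that neighbourhood
scans and all tabular outputs are deterministic.

Two on-disk representations are supported and round-trip exactly:

* GFF3 (CDS features with ``ID`` attributes) plus a protein FASTA whose
  record ids match those attributes;
* a flat TSV gene table with columns ``genome_id, contig_id, gene_id,
  start, end, strand, protein`` — the native format of the synthetic-data
  generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

GENE_TABLE_COLUMNS = [
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "protein",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass(frozen=True)
class Gene:
    """An annotated coding feature.

    Coordinates follow the GFF3/GenBank convention: 1-based, inclusive on
    both ends.  ``protein`` may be empty for features without an attached
    translation.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise AnnotationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """All genes of one genome, sorted by (contig_id, start, gene_id)."""

    genome_id: str
    contigs: dict[str, int] = field(default_factory=dict)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(
                    f"{self.genome_id}: duplicate gene id {g.gene_id}"
                )
            seen.add(g.gene_id)
            if self.contigs:
                if g.contig_id not in self.contigs:
                    raise AnnotationError(
                        f"{self.genome_id}: gene {g.gene_id} references unknown "
                        f"contig {g.contig_id}"
                    )
                if g.end > self.contigs[g.contig_id]:
                    raise AnnotationError(
                        f"{self.genome_id}: gene {g.gene_id} ends at {g.end}, past "
                        f"contig {g.contig_id} length {self.contigs[g.contig_id]}"
                    )
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, contig_id: str) -> list[Gene]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def proteins(self) -> dict[str, str]:
        """gene_id -> protein for every gene with a non-empty translation."""
        return {g.gene_id: g.protein for g in self.genes if g.protein}


@dataclass(frozen=True)
class TaxonomyLineage:
    """Lineage of one genome; any rank may be empty."""

    genome_id: str
    phylum: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise AnnotationError("lineage requires a non-empty genome_id")


@dataclass(frozen=True)
class Config:
    """Pipeline thresholds.

    evalue_threshold
        Full-sequence E-value cutoff for homology calls (default 1e-5).
    identity_threshold
        Percent identity below which a hit is non-redundant with already
        selected queries (default 97.0).
    selection_rounds
        Number of query-selection iterations; the final query set holds at
        most ``selection_rounds + 1`` sequences (default 20 -> 21 queries).
    cluster_gap_bp
        Maximum intergenic distance for an isomerase-reductase pair to be
        called a cluster (default 500).
    plot_gap_bp
        Histogram cutoff for the distance summaries (default 1000).
    rep16s_identity
        Percent identity threshold for greedy 16S centroid clustering
        (default 90.0).
    """

    evalue_threshold: float = 1e-5
    identity_threshold: float = 97.0
    selection_rounds: int = 20
    cluster_gap_bp: int = 500
    plot_gap_bp: int = 1000
    rep16s_identity: float = 90.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        for name in ("identity_threshold", "rep16s_identity"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        for name in ("selection_rounds", "cluster_gap_bp", "plot_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kw) -> "Config":
        return replace(self, **kw)


def _clean_protein(seq: str) -> str:
    seq = seq.upper()
    return seq[:-1] if seq.endswith("*") else seq


def _validate_gff_syntax(gff_path: Path) -> None:
    """Light syntax check: every feature line needs 9 tab-separated fields
    with integer coordinates (errors name the offending line)."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gff_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{gff_path}: line {lineno}: non-integer coordinates"
                ) from exc


def read_annotation(
    gff_path: str | Path,
    protein_fasta_path: str | Path,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GFF3 CDS features + protein FASTA.

    Features without a matching FASTA record keep an empty protein and are
    logged; FASTA records without a matching feature are ignored with a
    warning.  Proteins are uppercased and a terminal ``*`` is stripped.
    """
    gff_path = Path(gff_path)
    if genome_id is None:
        genome_id = gff_path.stem
    _validate_gff_syntax(gff_path)
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationError(f"{gff_path}: malformed GFF3 ({exc})") from exc

    proteins = {
        rec.id: _clean_protein(str(rec.seq))
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta")
    }

    contigs: dict[str, int] = {}
    for region in db.features_of_type(("region", "contig", "chromosome")):
        contigs[region.seqid] = region.end

    genes: list[Gene] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        fid = feat.attributes.get("ID", [feat.id])[0]
        if fid in seen:
            raise AnnotationError(f"{gff_path}: duplicate gene ID {fid}")
        seen.add(fid)
        if feat.strand not in STRANDS:
            raise AnnotationError(f"{gff_path}: CDS {fid} has no strand")
        protein = proteins.get(fid, "")
        if not protein:
            logger.warning("%s: CDS %s has no matching protein record", genome_id, fid)
        genes.append(
            Gene(
                gene_id=fid,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                protein=protein,
            )
        )

    unmatched = set(proteins) - seen
    if unmatched:
        logger.warning(
            "%s: %d FASTA record(s) without a CDS feature ignored: %s",
            genome_id,
            len(unmatched),
            ", ".join(sorted(unmatched)[:5]),
        )
    if not contigs:
        # fall back to per-contig max end so invariants still hold
        for g in genes:
            contigs[g.contig_id] = max(contigs.get(g.contig_id, 0), g.end)
    return GenomeAnnotation(genome_id=genome_id, contigs=contigs, genes=genes)


def read_gene_table(tsv_path: str | Path) -> list[GenomeAnnotation]:
    """Read the flat TSV gene table; returns one annotation per genome_id."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(
            f"{tsv_path}: missing column(s) {', '.join(sorted(missing))}"
        )
    annotations = []
    for genome_id, sub in df.groupby("genome_id", sort=True):
        genes = []
        for row in sub.itertuples(index=False):
            try:
                start, end = int(row.start), int(row.end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{tsv_path}: non-integer coordinate for gene "
                    f"{row.gene_id}: {exc}"
                ) from exc
            genes.append(
                Gene(
                    gene_id=row.gene_id,
                    contig_id=row.contig_id,
                    start=start,
                    end=end,
                    strand=row.strand,
                    protein=_clean_protein(row.protein),
                )
            )
        annotations.append(GenomeAnnotation(genome_id=str(genome_id), genes=genes))
    return annotations


def write_gene_table(
    annotations: Iterable[GenomeAnnotation], tsv_path: str | Path
) -> None:
    rows = [
        (ann.genome_id, g.contig_id, g.gene_id, g.start, g.end, g.strand, g.protein)
        for ann in annotations
        for g in ann.genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False
    )


def read_lineage_table(tsv_path: str | Path) -> dict[str, TaxonomyLineage]:
    """TSV with columns genome_id, phylum, family, genus, species (extra ignored)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    if "genome_id" not in df.columns:
        raise AnnotationError(f"{tsv_path}: missing genome_id column")
    out = {}
    for row in df.itertuples(index=False):
        lin = TaxonomyLineage(
            genome_id=row.genome_id,
            phylum=getattr(row, "phylum", ""),
            family=getattr(row, "family", ""),
            genus=getattr(row, "genus", ""),
            species=getattr(row, "species", ""),
        )
        out[lin.genome_id] = lin
    return out


def write_lineage_table(
    lineages: Mapping[str, TaxonomyLineage], tsv_path: str | Path
) -> None:
    rows = [
        (l.genome_id, l.phylum, l.family, l.genus, l.species)
        for l in lineages.values()
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "phylum", "family", "genus", "species"]
    ).sort_values("genome_id").to_csv(tsv_path, sep="\t", index=False)
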