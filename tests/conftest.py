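from __future__ import annotations

import numpy as np
import pytest

from gagclust.genome_model import Config, Gene, GenomeAnnotation
from gagclust.synthetic import default_family_seeds


@pytest.fixture(scope="session")
def family_seeds() -> dict[str, str]:
    return default_family_seeds()


@pytest.fixture
def cfg() -> Config:
    return Config()


def make_gene(gene_id, start, end, strand="+", contig="chr", protein=""):
    return Gene(gene_id=gene_id, contig_id=contig, start=start, end=end,
                strand=strand, protein=protein)


def make_annotation(genome_id, genes):
    return GenomeAnnotation(genome_id=genome_id, genes=list(genes))


def mirror_annotation(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Reverse-complement every contig: reflect coordinates, flip strands."""
    flipped = []
    for g in ann.genes:
        L = ann.contigs[g.contig_id]
        flipped.append(
            Gene(
                gene_id=g.gene_id,
                contig_id=g.contig_id,
                start=L - g.end + 1,
                end=L - g.start + 1,
                strand="-" if g.strand == "+" else "+",
                protein=g.protein,
            )
        )
    return GenomeAnnotation(
        genome_id=ann.genome_id, contigs=dict(ann.contigs), genes=flipped
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
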