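"""End-to-end orchestration of the cluster-mining pipeline.

Stages (in order): iterative query selection per family -> multiple
alignment and profile build -> profile search over all annotated
proteins -> best-hit family assignment -> pair finding and typing ->
tandem detection -> possession matrix -> co-occurrence ratios ->
separate-loci accounting -> type x phylum summary, plus the optional
abundance, habitat and representative-16S stages when their inputs are
given.  Stages communicate through documented TSVs so any stage can be
rerun independently; a manifest records the config, input checksums and
output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .cluster_typing import (
    ClusterCall,
    calls_to_frame,
    distance_table,
    find_pairs,
    merge_tandem,
    tandems_to_frame,
)
from .genome_model import (
    Config,
    GenomeAnnotation,
    TaxonomyLineage,
    read_annotation,
    read_gene_table,
    read_lineage_table,
)
from .inventory import (
    FAMILIES,
    assign_families,
    assignments_to_frame,
    cooccurrence_ratios,
    possession_matrix,
    separate_loci,
)
from .query_selection import family_profile, select_queries, write_queries_fasta
from .seqsearch import PairwiseSearchEngine, profile_search, write_hits_tsv
from .summaries import abundance_by_type, habitat_by_type, select_rep_16s, type_by_phylum

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256
    outputs: dict[str, str]  # stage name -> path
    version: str = __version__
    rng_seed: int = 0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_annotations(path: str | Path) -> list[GenomeAnnotation]:
    """Load genomes from a flat gene table (.tsv) or a directory of
    paired ``<genome>.gff3`` + ``<genome>.faa`` files."""
    path = Path(path)
    if path.is_file():
        return read_gene_table(path)
    annotations = []
    for gff in sorted(path.glob("*.gff3")) + sorted(path.glob("*.gff")):
        faa = gff.with_suffix(".faa")
        if not faa.exists():
            raise PipelineError(f"missing protein FASTA for {gff}")
        annotations.append(read_annotation(gff, faa))
    if not annotations:
        raise PipelineError(f"no annotations found under {path}")
    return annotations


def read_seed_fasta(path: str | Path) -> dict[str, str]:
    """Seed FASTA: record ids are family names (kduI, kduD, ...)."""
    seeds = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fam = rec.id
        if fam not in FAMILIES:
            raise PipelineError(
                f"seed record {fam!r} is not one of the known families"
            )
        seeds[fam] = str(rec.seq).upper().rstrip("*")
    if not seeds:
        raise PipelineError(f"no seed sequences in {path}")
    return seeds


def pooled_proteins(annotations: Sequence[GenomeAnnotation]) -> dict[str, str]:
    """All proteins across genomes, keyed ``genome_id|gene_id``."""
    pool = {}
    for ann in annotations:
        for gid, prot in ann.proteins().items():
            pool[f"{ann.genome_id}|{gid}"] = prot
    return pool


def run_all(
    annotations: Sequence[GenomeAnnotation] | str | Path,
    seeds: Mapping[str, str] | str | Path,
    out_dir: str | Path,
    lineages: Mapping[str, TaxonomyLineage] | str | Path | None = None,
    cfg: Config = Config(),
    abundance: pd.DataFrame | str | Path | None = None,
    habitat: pd.DataFrame | str | Path | None = None,
    sixteen_s: Mapping[str, Mapping[str, str]] | None = None,
) -> RunManifest:
    """Run every stage over the given genomes and write all outputs.

    ``sixteen_s`` maps genome_id -> {seq_id: nucleotide sequence} for the
    representative-16S stage.  A missing lineage table degrades the
    type-by-phylum stage to a single ``unclassified`` column.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    stage = "load_annotations"
    try:
        if isinstance(annotations, (str, Path)):
            p = Path(annotations)
            if p.is_file():
                inputs[str(p)] = _sha256(p)
            annotations = load_annotations(p)
        annotations = list(annotations)
        if isinstance(seeds, (str, Path)):
            inputs[str(seeds)] = _sha256(seeds)
            seeds = read_seed_fasta(seeds)
        if isinstance(lineages, (str, Path)):
            inputs[str(lineages)] = _sha256(lineages)
            lineages = read_lineage_table(lineages)
        if isinstance(abundance, (str, Path)):
            inputs[str(abundance)] = _sha256(abundance)
            abundance = pd.read_csv(abundance, sep="\t", index_col=0)
        if isinstance(habitat, (str, Path)):
            inputs[str(habitat)] = _sha256(habitat)
            habitat = pd.read_csv(habitat, sep="\t", index_col=0)
        if lineages is None:
            logger.warning("no lineage table: phylum summaries use 'unclassified'")
            lineages = {}

        outputs: dict[str, str] = {}
        pool = pooled_proteins(annotations)
        genome_ids = [a.genome_id for a in annotations]

        stage = "select_queries"
        engine = PairwiseSearchEngine()
        if pool:
            engine.calibrate(pool, seed=cfg.rng_seed)
        (out / "queries").mkdir(exist_ok=True)
        (out / "profiles").mkdir(exist_ok=True)
        all_hits = []
        for fam in FAMILIES:
            if fam not in seeds:
                continue
            qs = select_queries(seeds[fam], fam, pool, cfg, engine=engine)
            qpath = out / "queries" / f"{fam}.faa"
            write_queries_fasta(qs, qpath)
            outputs[f"queries/{fam}"] = str(qpath)

            stage = "family_profile"
            profile = family_profile(qs)
            ppath = out / "profiles" / f"{fam}.hmm"
            profile.save(ppath)
            outputs[f"profiles/{fam}"] = str(ppath)

            stage = "profile_search"
            all_hits.extend(profile_search(profile, pool, cfg.evalue_threshold))

        hits_path = out / "hits.tsv"
        write_hits_tsv(all_hits, hits_path)
        outputs["hits"] = str(hits_path)

        stage = "assign_families"
        assignments = []
        for a in assign_families(all_hits, cfg):
            genome_id, gene_id = a.gene_id.split("|", 1)
            assignments.append(
                dataclasses.replace(a, genome_id=genome_id, gene_id=gene_id)
            )
        apath = out / "assignments.tsv"
        assignments_to_frame(assignments).to_csv(apath, sep="\t", index=False)
        outputs["assignments"] = str(apath)

        stage = "find_pairs"
        calls: list[ClusterCall] = []
        tandems = []
        for ann in annotations:
            fams = {
                a.gene_id: a.family
                for a in assignments
                if a.genome_id == ann.genome_id
            }
            genome_calls = find_pairs(ann, fams, cfg)
            calls.extend(genome_calls)
            stage = "merge_tandem"
            tandems.extend(merge_tandem(genome_calls))
            stage = "find_pairs"
        cpath = out / "calls.tsv"
        calls_to_frame(calls).to_csv(cpath, sep="\t", index=False)
        outputs["calls"] = str(cpath)
        tpath = out / "tandems.tsv"
        tandems_to_frame(tandems).to_csv(tpath, sep="\t", index=False)
        outputs["tandems"] = str(tpath)

        stage = "distance_table"
        dt = distance_table(calls, cfg)
        dpath = out / "distance_stats.tsv"
        dt.stats.to_csv(dpath, sep="\t")
        dt.histogram.to_csv(out / "distance_histogram.tsv", sep="\t")
        outputs["distance_stats"] = str(dpath)
        outputs["distance_histogram"] = str(out / "distance_histogram.tsv")

        stage = "possession_matrix"
        matrix = possession_matrix(assignments, calls, genome_ids)
        matrix.booleans.to_csv(out / "possession.tsv", sep="\t")
        matrix.copies.to_csv(out / "copies.tsv", sep="\t")
        outputs["possession"] = str(out / "possession.tsv")
        outputs["copies"] = str(out / "copies.tsv")

        stage = "cooccurrence_ratios"
        ratios = cooccurrence_ratios(matrix, by_label=True)
        ratios_clusters = cooccurrence_ratios(
            matrix, by_label=False, calls=calls, unit="cluster"
        )
        ratios.to_csv(out / "cooccurrence_by_strain.tsv", sep="\t", index=False)
        ratios_clusters.to_csv(
            out / "cooccurrence_by_cluster.tsv", sep="\t", index=False
        )
        outputs["cooccurrence_by_strain"] = str(out / "cooccurrence_by_strain.tsv")
        outputs["cooccurrence_by_cluster"] = str(out / "cooccurrence_by_cluster.tsv")

        stage = "separate_loci"
        sep = separate_loci(matrix)
        sep.to_csv(out / "separate_loci.tsv", sep="\t")
        outputs["separate_loci"] = str(out / "separate_loci.tsv")

        stage = "type_by_phylum"
        tp = type_by_phylum(matrix, lineages)
        tp.counts.to_csv(out / "type_by_phylum_counts.tsv", sep="\t")
        tp.label_proportions.to_csv(out / "type_by_phylum_props.tsv", sep="\t")
        outputs["type_by_phylum_counts"] = str(out / "type_by_phylum_counts.tsv")
        outputs["type_by_phylum_props"] = str(out / "type_by_phylum_props.tsv")

        if abundance is not None:
            stage = "abundance_by_type"
            ab = abundance_by_type(abundance, matrix)
            ab.per_sample.to_csv(out / "abundance_by_type.tsv", sep="\t")
            pd.DataFrame(
                {
                    "statistic": ["kruskal_p"]
                    + [f"wilcoxon_{ab.focal_label}_vs_{l}" for l in ab.pairwise_p],
                    "value": [ab.kruskal_p] + list(ab.pairwise_p.values()),
                }
            ).to_csv(out / "abundance_tests.tsv", sep="\t", index=False)
            outputs["abundance_by_type"] = str(out / "abundance_by_type.tsv")
            outputs["abundance_tests"] = str(out / "abundance_tests.tsv")

        if habitat is not None:
            stage = "habitat_by_type"
            hb = habitat_by_type(habitat, matrix)
            hb.means.to_csv(out / "habitat_by_type.tsv", sep="\t")
            hb.flags.to_csv(out / "habitat_flags.tsv", sep="\t")
            outputs["habitat_by_type"] = str(out / "habitat_by_type.tsv")
            outputs["habitat_flags"] = str(out / "habitat_flags.tsv")

        if sixteen_s is not None:
            stage = "select_rep_16s"
            with open(out / "rep16s.fasta", "w") as fh:
                for genome_id in sorted(sixteen_s):
                    rep_id, rep_seq = select_rep_16s(sixteen_s[genome_id], cfg)
                    fh.write(f">{genome_id} {rep_id}\n{rep_seq}\n")
            outputs["rep16s"] = str(out / "rep16s.fasta")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        inputs=inputs,
        outputs=outputs,
        rng_seed=cfg.rng_seed,
    )
    manifest.write(out / "manifest.json")
    return manifest
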