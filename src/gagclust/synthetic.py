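"""Synthetic annotated genomes with planted isomerase-reductase clusters.

Every input the pipeline consumes can be generated here with a known
ground truth: protein families as identity ladders around a seed,
annotated contigs with planted two- and three-gene clusters of a
requested type/gap/strand plus composition-matched decoys, strain cohorts
with phylum labels and per-type frequencies, and relative-abundance
tables with a planted per-type enrichment.  All generators are pure
functions of their integer seed.

Planted proteins are mutated copies of a family seed at a controlled
ungapped identity; decoys are residue-shuffled seeds (same composition,
no homology).  Gene lengths are drawn from 600-1500 bp, the typical
bacterial CDS range; small intervening genes (e.g. the cupin-like gene
found inside some kduD-dhuI clusters) default to 270-360 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_typing import (
    ClusterTypeLabel,
    ISOMERASES,
    ORDER_FROM_LETTER,
    REDUCTASES,
    classify_pair,
    intergenic_gap,
)
from .genome_model import Gene, GenomeAnnotation, TaxonomyLineage
from .inventory import FAMILIES, LABEL_COLUMNS, PossessionMatrix
from .seqsearch import AMINO_ACIDS, DEFAULT_MODEL

# Robinson & Robinson amino-acid background frequencies (order ACDEFGHIKLMNPQRSTVWY)
BACKGROUND_FREQS = np.array([
    0.0787, 0.0151, 0.0535, 0.0668, 0.0397, 0.0695, 0.0229, 0.0590,
    0.0595, 0.0963, 0.0238, 0.0414, 0.0484, 0.0383, 0.0512, 0.0683,
    0.0541, 0.0662, 0.0109, 0.0339,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

# typical mature-protein lengths for each family's seed
_SEED_LENGTHS = {
    "kduI": 278, "dhuI": 149, "kduD": 253, "dhuD": 245,
    "ugl": 377, "ogl": 388, "yteR": 349, "kdgA": 205, "kdgK": 309,
    "kdgF": 113,
}

_GENE_LEN_RANGE = (600, 1500)
_CUPIN_LEN_RANGE = (270, 360)


class SynthesisError(ValueError):
    pass


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND_FREQS)
    )


def default_family_seeds(base_seed: int = 20_240_101) -> dict[str, str]:
    """Deterministic synthetic seed protein per family (stand-ins for the
    real seed accessions, which are user inputs; synthetic by construction)."""
    seeds = {}
    for i, fam in enumerate(FAMILIES):
        rng = np.random.default_rng([base_seed, i])
        seeds[fam] = random_protein(_SEED_LENGTHS[fam], rng)
    return seeds


def mutate_protein(seed: str, target_identity: float, rng_seed: int) -> str:
    """Substitute positions until the ungapped identity to ``seed`` is
    within +/-1 percentage point of ``target_identity``.

    Substitutions prefer residues with a non-negative substitution score
    against the original (conservative changes), falling back to any other
    residue.  Deterministic per ``rng_seed``.
    """
    if not 0 < target_identity <= 100:
        raise SynthesisError("target identity must be in (0, 100]")
    L = len(seed)
    if L == 0:
        raise SynthesisError("empty seed")
    n_sub = int(round(L * (1 - target_identity / 100.0)))
    achieved = 100.0 * (L - n_sub) / L
    if abs(achieved - target_identity) > 1.0:
        raise SynthesisError(
            f"identity {target_identity}% not reachable within 1 point for "
            f"length-{L} seed"
        )
    if n_sub == 0:
        return seed
    rng = np.random.default_rng(rng_seed)
    matrix = DEFAULT_MODEL.score_matrix
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(seed)
    for pos in positions:
        orig = out[pos]
        if orig in AMINO_ACIDS:
            preferred = [
                a for a in AMINO_ACIDS if a != orig and matrix[orig, a] >= 0
            ]
        else:
            preferred = []
        pool = preferred or [a for a in AMINO_ACIDS if a != orig]
        out[pos] = pool[rng.integers(len(pool))]
    return "".join(out)


@dataclass(frozen=True)
class FamilyMember:
    member_id: str
    sequence: str
    target_identity: float


def synth_family(
    seed: str,
    n: int,
    identity_range: tuple[float, float],
    rng_seed: int,
    prefix: str = "fam",
) -> list[FamilyMember]:
    """n variants with target identities evenly spaced across the range."""
    if n < 1:
        raise SynthesisError("n must be >= 1")
    lo, hi = identity_range
    targets = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    rng = np.random.default_rng(rng_seed)
    members = []
    for i, t in enumerate(targets):
        child = int(rng.integers(2**31))
        members.append(
            FamilyMember(
                member_id=f"{prefix}_{i:03d}",
                sequence=mutate_protein(seed, float(t), child),
                target_identity=float(t),
            )
        )
    return members


@dataclass(frozen=True)
class ClusterPlan:
    """A planted isomerase-reductase pair."""

    label: ClusterTypeLabel
    gap_bp: int
    contig_id: str = "chr"
    anchor_position: int = 1000
    intervening: tuple[int, ...] = ()  # decoy gene lengths inside the gap
    strand: str | None = None  # parallel pairs only; None -> drawn

    def __post_init__(self) -> None:
        if self.gap_bp < 0:
            raise SynthesisError("gap_bp must be >= 0")
        if self.intervening and sum(self.intervening) > self.gap_bp:
            raise SynthesisError("intervening genes do not fit in the gap")


@dataclass(frozen=True)
class PlantedCall:
    label: str
    iso_gene_id: str
    red_gene_id: str
    gap_bp: int


@dataclass
class SyntheticTruth:
    genome_id: str
    calls: list[PlantedCall] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=dict)
    decoy_ids: list[str] = field(default_factory=list)


def _draw_len(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo // 3, hi // 3 + 1)) * 3


def _family_protein(
    family: str,
    seeds: Mapping[str, str],
    rng: np.random.Generator,
    identity_range: tuple[float, float],
) -> str:
    ident = float(rng.uniform(*identity_range))
    return mutate_protein(seeds[family], ident, int(rng.integers(2**31)))


def synth_genome(
    genome_id: str,
    plans: Sequence[ClusterPlan],
    family_seeds: Mapping[str, str] | None = None,
    decoy_count: int = 5,
    rng_seed: int = 0,
    singletons: Sequence[str] = (),
    identity_range: tuple[float, float] = (60.0, 90.0),
) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Emit an annotated genome realizing each plan, plus ground truth.

    Each planted pair is self-checked: the emitted genes classify to the
    requested label with the requested gap.  ``singletons`` plants
    stand-alone family genes (auxiliary families, or isomerase/reductase
    genes at separate loci).  Decoys are shuffled family seeds.
    """
    if family_seeds is None:
        family_seeds = default_family_seeds()
    rng = np.random.default_rng(rng_seed)
    genes: list[Gene] = []
    truth = SyntheticTruth(genome_id=genome_id)
    spans: dict[str, list[tuple[int, int]]] = {}
    counter = 0

    def next_id(tag: str) -> str:
        nonlocal counter
        counter += 1
        return f"{genome_id}_{tag}{counter:04d}"

    for plan in plans:
        label = plan.label
        f1, f2 = ORDER_FROM_LETTER[label.letter]  # transcription order
        iso_fam = f1 if f1 in ISOMERASES else f2
        red_fam = f1 if f1 in REDUCTASES else f2
        len1 = _draw_len(rng, *_GENE_LEN_RANGE)
        len2 = _draw_len(rng, *_GENE_LEN_RANGE)
        a = plan.anchor_position
        if not label.antiparallel:
            strand = plan.strand or ("+" if rng.integers(2) else "-")
            if strand == "+":
                g_first = (a, a + len1 - 1, "+")
                g_second = (a + len1 + plan.gap_bp, a + len1 + plan.gap_bp + len2 - 1, "+")
            else:
                # transcription right-to-left: first gene sits rightmost
                g_second = (a, a + len2 - 1, "-")
                g_first = (a + len2 + plan.gap_bp, a + len2 + plan.gap_bp + len1 - 1, "-")
            first_id = next_id("g")
            second_id = next_id("g")
            made = {
                f1: Gene(first_id, plan.contig_id, g_first[0], g_first[1], g_first[2]),
                f2: Gene(second_id, plan.contig_id, g_second[0], g_second[1], g_second[2]),
            }
        else:
            # divergent (<- ->) when the letter is the isomerase-first one,
            # convergent (-> <-) otherwise; isomerase placed leftmost
            divergent = f1 in ISOMERASES
            left_strand, right_strand = ("-", "+") if divergent else ("+", "-")
            g_left = (a, a + len1 - 1, left_strand)
            g_right = (a + len1 + plan.gap_bp, a + len1 + plan.gap_bp + len2 - 1, right_strand)
            iso_id = next_id("g")
            red_id = next_id("g")
            made = {
                iso_fam: Gene(iso_id, plan.contig_id, g_left[0], g_left[1], g_left[2]),
                red_fam: Gene(red_id, plan.contig_id, g_right[0], g_right[1], g_right[2]),
            }
        iso_gene, red_gene = made[iso_fam], made[red_fam]

        # self-check: emitted pair must classify to the plan
        got = classify_pair(iso_gene, iso_fam, red_gene, red_fam)
        gap = intergenic_gap(iso_gene, red_gene)
        if got != label or gap != plan.gap_bp:
            raise SynthesisError(
                f"plan self-check failed: wanted {label.render()}/{plan.gap_bp}, "
                f"emitted {got.render()}/{gap}"
            )

        span_lo = min(iso_gene.start, red_gene.start)
        span_hi = max(iso_gene.end, red_gene.end)
        for lo_, hi_ in spans.get(plan.contig_id, []):
            if span_lo <= hi_ and lo_ <= span_hi:
                raise SynthesisError(
                    f"{genome_id}: overlapping plans on {plan.contig_id}"
                )
        spans.setdefault(plan.contig_id, []).append((span_lo, span_hi))

        iso_gene = Gene(
            iso_gene.gene_id, iso_gene.contig_id, iso_gene.start, iso_gene.end,
            iso_gene.strand,
            _family_protein(iso_fam, family_seeds, rng, identity_range),
        )
        red_gene = Gene(
            red_gene.gene_id, red_gene.contig_id, red_gene.start, red_gene.end,
            red_gene.strand,
            _family_protein(red_fam, family_seeds, rng, identity_range),
        )
        genes.extend([iso_gene, red_gene])
        truth.families[iso_gene.gene_id] = iso_fam
        truth.families[red_gene.gene_id] = red_fam
        truth.calls.append(
            PlantedCall(
                label=label.render(),
                iso_gene_id=iso_gene.gene_id,
                red_gene_id=red_gene.gene_id,
                gap_bp=plan.gap_bp,
            )
        )

        # intervening decoy genes inside the gap
        left_gene = iso_gene if iso_gene.start < red_gene.start else red_gene
        cursor = left_gene.end + 1
        for length in plan.intervening:
            gid = next_id("i")
            seed_choice = list(family_seeds.values())[int(rng.integers(len(family_seeds)))]
            prot = "".join(rng.permutation(list(seed_choice)))
            strand = "+" if rng.integers(2) else "-"
            genes.append(
                Gene(gid, plan.contig_id, cursor, cursor + length - 1, strand, prot)
            )
            truth.decoy_ids.append(gid)
            cursor += length

    # stand-alone family genes, far from any plan
    aux_cursor = 1000
    for fam in singletons:
        gid = next_id("s")
        length = _draw_len(rng, *_GENE_LEN_RANGE)
        strand = "+" if rng.integers(2) else "-"
        genes.append(
            Gene(gid, "aux", aux_cursor, aux_cursor + length - 1, strand,
                 _family_protein(fam, family_seeds, rng, identity_range))
        )
        truth.families[gid] = fam
        aux_cursor += length + 10_000

    # decoys on their own contig
    decoy_cursor = 1000
    fam_list = sorted(family_seeds)
    for _ in range(decoy_count):
        gid = next_id("d")
        seed_choice = family_seeds[fam_list[int(rng.integers(len(fam_list)))]]
        prot = "".join(rng.permutation(list(seed_choice)))
        strand = "+" if rng.integers(2) else "-"
        genes.append(
            Gene(gid, "decoys", decoy_cursor, decoy_cursor + len(prot) * 3 + 2, strand, prot)
        )
        truth.decoy_ids.append(gid)
        decoy_cursor += len(prot) * 3 + 5_000

    contigs: dict[str, int] = {}
    for g in genes:
        contigs[g.contig_id] = max(contigs.get(g.contig_id, 0), g.end + 1000)
    ann = GenomeAnnotation(genome_id=genome_id, contigs=contigs, genes=genes)
    return ann, truth


@dataclass
class Cohort:
    strains: list[tuple[GenomeAnnotation, SyntheticTruth]]
    lineages: dict[str, TaxonomyLineage]

    @property
    def genome_ids(self) -> list[str]:
        return [ann.genome_id for ann, _ in self.strains]

    def truth_possession(self) -> PossessionMatrix:
        """Possession matrix derived from planted truth (noise-free)."""
        idx = pd.Index(self.genome_ids, name="genome_id")
        columns = list(FAMILIES) + LABEL_COLUMNS + ["any_cluster"]
        booleans = pd.DataFrame(False, index=idx, columns=columns)
        copies = pd.DataFrame(0, index=idx, columns=list(FAMILIES))
        for ann, truth in self.strains:
            for fam in truth.families.values():
                booleans.loc[ann.genome_id, fam] = True
                copies.loc[ann.genome_id, fam] += 1
            for call in truth.calls:
                booleans.loc[ann.genome_id, call.label] = True
                booleans.loc[ann.genome_id, "any_cluster"] = True
        return PossessionMatrix(booleans=booleans, copies=copies)


def synth_cohort(
    n_strains: int,
    phylum_weights: Mapping[str, float],
    label_frequencies: Mapping[str, float],
    aux_possession_probs: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    family_seeds: Mapping[str, str] | None = None,
    gap_range: tuple[int, int] = (0, 400),
    decoy_count: int = 2,
    label_counts: Mapping[str, int] | None = None,
) -> Cohort:
    """Independent per-strain draws of cluster labels and auxiliary families.

    Each positive label becomes one planted cluster; auxiliary families
    are planted as stand-alone genes.  Emits one annotation + truth per
    strain and a lineage table.

    With ``label_counts`` the Bernoulli draws are replaced by a matched
    design: exactly the given number of strains per label, one label per
    strain, assigned to a random disjoint subset of the cohort.  This is
    the right null for abundance comparisons, where unequal numbers of
    positive strains would by themselves shift per-type sums.
    """
    for name, probs in (("label", label_frequencies),
                        ("aux", aux_possession_probs or {})):
        for k, p in probs.items():
            if not 0 <= p <= 1:
                raise SynthesisError(f"{name} frequency for {k} out of [0,1]")
    if family_seeds is None:
        family_seeds = default_family_seeds()
    aux_possession_probs = aux_possession_probs or {}
    rng = np.random.default_rng(rng_seed)
    phyla = sorted(phylum_weights)
    w = np.array([phylum_weights[p] for p in phyla], dtype=float)
    w = w / w.sum()

    fixed_assignment: dict[int, str] = {}
    if label_counts is not None:
        total = sum(label_counts.values())
        if total > n_strains:
            raise SynthesisError("label_counts exceed the cohort size")
        order = rng.permutation(n_strains)
        pos = 0
        for label_str in sorted(label_counts):
            for _ in range(label_counts[label_str]):
                fixed_assignment[int(order[pos])] = label_str
                pos += 1

    strains = []
    lineages = {}
    for i in range(n_strains):
        genome_id = f"synth{i:04d}"
        phylum = phyla[int(rng.choice(len(phyla), p=w))]
        plans = []
        cursor = 1000
        if label_counts is not None:
            chosen = [fixed_assignment[i]] if i in fixed_assignment else []
        else:
            chosen = [
                label_str
                for label_str in sorted(label_frequencies)
                if rng.random() < label_frequencies[label_str]
            ]
        for label_str in chosen:
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            plans.append(
                ClusterPlan(
                    label=ClusterTypeLabel.parse(label_str),
                    gap_bp=gap,
                    contig_id="chr",
                    anchor_position=cursor,
                )
            )
            cursor += 10_000
        singles = [
            fam for fam in sorted(aux_possession_probs)
            if rng.random() < aux_possession_probs[fam]
        ]
        ann, truth = synth_genome(
            genome_id,
            plans,
            family_seeds=family_seeds,
            decoy_count=decoy_count,
            rng_seed=int(rng.integers(2**31)),
            singletons=singles,
        )
        strains.append((ann, truth))
        lineages[genome_id] = TaxonomyLineage(genome_id=genome_id, phylum=phylum)
    return Cohort(strains=strains, lineages=lineages)


def synth_abundance(
    cohort: Cohort,
    n_samples: int,
    enrichment: Mapping[str, float] | None = None,
    noise_dispersion: float = 1.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-sample log-normal relative abundances, normalized to sum to 1.

    Strains positive (by planted truth) for an enriched label have their
    abundance mean multiplied by the fold factor (max over their labels).
    """
    enrichment = enrichment or {}
    for label, fold in enrichment.items():
        if fold <= 0:
            raise SynthesisError(f"fold for {label} must be > 0")
    rng = np.random.default_rng(rng_seed)
    genome_ids = cohort.genome_ids
    folds = np.ones(len(genome_ids))
    for j, (_, truth) in enumerate(cohort.strains):
        labels = {c.label for c in truth.calls}
        factors = [enrichment.get(l, 1.0) for l in labels]
        if factors:
            folds[j] = max(factors)
    raw = rng.lognormal(mean=0.0, sigma=noise_dispersion,
                        size=(n_samples, len(genome_ids))) * folds
    raw = raw / raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        raw,
        index=pd.Index([f"sample{i:03d}" for i in range(n_samples)], name="sample_id"),
        columns=genome_ids,
    )
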