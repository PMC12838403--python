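"""Downstream aggregations over the possession matrix.

Covers four analyses: cluster-type x phylum tables, per-sample relative
abundance summed by cluster type (with Kruskal-Wallis and pairwise
Wilcoxon rank tests), habitat-preference scores averaged by cluster type,
and the greedy centroid rule that picks one representative 16S rRNA
sequence per strain.

A strain positive for two labels (e.g. a tandem carrying both constituent
types) counts once under each label in every aggregation; this
double-counting is deliberate and matches the per-type accounting used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .genome_model import Config, TaxonomyLineage
from .inventory import LABEL_COLUMNS, PossessionMatrix


class SummaryError(ValueError):
    pass


@dataclass
class TypePhylumTable:
    counts: pd.DataFrame  # rows = 16 labels, cols = phyla
    label_proportions: pd.DataFrame  # row-normalized (share of phyla per label)
    phylum_proportions: pd.DataFrame  # column-normalized (share of labels per phylum)

    @property
    def label_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def type_by_phylum(
    matrix: PossessionMatrix,
    lineages: Mapping[str, TaxonomyLineage],
) -> TypePhylumTable:
    """Strain counts per (cluster label, phylum).

    Strains without a lineage are grouped under ``unclassified``.
    """
    bools = matrix.booleans
    phyla = sorted(
        {
            (lineages[g].phylum or "unclassified") if g in lineages else "unclassified"
            for g in bools.index
        }
    )
    counts = pd.DataFrame(
        0, index=pd.Index(LABEL_COLUMNS, name="label"), columns=phyla
    )
    for genome_id in bools.index:
        lin = lineages.get(genome_id)
        phylum = (lin.phylum if lin and lin.phylum else "unclassified")
        for label in LABEL_COLUMNS:
            if bools.loc[genome_id, label]:
                counts.loc[label, phylum] += 1
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    col_tot = counts.sum(axis=0).replace(0, np.nan)
    return TypePhylumTable(
        counts=counts,
        label_proportions=counts.div(row_tot, axis=0),
        phylum_proportions=counts.div(col_tot, axis=1),
    )


@dataclass
class AbundanceByType:
    per_sample: pd.DataFrame  # samples x labels, summed relative abundance
    cohort_mean: pd.Series  # per-label mean over samples
    kruskal_p: float
    pairwise_p: dict[str, float]  # focal label vs each other label (Wilcoxon)
    focal_label: str


def abundance_by_type(
    abundance: pd.DataFrame,
    matrix: PossessionMatrix,
    focal_label: str | None = None,
) -> AbundanceByType:
    """Per-sample summed relative abundance of strains positive for each label.

    ``abundance`` is samples x genome_id.  Labels with no positive strain
    are dropped.  The omnibus Kruskal-Wallis test runs across labels; the
    focal label (highest median by default) is compared against each other
    label with a paired two-sided Wilcoxon signed-rank test.
    """
    common = [g for g in abundance.columns if g in matrix.booleans.index]
    if not common:
        raise SummaryError("no overlapping genome ids between abundance and matrix")
    bools = matrix.booleans
    cols = {}
    for label in LABEL_COLUMNS:
        members = [g for g in common if bools.loc[g, label]]
        if members:
            cols[label] = abundance[members].sum(axis=1)
    if not cols:
        raise SummaryError("no label has any positive strain")
    per_sample = pd.DataFrame(cols)

    groups = [per_sample[c].to_numpy() for c in per_sample.columns]
    if len(groups) < 2:
        kruskal_p = float("nan")
    elif all(np.array_equal(groups[0], g) for g in groups[1:]):
        kruskal_p = 1.0  # identical groups carry no signal
    else:
        kruskal_p = float(stats.kruskal(*groups).pvalue)

    if focal_label is None:
        focal_label = per_sample.median().idxmax()
    pairwise = {}
    for label in per_sample.columns:
        if label == focal_label:
            continue
        diff = per_sample[focal_label] - per_sample[label]
        if np.allclose(diff, 0):
            pairwise[label] = 1.0
        else:
            pairwise[label] = float(
                stats.wilcoxon(diff, alternative="two-sided").pvalue
            )
    return AbundanceByType(
        per_sample=per_sample,
        cohort_mean=per_sample.mean(),
        kruskal_p=kruskal_p,
        pairwise_p=pairwise,
        focal_label=focal_label,
    )


@dataclass
class HabitatByType:
    means: pd.DataFrame  # labels x kept categories
    flags: pd.DataFrame  # 'above' / 'below' vs per-category overall mean
    overall: pd.Series  # per-category mean across labels


def habitat_by_type(
    scores: pd.DataFrame,
    matrix: PossessionMatrix,
    categories: Sequence[str] | None = None,
    min_mean: float = 10.0,
) -> HabitatByType:
    """Mean habitat-preference score per (cluster label, habitat category).

    ``scores`` is genome_id x category.  Labels with zero positive strains
    are excluded.  Categories are kept only if some label's mean exceeds
    ``min_mean`` (unless an explicit category list is given).  Each kept
    cell is flagged above/below the per-category mean across labels.
    """
    bools = matrix.booleans
    rows = {}
    for label in LABEL_COLUMNS:
        members = [g for g in scores.index if g in bools.index and bools.loc[g, label]]
        if members:
            rows[label] = scores.loc[members].mean()
    if not rows:
        raise SummaryError("no label has any scored strain")
    means = pd.DataFrame(rows).T
    if categories is None:
        keep = [c for c in means.columns if means[c].max() > min_mean]
    else:
        keep = [c for c in categories if c in means.columns]
    means = means[keep]
    overall = means.mean(axis=0)
    flags = means.apply(
        lambda col: np.where(col > overall[col.name], "above", "below"), axis=0
    )
    flags = pd.DataFrame(flags, index=means.index, columns=means.columns)
    return HabitatByType(means=means, flags=flags, overall=overall)


# ---------------------------------------------------------------------------
# representative 16S selection
# ---------------------------------------------------------------------------

_NUC_ALIGNER = None


def _nucleotide_aligner() -> Align.PairwiseAligner:
    global _NUC_ALIGNER
    if _NUC_ALIGNER is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = 1
        al.mismatch_score = -1
        al.open_gap_score = -3  # gap of length k costs 2 + k
        al.extend_gap_score = -1
        _NUC_ALIGNER = al
    return _NUC_ALIGNER


def nucleotide_identity(a: str, b: str) -> float:
    """Global percent identity over the full alignment length."""
    if not a or not b:
        raise SummaryError("empty nucleotide sequence")
    aln = _nucleotide_aligner().align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.shape[1]


def cluster_16s(
    seqs: Mapping[str, str], cfg: Config = Config()
) -> list[list[str]]:
    """Greedy centroid clustering of 16S sequences.

    Sequences are processed longest-first (ties by id); each joins the
    first existing centroid with identity >= ``cfg.rep16s_identity``,
    otherwise it founds a new cluster.  Returns clusters as id lists whose
    first element is the centroid.
    """
    if not seqs:
        raise SummaryError("no 16S sequences supplied")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    clusters: list[list[str]] = []
    for sid in order:
        for cluster in clusters:
            centroid = cluster[0]
            if nucleotide_identity(seqs[sid], seqs[centroid]) >= cfg.rep16s_identity:
                cluster.append(sid)
                break
        else:
            clusters.append([sid])
    return clusters


def select_rep_16s(
    seqs: Mapping[str, str], cfg: Config = Config()
) -> tuple[str, str]:
    """Centroid of the largest 16S cluster (ties: longest centroid, then id)."""
    clusters = cluster_16s(seqs, cfg)
    best = min(
        clusters,
        key=lambda cl: (-len(cl), -len(seqs[cl[0]]), cl[0]),
    )
    centroid = best[0]
    return centroid, seqs[centroid]
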