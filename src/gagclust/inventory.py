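"""Per-gene family assignment and strain-level possession accounting.

KduD and DhuD are both short-chain dehydrogenase-reductases, so their
profiles cross-react; a best-hit rule (minimum full-sequence E-value, ties
broken by score and then a fixed family priority) keeps each gene in
exactly one family.  Possession is then rolled up per strain into a
boolean matrix over the ten gene families, the 16 cluster labels and an
``any_cluster`` column, together with per-family copy counts (duplications
are retained, not capped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster_typing import ALL_LABELS, ClusterCall, CORE_FAMILIES
from .genome_model import Config
from .seqsearch import SearchHit

FAMILIES = (
    "kduI", "dhuI", "kduD", "dhuD",
    "ugl", "ogl", "yteR", "kdgA", "kdgK", "kdgF",
)
_PRIORITY = {fam: i for i, fam in enumerate(FAMILIES)}

LABEL_COLUMNS = [l.render() for l in ALL_LABELS]


class InventoryError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyAssignment:
    genome_id: str
    gene_id: str
    family: str
    evalue: float
    score: float


def assign_families(
    hits: Iterable[SearchHit],
    cfg: Config = Config(),
    genome_id: str = "",
) -> list[FamilyAssignment]:
    """Best-hit family per gene; genes whose best E-value is at or above
    the threshold are dropped."""
    best: dict[str, SearchHit] = {}
    for h in hits:
        if h.family not in _PRIORITY:
            raise InventoryError(f"unknown family {h.family!r}")
        cur = best.get(h.target_gene_id)
        if cur is None or (h.evalue, -h.score, _PRIORITY[h.family]) < (
            cur.evalue, -cur.score, _PRIORITY[cur.family]
        ):
            best[h.target_gene_id] = h
    out = [
        FamilyAssignment(
            genome_id=genome_id,
            gene_id=gid,
            family=h.family,
            evalue=h.evalue,
            score=h.score,
        )
        for gid, h in best.items()
        if h.evalue < cfg.evalue_threshold
    ]
    out.sort(key=lambda a: a.gene_id)
    return out


@dataclass
class PossessionMatrix:
    """Strain-level possession booleans and per-family copy counts."""

    booleans: pd.DataFrame  # index genome_id; families + labels + any_cluster
    copies: pd.DataFrame  # index genome_id; one column per family

    def positives(self, column: str) -> list[str]:
        return list(self.booleans.index[self.booleans[column]])


def possession_matrix(
    assignments: Iterable[FamilyAssignment],
    calls: Iterable[ClusterCall],
    genome_ids: Sequence[str],
) -> PossessionMatrix:
    genome_ids = sorted(set(genome_ids))
    columns = list(FAMILIES) + LABEL_COLUMNS + ["any_cluster"]
    booleans = pd.DataFrame(False, index=pd.Index(genome_ids, name="genome_id"),
                            columns=columns)
    copies = pd.DataFrame(0, index=booleans.index, columns=list(FAMILIES))

    for a in assignments:
        if a.genome_id not in booleans.index:
            raise InventoryError(f"assignment for unknown genome {a.genome_id}")
        booleans.loc[a.genome_id, a.family] = True
        copies.loc[a.genome_id, a.family] += 1

    for c in calls:
        label = c.label.render()
        booleans.loc[c.genome_id, label] = True
        booleans.loc[c.genome_id, "any_cluster"] = True

    return PossessionMatrix(booleans=booleans, copies=copies)


def cooccurrence_ratios(
    matrix: PossessionMatrix,
    by_label: bool = True,
    calls: Sequence[ClusterCall] | None = None,
    unit: str = "strain",
    aux_families: Sequence[str] = ("kdgF", "kdgA", "kdgK", "ugl", "ogl", "yteR"),
) -> pd.DataFrame:
    """Fraction of cluster-positive strains (or clusters) that also carry
    each auxiliary gene family.

    ``unit='strain'``: denominator = strains positive for the label (or any
    cluster).  ``unit='cluster'``: denominator = individual cluster calls,
    counting a call as co-occurring when its strain carries the family
    (requires ``calls``).  Ratios with zero denominator are NaN.
    """
    rows = []
    groups = LABEL_COLUMNS if by_label else ["any_cluster"]
    bools = matrix.booleans
    if unit == "strain":
        for col in groups:
            members = bools.index[bools[col]]
            for fam in aux_families:
                n = int(bools.loc[members, fam].sum())
                N = len(members)
                rows.append((col, fam, n, N, n / N if N else float("nan")))
    elif unit == "cluster":
        if calls is None:
            raise InventoryError("unit='cluster' requires the cluster calls")
        for col in groups:
            sub = [
                c for c in calls
                if col == "any_cluster" or c.label.render() == col
            ]
            for fam in aux_families:
                n = sum(bool(bools.loc[c.genome_id, fam]) for c in sub)
                N = len(sub)
                rows.append((col, fam, n, N, n / N if N else float("nan")))
    else:
        raise InventoryError(f"unknown unit {unit!r}")
    return pd.DataFrame(rows, columns=["label", "family", "n", "N", "ratio"])


def separate_loci(matrix: PossessionMatrix) -> pd.DataFrame:
    """Family possession among cluster-negative strains.

    Rows: per-family positive counts for the four core families, the
    cross-tabulations kduI&kduD, dhuI&dhuD, dhuI&kduD, and the count of
    strains lacking all four.
    """
    bools = matrix.booleans
    neg = bools[~bools["any_cluster"]]
    rows = {f"{fam}_positive": int(neg[fam].sum()) for fam in CORE_FAMILIES}
    rows["kduI_and_kduD"] = int((neg["kduI"] & neg["kduD"]).sum())
    rows["dhuI_and_dhuD"] = int((neg["dhuI"] & neg["dhuD"]).sum())
    rows["dhuI_and_kduD"] = int((neg["dhuI"] & neg["kduD"]).sum())
    rows["lacks_all_four"] = int(
        (~neg[list(CORE_FAMILIES)].any(axis=1)).sum()
    )
    rows["cluster_negative_strains"] = len(neg)
    return pd.DataFrame(
        {"count": pd.Series(rows)}
    ).rename_axis("category")


def assignments_to_frame(assignments: Iterable[FamilyAssignment]) -> pd.DataFrame:
    rows = [
        (a.genome_id, a.gene_id, a.family, a.evalue, a.score)
        for a in assignments
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "family", "evalue", "score"]
    )


def assignments_to_family_map(
    assignments: Iterable[FamilyAssignment],
) -> dict[str, str]:
    out: dict[str, str] = {}
    for a in assignments:
        if a.gene_id in out:
            raise InventoryError(f"gene {a.gene_id} assigned twice")
        out[a.gene_id] = a.family
    return out
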