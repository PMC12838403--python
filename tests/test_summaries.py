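import numpy as np
import pandas as pd
import pytest

from gagclust.genome_model import TaxonomyLineage
from gagclust.summaries import (
    SummaryError,
    abundance_by_type,
    cluster_16s,
    habitat_by_type,
    nucleotide_identity,
    select_rep_16s,
    type_by_phylum,
)
from gagclust.synthetic import synth_abundance, synth_cohort

import edlib

from _oracles import greedy_centroid_clusters


def _matrix_from_labels(label_map, families=()):
    """Minimal possession matrix from genome -> [labels]."""
    from gagclust.inventory import FAMILIES, LABEL_COLUMNS, PossessionMatrix

    idx = pd.Index(sorted(label_map), name="genome_id")
    cols = list(FAMILIES) + LABEL_COLUMNS + ["any_cluster"]
    booleans = pd.DataFrame(False, index=idx, columns=cols)
    for genome, labels in label_map.items():
        for label in labels:
            booleans.loc[genome, label] = True
            booleans.loc[genome, "any_cluster"] = True
    copies = pd.DataFrame(0, index=idx, columns=list(FAMILIES))
    return PossessionMatrix(booleans=booleans, copies=copies)


class TestTypeByPhylum:
    def test_counts_and_proportions(self):
        matrix = _matrix_from_labels(
            {"s1": ["A"], "s2": ["A"], "s3": ["A"], "s4": []}
        )
        lineages = {
            "s1": TaxonomyLineage("s1", phylum="Pseudomonadota"),
            "s2": TaxonomyLineage("s2", phylum="Pseudomonadota"),
            "s3": TaxonomyLineage("s3", phylum="Bacillota"),
        }
        table = type_by_phylum(matrix, lineages)
        assert table.counts.loc["A", "Pseudomonadota"] == 2
        assert table.label_proportions.loc["A", "Pseudomonadota"] == pytest.approx(2 / 3)
        assert table.label_totals["A"] == 3

    def test_tandem_strain_counted_under_both_labels(self):
        matrix = _matrix_from_labels({"s1": ["A", "H"]})
        lineages = {"s1": TaxonomyLineage("s1", phylum="Pseudomonadota")}
        table = type_by_phylum(matrix, lineages)
        assert table.counts.loc["A", "Pseudomonadota"] == 1
        assert table.counts.loc["H", "Pseudomonadota"] == 1

    def test_missing_lineage_grouped_as_unclassified(self):
        matrix = _matrix_from_labels({"s1": ["A"]})
        table = type_by_phylum(matrix, {})
        assert table.counts.loc["A", "unclassified"] == 1

    def test_empty_matrix_gives_zero_table(self):
        matrix = _matrix_from_labels({"s1": []})
        table = type_by_phylum(matrix, {})
        assert table.counts.to_numpy().sum() == 0


class TestAbundanceByType:
    def test_per_sample_sum(self):
        matrix = _matrix_from_labels({"s1": ["A"], "s2": ["A"]})
        ab = pd.DataFrame({"s1": [0.2], "s2": [0.3]}, index=["sample0"])
        result = abundance_by_type(ab, matrix)
        assert result.per_sample.loc["sample0", "A"] == pytest.approx(0.5)

    def test_double_count_across_labels(self):
        matrix = _matrix_from_labels({"s1": ["A", "H"]})
        ab = pd.DataFrame({"s1": [0.4]}, index=["sample0"])
        result = abundance_by_type(ab, matrix)
        assert result.per_sample.loc["sample0", "A"] == pytest.approx(0.4)
        assert result.per_sample.loc["sample0", "H"] == pytest.approx(0.4)

    def test_disjoint_genomes_raise(self):
        matrix = _matrix_from_labels({"s1": ["A"]})
        ab = pd.DataFrame({"other": [0.4]}, index=["sample0"])
        with pytest.raises(SummaryError):
            abundance_by_type(ab, matrix)

    def test_planted_enrichment_detected(self):
        cohort = synth_cohort(
            n_strains=36,
            phylum_weights={"p": 1.0},
            label_frequencies={},
            label_counts={"A": 6, "B": 6, "D": 6, "E": 6, "H": 6},
            rng_seed=7,
        )
        ab = synth_abundance(cohort, n_samples=40, enrichment={"E": 3.0}, rng_seed=7)
        result = abundance_by_type(ab, cohort.truth_possession())
        assert result.focal_label == "E"
        assert result.kruskal_p < 0.01
        assert max(result.pairwise_p.values()) < 0.01


class TestHabitatByType:
    def test_means_filter_and_flags(self):
        matrix = _matrix_from_labels({"s1": ["G"], "s2": ["G"], "s3": ["A"]})
        scores = pd.DataFrame(
            {"soil": [20.0, 30.0, 5.0], "moon": [1.0, 2.0, 3.0]},
            index=["s1", "s2", "s3"],
        )
        result = habitat_by_type(scores, matrix)
        assert result.means.loc["G", "soil"] == pytest.approx(25.0)
        assert "moon" not in result.means.columns  # no label mean above 10
        assert result.flags.loc["G", "soil"] == "above"
        assert result.flags.loc["A", "soil"] == "below"

    def test_labels_without_strains_are_excluded(self):
        matrix = _matrix_from_labels({"s1": ["G"]})
        scores = pd.DataFrame({"soil": [20.0]}, index=["s1"])
        result = habitat_by_type(scores, matrix)
        assert list(result.means.index) == ["G"]


def _mutate_nt(seq, n_sub, rng):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        out[pos] = rng.choice([c for c in "ACGT" if c != out[pos]])
    return "".join(out)


class TestRep16S:
    def test_single_sequence_returns_itself(self):
        rep_id, seq = select_rep_16s({"only": "ACGTACGTACGT"})
        assert rep_id == "only"

    def test_largest_cluster_wins(self, rng):
        base1 = "".join(rng.choice(list("ACGT"), size=300))
        base2 = "".join(rng.choice(list("ACGT"), size=300))
        seqs = {
            "a1": base1,
            "a2": _mutate_nt(base1, 10, rng),
            "a3": _mutate_nt(base1, 12, rng),
            "b1": base2,
            "b2": _mutate_nt(base2, 10, rng),
        }
        rep_id, _ = select_rep_16s(seqs)
        clusters = cluster_16s(seqs)
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [2, 3]
        assert rep_id in {"a1", "a2", "a3"}

    def test_size_tie_returns_longer_centroid(self, rng):
        short = "".join(rng.choice(list("ACGT"), size=280))
        long = "".join(rng.choice(list("ACGT"), size=320))
        seqs = {
            "s1": short,
            "s2": _mutate_nt(short, 8, rng),
            "l1": long,
            "l2": _mutate_nt(long, 8, rng),
        }
        rep_id, rep_seq = select_rep_16s(seqs)
        assert rep_id == "l1"
        assert len(rep_seq) == 320

    def test_every_member_meets_threshold_to_its_centroid(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=300))
        seqs = {f"m{i}": _mutate_nt(base, int(rng.integers(0, 25)), rng)
                for i in range(6)}
        clusters = cluster_16s(seqs)
        for cluster in clusters:
            centroid = cluster[0]
            for member in cluster[1:]:
                assert nucleotide_identity(seqs[member], seqs[centroid]) >= 90.0

    def test_matches_independent_clustering_oracle(self, rng):
        """Greedy clustering agrees with an edit-distance-based oracle when
        identities are far from the 90% threshold."""
        bases = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(3)]
        seqs = {}
        for bi, base in enumerate(bases):
            for k in range(bi + 1):
                seqs[f"c{bi}m{k}"] = _mutate_nt(base, int(rng.integers(0, 8)), rng)

        def edlib_identity(a, b):
            res = edlib.align(a, b, task="path", mode="NW")
            aln_len = max(len(a), len(b))
            return 100.0 * (1 - res["editDistance"] / aln_len)

        ours = sorted(sorted(c) for c in cluster_16s(seqs))
        oracle = sorted(
            sorted(c)
            for c in greedy_centroid_clusters(seqs, edlib_identity, 90.0)
        )
        assert ours == oracle
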