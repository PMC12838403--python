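import numpy as np
import pytest

from gagclust.cluster_typing import (
    ALL_LABELS,
    ClusterTypeLabel,
    TypingError,
    classify_pair,
    distance_table,
    enumerate_configurations,
    find_pairs,
    intergenic_gap,
    merge_tandem,
)
from gagclust.genome_model import Config, GenomeAnnotation
from gagclust.synthetic import ClusterPlan, synth_genome

from conftest import make_annotation, make_gene, mirror_annotation


class TestIntergenicGap:
    def test_simple_distance(self):
        u = make_gene("u", 100, 1000)
        v = make_gene("v", 1100, 1900)
        assert intergenic_gap(u, v) == 99
        assert intergenic_gap(v, u) == 99  # symmetric

    def test_abutting_genes_have_zero_gap(self):
        assert intergenic_gap(make_gene("u", 100, 1000), make_gene("v", 1001, 1900)) == 0

    def test_overlapping_genes_clamp_to_zero(self):
        assert intergenic_gap(make_gene("u", 100, 1000), make_gene("v", 900, 1900)) == 0

    def test_different_contigs_rejected(self):
        with pytest.raises(TypingError):
            intergenic_gap(
                make_gene("u", 1, 10, contig="c1"), make_gene("v", 1, 10, contig="c2")
            )


class TestTypology:
    def test_sixteen_labels_eight_parallel_eight_antiparallel(self):
        labels = enumerate_configurations()
        assert len(labels) == 16
        assert len(set(labels)) == 16
        parallel = [l for l in labels if not l.antiparallel]
        assert sorted(l.letter for l in parallel) == list("ABCDEFGH")
        assert sorted(l.letter for l in labels if l.antiparallel) == list("ABCDEFGH")

    def test_raw_configurations_collapse_pairwise_under_reverse_complement(self):
        """The 32 raw (content, side, strand, strand) configurations form 16
        mirror-equivalent pairs, each mapped to one label."""
        raw = []
        for iso_fam in ("kduI", "dhuI"):
            for red_fam in ("kduD", "dhuD"):
                for iso_left in (True, False):
                    for left_strand in "+-":
                        for right_strand in "+-":
                            raw.append(
                                (iso_fam, red_fam, iso_left, left_strand, right_strand)
                            )
        assert len(raw) == 32

        def label_of(config):
            iso_fam, red_fam, iso_left, left_strand, right_strand = config
            left = make_gene("left", 100, 1000, left_strand)
            right = make_gene("right", 1200, 2000, right_strand)
            iso, red = (left, right) if iso_left else (right, left)
            return classify_pair(iso, iso_fam, red, red_fam)

        def mirrored(config):
            # reverse-complement swaps the left/right slots and flips strands
            iso_fam, red_fam, iso_left, left_strand, right_strand = config
            flip = {"+": "-", "-": "+"}
            return (
                iso_fam, red_fam, not iso_left, flip[right_strand], flip[left_strand]
            )

        by_label = {}
        for config in raw:
            by_label.setdefault(label_of(config).render(), []).append(config)
        assert len(by_label) == 16
        for label, configs in by_label.items():
            assert len(configs) == 2
            a, b = configs
            assert mirrored(a) == b or mirrored(b) == a

    @pytest.mark.parametrize(
        "iso_fam,iso,red_fam,red,expected",
        [
            # kduI upstream of kduD, same direction
            ("kduI", (100, 1000, "+"), "kduD", (1100, 1900, "+"), "A"),
            # kduD upstream of dhuI
            ("dhuI", (1400, 1900, "+"), "kduD", (100, 1000, "+"), "H"),
            # reverse-complement of the type A case
            ("kduI", (1100, 1900, "-"), "kduD", (100, 1000, "-"), "A"),
            ("kduI", (100, 1000, "+"), "dhuD", (1100, 1900, "+"), "E"),
            ("dhuI", (1100, 1900, "+"), "dhuD", (100, 1000, "+"), "D"),
            # divergent antiparallel kduI/kduD -> Ac; convergent -> Bc
            ("kduI", (100, 1000, "-"), "kduD", (1100, 1900, "+"), "Ac"),
            ("kduI", (100, 1000, "+"), "kduD", (1100, 1900, "-"), "Bc"),
        ],
    )
    def test_letter_assignments(self, iso_fam, iso, red_fam, red, expected):
        label = classify_pair(
            make_gene("i", *iso), iso_fam, make_gene("r", *red), red_fam
        )
        assert label.render() == expected

    def test_invalid_families_rejected(self):
        with pytest.raises(TypingError):
            classify_pair(
                make_gene("i", 1, 10), "ugl", make_gene("r", 20, 30), "kduD"
            )

    def test_label_parse_round_trip(self):
        for label in ALL_LABELS:
            assert ClusterTypeLabel.parse(label.render()) == label


class TestFindPairs:
    def _ann(self, genes):
        return make_annotation("g", genes)

    def test_gap_boundary_500_in_501_out(self):
        fams = {"i": "kduI", "r": "kduD"}
        for gap, expect in [(500, 1), (501, 0)]:
            ann = self._ann(
                [make_gene("i", 100, 1000), make_gene("r", 1001 + gap, 1900 + gap)]
            )
            calls = find_pairs(ann, fams, Config())
            assert len(calls) == expect, gap
            if calls:
                assert calls[0].gap_bp == 500

    def test_shared_gene_yields_two_calls(self):
        # kduI 80 bp upstream of kduD, dhuI 120 bp downstream: calls A and H
        ann = self._ann(
            [
                make_gene("a", 100, 1000),
                make_gene("b", 1081, 1900),
                make_gene("c", 2021, 2800),
            ]
        )
        fams = {"a": "kduI", "b": "kduD", "c": "dhuI"}
        calls = find_pairs(ann, fams, Config())
        assert sorted(c.label.render() for c in calls) == ["A", "H"]

    def test_intervening_gene_recorded_not_blocking(self):
        ann = self._ann(
            [
                make_gene("r", 100, 1000),
                make_gene("cupin", 1100, 1400),
                make_gene("i", 1450, 1900),
            ]
        )
        fams = {"r": "kduD", "i": "dhuI"}
        calls = find_pairs(ann, fams, Config())
        assert len(calls) == 1
        assert calls[0].label.render() == "H"
        assert calls[0].intervening_gene_ids == ("cupin",)

    def test_pairing_ignores_relative_strand(self):
        ann = self._ann(
            [make_gene("i", 100, 1000, "+"), make_gene("r", 1100, 1900, "-")]
        )
        calls = find_pairs(ann, {"i": "kduI", "r": "kduD"}, Config())
        assert len(calls) == 1
        assert calls[0].label.antiparallel

    def test_output_independent_of_gene_input_order(self):
        genes = [
            make_gene("a", 100, 1000),
            make_gene("b", 1081, 1900),
            make_gene("c", 2021, 2800),
        ]
        fams = {"a": "kduI", "b": "kduD", "c": "dhuI"}
        calls1 = find_pairs(make_annotation("g", genes), fams)
        calls2 = find_pairs(make_annotation("g", genes[::-1]), fams)
        assert calls1 == calls2


class TestMergeTandem:
    @pytest.mark.parametrize(
        "chain,expected_labels",
        [
            (("kduI", "kduD", "dhuI"), {"A", "H"}),
            (("kduI", "dhuD", "dhuI"), {"E", "D"}),
            (("kduD", "kduI", "dhuD"), {"B", "E"}),
        ],
    )
    def test_observed_tandem_chains(self, chain, expected_labels):
        genes = [
            make_gene(f"g{k}", 100 + k * 1000, 900 + k * 1000) for k in range(3)
        ]
        fams = dict(zip((g.gene_id for g in genes), chain))
        calls = find_pairs(make_annotation("g", genes), fams)
        assert len(calls) == 2  # pair calls are retained
        tandems = merge_tandem(calls)
        assert len(tandems) == 1
        assert tandems[0].chain_string == "-".join(chain)
        assert {l.render() for l in tandems[0].constituent_labels} == expected_labels

    def test_single_call_is_not_a_tandem(self):
        genes = [make_gene("a", 100, 1000), make_gene("b", 1100, 1900)]
        calls = find_pairs(
            make_annotation("g", genes), {"a": "kduI", "b": "kduD"}
        )
        assert merge_tandem(calls) == []

    def test_minus_strand_chain_reported_in_transcription_order(self):
        # on '-', transcription runs right to left
        genes = [
            make_gene("g0", 100, 900, "-"),
            make_gene("g1", 1100, 1900, "-"),
            make_gene("g2", 2100, 2900, "-"),
        ]
        fams = {"g2": "kduI", "g1": "kduD", "g0": "dhuI"}
        calls = find_pairs(make_annotation("g", genes), fams)
        tandems = merge_tandem(calls)
        assert tandems[0].chain_string == "kduI-kduD-dhuI"

    def test_antiparallel_calls_excluded_from_chains(self):
        genes = [
            make_gene("a", 100, 1000, "+"),
            make_gene("b", 1100, 1900, "-"),
            make_gene("c", 2100, 2900, "+"),
        ]
        fams = {"a": "kduI", "b": "kduD", "c": "dhuI"}
        calls = find_pairs(make_annotation("g", genes), fams)
        assert merge_tandem(calls) == []


class TestReverseComplementInvariance:
    def test_mirroring_contigs_changes_nothing(self):
        """Labels, gaps and tandem chains are strand-convention-free."""
        rng = np.random.default_rng(99)
        for rep in range(25):
            labels = rng.choice(len(ALL_LABELS), size=3, replace=False)
            plans = [
                ClusterPlan(
                    label=ALL_LABELS[i],
                    gap_bp=int(rng.integers(0, 501)),
                    contig_id="chr",
                    anchor_position=1000 + k * 10_000,
                )
                for k, i in enumerate(labels)
            ]
            ann, truth = synth_genome(
                f"g{rep}", plans, decoy_count=2, rng_seed=int(rng.integers(2**31))
            )
            fams = truth.families
            calls = find_pairs(ann, fams)
            mirrored = mirror_annotation(ann)
            mcalls = find_pairs(mirrored, fams)
            key = lambda cs: sorted(
                (c.label.render(), c.gap_bp, c.iso_gene.gene_id, c.red_gene.gene_id)
                for c in cs
            )
            assert key(calls) == key(mcalls)
            t1 = [(t.chain_string, t.gene_ids) for t in merge_tandem(calls)]
            t2 = [(t.chain_string, t.gene_ids) for t in merge_tandem(mcalls)]
            assert sorted(t1) == sorted(t2)


class TestDistanceTable:
    def test_median_and_conservation(self):
        genes = []
        fams = {}
        for k, gap in enumerate((0, 99, 480)):
            i = make_gene(f"i{k}", 100 + k * 10_000, 1000 + k * 10_000)
            r = make_gene(f"r{k}", i.end + gap + 1, i.end + gap + 800)
            genes += [i, r]
            fams[i.gene_id] = "kduI"
            fams[r.gene_id] = "kduD"
        calls = find_pairs(make_annotation("g", genes), fams)
        table = distance_table(calls)
        assert table.stats.loc["A", "count"] == 3
        assert table.stats.loc["A", "median"] == 99
        assert table.histogram["A"].sum() == 3

    def test_empty_input_gives_empty_table(self):
        table = distance_table([])
        assert table.stats.empty
        assert table.histogram.empty
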