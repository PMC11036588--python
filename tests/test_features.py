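"""Spacer extraction, homologous grouping, presence and feature classes."""

import pytest

from plastigs.features import (
    classify_feature_class,
    dedup_ir_records,
    extract_igs,
    group_homologous_igs,
    presence_table,
    total_footprint_length,
)
from plastigs.genome import Annotation, GenomicInterval

from conftest import make_plastome


class TestExtractIgs:
    def test_toy_layout_with_wrap_gap(self):
        p = make_plastome(400, [("geneA", 0, 100, "+"), ("geneB", 200, 300, "+")])
        recs = extract_igs(p)
        assert [(r.left_gene, r.right_gene, r.length) for r in recs] == [
            ("geneA", "geneB", 100),
            ("geneB", "geneA", 100),
        ]
        assert recs[0].interval.start == 100 and recs[0].interval.end == 200
        assert recs[1].interval.start == 300 and recs[1].interval.end == 400

    def test_overlapping_genes_leave_no_gap(self):
        p = make_plastome(300, [("a", 0, 150, "+"), ("b", 100, 200, "+"), ("c", 200, 280, "+")])
        recs = extract_igs(p)
        # only the wrap gap c..a remains; a-b overlap and b-c abutment give none
        assert [(r.left_gene, r.right_gene, r.length) for r in recs] == [("c", "a", 20)]

    def test_gap_through_origin(self):
        p = make_plastome(400, [("a", 50, 100, "+"), ("b", 300, 380, "+")])
        recs = extract_igs(p)
        wrap = [r for r in recs if r.interval.wraps_origin]
        assert len(wrap) == 1
        assert (wrap[0].left_gene, wrap[0].right_gene, wrap[0].length) == ("b", "a", 70)

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            extract_igs(make_plastome(100, [("solo", 0, 10, "+")]))

    def test_coverage_identity(self, analyzed_small):
        canon, records, _ = analyzed_small
        for p in canon:
            total = total_footprint_length(p) + sum(r.length for r in records[p.accession])
            assert total == len(p.sequence)

    def test_lengths_match_generator_truth(self, analyzed_small):
        canon, records, manifest = analyzed_small
        for p in canon:
            by_key = {r.key: r.length for r in records[p.accession]}
            for cell_key, info in manifest.species[p.accession].cells.items():
                assert by_key[tuple(cell_key.split("|"))] == info["length"]


class TestGrouping:
    def _three(self, lengths):
        out = []
        for i, ln in enumerate(lengths):
            out.append(
                make_plastome(
                    300 + ln,
                    [("A", 0, 100, "+"), ("B", 100 + ln, 200 + ln, "+")],
                    accession=f"G{i}",
                )
            )
        return out

    def test_mean_over_present(self):
        groups = group_homologous_igs(self._three([100, 200, 600]))
        g = next(g for g in groups if g.key == ("A", "B"))
        assert g.lengths == {"G0": 100, "G1": 200, "G2": 600}
        assert g.mean_length == 300

    def test_missing_species_excluded_from_mean(self):
        cohort = self._three([100, 200, 600])
        # drop gene B from the last genome: its A-B spacer no longer exists
        cohort[2] = make_plastome(900, [("A", 0, 100, "+"), ("C", 800, 880, "+")], accession="G2")
        groups = group_homologous_igs(cohort)
        g = next(g for g in groups if g.key == ("A", "B"))
        assert set(g.lengths) == {"G0", "G1"}
        assert g.mean_length == 150

    def test_inverted_flank_order_same_group(self):
        a = make_plastome(400, [("A", 0, 100, "+"), ("B", 200, 300, "+")], accession="G0")
        b = make_plastome(400, [("B", 0, 100, "-"), ("A", 200, 300, "-")], accession="G1")
        groups = group_homologous_igs([a, b])
        keys = {g.key for g in groups}
        assert keys == {("A", "B")}
        g = groups[0]
        assert set(g.lengths) == {"G0", "G1"}


class TestPresence:
    def test_deleted_genes_absent(self, small_cohort):
        cohort, manifest = small_cohort
        table = presence_table(list(cohort), ["trnT-UGU", "trnR-UCG", "rbcL"])
        for p in cohort:
            lost = set(manifest.species[p.accession].lost_genes)
            for g in ("trnT-UGU", "trnR-UCG"):
                assert table[(p.accession, g)] == (g not in lost)
            assert table[(p.accession, "rbcL")]

    def test_ir_duplicate_counts_present(self):
        p = make_plastome(500, [("dup", 0, 50, "+"), ("dup", 400, 450, "-"), ("x", 100, 200, "+")])
        assert presence_table([p], ["dup"])[("TOY", "dup")]

    def test_empty_genome_all_absent(self):
        p = make_plastome(100, [])
        table = presence_table([p], ["a", "b"])
        assert not any(table.values())


class TestFeatureClass:
    @pytest.fixture()
    def spliced(self):
        p = make_plastome(
            400,
            [("g", 0, 100, "+", "gene")],
        )
        p.annotations.append(
            Annotation("g", "CDS", "+", (GenomicInterval(0, 40), GenomicInterval(60, 100)))
        )
        return p

    def test_inside_cds(self, spliced):
        assert classify_feature_class(spliced, GenomicInterval(5, 30)) == "CDS"

    def test_inside_intron(self, spliced):
        assert classify_feature_class(spliced, GenomicInterval(42, 58)) == "intron"

    def test_straddling_interval_majority_wins(self, spliced):
        # 40 bp of CDS (60..100) vs 60 bp of spacer (100..160)
        assert classify_feature_class(spliced, GenomicInterval(60, 160)) == "IGS"


def test_dedup_ir_keeps_one_copy_per_key(analyzed_small):
    canon, records, _ = analyzed_small
    for p in canon:
        recs = records[p.accession]
        dedup = dedup_ir_records(recs)
        ir_keys = [r.key for r in recs if r.region in ("IRa", "IRb")]
        dedup_ir_keys = [r.key for r in dedup if r.region in ("IRa", "IRb")]
        assert len(dedup_ir_keys) == len(set(ir_keys))
        assert len(set(dedup_ir_keys)) == len(dedup_ir_keys)
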