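"""Plastome model: intervals, GenBank IO, quadripartite detection."""

import numpy as np
import pytest

from plastigs.genome import (
    Annotation,
    GenomicInterval,
    NoInvertedRepeatError,
    Plastome,
    canonicalize,
    detect_quadripartite,
    locate_region,
    read_genbank,
    revcomp,
)
from plastigs.simulate import write_genbank

from conftest import make_plastome


class TestGenomicInterval:
    def test_plain_interval(self):
        iv = GenomicInterval(10, 50)
        assert iv.length() == 40
        assert iv.contains(10) and iv.contains(49)
        assert not iv.contains(50)
        assert iv.midpoint() == 30

    def test_wrapping_interval(self):
        iv = GenomicInterval(90, 10, wraps_origin=True)
        assert iv.length(100) == 20
        assert iv.contains(95) and iv.contains(5)
        assert not iv.contains(50)
        assert iv.midpoint(100) == 0
        assert iv.slice("A" * 90 + "C" * 10) == "C" * 10 + "A" * 10

    def test_annotation_invariants(self):
        with pytest.raises(ValueError):
            Annotation("", "gene", "+", (GenomicInterval(0, 10),))
        with pytest.raises(ValueError):
            Annotation("x", "gene", "+", ())


class TestGenbankRoundTrip:
    def test_three_gene_fixture(self, tmp_path):
        p = make_plastome(
            1000,
            [("rpoB", 100, 400, "-"), ("trnD-GUC", 500, 574, "-", "tRNA"), ("psbA", 600, 900, "+")],
        )
        f = tmp_path / "toy.gb"
        write_genbank(p, f)
        q = read_genbank(f)
        assert q.sequence == p.sequence
        got = sorted((a.name, a.kind, a.strand) for a in q.annotations)
        assert got == [("psbA", "gene", "+"), ("rpoB", "gene", "-"), ("trnD-GUC", "tRNA", "-")]

    def test_origin_spanning_join(self, tmp_path):
        p = Plastome(
            "TOY",
            "Toyus",
            "".join(np.random.default_rng(1).choice(list("ACGT"), 500)),
            [
                Annotation(
                    "wrapped", "gene", "+",
                    (GenomicInterval(450, 500), GenomicInterval(0, 30)),
                )
            ],
        )
        f = tmp_path / "wrap.gb"
        write_genbank(p, f)
        q = read_genbank(f)
        (a,) = q.annotations
        assert len(a.parts) == 2
        assert sum(part.length() for part in a.parts) == 80
        assert a.span(500).wraps_origin and a.span(500).length(500) == 80

    def test_no_features_warns(self, tmp_path):
        p = Plastome("EMPTY", "Nullus", "ACGT" * 100, [])
        f = tmp_path / "empty.gb"
        write_genbank(p, f)
        with pytest.warns(UserWarning, match="no annotated"):
            q = read_genbank(f)
        assert len(q.sequence) == 400


class TestDetectQuadripartite:
    def test_recovers_injected_partition(self, small_cohort):
        cohort, manifest = small_cohort
        for p in cohort:
            part = detect_quadripartite(p)
            got = {
                "LSC": [part.lsc.start, part.lsc.end],
                "IRb": [part.irb.start, part.irb.end],
                "SSC": [part.ssc.start, part.ssc.end],
                "IRa": [part.ira.start, part.ira.end],
            }
            assert got == manifest.species[p.accession].partition

    def test_ir_symmetry_and_tiling(self, analyzed_small):
        canon, _, _ = analyzed_small
        for p in canon:
            part = p.partition
            assert sum(part.lengths.values()) == len(p.sequence)
            ira_seq = part.ira.slice(p.sequence)
            irb_seq = part.irb.slice(p.sequence)
            assert revcomp(ira_seq) == irb_seq

    def test_random_sequence_has_no_ir(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 30_000))
        p = Plastome("RND", "Randomus", seq, [])
        with pytest.raises(NoInvertedRepeatError):
            detect_quadripartite(p)

    def test_too_short_genome_rejected(self):
        p = Plastome("S", "s", "ACGT" * 100, [])
        with pytest.raises(NoInvertedRepeatError):
            detect_quadripartite(p, min_ir=1000)


class TestLocateRegion:
    def test_boundary_conventions(self, analyzed_small):
        canon, _, _ = analyzed_small
        p = canon[0]
        assert locate_region(p, p.partition.lsc.start) == "LSC"
        assert locate_region(p, p.partition.lsc.end) == "IRb"  # half-open
        assert locate_region(p, p.partition.irb.end) == "SSC"
        assert locate_region(p, len(p.sequence) - 1) == "IRa"

    def test_counts_proportional_to_lengths(self, analyzed_small):
        canon, _, _ = analyzed_small
        p = canon[0]
        n = len(p.sequence)
        counts = {"LSC": 0, "IRb": 0, "SSC": 0, "IRa": 0}
        positions = range(0, n, max(1, n // 1000))
        for pos in positions:
            counts[locate_region(p, pos)] += 1
        total = sum(counts.values())
        for label, ln in p.partition.lengths.items():
            assert counts[label] / total == pytest.approx(ln / n, abs=0.01)

    def test_requires_partition(self):
        p = make_plastome(100, [("a", 0, 10, "+")])
        with pytest.raises(RuntimeError):
            locate_region(p, 5)


def test_canonical_orientation_starts_at_lsc(small_cohort):
    cohort, _ = small_cohort
    p = cohort[0]
    part = detect_quadripartite(p)
    p2 = canonicalize(p, part)
    assert p2.partition.lsc.start == 0
    assert p2.partition.irb.start == p2.partition.lsc.end
    assert p2.partition.ssc.start == p2.partition.irb.end
    assert p2.partition.ira.start == p2.partition.ssc.end
    assert p2.partition.ira.end == len(p2.sequence)
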