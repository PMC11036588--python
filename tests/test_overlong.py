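"""Overlong classification, spacer totals and cohort contrasts."""

import pytest

from plastigs.features import HomologousIgsGroup, IgsRecord
from plastigs.genome import GenomicInterval, Plastome
from plastigs.overlong import (
    classify_overlong,
    contrast_overlong,
    recovery_metrics,
    total_igs_length,
)
from plastigs.published import (
    compare_with_published_bold,
    load_overlong_matrix,
    matrix_to_groups,
)

from oracles import brute_mannwhitney_p


def group(lengths: dict, key=("A", "B")):
    g = HomologousIgsGroup(key=key, display_name="-".join(key))
    g.lengths.update(lengths)
    return g


class TestClassify:
    def test_strict_mean_rule(self):
        calls = classify_overlong([group({"s1": 100, "s2": 200, "s3": 600})])
        assert [(c.accession, c.is_overlong) for c in calls] == [
            ("s1", False),
            ("s2", False),
            ("s3", True),
        ]
        assert all(c.group_mean == 300 for c in calls)

    def test_all_equal_none_called(self):
        calls = classify_overlong([group({"a": 50, "b": 50, "c": 50})])
        assert not any(c.is_overlong for c in calls)

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            calls = classify_overlong([group({"only": 100})])
        assert calls == []

    def test_scale_equivariance(self):
        lengths = {"a": 120, "b": 480, "c": 333, "d": 90}
        base = {c.accession: c.is_overlong for c in classify_overlong([group(lengths)])}
        scaled = {
            c.accession: c.is_overlong
            for c in classify_overlong([group({k: v * 3 for k, v in lengths.items()})])
        }
        assert base == scaled

    def test_adding_longer_species_raises_mean_only(self):
        g1 = group({"a": 100, "b": 200})
        g2 = group({"a": 100, "b": 200, "c": 900})
        m1 = {c.accession: c.group_mean for c in classify_overlong([g1])}
        m2 = {c.accession: c.group_mean for c in classify_overlong([g2])}
        assert m2["a"] > m1["a"]
        flips = [
            acc
            for acc in ("a", "b")
            if not [c for c in classify_overlong([g1]) if c.accession == acc][0].is_overlong
            and [c for c in classify_overlong([g2]) if c.accession == acc][0].is_overlong
        ]
        assert flips == []  # a shorter cell never turns overlong by adding a longer one


class TestPublishedMatrix:
    def test_bold_reference_cells_called(self):
        lengths, bold = load_overlong_matrix()
        calls = classify_overlong(matrix_to_groups(lengths))
        by = {(c.key, c.accession): c for c in calls}
        rpoB = tuple(sorted(("rpoB", "trnD-GUC")))
        rps12 = tuple(sorted(("rps12", "rrn16")))
        assert by[(rpoB, "Adiantum malesianum")].length == 6877
        assert by[(rpoB, "Adiantum malesianum")].is_overlong
        assert by[(rps12, "Hemionitis subcordata")].length == 9179
        assert by[(rps12, "Hemionitis subcordata")].is_overlong

    def test_discrepancies_surfaced_not_hidden(self):
        lengths, bold = load_overlong_matrix()
        calls = classify_overlong(matrix_to_groups(lengths))
        disc = compare_with_published_bold(calls, bold)
        # the strict rule flags at least one unbolded cell; it must be reported
        assert {"species", "igs", "rule_overlong", "published_bold"} <= set(disc.columns)
        assert (
            (disc.species == "Adiantum aleuticum") & (disc.igs == "psbE-petL")
        ).any()


def _rec(acc, left, right, start, end, region):
    return IgsRecord(acc, left, right, GenomicInterval(start, end), end - start, 0.4, region)


class TestTotals:
    def test_no_ir_spacers_flag_irrelevant(self):
        p = Plastome("X", "x", "A" * 1000, [])
        recs = [_rec("X", "a", "b", 0, 100, "LSC"), _rec("X", "b", "c", 200, 350, "SSC")]
        assert total_igs_length(p, recs, dedup_ir=True) == 250
        assert total_igs_length(p, recs, dedup_ir=False) == 250

    def test_ir_copy_counted_once_when_dedup(self):
        p = Plastome("X", "x", "A" * 20000, [])
        recs = [
            _rec("X", "a", "b", 0, 100, "LSC"),
            _rec("X", "u", "v", 5000, 10000, "IRb"),
            _rec("X", "u", "v", 12000, 17000, "IRa"),
        ]
        assert total_igs_length(p, recs, dedup_ir=False) == 10100
        assert total_igs_length(p, recs, dedup_ir=True) == 5100

    def test_manifest_totals(self, analyzed_small):
        canon, records, manifest = analyzed_small
        for p in canon:
            st = manifest.species[p.accession]
            truth_total = sum(c["length"] * c["copies"] for c in st.cells.values())
            assert total_igs_length(p, records[p.accession], dedup_ir=False) == truth_total


class TestContrast:
    def test_exact_p_for_separated_gc(self):
        calls = []
        values = {}
        for i in range(5):
            key = (f"g{i}", f"h{i}")
            calls.append(
                classify_overlong([group({"s1": 100, "s2": 100, "s3": 5000}, key=key)])
            )
        calls = [c for cs in calls for c in cs]
        for c in calls:
            values[(c.key, c.accession)] = 0.55 if c.is_overlong else 0.40
        # keep one non-overlong value per group to get 5 vs 5
        values = {
            k: v
            for k, v in values.items()
            if v == 0.55 or k[1] == "s1"
        }
        res = contrast_overlong(calls, values, restrict_mixed=True)
        p_ref, _ = brute_mannwhitney_p([0.55] * 5, [0.40] * 5)
        assert res.p == pytest.approx(p_ref) == pytest.approx(2 / 252)

    def test_identical_distributions(self):
        calls = classify_overlong([group({"a": 100, "b": 100, "c": 900})])
        values = {(c.key, c.accession): 0.5 for c in calls}
        res = contrast_overlong(calls, values, restrict_mixed=True)
        assert res.p == 1.0

    def test_one_class_empty_returns_none(self):
        calls = classify_overlong([group({"a": 50, "b": 50, "c": 50})])
        values = {(c.key, c.accession): 0.5 for c in calls}
        assert contrast_overlong(calls, values) is None


def test_recovery_metrics_counts():
    calls = classify_overlong([group({"a": 100, "b": 100, "c": 900})])
    truth = {(("A", "B"), acc): acc == "c" for acc in "abc"}
    assert recovery_metrics(calls, truth) == (1.0, 1.0)
    truth_bad = {(("A", "B"), acc): acc == "a" for acc in "abc"}
    sens, prec = recovery_metrics(calls, truth_bad)
    assert sens == 0.0 and prec == 0.0
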