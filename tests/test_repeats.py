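"""Repeat scanners against planted repeats and brute-force oracles."""

import numpy as np
import pytest

from plastigs.genome import GenomicInterval, revcomp
from plastigs.repeats import (
    DEFAULT_SSR_THRESHOLDS,
    canonical_motif,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    localize_hits,
    minimal_period,
)

from oracles import brute_dispersed, brute_ssrs, brute_tandem


def random_seq(rng, n, with_n=False):
    if with_n:
        return "".join(rng.choice(list("ACGTN"), n, p=[0.27, 0.23, 0.23, 0.26, 0.01]))
    return "".join(rng.choice(list("ACGT"), n))


class TestSsr:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("A" * 10, [("A", 10)]),
            ("A" * 9, []),
            ("GGTCC" + "AT" * 5 + "GCGAA", [("AT", 5)]),
            ("AT" * 10, [("AT", 10)]),  # smallest period only, never as ATAT
            ("TTA" + "CAG" * 4 + "TTA", [("CAG", 4)]),
            ("ACGTAC" * 3, [("ACGTAC", 3)]),
        ],
    )
    def test_known_cases(self, seq, expected):
        assert [(h.motif, h.copies) for h in find_ssrs(seq)] == expected

    def test_partial_final_copy_excluded_from_interval(self):
        hits = find_ssrs("AAT" * 5 + "AA")
        (h,) = hits
        assert (h.interval.start, h.interval.end, h.copies) == (0, 15, 5)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            find_ssrs("ACGU")

    def test_matches_bruteforce_on_random(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            seq = random_seq(rng, int(rng.integers(60, 400)), with_n=True)
            got = sorted(
                (h.motif, h.copies, h.interval.start, h.interval.end) for h in find_ssrs(seq)
            )
            assert got == brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)

    def test_canonical_motif_pools_rotations_and_strands(self):
        assert canonical_motif("GAA") == "AAG"
        assert canonical_motif("TTC") == "AAG"  # reverse complement family
        assert canonical_motif("A") == "A" and canonical_motif("T") == "A"

    def test_minimal_period(self):
        assert minimal_period("ATATAT") == 2
        assert minimal_period("AAT" * 3) == 3
        assert minimal_period("ACGTT") == 5


class TestTandem:
    def test_thirty_bp_unit_four_copies(self):
        rng = np.random.default_rng(3)
        unit = random_seq(rng, 30)
        while minimal_period(unit) != 30:
            unit = random_seq(rng, 30)
        seq = random_seq(rng, 50) + unit * 4 + random_seq(rng, 50)
        hits = find_tandem_repeats(seq)
        assert any(h.period == 30 and h.copies >= 4 for h in hits)

    def test_polya_is_ssr_domain(self):
        assert find_tandem_repeats("A" * 50) == []

    def test_matches_bruteforce_on_random(self):
        rng = np.random.default_rng(8)
        for i in range(20):
            seq = random_seq(rng, int(rng.integers(100, 600)), with_n=True)
            if i % 3 == 0:
                seq = seq[:40] + seq[40:60] * 3 + seq[60:]
            got = sorted(
                (h.period, h.interval.start, h.interval.end)
                for h in find_tandem_repeats(seq, 7, 64, 24)
            )
            assert got == brute_tandem(seq, 7, 64, 24)


class TestDispersed:
    def test_planted_forward_duplication(self):
        rng = np.random.default_rng(0)
        bg = random_seq(rng, 300)
        block = random_seq(rng, 40)
        seq = bg[:100] + block + bg[100:200] + block + bg[200:]
        hits = find_dispersed_repeats(seq)
        covering = [
            h
            for h in hits
            if h.klass == "forward"
            and h.pos1.start <= 100
            and h.pos1.end >= 140
            and h.length >= 40
        ]
        assert covering and all(h.mismatches <= 3 for h in covering)

    def test_planted_palindrome(self):
        rng = np.random.default_rng(1)
        bg = random_seq(rng, 300)
        block = random_seq(rng, 40)
        seq = bg[:100] + block + bg[100:200] + revcomp(block) + bg[200:]
        pal = [h for h in find_dispersed_repeats(seq) if h.klass == "palindromic"]
        assert any(h.pos1.start <= 100 and h.pos1.end >= 140 and h.length >= 40 for h in pal)

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            find_dispersed_repeats("ACGT" * 50, min_len=6)

    def test_hits_are_maximal(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 400)
        seq = seq[:50] + seq[200:260] + seq[50:]
        for h in find_dispersed_repeats(seq):
            i, j, ln = h.pos1.start, h.pos2.start, h.length
            assert _hamming(seq, h) == h.mismatches <= 3
            for di in (-1, 1):
                grown = _grow(seq, h, di)
                if grown is not None:
                    assert grown > 3  # any extension adds a 4th mismatch

    def test_strand_involution_forward_palindromic(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 300)
        seq = seq[:40] + seq[150:190] + seq[40:150] + revcomp(seq[150:190]) + seq[190:]
        a = find_dispersed_repeats(seq)
        b = find_dispersed_repeats(revcomp(seq))
        for klass in ("forward", "palindromic"):
            la = sorted(h.length for h in a if h.klass == klass)
            lb = sorted(h.length for h in b if h.klass == klass)
            assert la == lb

    def test_matches_bruteforce_on_random(self):
        rng = np.random.default_rng(9)
        for i in range(15):
            seq = random_seq(rng, int(rng.integers(120, 500)), with_n=(i % 4 == 0))
            if i % 3 == 0:
                seq = seq[:30] + seq[60:100] + seq[30:]
            got = sorted(
                (h.klass, h.pos1.start, h.pos2.start, h.length, h.mismatches)
                for h in find_dispersed_repeats(seq)
            )
            assert got == brute_dispersed(seq, 30, 3)

    def test_mask_suppresses_pairs_inside_mask(self):
        rng = np.random.default_rng(6)
        bg = random_seq(rng, 400)
        block = random_seq(rng, 50)
        seq = bg[:50] + block + bg[50:100] + block + bg[100:]
        mask = [GenomicInterval(0, 220)]
        masked = find_dispersed_repeats(seq, mask=mask)
        assert not any(
            m.start <= h.pos1.start and h.pos2.end <= m.end for h in masked for m in mask
        )


def _transform(seq, h):
    s2 = seq[h.pos2.start : h.pos2.end]
    if h.klass == "forward":
        return s2
    if h.klass == "palindromic":
        return revcomp(s2)
    if h.klass == "reverse":
        return s2[::-1]
    return revcomp(s2)[::-1]  # complement


def _hamming(seq, h):
    s1 = seq[h.pos1.start : h.pos1.end]
    return sum(a != b or a == "N" for a, b in zip(s1, _transform(seq, h)))


def _grow(seq, h, direction):
    """Mismatch count after widening both copies by one base; None if out of
    bounds.  For the flipped classes copy2 grows on the opposite end."""
    n = len(seq)
    i1, j1, ln = h.pos1.start, h.pos2.start, h.length
    if h.klass in ("forward", "complement"):
        if direction < 0:
            i1 -= 1
            j1 -= 1
    else:  # reverse / palindromic: anti-parallel pairing
        if direction < 0:
            i1 -= 1  # copy2 grows right: j1 unchanged
        else:
            j1 -= 1  # copy1 grows right: copy2 grows left
    ln += 1
    if i1 < 0 or j1 < 0 or i1 + ln > n or j1 + ln > n:
        return None

    class G:  # widened pseudo-hit
        pos1 = GenomicInterval(i1, i1 + ln)
        pos2 = GenomicInterval(j1, j1 + ln)
        klass = h.klass
        length = ln

    return _hamming(seq, G)


def test_localize_percentages(analyzed_small):
    canon, _, _ = analyzed_small
    p = canon[0]
    ssr = find_ssrs(p.sequence)
    localized, summary = localize_hits(p, ssr)
    assert len(localized) == len(ssr)
    if summary["n"]:
        assert sum(summary["region_percent"].values()) == pytest.approx(100, abs=0.01)
        assert sum(summary["class_percent"].values()) == pytest.approx(100, abs=0.01)
        assert all(h.region != "unknown" for h in localized)
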