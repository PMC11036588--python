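"""Microsatellite (SSR), tandem-array and dispersed maximal-repeat scanners.

Three detectors with the conventional plastome-survey thresholds:

* SSRs: maximal perfect tandem runs of a 1-6 nt motif with minimum copy
  numbers 10/5/4/3/3/3 by motif length.  A run is reported only at its
  smallest period (a poly-A run is a mononucleotide SSR, not a degenerate
  "AA" dinucleotide).
* Tandem repeats: maximal exact tandem arrays with period 7-500 bp and at
  least two full copies, an exact-copy simplification of the usual fuzzy
  tandem finder.
* Dispersed repeats: maximal pairs of length >= 30 bp within Hamming
  distance 3, in four classes — forward (direct copy), palindromic
  (reverse-complement copy), reverse (reversed copy) and complement
  (complemented copy).  "Maximal" means extending either end would add a
  fourth mismatch or run off the sequence.

All scanners work on a linear DNA string over ACGTN; N never matches
anything, including itself.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import GenomicInterval, Plastome, locate_region, revcomp
from .features import classify_feature_class

__all__ = [
    "SsrHit",
    "TandemHit",
    "DispersedHit",
    "find_ssrs",
    "find_tandem_repeats",
    "find_dispersed_repeats",
    "localize_hits",
    "canonical_motif",
    "DEFAULT_SSR_THRESHOLDS",
    "DISPERSED_CLASSES",
]

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
DISPERSED_CLASSES = ("forward", "palindromic", "reverse", "complement")

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SsrHit:
    motif: str
    canonical_motif: str
    copies: int
    interval: GenomicInterval
    region: str = "unknown"
    feature_class: str = "unknown"

    @property
    def length(self) -> int:
        return len(self.motif) * self.copies


@dataclass(frozen=True)
class TandemHit:
    period: int
    copies: float
    interval: GenomicInterval
    consensus: str
    region: str = "unknown"
    feature_class: str = "unknown"

    @property
    def length(self) -> int:
        return self.interval.end - self.interval.start


@dataclass(frozen=True)
class DispersedHit:
    klass: str
    length: int
    pos1: GenomicInterval
    pos2: GenomicInterval
    mismatches: int
    region: str = "unknown"
    feature_class: str = "unknown"


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")


def minimal_period(s: str) -> int:
    """Smallest p with s[i] == s[i-p] for all i >= p (KMP failure function)."""
    n = len(s)
    fail = [0] * (n + 1)
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k]
        if s[i] == s[k]:
            k += 1
        fail[i + 1] = k
    return n - fail[n]


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over the motif's rotations and their reverse
    complements; used to pool A/T-type vs C/G-type motifs in summaries."""
    cands = []
    for m in (motif, revcomp(motif)):
        for i in range(len(m)):
            cands.append(m[i:] + m[:i])
    return min(cands)


def _shift_runs(arr: np.ndarray, p: int, valid: np.ndarray, min_run: int = 0):
    """Maximal runs [a, b) where arr[j] == arr[j-p] for all j in [a+p, b).

    Yields (a, b) with b - a >= ``min_run``.  ``valid`` masks out N positions
    (N matches nothing).  Run lengths are filtered vectorized so the Python
    loop only sees candidate runs.
    """
    n = len(arr)
    if n < 2 * p:
        return
    eq = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
    if not eq.any():
        return
    idx = np.flatnonzero(eq)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    a_arr = idx[starts]              # first matching j-p offset
    b_arr = idx[ends] + p + 1        # one past last matching j
    keep = b_arr - a_arr >= min_run
    for a, b in zip(a_arr[keep], b_arr[keep]):
        yield int(a), int(b)


def find_ssrs(seq: str, thresholds: dict[int, int] | None = None) -> list[SsrHit]:
    """Maximal perfect 1-6 nt microsatellites meeting the copy thresholds.

    The reported interval covers whole copies only: a 11 bp poly-A run is a
    mono-A SSR of 11 copies over 11 bp, but a 17 bp run of "AAT" gives 5
    copies over 15 bp anchored at the run start.
    """
    _check_alphabet(seq)
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    hits: list[SsrHit] = []
    for u, min_copies in sorted(thresholds.items()):
        for a, b in _shift_runs(arr, u, valid, min_run=u * min_copies):
            copies = (b - a) // u
            if copies < min_copies:
                continue
            if minimal_period(seq[a:b]) != u:
                continue  # reported at its smallest period instead
            motif = seq[a : a + u]
            iv = GenomicInterval(a, a + u * copies)
            hits.append(SsrHit(motif, canonical_motif(motif), copies, iv))
    hits.sort(key=lambda h: (h.interval.start, len(h.motif)))
    return hits


def find_tandem_repeats(
    seq: str, min_period: int = 7, max_period: int = 500, min_total: int = 24
) -> list[TandemHit]:
    """Maximal exact tandem arrays (>= 2 full copies) with period in range.

    An array is reported at the smallest period explaining its full run;
    periods below ``min_period`` belong to the SSR domain and are skipped.
    Copy number may be fractional (trailing partial copy).
    """
    _check_alphabet(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    n = len(seq)
    hits: list[TandemHit] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        for a, b in _shift_runs(arr, p, valid, min_run=max(2 * p, min_total)):
            if minimal_period(seq[a:b]) != p:
                continue
            hits.append(
                TandemHit(
                    period=p,
                    copies=round((b - a) / p, 2),
                    interval=GenomicInterval(a, b),
                    consensus=seq[a : a + p],
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.period))
    return hits


# ---------------------------------------------------------------------------
# Dispersed maximal pairs


def _class_target(seq: str, klass: str) -> str:
    if klass == "forward":
        return seq
    if klass == "palindromic":
        return revcomp(seq)
    if klass == "reverse":
        return seq[::-1]
    if klass == "complement":
        return seq.translate(_COMP)
    raise ValueError(f"unknown dispersed-repeat class: {klass}")


def _map_copy2(klass: str, u: int, length: int, n: int) -> int:
    """Start of copy2 in genome coordinates given its start u in the
    transformed string."""
    if klass in ("forward", "complement"):
        return u
    return n - u - length  # reverse / palindromic: transformed string is flipped


def _canonical_pair(klass: str, i1: int, i2: int, length: int):
    a, b = sorted((i1, i2))
    return (klass, a, b, length)


def _diag_windows(mism: Sequence[int], span: int, k: int):
    """All maximal <=k-mismatch windows on a full diagonal given its mismatch
    positions; used by the genome-scale path and mirrored by test oracles."""
    t = len(mism)
    if t <= k:
        return [(0, span - 1)]
    out = []
    for j in range(t - k + 1):
        left = mism[j - 1] + 1 if j > 0 else 0
        right = mism[j + k] - 1 if j + k < t else span - 1
        out.append((left, right))
    return out


def find_dispersed_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    mask: Optional[list[GenomicInterval]] = None,
    classes: Iterable[str] = DISPERSED_CLASSES,
) -> list[DispersedHit]:
    """All maximal dispersed repeat pairs in the four orientation classes.

    Seed-and-extend: every qualifying pair contains an exact seed of width
    ``ceil((min_len - k) / (k + 1))`` by pigeonhole, so exact seed matching
    loses nothing.  The trivial self pair is excluded; with ``mask`` given,
    pairs whose two copies both lie inside masked intervals (e.g. the IR pair
    itself) are suppressed.
    """
    _check_alphabet(seq)
    if min_len < 8:
        raise ValueError("min_len below 8 is under the seed width; not supported")
    k = max_mismatch
    w = -(-(min_len - k) // (k + 1))  # ceil
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int16)
    a[a == ord("N")] = -1  # N matches nothing
    hits: dict[tuple, DispersedHit] = {}
    for klass in classes:
        tgt = _class_target(seq, klass)
        b = np.frombuffer(tgt.encode(), dtype=np.uint8).astype(np.int16)
        b[b == ord("N")] = -2  # N in target also matches nothing (incl. N-N)
        index: dict[str, list[int]] = {}
        for u in range(n - w + 1):
            index.setdefault(tgt[u : u + w], []).append(u)
        run_gate: dict[int, int] = {}  # diagonal -> exact-run end already handled
        for i in range(n - w + 1):
            wmer = seq[i : i + w]
            if "N" in wmer:
                continue  # N matches nothing; exact seeds are N-free
            us = index.get(wmer)
            if not us:
                continue
            for u in us:
                d = u - i  # diagonal: b position minus a position
                # diagonal overlap in t-space: a[t] vs b[t + d]
                t0 = max(0, -d)
                t1 = min(n, n - d)  # exclusive
                span = t1 - t0
                if span < min_len:
                    continue
                seed_rel = i - t0
                gate = run_gate.get(d)
                if gate is not None and seed_rel <= gate:
                    continue
                # exact run around seed, then k+1 mismatches outward each way
                lo = seed_rel
                off_a, off_b = t0, t0 + d
                while lo > 0 and a[off_a + lo - 1] == b[off_b + lo - 1]:
                    lo -= 1
                hi = seed_rel + w - 1
                while hi + 1 < span and a[off_a + hi + 1] == b[off_b + hi + 1]:
                    hi += 1
                run_gate[d] = hi
                mism_left = []
                t = lo - 1
                while t >= 0 and len(mism_left) <= k:
                    if a[off_a + t] != b[off_b + t]:
                        mism_left.append(t)
                    t -= 1
                mism_right = []
                t = hi + 1
                while t < span and len(mism_right) <= k:
                    if a[off_a + t] != b[off_b + t]:
                        mism_right.append(t)
                    t += 1
                L, R = len(mism_left), len(mism_right)
                for n_left in range(k + 1):
                    n_right = k - n_left
                    # a truncated edge frees budget for the other side: such a
                    # window is maximal only if that other side is truncated too
                    if (n_left > L and n_right < R) or (n_right > R and n_left < L):
                        continue
                    left = mism_left[n_left] + 1 if n_left < L else 0
                    right = mism_right[n_right] - 1 if n_right < R else span - 1
                    length = right - left + 1
                    if length < min_len:
                        continue
                    i1 = t0 + left
                    u1 = t0 + d + left
                    j1 = _map_copy2(klass, u1, length, n)
                    if i1 == j1:
                        continue  # trivial self pair
                    key = _canonical_pair(klass, i1, j1, length)
                    if key in hits:
                        continue
                    mm = int((a[i1 : i1 + length] != b[u1 : u1 + length]).sum())
                    hits[key] = DispersedHit(
                        klass=klass,
                        length=length,
                        pos1=GenomicInterval(key[1], key[1] + length),
                        pos2=GenomicInterval(key[2], key[2] + length),
                        mismatches=mm,
                    )
    out = list(hits.values())
    if mask:
        def inside(iv: GenomicInterval) -> bool:
            return any(m.start <= iv.start and iv.end <= m.end for m in mask)

        out = [h for h in out if not (inside(h.pos1) and inside(h.pos2))]
    out.sort(key=lambda h: (h.pos1.start, h.pos2.start, h.klass, h.length))
    return out


# ---------------------------------------------------------------------------
# Localization


def localize_hits(p: Plastome, hits: list) -> tuple[list, dict]:
    """Fill region and feature class for each hit; summarize percentages.

    Region is assigned by the hit midpoint (copy 1 for dispersed pairs);
    IRa and IRb are pooled as "IR" in the summary.  Percentages are over the
    supplied hits and each block sums to 100.
    """
    if p.partition is None:
        raise RuntimeError("plastome has no partition")
    n = len(p.sequence)
    localized = []
    region_counts = {"LSC": 0, "IR": 0, "SSC": 0}
    class_counts = {"CDS": 0, "intron": 0, "IGS": 0}
    for h in hits:
        iv = h.pos1 if isinstance(h, DispersedHit) else h.interval
        region = locate_region(p, iv.midpoint(n))
        fclass = classify_feature_class(p, iv)
        localized.append(replace(h, region=region, feature_class=fclass))
        region_counts["IR" if region in ("IRa", "IRb") else region] += 1
        class_counts[fclass] += 1
    total = len(localized)
    summary = {
        "n": total,
        "region_percent": {
            k: (100.0 * v / total if total else 0.0) for k, v in region_counts.items()
        },
        "class_percent": {
            k: (100.0 * v / total if total else 0.0) for k, v in class_counts.items()
        },
    }
    return localized, summary
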