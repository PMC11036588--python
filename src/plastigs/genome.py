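"""Circular plastome model: intervals, annotations, quadripartite partition.

Coordinates are 0-based, half-open, on the forward strand throughout.
GenBank's 1-based inclusive convention is converted on read and write.
Genomes are circular: an interval may wrap the origin, in which case
``start > end`` and its span is ``[start, L) ∪ [0, end)``.

The quadripartite partition (LSC / IRb / SSC / IRa) is either detected from
the sequence itself (the two largest inverted-repeat copies) or taken from
explicit ``repeat_region`` annotations when the caller trusts them.  The
canonical orientation used for cross-species comparison is
LSC → IRb → SSC → IRa with the LSC start at position 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Annotation",
    "RegionPartition",
    "Plastome",
    "NoInvertedRepeatError",
    "revcomp",
    "read_genbank",
    "detect_quadripartite",
    "locate_region",
    "canonicalize",
    "gc_fraction",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FOOTPRINT_KINDS = ("gene", "tRNA", "rRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (Ns map to Ns)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); Ns excluded from numerator and denominator."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    return gc / atgc if atgc else 0.0


class NoInvertedRepeatError(ValueError):
    """Raised when no inverted-repeat pair qualifies as a quadripartite IR."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a circular genome.

    ``wraps_origin`` marks intervals spanning the origin: ``[start, L) ∪ [0, end)``.
    """

    start: int
    end: int
    wraps_origin: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for a wrapping interval")
            return self.end - self.start + genome_length
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        if self.wraps_origin:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def midpoint(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for a wrapping interval")
            return (self.start + self.length(genome_length) // 2) % genome_length
        return (self.start + self.end) // 2

    def slice(self, seq: str) -> str:
        """Sequence of the interval, reading through the origin if needed."""
        if self.wraps_origin:
            return seq[self.start :] + seq[: self.end]
        return seq[self.start : self.end]


@dataclass(frozen=True)
class Annotation:
    """A named feature: gene/CDS/tRNA/rRNA/intron with one or more parts.

    Multi-part features arise from spliced genes and from features spanning
    the circular origin (GenBank ``join`` locations).
    """

    name: str
    kind: str
    strand: str
    parts: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if not self.name:
            raise ValueError("annotation name must be non-empty")
        if not self.parts:
            raise ValueError("annotation needs at least one part")

    def total_length(self, genome_length: int | None = None) -> int:
        return sum(p.length(genome_length) for p in self.parts)

    def span(self, genome_length: int) -> GenomicInterval:
        """Smallest interval covering all parts.

        Adjacent parts written as ``[x, L) + [0, y)`` are folded into a single
        origin-wrapping interval; otherwise the linear hull is returned.
        """
        if len(self.parts) == 1:
            return self.parts[0]
        ps = sorted(self.parts, key=lambda p: p.start)
        if len(ps) == 2 and ps[1].end == genome_length and ps[0].start == 0:
            return GenomicInterval(ps[1].start, ps[0].end, wraps_origin=True)
        return GenomicInterval(ps[0].start, ps[-1].end)


@dataclass(frozen=True)
class RegionPartition:
    """The four quadripartite regions. IRa and IRb have equal length."""

    lsc: GenomicInterval
    irb: GenomicInterval
    ssc: GenomicInterval
    ira: GenomicInterval
    genome_length: int

    @property
    def lengths(self) -> dict[str, int]:
        L = self.genome_length
        return {
            "LSC": self.lsc.length(L),
            "IRb": self.irb.length(L),
            "SSC": self.ssc.length(L),
            "IRa": self.ira.length(L),
        }

    def validate(self) -> None:
        ln = self.lengths
        if ln["IRa"] != ln["IRb"]:
            raise ValueError("IR copies differ in length")
        if sum(ln.values()) != self.genome_length:
            raise ValueError("partition does not tile the genome")


@dataclass
class Plastome:
    """One circular annotated chloroplast genome."""

    accession: str
    species: str
    sequence: str
    annotations: list[Annotation] = field(default_factory=list)
    partition: Optional[RegionPartition] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def footprint_annotations(self, kinds: Iterable[str] = FOOTPRINT_KINDS) -> list[Annotation]:
        """Gene-level features (full extents; introns included).

        Falls back to CDS features for records annotated without ``gene``
        features.
        """
        kinds = tuple(kinds)
        out = [a for a in self.annotations if a.kind in kinds]
        if not any(a.kind == "gene" for a in out):
            out += [a for a in self.annotations if a.kind == "CDS"]
        return out


# ---------------------------------------------------------------------------
# GenBank input


def _parts_from_location(loc, genome_length: int) -> tuple[GenomicInterval, ...]:
    parts = []
    for p in loc.parts:
        s, e = int(p.start), int(p.end)
        if not (0 <= s < e <= genome_length):
            raise ValueError(f"feature part [{s},{e}) outside genome")
        parts.append(GenomicInterval(s, e))
    return tuple(parts)


def read_genbank(path: str | Path) -> Plastome:
    """Parse a GenBank flat file into a :class:`Plastome`.

    Captures gene/CDS/tRNA/rRNA/intron features; compound locations (spliced
    or origin-spanning joins) become multi-part annotations.  A record with
    no such features is returned with a warning; a record without sequence is
    an error.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    n = len(seq)
    species = rec.annotations.get("organism", "") or rec.description
    anns: list[Annotation] = []
    ir_hints: list[GenomicInterval] = []
    for f in rec.features:
        if f.type in ("gene", "CDS", "tRNA", "rRNA", "intron"):
            q = f.qualifiers
            name = (q.get("gene") or q.get("locus_tag") or q.get("product") or [""])[0]
            if not name:
                continue
            strand = "-" if f.location.strand == -1 else "+"
            anns.append(Annotation(name, f.type, strand, _parts_from_location(f.location, n)))
        elif f.type in ("repeat_region", "misc_feature"):
            note = " ".join(f.qualifiers.get("note", []) + f.qualifiers.get("rpt_type", []))
            if "inverted" in note.lower() or note.lower().startswith("ir"):
                s, e = int(f.location.start), int(f.location.end)
                ir_hints.append(GenomicInterval(s, e))
    if not anns:
        warnings.warn(f"{path}: no annotated gene features", stacklevel=2)
    p = Plastome(rec.id or rec.name, species, seq, anns)
    p._ir_hints = ir_hints  # type: ignore[attr-defined]
    return p


# ---------------------------------------------------------------------------
# Quadripartite detection

_SEED_K = 25
_BRIDGE_ANCHOR = 20


def _seed_pairs(seq: str, k: int) -> dict[int, list[tuple[int, int]]]:
    """Exact inverted k-mer seed pairs grouped by anti-diagonal a+b+k.

    A pair (a, b) means seq[a:a+k] == revcomp(seq[b:b+k]), a <= b.
    """
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    rc = revcomp(seq)
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for t in range(n - k + 1):
        hits = index.get(rc[t : t + k])
        if not hits:
            continue
        b = n - t - k  # position in seq whose revcomp k-mer sits at t in rc
        for a in hits:
            if a > b:
                continue
            by_diag.setdefault(a + b + k, []).append((a, b))
    return by_diag


def _extend_inverted(seq: str, a: int, b: int, ln: int, min_identity: float):
    """Grow an inverted pair seq[a:a+ln] ~ revcomp(seq[b:b+ln]).

    Extends exactly in both directions; a mismatch is bridged only when it is
    followed by ``_BRIDGE_ANCHOR`` exact matches (keeps extension from creeping
    into random flanking sequence) and only while overall identity stays at or
    above ``min_identity``.  Returns (a, b, ln, mismatches).
    """
    n = len(seq)
    mism = 0
    while True:
        grown = False
        while a + ln < b and seq[a + ln] == _COMP_ONE[seq[b - 1]]:
            b -= 1
            ln += 1
            grown = True
        while a > 0 and b + ln < n and seq[a - 1] == _COMP_ONE[seq[b + ln]]:
            a -= 1
            ln += 1
            grown = True
        # try bridging one mismatch on either side
        bridged = False
        if a + ln < b - 1:  # room for a right-side mismatch plus continuation
            ok = all(
                a + ln + 1 + t < b - 1 - t and seq[a + ln + 1 + t] == _COMP_ONE[seq[b - 2 - t]]
                for t in range(_BRIDGE_ANCHOR)
            )
            if ok and (mism + 1) <= (1.0 - min_identity) * (ln + 1 + _BRIDGE_ANCHOR):
                b -= 1
                ln += 1
                mism += 1
                bridged = True
        if not bridged and a > 0 and b + ln < n - 1:
            ok = all(
                a - 2 - t >= 0
                and b + ln + 1 + t < n
                and seq[a - 2 - t] == _COMP_ONE[seq[b + ln + 1 + t]]
                for t in range(_BRIDGE_ANCHOR)
            )
            if ok and (mism + 1) <= (1.0 - min_identity) * (ln + 1 + _BRIDGE_ANCHOR):
                a -= 1
                ln += 1
                mism += 1
                bridged = True
        if not (grown or bridged):
            return a, b, ln, mism


_COMP_ONE = {c: c.translate(_COMP) for c in "ACGTN"}


def _best_inverted_pair(seq: str, min_ir: int, min_identity: float):
    best = None
    for diag, seeds in _seed_pairs(seq, _SEED_K).items():
        seeds.sort()
        done_until = -1
        for a0, b0 in seeds:
            if a0 <= done_until:
                continue
            a, b, ln, mism = _extend_inverted(seq, a0, b0, _SEED_K, min_identity)
            done_until = a + ln - 1
            if ln >= min_ir and (ln - mism) / ln >= min_identity:
                if best is None or ln > best[2] or (ln == best[2] and (a, b) < (best[0], best[1])):
                    best = (a, b, ln, mism)
    return best


def _partition_from_pair(n: int, a: int, b: int, ln: int) -> RegionPartition:
    copy1 = GenomicInterval(a, a + ln)
    copy2 = GenomicInterval(b, b + ln)
    inner = GenomicInterval(a + ln, b)
    outer_len = n - (b + ln) + a
    if outer_len == 0 or inner.length() == 0:
        raise NoInvertedRepeatError("inverted pair leaves no single-copy regions")
    if b + ln == n:
        outer = GenomicInterval(0, a)
    elif a == 0:
        outer = GenomicInterval(b + ln, n)
    else:
        outer = GenomicInterval(b + ln, a, wraps_origin=True)
    if outer_len >= inner.length():
        lsc, ssc = outer, inner
        irb, ira = copy1, copy2  # circle order: outer, copy1, inner, copy2
    else:
        lsc, ssc = inner, outer
        irb, ira = copy2, copy1  # circle order: inner, copy2, outer, copy1
    part = RegionPartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n)
    part.validate()
    return part


def detect_quadripartite(
    p: Plastome,
    min_ir: int = 1000,
    min_identity: float = 0.99,
    trust_annotations: bool = False,
) -> RegionPartition:
    """Find the LSC/IRb/SSC/IRa partition from the largest inverted-repeat pair.

    Seed-and-extend from exact 25-mers shared between the sequence and its
    reverse complement; the partition maximizing IR length among pairs of
    length >= ``min_ir`` at identity >= ``min_identity`` is returned (longer
    single-copy segment labelled LSC).  Ns count as mismatches.  The scan is
    over the linearized sequence; if nothing is found, a half-rotation is
    retried to catch an IR split across the origin.

    With ``trust_annotations`` and a file carrying explicit IR annotations
    (``repeat_region``), those intervals are used instead of detection.
    """
    n = len(p.sequence)
    if n <= 2 * min_ir:
        raise NoInvertedRepeatError(f"genome length {n} <= 2*min_ir")
    if trust_annotations:
        hints = getattr(p, "_ir_hints", [])
        if len(hints) == 2:
            h = sorted(hints, key=lambda iv: iv.start)
            return _partition_from_pair(n, h[0].start, h[1].start, h[0].length())
    best = _best_inverted_pair(p.sequence, min_ir, min_identity)
    if best is not None:
        a, b, ln, _ = best
        return _partition_from_pair(n, a, b, ln)
    # retry on a half-rotated copy (IR split across the origin)
    shift = n // 2
    rot = p.sequence[shift:] + p.sequence[:shift]
    best = _best_inverted_pair(rot, min_ir, min_identity)
    if best is None:
        raise NoInvertedRepeatError(
            f"{p.accession}: no inverted pair >= {min_ir} bp at identity >= {min_identity}"
        )
    a, b, ln, _ = best
    part = _partition_from_pair(n, a, b, ln)
    unrot = lambda iv: _rotate_interval(iv, -shift, n)  # noqa: E731 — map back to file coords
    return RegionPartition(
        lsc=unrot(part.lsc), irb=unrot(part.irb), ssc=unrot(part.ssc), ira=unrot(part.ira),
        genome_length=n,
    )


def locate_region(p: Plastome, pos: int) -> str:
    """Region label (LSC/IRb/SSC/IRa) containing a position."""
    if p.partition is None:
        raise RuntimeError("plastome has no partition")
    if not 0 <= pos < len(p.sequence):
        raise ValueError(f"position {pos} outside genome")
    for label, iv in (
        ("LSC", p.partition.lsc),
        ("IRb", p.partition.irb),
        ("SSC", p.partition.ssc),
        ("IRa", p.partition.ira),
    ):
        if iv.contains(pos):
            return label
    raise AssertionError("partition does not tile the genome")


# ---------------------------------------------------------------------------
# Canonical orientation


def _rotate_interval(iv: GenomicInterval, shift: int, n: int) -> GenomicInterval:
    if iv.length(n) == n:
        return GenomicInterval(0, n)
    s = (iv.start - shift) % n
    e = (iv.end - shift) % n
    if s < e:
        return GenomicInterval(s, e)
    if e == 0:
        return GenomicInterval(s, n)
    return GenomicInterval(s, e, wraps_origin=True)


def _rotate_parts(parts: tuple[GenomicInterval, ...], shift: int, n: int):
    """Rotate annotation parts; a part that newly straddles the origin splits in two."""
    out = []
    for iv in parts:
        riv = _rotate_interval(iv, shift, n)
        if riv.wraps_origin:
            out.append(GenomicInterval(riv.start, n))
            out.append(GenomicInterval(0, riv.end))
        else:
            out.append(riv)
    return tuple(out)


def canonicalize(p: Plastome, partition: RegionPartition) -> Plastome:
    """Rotate a plastome so the detected LSC starts at position 0.

    Region order becomes LSC → IRb → SSC → IRa.  Annotations are rotated with
    the sequence (parts split where they now cross the origin).  No strand
    flip is applied; SSC orientation is reported, not normalized, by the
    junction analysis.
    """
    n = len(p.sequence)
    shift = partition.lsc.start
    if shift == 0:
        q = replace_partition(p, partition)
        return q
    seq = p.sequence[shift:] + p.sequence[:shift]
    anns = [
        Annotation(a.name, a.kind, a.strand, _rotate_parts(a.parts, shift, n))
        for a in p.annotations
    ]
    part = RegionPartition(
        lsc=_rotate_interval(partition.lsc, shift, n),
        irb=_rotate_interval(partition.irb, shift, n),
        ssc=_rotate_interval(partition.ssc, shift, n),
        ira=_rotate_interval(partition.ira, shift, n),
        genome_length=n,
    )
    part.validate()
    return Plastome(p.accession, p.species, seq, anns, part)


def replace_partition(p: Plastome, partition: RegionPartition) -> Plastome:
    q = Plastome(p.accession, p.species, p.sequence, list(p.annotations), partition)
    if hasattr(p, "_ir_hints"):
        q._ir_hints = p._ir_hints  # type: ignore[attr-defined]
    return q
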