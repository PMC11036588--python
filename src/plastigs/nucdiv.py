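"""Per-locus nucleotide diversity (Pi) from multiple alignments.

Pi is the average proportion of differing sites over all sequence pairs.
Gap handling follows the two conventional modes: *complete deletion*
(default) drops every column containing a gap or N before comparing, so all
pairs share one site set; *pairwise deletion* compares each pair over the
columns where both have an unambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = ["LocusAlignment", "PiResult", "nucleotide_diversity", "read_alignment"]

_MISSING = set("-N")


@dataclass(frozen=True)
class LocusAlignment:
    locus: str
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len({len(s) for s in self.sequences}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class PiResult:
    locus: str
    pi: float
    sites_used: int
    n: int
    degenerate: bool = False  # no usable sites


def read_alignment(path: str | Path, locus: str | None = None) -> LocusAlignment:
    """Aligned FASTA -> LocusAlignment (locus defaults to the file stem)."""
    path = Path(path)
    rows = tuple(str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta"))
    return LocusAlignment(locus or path.stem, rows)


def nucleotide_diversity(a: LocusAlignment, gap_mode: str = "complete-deletion") -> PiResult:
    """Average pairwise difference per comparable site.

    With no usable sites the result is flagged degenerate with pi = 0.
    """
    if gap_mode not in ("complete-deletion", "pairwise-deletion"):
        raise ValueError(f"unknown gap_mode: {gap_mode}")
    rows = a.sequences
    if gap_mode == "complete-deletion":
        keep = [
            j for j in range(a.length) if not any(r[j] in _MISSING for r in rows)
        ]
        if not keep:
            return PiResult(a.locus, 0.0, 0, a.n, degenerate=True)
        total = 0.0
        pairs = 0
        for i in range(a.n):
            for j in range(i + 1, a.n):
                d = sum(1 for c in keep if rows[i][c] != rows[j][c])
                total += d / len(keep)
                pairs += 1
        return PiResult(a.locus, total / pairs, len(keep), a.n)

    total = 0.0
    pairs = 0
    max_sites = 0
    any_usable = False
    for i in range(a.n):
        for j in range(i + 1, a.n):
            diffs = sites = 0
            for x, y in zip(rows[i], rows[j]):
                if x in _MISSING or y in _MISSING:
                    continue
                sites += 1
                diffs += x != y
            pairs += 1
            if sites:
                any_usable = True
                total += diffs / sites
                max_sites = max(max_sites, sites)
    if not any_usable:
        return PiResult(a.locus, 0.0, 0, a.n, degenerate=True)
    return PiResult(a.locus, total / pairs, max_sites, a.n)
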