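"""Gene / intron / intergenic-spacer partition of a plastome and
cross-species homologous spacer groups.

An intergenic spacer (IGS) is a maximal interval of the circular genome not
covered by any gene-level footprint (gene extents including introns; tRNA and
rRNA count as genes).  Spacers are named by their flanking genes, e.g.
``rpoB-trnD-GUC``; the homologous-group key is the *unordered* flank pair, so
a local inversion does not split a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomicInterval, Plastome, gc_fraction

__all__ = [
    "IgsRecord",
    "HomologousIgsGroup",
    "extract_igs",
    "group_homologous_igs",
    "presence_table",
    "classify_feature_class",
    "MISSING",
]

MISSING = None  # sentinel for a species absent from a homologous group


@dataclass(frozen=True)
class IgsRecord:
    """One intergenic spacer in one genome."""

    accession: str
    left_gene: str
    right_gene: str
    interval: GenomicInterval
    length: int
    gc: float
    region: str  # LSC / IRb / SSC / IRa / unknown

    @property
    def key(self) -> tuple[str, str]:
        """Orientation-normalized (unordered) flank pair."""
        return tuple(sorted((self.left_gene, self.right_gene)))

    @property
    def name(self) -> str:
        return f"{self.left_gene}-{self.right_gene}"


@dataclass
class HomologousIgsGroup:
    """Lengths of one spacer across a cohort, keyed by its flank pair.

    ``lengths[accession]`` is the spacer length, or absent when the two flank
    genes are not adjacent in that genome (gene lost or rearranged) — the
    "-" cells of a cross-species spacer table.
    """

    key: tuple[str, str]
    display_name: str
    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def mean_length(self) -> float:
        vals = list(self.lengths.values())
        return sum(vals) / len(vals) if vals else float("nan")

    @property
    def n_present(self) -> int:
        return len(self.lengths)


def extract_igs(p: Plastome) -> list[IgsRecord]:
    """All intergenic spacers of a plastome, flanked and region-assigned.

    Zero-length gaps (abutting or overlapping genes) are omitted.  The region
    is assigned by the spacer midpoint; without a partition it is "unknown".
    Raises if fewer than two gene-level annotations exist.
    """
    genes = p.footprint_annotations()
    if len(genes) < 2:
        raise ValueError(f"{p.accession}: need >= 2 gene annotations to define spacers")
    n = len(p.sequence)

    blocks: list[tuple[int, int]] = []
    start_names: dict[int, list[str]] = {}
    end_names: dict[int, list[str]] = {}
    for a in genes:
        span = a.span(n)
        if span.wraps_origin:
            blocks.append((span.start, n))
            blocks.append((0, span.end))
        else:
            blocks.append((span.start, span.end))
        start_names.setdefault(span.start % n, []).append(a.name)
        end_names.setdefault(span.end % n, []).append(a.name)

    merged = _merge_circular_linear(blocks)
    if len(merged) == 1 and merged[0][0] == 0 and merged[0][1] == n:
        return []  # fully covered genome: no spacers
    records: list[IgsRecord] = []
    for i, (s, e) in enumerate(merged):
        if i + 1 < len(merged):
            gap_len = merged[i + 1][0] - e
        else:
            gap_len = merged[0][0] + n - e  # wrap gap, possibly through the origin
        if gap_len <= 0:
            continue
        gap_start = e % n
        gap_end = (e + gap_len) % n
        wraps = gap_start + gap_len > n
        iv = GenomicInterval(gap_start, gap_end if wraps else gap_start + gap_len, wraps_origin=wraps)
        left = sorted(end_names.get(gap_start, []))
        right = sorted(start_names.get(gap_end, []))
        left_gene = left[0] if left else "?"
        right_gene = right[0] if right else "?"
        seq = iv.slice(p.sequence)
        region = "unknown"
        if p.partition is not None:
            from .genome import locate_region

            region = locate_region(p, iv.midpoint(n))
        records.append(
            IgsRecord(
                accession=p.accession,
                left_gene=left_gene,
                right_gene=right_gene,
                interval=iv,
                length=gap_len,
                gc=gc_fraction(seq),
                region=region,
            )
        )
    records.sort(key=lambda r: r.interval.start)
    return records


def dedup_ir_records(records: list[IgsRecord]) -> list[IgsRecord]:
    """One record per flank-pair key among IR-region spacers.

    The two mirrored IR copies of a spacer have the same key and the same
    length; only one is kept (the first by coordinate).  Single-copy spacers
    are untouched.
    """
    seen_ir: set[tuple[str, str]] = set()
    out = []
    for r in records:
        if r.region in ("IRa", "IRb"):
            if r.key in seen_ir:
                continue
            seen_ir.add(r.key)
        out.append(r)
    return out


def group_homologous_igs(
    cohort: list[Plastome], records_by_acc: dict[str, list[IgsRecord]] | None = None
) -> list[HomologousIgsGroup]:
    """Cross-species homologous spacer groups keyed by unordered flank pair.

    A species whose flank genes are not adjacent (gene lost, inserted gene,
    rearrangement) is simply absent from the group's length map.  Mirrored IR
    copies contribute a single entry per genome.  Empty groups are dropped.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 plastomes to group homologous spacers")
    groups: dict[tuple[str, str], HomologousIgsGroup] = {}
    for p in cohort:
        recs = (records_by_acc or {}).get(p.accession) or extract_igs(p)
        recs = dedup_ir_records(recs)
        for r in recs:
            g = groups.get(r.key)
            if g is None:
                g = HomologousIgsGroup(key=r.key, display_name=r.name)
                groups[r.key] = g
            # duplicate key within one genome outside the IRs: keep the longest
            if r.accession not in g.lengths or r.length > g.lengths[r.accession]:
                g.lengths[r.accession] = r.length
    return sorted(groups.values(), key=lambda g: g.key)


def presence_table(cohort: list[Plastome], gene_set: list[str]) -> dict[tuple[str, str], bool]:
    """(accession, gene) -> present, by case-insensitive exact symbol match."""
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    table: dict[tuple[str, str], bool] = {}
    for p in cohort:
        have = {a.name.casefold() for a in p.annotations}
        for g in gene_set:
            table[(p.accession, g)] = g.casefold() in have
    return table


def _interval_positions(iv: GenomicInterval, n: int) -> list[tuple[int, int]]:
    if iv.wraps_origin:
        return [(iv.start, n), (0, iv.end)]
    return [(iv.start, iv.end)]


def _overlap_bp(iv: GenomicInterval, blocks: list[tuple[int, int]], n: int) -> int:
    total = 0
    for s, e in _interval_positions(iv, n):
        for bs, be in blocks:
            total += max(0, min(e, be) - max(s, bs))
    return total


def classify_feature_class(p: Plastome, interval: GenomicInterval) -> str:
    """CDS / intron / IGS by largest base-pair overlap (ties: CDS > intron > IGS).

    "CDS" covers exonic coding plus tRNA/rRNA exons; "intron" is gene
    footprint not covered by exons; "IGS" is everything else.
    """
    n = len(p.sequence)
    exon_blocks: list[tuple[int, int]] = []
    for a in p.annotations:
        if a.kind in ("CDS", "tRNA", "rRNA"):
            for part in a.parts:
                exon_blocks.extend(_interval_positions(part, n))
    foot_blocks: list[tuple[int, int]] = []
    for a in p.footprint_annotations():
        for part in a.parts:
            foot_blocks.extend(_interval_positions(part, n))
    exon_blocks = [tuple(b) for b in _merge_circular_linear(exon_blocks)]
    foot_blocks = [tuple(b) for b in _merge_circular_linear(foot_blocks)]
    if not exon_blocks:
        # gene-only annotation: gene footprints count as coding sequence
        exon_blocks = foot_blocks
    cds_bp = _overlap_bp(interval, exon_blocks, n)
    foot_bp = _overlap_bp(interval, foot_blocks, n)
    intron_bp = max(0, foot_bp - cds_bp)
    igs_bp = interval.length(n) - foot_bp
    best = max(cds_bp, intron_bp, igs_bp)
    if cds_bp == best:
        return "CDS"
    if intron_bp == best:
        return "intron"
    return "IGS"


def _merge_circular_linear(blocks: list[tuple[int, int]]) -> list[list[int]]:
    if not blocks:
        return []
    blocks = sorted(blocks)
    merged = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def total_footprint_length(p: Plastome) -> int:
    """Total gene-footprint base pairs (introns included, overlaps merged)."""
    n = len(p.sequence)
    blocks: list[tuple[int, int]] = []
    for a in p.footprint_annotations():
        span = a.span(n)
        blocks.extend(_interval_positions(span, n))
    return sum(e - s for s, e in _merge_circular_linear(blocks))
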