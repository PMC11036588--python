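"""Overlong intergenic spacers and the cohort-level associations.

Within a homologous spacer group, a copy is *overlong* when its length
strictly exceeds the plain arithmetic mean over the species actually carrying
that spacer (the focal cell included; missing cells are never classified).
The cohort statistics tie this classification to genome size, GC content and
repeat content:

* Pearson correlation between per-species total IGS length and genome size;
* Mann-Whitney contrasts of GC (and repeat counts) between overlong and
  non-overlong copies, the GC contrast restricted to groups containing both
  classes;
* Pearson correlations between overlong-spacer length and the repeat base
  pairs they contain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .features import HomologousIgsGroup, IgsRecord, dedup_ir_records
from .genome import Plastome
from .stats import CorrelationResult, RankTestResult, mann_whitney_u, pearson_r

__all__ = [
    "OverlongCall",
    "AssociationReport",
    "classify_overlong",
    "total_igs_length",
    "correlate",
    "contrast_overlong",
]


@dataclass(frozen=True)
class OverlongCall:
    key: tuple[str, str]
    accession: str
    length: int
    group_mean: float
    is_overlong: bool


@dataclass
class AssociationReport:
    size_vs_igs: Optional[CorrelationResult] = None
    gc_contrast: Optional[RankTestResult] = None
    ssr_contrast: Optional[RankTestResult] = None
    tandem_contrast: Optional[RankTestResult] = None
    dispersed_contrast: Optional[RankTestResult] = None
    ssr_len_corr: Optional[CorrelationResult] = None
    tandem_len_corr: Optional[CorrelationResult] = None
    dispersed_len_corr: Optional[CorrelationResult] = None
    notes: list = None

    def __post_init__(self):
        if self.notes is None:
            self.notes = []


def classify_overlong(groups: Sequence[HomologousIgsGroup]) -> list[OverlongCall]:
    """One call per present cell; strict inequality against the group mean.

    Groups with fewer than two present species cannot define a meaningful
    mean and are skipped with a warning.
    """
    calls: list[OverlongCall] = []
    for g in groups:
        if g.n_present < 2:
            warnings.warn(f"group {g.display_name}: <2 entries, skipped", stacklevel=2)
            continue
        mean = g.mean_length
        for acc, ln in sorted(g.lengths.items()):
            calls.append(OverlongCall(g.key, acc, ln, mean, ln > mean))
    return calls


def total_igs_length(p: Plastome, records: Sequence[IgsRecord], dedup_ir: bool = True) -> int:
    """Total spacer length of one genome.

    With ``dedup_ir`` (default) the two mirrored IR copies of a spacer are
    counted once — the one-copy convention of per-species spacer totals.
    """
    recs = [r for r in records if r.accession == p.accession]
    if dedup_ir:
        recs = dedup_ir_records(list(recs))
    return sum(r.length for r in recs)


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation (delegates to the stats core)."""
    return pearson_r(x, y)


def contrast_overlong(
    calls: Sequence[OverlongCall],
    values: Mapping[tuple[tuple[str, str], str], float],
    restrict_mixed: bool = True,
) -> Optional[RankTestResult]:
    """Mann-Whitney contrast of a per-cell value between overlong and
    non-overlong copies.

    ``values`` maps (group key, accession) to the cell's value (GC fraction,
    repeat count, ...).  With ``restrict_mixed`` only groups containing both
    classes contribute — the within-spacer comparison.  Returns None when one
    class is empty (insufficient data).
    """
    by_group: dict[tuple[str, str], list[OverlongCall]] = {}
    for c in calls:
        by_group.setdefault(c.key, []).append(c)
    over, normal = [], []
    for key, cs in by_group.items():
        if restrict_mixed:
            flags = {c.is_overlong for c in cs}
            if flags != {True, False}:
                continue
        for c in cs:
            v = values.get((c.key, c.accession))
            if v is None:
                continue
            (over if c.is_overlong else normal).append(v)
    if not over or not normal:
        return None
    return mann_whitney_u(over, normal)


def repeat_counts_per_igs(
    records: Sequence[IgsRecord], hits: Sequence, genome_length: int
) -> dict[tuple[tuple[str, str], str], int]:
    """Number of repeat hits whose midpoint falls inside each spacer.

    Keys follow the (group key, accession) convention of
    :func:`contrast_overlong`.  When the two mirrored IR copies share a key,
    hits in either copy accumulate on the same cell.
    """
    counts: dict[tuple[tuple[str, str], str], int] = {}
    for r in records:
        counts.setdefault((r.key, r.accession), 0)
    for h in hits:
        iv = getattr(h, "pos1", None) or h.interval
        mid = iv.midpoint(genome_length)
        for r in records:
            if r.interval.contains(mid):
                counts[(r.key, r.accession)] += 1
                break
    return counts


def repeat_bp_per_igs(
    records: Sequence[IgsRecord], hits: Sequence, genome_length: int
) -> dict[tuple[tuple[str, str], str], int]:
    """Summed repeat base pairs (hit lengths) per spacer, midpoint-assigned."""
    bp: dict[tuple[tuple[str, str], str], int] = {}
    for r in records:
        bp.setdefault((r.key, r.accession), 0)
    for h in hits:
        iv = getattr(h, "pos1", None) or h.interval
        mid = iv.midpoint(genome_length)
        ln = h.length if hasattr(h, "length") else iv.length(genome_length)
        for r in records:
            if r.interval.contains(mid):
                bp[(r.key, r.accession)] += int(ln)
                break
    return bp


def recovery_metrics(
    calls: Sequence[OverlongCall], truth: Mapping[tuple[tuple[str, str], str], bool]
) -> tuple[float, float]:
    """(sensitivity, precision) of overlong calls against ground truth.

    Only cells present in both the calls and the truth map are scored.
    """
    tp = fp = fn = 0
    for c in calls:
        t = truth.get((c.key, c.accession))
        if t is None:
            continue
        if c.is_overlong and t:
            tp += 1
        elif c.is_overlong and not t:
            fp += 1
        elif not c.is_overlong and t:
            fn += 1
    sens = tp / (tp + fn) if tp + fn else 1.0
    prec = tp / (tp + fp) if tp + fp else 1.0
    return sens, prec
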