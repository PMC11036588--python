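"""Genes at the four IR/single-copy junctions, with distances.

For each of the four boundary points (LSC/IRb, IRb/SSC, SSC/IRa, IRa/LSC)
the report lists the nearest gene strictly on each side together with its
distance to the junction (0 when abutting), plus a *spanning* call when a
gene footprint straddles the point.  Cross-species comparison then flags
genomes whose junction gene sets deviate from the cohort's modal pattern —
the usual signature of IR expansion/contraction or an SSC inversion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome import Plastome

__all__ = ["JunctionGeneCall", "junction_report", "compare_junctions", "JUNCTIONS"]

JUNCTIONS = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


@dataclass(frozen=True)
class JunctionGeneCall:
    junction: str
    side: str  # upstream / downstream / spanning
    gene: str
    distance: int  # bp from the gene edge to the junction point (0 = abutting)
    gene_length: int


def _junction_points(p: Plastome) -> dict[str, int]:
    part = p.partition
    n = len(p.sequence)
    return {
        "LSC/IRb": part.lsc.end % n,
        "IRb/SSC": part.irb.end % n,
        "SSC/IRa": part.ssc.end % n,
        "IRa/LSC": part.ira.end % n,
    }


def junction_report(p: Plastome) -> list[JunctionGeneCall]:
    """Nearest genes (and spanning genes) at each of the four junctions.

    Distances are measured on the circle; ties between equidistant genes are
    reported for all tied genes, ordered by symbol.
    """
    if p.partition is None:
        raise ValueError(f"{p.accession}: partition required for junction analysis")
    n = len(p.sequence)
    genes = []
    for a in p.footprint_annotations():
        span = a.span(n)
        genes.append((a.name, span, a.total_length(n)))
    calls: list[JunctionGeneCall] = []
    for junction, pos in _junction_points(p).items():
        spanning, upstream, downstream = [], [], []
        for name, span, glen in genes:
            s, e = span.start, span.end
            if span.wraps_origin:
                inside = pos > s or pos < e
            else:
                inside = s < pos < e
            if inside:
                spanning.append((0, name, glen))
                continue
            d_up = (pos - e) % n  # gene ends before the junction
            d_down = (s - pos) % n  # gene starts after the junction
            upstream.append((d_up, name, glen))
            downstream.append((d_down, name, glen))
        for side, cands in (("upstream", upstream), ("downstream", downstream)):
            if not cands:
                continue
            best = min(d for d, _, _ in cands)
            for d, name, glen in sorted(c for c in cands if c[0] == best):
                calls.append(JunctionGeneCall(junction, side, name, d, glen))
        for _, name, glen in sorted(spanning, key=lambda c: c[1]):
            calls.append(JunctionGeneCall(junction, "spanning", name, 0, glen))
    return calls


def compare_junctions(cohort: list[Plastome]) -> dict:
    """Tabulate per-species junction gene sets and flag deviants.

    Returns {"matrix": {(accession, junction): sorted gene tuple},
    "mode": {junction: modal gene tuple}, "flagged": {accession: [junctions]}}.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 genomes to compare junctions")
    matrix: dict[tuple[str, str], tuple[str, ...]] = {}
    for p in cohort:
        report = junction_report(p)
        for junction in JUNCTIONS:
            genes = tuple(sorted({c.gene for c in report if c.junction == junction}))
            matrix[(p.accession, junction)] = genes
    mode: dict[str, tuple[str, ...]] = {}
    for junction in JUNCTIONS:
        counts = Counter(matrix[(p.accession, junction)] for p in cohort)
        mode[junction] = counts.most_common(1)[0][0]
    flagged: dict[str, list[str]] = {}
    for p in cohort:
        bad = [j for j in JUNCTIONS if matrix[(p.accession, j)] != mode[j]]
        if bad:
            flagged[p.accession] = bad
    return {"matrix": matrix, "mode": mode, "flagged": flagged}
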