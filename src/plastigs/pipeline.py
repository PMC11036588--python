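"""Cohort-level orchestration: read genomes, partition, extract spacers,
scan repeats, classify overlong spacers and assemble the association report.

Outputs are deterministic: rows are sorted, floats are fixed-format in TSVs
(full precision in JSON), and every file starts with a header naming the
package version and configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .features import dedup_ir_records, extract_igs, group_homologous_igs, presence_table
from .genome import NoInvertedRepeatError, Plastome, canonicalize, detect_quadripartite, gc_fraction, read_genbank
from .junctions import compare_junctions, junction_report
from .overlong import (
    AssociationReport,
    classify_overlong,
    contrast_overlong,
    correlate,
    repeat_bp_per_igs,
    repeat_counts_per_igs,
    total_igs_length,
)
from .repeats import (
    DEFAULT_SSR_THRESHOLDS,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    localize_hits,
)

log = logging.getLogger("plastigs")

__all__ = ["RunConfig", "run_full_analysis", "range_summary", "load_cohort", "scan_genome"]


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    ssr_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_SSR_THRESHOLDS))
    tandem_min_period: int = 7
    tandem_max_period: int = 500
    tandem_min_total: int = 24
    dispersed_min_len: int = 30
    dispersed_max_mismatch: int = 3
    min_ir: int = 1000
    min_identity: float = 0.99
    dedup_ir: bool = True
    gap_mode: str = "complete-deletion"
    stat_mode: str = "auto"
    skip_bad: bool = False
    scan_repeats: bool = True
    seed: int = 0

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (I/O paths excluded, so the
        same analysis on the same data hashes identically anywhere)."""
        doc = {k: v for k, v in asdict(self).items() if k not in ("input_dir", "output_dir")}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (
        f"# plastigs {__version__} | config {cfg.digest()} | "
        "coordinates 0-based half-open (BED convention)\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.4g")


def load_cohort(cfg: RunConfig) -> list[Plastome]:
    """Read, partition and canonicalize every GenBank file in the input dir."""
    paths = sorted(Path(cfg.input_dir).glob("*.gb")) + sorted(Path(cfg.input_dir).glob("*.gbk"))
    if not paths:
        raise FileNotFoundError(f"no GenBank files in {cfg.input_dir}")
    cohort = []
    for path in paths:
        try:
            p = read_genbank(path)
            part = detect_quadripartite(p, min_ir=cfg.min_ir, min_identity=cfg.min_identity)
            p = canonicalize(p, part)
        except (NoInvertedRepeatError, ValueError) as exc:
            if cfg.skip_bad:
                log.warning("skipping %s: %s", path.name, exc)
                continue
            raise
        log.info("loaded %s (%d bp)", p.accession, len(p.sequence))
        cohort.append(p)
    return cohort


def scan_genome(p: Plastome, cfg: RunConfig):
    """All three repeat scans on one genome, localized; IR pair masked for
    the dispersed scan."""
    ssr = find_ssrs(p.sequence, cfg.ssr_thresholds)
    tandem = find_tandem_repeats(
        p.sequence, cfg.tandem_min_period, cfg.tandem_max_period, cfg.tandem_min_total
    )
    mask = None
    if p.partition is not None:
        pad = 100
        mask = []
        for iv in (p.partition.irb, p.partition.ira):
            mask.append(
                type(iv)(max(0, iv.start - pad), min(len(p.sequence), iv.end + pad))
            )
    dispersed = find_dispersed_repeats(
        p.sequence, cfg.dispersed_min_len, cfg.dispersed_max_mismatch, mask=mask
    )
    out = {}
    for name, hits in (("ssr", ssr), ("tandem", tandem), ("dispersed", dispersed)):
        localized, summary = localize_hits(p, hits)
        out[name] = (localized, summary)
    return out


def range_summary(table: pd.DataFrame) -> dict:
    """Column extrema (with the species attaining them) of a cohort feature
    table with columns species, size_bp, gc_percent, lsc_bp, ir_bp, ssc_bp."""
    if table.empty:
        raise ValueError("empty feature table")
    out = {}
    for col in ("size_bp", "gc_percent", "lsc_bp", "ssc_bp", "ir_bp"):
        lo, hi = table[col].min(), table[col].max()
        # ties broken by species name for order-independent attribution
        lo_sp = table.loc[table[col] == lo, "species"].min()
        hi_sp = table.loc[table[col] == hi, "species"].min()
        out[col] = {
            "min": float(lo),
            "min_species": str(lo_sp),
            "max": float(hi),
            "max_species": str(hi_sp),
        }
    return out


def _result_to_dict(res) -> dict | None:
    if res is None:
        return {"status": "insufficient-data"}
    d = asdict(res)
    d["status"] = "ok"
    return d


def build_association_report(
    cohort: list[Plastome],
    records_by_acc: dict,
    scans_by_acc: dict | None,
    stat_mode: str = "auto",
    dedup_ir: bool = True,
) -> tuple[AssociationReport, list]:
    """All cohort statistics: size correlation, GC and repeat contrasts,
    repeat-length correlations over overlong cells."""
    report = AssociationReport()
    groups = group_homologous_igs(cohort, records_by_acc)
    calls = classify_overlong([g for g in groups if g.n_present >= 2])

    sizes, totals = [], []
    for p in cohort:
        sizes.append(len(p.sequence))
        totals.append(total_igs_length(p, records_by_acc[p.accession], dedup_ir=dedup_ir))
    try:
        report.size_vs_igs = correlate(totals, sizes)
    except ValueError as exc:
        report.notes.append(f"size correlation: {exc}")

    gc_by_cell = {}
    for p in cohort:
        for r in dedup_ir_records(records_by_acc[p.accession]):
            gc_by_cell[(r.key, r.accession)] = r.gc
    report.gc_contrast = contrast_overlong(calls, gc_by_cell, restrict_mixed=True)

    if scans_by_acc:
        for kind in ("ssr", "tandem", "dispersed"):
            counts, bps = {}, {}
            for p in cohort:
                recs = dedup_ir_records(records_by_acc[p.accession])
                hits = scans_by_acc[p.accession][kind][0]
                counts.update(repeat_counts_per_igs(recs, hits, len(p.sequence)))
                bps.update(repeat_bp_per_igs(recs, hits, len(p.sequence)))
            setattr(
                report,
                f"{kind}_contrast",
                contrast_overlong(calls, counts, restrict_mixed=False),
            )
            over = [c for c in calls if c.is_overlong and (c.key, c.accession) in bps]
            if len(over) >= 3:
                x = [c.length for c in over]
                y = [bps[(c.key, c.accession)] for c in over]
                try:
                    setattr(report, f"{kind}_len_corr", correlate(x, y))
                except ValueError as exc:
                    report.notes.append(f"{kind} length correlation: {exc}")
    return report, calls


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the whole comparative analysis over a genome directory.

    Writes the per-genome feature table, the spacer tables (records, groups,
    overlong calls), the three repeat tables with a localization summary,
    the junction table and the association report.  Returns the output paths.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(cfg)
    if not cohort:
        raise RuntimeError("no usable genomes")

    # per-genome feature table (published table schema; IR = both copies)
    rows = []
    for p in cohort:
        ln = p.partition.lengths
        rows.append(
            {
                "accession": p.accession,
                "species": p.species,
                "size_bp": len(p.sequence),
                "gc_percent": round(100 * gc_fraction(p.sequence), 1),
                "lsc_bp": ln["LSC"],
                "ir_bp": ln["IRa"] + ln["IRb"],
                "ssc_bp": ln["SSC"],
            }
        )
    table1 = pd.DataFrame(rows).sort_values("accession").reset_index(drop=True)
    _write_tsv(table1, outdir / "table1_report.tsv", cfg)

    # gene presence/absence over the union of symbols seen anywhere
    gene_set = sorted({a.name for p in cohort for a in p.footprint_annotations()})
    presence = presence_table(cohort, gene_set)
    prows = [
        {
            "accession": p.accession,
            **{g: int(presence[(p.accession, g)]) for g in gene_set},
        }
        for p in cohort
    ]
    _write_tsv(pd.DataFrame(prows), outdir / "presence.tsv", cfg)

    records_by_acc = {p.accession: extract_igs(p) for p in cohort}
    igs_rows = [
        {
            "accession": r.accession,
            "igs": r.name,
            "start": r.interval.start,
            "end": r.interval.end,
            "wraps_origin": r.interval.wraps_origin,
            "length": r.length,
            "gc": round(r.gc, 4),
            "region": r.region,
        }
        for p in cohort
        for r in records_by_acc[p.accession]
    ]
    _write_tsv(pd.DataFrame(igs_rows), outdir / "igs_table.tsv", cfg)

    scans_by_acc = None
    if cfg.scan_repeats:
        scans_by_acc = {}
        for p in cohort:
            scans_by_acc[p.accession] = scan_genome(p, cfg)
            log.info("scanned %s", p.accession)
        for kind in ("ssr", "tandem", "dispersed"):
            rows = []
            for p in cohort:
                for h in scans_by_acc[p.accession][kind][0]:
                    base = {"accession": p.accession, "region": h.region, "class": h.feature_class}
                    if kind == "ssr":
                        base.update(
                            motif=h.motif, canonical=h.canonical_motif, copies=h.copies,
                            start=h.interval.start, end=h.interval.end,
                        )
                    elif kind == "tandem":
                        base.update(
                            period=h.period, copies=h.copies,
                            start=h.interval.start, end=h.interval.end,
                        )
                    else:
                        base.update(
                            klass=h.klass, length=h.length, mismatches=h.mismatches,
                            start=h.pos1.start, end=h.pos1.end,
                            start2=h.pos2.start, end2=h.pos2.end,
                        )
                    rows.append(base)
            _write_tsv(pd.DataFrame(rows), outdir / f"{kind}.tsv", cfg)
        summary = {
            "version": __version__,
            "config": cfg.digest(),
        }
        summary.update(
            {
                p.accession: {
                    k: scans_by_acc[p.accession][k][1] for k in ("ssr", "tandem", "dispersed")
                }
                for p in cohort
            }
        )
        (outdir / "repeat_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    jrows = [
        {
            "accession": p.accession,
            "junction": c.junction,
            "side": c.side,
            "gene": c.gene,
            "distance": c.distance,
            "gene_length": c.gene_length,
        }
        for p in cohort
        for c in junction_report(p)
    ]
    _write_tsv(pd.DataFrame(jrows), outdir / "junctions.tsv", cfg)

    result = {"outputs": sorted(str(f) for f in outdir.iterdir())}
    if len(cohort) >= 2:
        groups = group_homologous_igs(cohort, records_by_acc)
        grows = []
        accs = [p.accession for p in cohort]
        for g in groups:
            row = {"igs": g.display_name, "mean_length": round(g.mean_length, 1)}
            for acc in accs:
                row[acc] = g.lengths.get(acc, "-")
            grows.append(row)
        _write_tsv(pd.DataFrame(grows), outdir / "igs_groups.tsv", cfg)

        report, calls = build_association_report(
            cohort, records_by_acc, scans_by_acc, cfg.stat_mode, cfg.dedup_ir
        )
        crows = [
            {
                "igs": "-".join(c.key),
                "accession": c.accession,
                "length": c.length,
                "group_mean": round(c.group_mean, 1),
                "is_overlong": c.is_overlong,
            }
            for c in calls
        ]
        _write_tsv(pd.DataFrame(crows), outdir / "overlong_calls.tsv", cfg)
        doc = {
            "config": cfg.digest(),
            "version": __version__,
            "junction_comparison": {
                "flagged": compare_junctions(cohort)["flagged"],
            },
            "associations": {
                name: _result_to_dict(getattr(report, name))
                for name in (
                    "size_vs_igs", "gc_contrast", "ssr_contrast", "tandem_contrast",
                    "dispersed_contrast", "ssr_len_corr", "tandem_len_corr",
                    "dispersed_len_corr",
                )
            },
            "notes": report.notes,
        }
        (outdir / "association_report.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
        result["report"] = doc
    else:
        log.warning("single genome: cohort statistics skipped")
    result["outputs"] = sorted(str(f) for f in outdir.iterdir())
    return result


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
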