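#!/usr/bin/env python
"""Score the overlong-spacer classification against the generator's ground
truth and summarize what drives genome-size variation in the cohort.

Reads results/cohort/; writes results/recovery.json.
"""

import json
from pathlib import Path

from plastigs.features import dedup_ir_records, extract_igs, group_homologous_igs
from plastigs.genome import canonicalize, detect_quadripartite, read_genbank
from plastigs.overlong import (
    classify_overlong,
    contrast_overlong,
    recovery_metrics,
    total_igs_length,
)
from plastigs.simulate import SyntheticConfig, TruthManifest
from plastigs.stats import pearson_r

ROOT = Path(__file__).resolve().parent.parent
IN = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "recovery.json"


def load_manifest() -> dict:
    return json.loads((IN / "manifest.json").read_text())


def main() -> None:
    if not IN.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    doc = load_manifest()
    truth = {}
    for acc, st in doc["species"].items():
        for cell_key, info in st["cells"].items():
            truth[(tuple(cell_key.split("|")), acc)] = bool(info["expanded"])

    canon, records = [], {}
    for gb in sorted(IN.glob("*.gb")):
        p = read_genbank(gb)
        p = canonicalize(p, detect_quadripartite(p))
        canon.append(p)
        records[p.accession] = extract_igs(p)

    groups = group_homologous_igs(canon, records)
    calls = classify_overlong([g for g in groups if g.n_present >= 2])
    sens, prec = recovery_metrics(calls, truth)

    totals = [total_igs_length(p, records[p.accession], dedup_ir=False) for p in canon]
    sizes = [len(p.sequence) for p in canon]
    corr = pearson_r(totals, sizes)

    gc = {}
    for p in canon:
        for r in dedup_ir_records(records[p.accession]):
            gc[(r.key, r.accession)] = r.gc
    gc_res = contrast_overlong(calls, gc, restrict_mixed=True)

    out = {
        "n_genomes": len(canon),
        "n_classified_cells": len(calls),
        "n_overlong_calls": sum(c.is_overlong for c in calls),
        "sensitivity": sens,
        "precision": prec,
        "igs_total_vs_size_r": corr.r,
        "igs_total_vs_size_p": corr.p,
        "gc_contrast_p": gc_res.p if gc_res else None,
    }
    OUT.write_text(json.dumps(out, indent=1, sort_keys=True))
    print(f"classified {out['n_classified_cells']} cells, "
          f"{out['n_overlong_calls']} called overlong")
    print(f"recovery vs ground truth: sensitivity {sens:.3f}, precision {prec:.3f}")
    print(f"spacer total vs genome size: r = {corr.r:.4f} (p = {corr.p:.3g})")
    if gc_res:
        print(f"GC overlong-vs-baseline contrast: p = {gc_res.p:.3g}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
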