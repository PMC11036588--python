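#!/usr/bin/env python
"""Per-locus nucleotide diversity (Pi) from user-supplied multiple
alignments.

The published Pi ranges come from alignments of the shared genes and
spacers of the 41 accessions; those alignments are built externally and are
not bundled here.  Point this script at a directory of aligned FASTA files
(one locus per file) to reproduce that table for your own data:

    python analysis/05_nucleotide_diversity.py <alignment_dir>

Writes results/pi.tsv.
"""

import sys
from pathlib import Path

from plastigs.nucdiv import nucleotide_diversity, read_alignment

OUT = Path(__file__).resolve().parent.parent / "results" / "pi.tsv"


def main() -> None:
    if len(sys.argv) != 2:
        raise SystemExit(__doc__)
    aln_dir = Path(sys.argv[1])
    files = sorted(list(aln_dir.glob("*.fa")) + list(aln_dir.glob("*.fasta")))
    if not files:
        raise SystemExit(f"no aligned FASTA files in {aln_dir}")
    rows = []
    for f in files:
        res = nucleotide_diversity(read_alignment(f))
        rows.append((res.locus, res.n, res.sites_used, res.pi))
        print(f"{res.locus}\tn={res.n}\tsites={res.sites_used}\tpi={res.pi:.4f}")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        fh.write("locus\tn\tsites_used\tpi\n")
        for locus, n, sites, pi in rows:
            fh.write(f"{locus}\t{n}\t{sites}\t{pi:.6f}\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
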