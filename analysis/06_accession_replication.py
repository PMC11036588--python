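#!/usr/bin/env python
"""Optional replication on real accessions: SSR totals with the survey
thresholds (mono >= 10, di >= 5, tri >= 4, tetra/penta/hexa >= 3).

The reference counts for the two extreme genomes of the published cohort are
28 (Vittaria appalachiana, NC_040219.1) and 172 (Acrostichum speciosum,
NC_053768.1).  Exact replication is sensitive to the upstream tool's motif
conventions (compound-run merging, redundancy handling), so agreement should
be judged qualitatively.

This script never downloads anything: fetch the GenBank flat files yourself
(e.g. NCBI Datasets or Entrez) into a directory and run

    python analysis/06_accession_replication.py <genbank_dir>
"""

import sys
from pathlib import Path

from plastigs.genome import read_genbank
from plastigs.repeats import find_ssrs

REFERENCE = {"NC_040219.1": 28, "NC_053768.1": 172}


def main() -> None:
    if len(sys.argv) != 2:
        raise SystemExit(__doc__)
    gb_dir = Path(sys.argv[1])
    files = sorted(list(gb_dir.glob("*.gb")) + list(gb_dir.glob("*.gbk")))
    if not files:
        raise SystemExit(f"no GenBank files in {gb_dir}")
    print("accession\tssr_total\treference")
    for f in files:
        p = read_genbank(f)
        total = len(find_ssrs(p.sequence))
        ref = REFERENCE.get(p.accession, "-")
        print(f"{p.accession}\t{total}\t{ref}")


if __name__ == "__main__":
    main()
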