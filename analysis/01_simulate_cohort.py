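#!/usr/bin/env python
"""Generate the default synthetic plastome cohort used by the downstream
analyses: 20 annotated circular quadripartite genomes with known spacer
expansions, plus the ground-truth manifest.

Writes results/cohort/*.gb and results/cohort/manifest.json.
"""

from pathlib import Path

from plastigs.simulate import SyntheticConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = SyntheticConfig(seed=7)
    cohort, manifest = generate_cohort(cfg)
    write_cohort(cohort, manifest, OUT)
    sizes = sorted(len(p.sequence) for p in cohort)
    n_exp = sum(
        c["expanded"] for st in manifest.species.values() for c in st.cells.values()
    )
    print(f"wrote {len(cohort)} genomes to {OUT}")
    print(f"genome sizes {sizes[0]:,}-{sizes[-1]:,} bp; {n_exp} expanded spacer cells")
    print(
        "lost genes:",
        {a: s.lost_genes for a, s in manifest.species.items() if s.lost_genes} or "none",
    )
    print(
        "SSC-inverted:",
        [a for a, s in manifest.species.items() if s.ssc_inverted] or "none",
    )


if __name__ == "__main__":
    main()
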