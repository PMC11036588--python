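import numpy as np
import pytest

from plastigs.features import extract_igs
from plastigs.genome import Annotation, GenomicInterval, Plastome, canonicalize, detect_quadripartite
from plastigs.simulate import SyntheticConfig, generate_cohort


def make_plastome(length, genes, seq=None, accession="TOY", species="Toyus toyensis"):
    """Toy circular genome: genes = [(name, start, end, strand[, kind])]."""
    if seq is None:
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), length))
    anns = []
    for g in genes:
        name, start, end, strand = g[:4]
        kind = g[4] if len(g) > 4 else "gene"
        anns.append(Annotation(name, kind, strand, (GenomicInterval(start, end),)))
    return Plastome(accession, species, seq, anns)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-species synthetic cohort with ground truth (fixed seed)."""
    return generate_cohort(SyntheticConfig(n_species=5, seed=11))


@pytest.fixture(scope="session")
def analyzed_small(small_cohort):
    """The small cohort after partition detection, canonicalization and
    spacer extraction."""
    cohort, manifest = small_cohort
    canon, records = [], {}
    for p in cohort:
        p2 = canonicalize(p, detect_quadripartite(p))
        canon.append(p2)
        records[p2.accession] = extract_igs(p2)
    return canon, records, manifest
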