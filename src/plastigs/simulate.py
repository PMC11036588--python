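"""Synthetic annotated quadripartite plastome cohorts with ground truth.

The generator emulates the structure behind a comparative plastome survey:
a fixed gene template spread over LSC / IR / SSC compartments, spacers
between genes, and controlled per-(species, spacer) length *expansions* with
their own GC composition and injected repeats.  Everything that varies
between species — expansions, gene losses, SSC inversion — is recorded in a
:class:`TruthManifest`, so the whole analysis pipeline can be validated in a
closed loop.

Design points that make recovery exact by construction:

* Gene lengths, gene sequences and baseline spacer lengths are drawn once
  per cohort and shared by every species, so inter-species genome-size
  variation is entirely expansion-driven (a ``baseline_jitter`` knob can
  relax this for power studies).
* The first base of the SSC is forced to break inverted-repeat extension, so
  the detected IR pair equals the injected one exactly.
* Expansion deltas start above the largest possible baseline spacer, and
  within each spacer the deltas are drawn so the smallest exceeds that
  spacer's mean expansion load across the cohort — together these make the
  strict-mean overlong rule separate expanded from baseline cells exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome import Annotation, GenomicInterval, Plastome

__all__ = [
    "SyntheticConfig",
    "TruthManifest",
    "SpeciesTruth",
    "default_gene_template",
    "generate_cohort",
    "expansion_sequence",
    "write_genbank",
    "write_cohort",
]

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_gene_template() -> list[tuple[str, int, str, str]]:
    """(gene, length bp, strand, compartment) for a ~26 kb coding skeleton.

    Real plastid gene symbols at plausible lengths; the LSC is kept well
    clear of the SSC in size so the longer-single-copy labelling is stable
    under any draw of expansions.
    """
    lsc = [
        ("psbA", 1062, "-"), ("trnK-UUU", 72, "-"), ("matK", 1500, "+"),
        ("rps16", 813, "-"), ("trnQ-UUG", 72, "-"), ("psbK", 186, "+"),
        ("atpA", 1524, "-"), ("rpoB", 3212, "-"), ("trnD-GUC", 74, "-"),
        ("trnY-GUA", 84, "-"), ("trnE-UUC", 73, "-"), ("trnR-UCG", 72, "+"),
        ("psbD", 1062, "+"), ("psbC", 1386, "+"), ("ndhC", 363, "-"),
        ("trnV-UAC", 73, "-"), ("atpB", 1497, "-"), ("rbcL", 1428, "+"),
        ("accD", 1467, "+"), ("psaJ", 129, "+"), ("petA", 963, "+"),
        ("psbE", 252, "-"), ("petL", 96, "-"), ("clpP", 591, "-"),
        ("psbB", 1527, "+"), ("rpoA", 1011, "-"), ("rps4", 606, "+"),
        ("trnT-UGU", 73, "-"),
    ]
    ir = [
        ("rpl23", 282, "+"), ("trnI-CAU", 74, "+"), ("ndhB", 1533, "-"),
        ("rps12", 372, "-"), ("rrn16", 1491, "+"), ("trnR-ACG", 74, "+"),
    ]
    ssc = [
        ("ndhF", 2241, "-"), ("rps15", 273, "-"), ("ycf1", 3600, "+"),
        ("chlL", 873, "+"),
    ]
    return (
        [(n, l, s, "LSC") for n, l, s in lsc]
        + [(n, l, s, "IR") for n, l, s in ir]
        + [(n, l, s, "SSC") for n, l, s in ssc]
    )


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults: 20 species; baseline spacers 100-1,000 bp; 15% of eligible
    (species, spacer) cells expanded by 2-8 kb at GC 0.55 over a 0.40
    background; rare losses of the two loss-prone tRNAs; occasional SSC
    inversion.
    """

    n_species: int = 20
    gene_template: list = field(default_factory=default_gene_template)
    baseline_igs: tuple[int, int] = (100, 1000)
    p_expand: float = 0.15
    expand_delta: tuple[int, int] = (2000, 8000)
    gc_background: float = 0.40
    gc_expansion: float = 0.55
    repeat_injection: dict = field(
        default_factory=lambda: {"tandem": 0.4, "dispersed": 0.3, "ssr": 0.5}
    )  # expected arrays per kb of expansion
    p_gene_loss: float = 0.10
    losable_genes: tuple[str, ...] = ("trnT-UGU", "trnR-UCG")
    p_ssc_invert: float = 0.10
    baseline_jitter: int = 0  # +- bp of per-species spacer noise (off by default)
    seed: int = 7

    def validate(self) -> None:
        for prob in (self.p_expand, self.p_gene_loss, self.p_ssc_invert):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.expand_delta[0] <= self.baseline_igs[1]:
            raise ValueError(
                "expansion minimum must exceed the baseline maximum "
                "(separability of the overlong classifier)"
            )
        per_comp = {"LSC": 0, "IR": 0, "SSC": 0}
        for _, _, _, comp in self.gene_template:
            per_comp[comp] += 1
        if min(per_comp.values()) < 2:
            raise ValueError("template needs >= 2 genes per compartment")


@dataclass
class SpeciesTruth:
    accession: str
    species: str
    genome_length: int
    partition: dict  # label -> (start, end)
    lost_genes: list
    ssc_inverted: bool
    cells: dict  # "a|b" -> {"length", "expanded", "delta", "region", ...}
    injected_repeats: list  # (kind, start, end) genome coordinates


@dataclass
class TruthManifest:
    config: SyntheticConfig
    species: dict = field(default_factory=dict)  # accession -> SpeciesTruth

    def truth_map(self) -> dict[tuple[tuple[str, str], str], bool]:
        """(group key, accession) -> expanded flag, for recovery scoring."""
        out = {}
        for acc, st in self.species.items():
            for cell_key, info in st.cells.items():
                key = tuple(cell_key.split("|"))
                out[(key, acc)] = bool(info["expanded"])
        return out

    def to_json(self) -> str:
        doc = {
            "config": {
                k: v for k, v in vars(self.config).items() if k != "gene_template"
            },
            "species": {
                acc: {
                    "species": st.species,
                    "genome_length": st.genome_length,
                    "partition": st.partition,
                    "lost_genes": st.lost_genes,
                    "ssc_inverted": st.ssc_inverted,
                    "cells": st.cells,
                    "injected_repeats": st.injected_repeats,
                }
                for acc, st in sorted(self.species.items())
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence synthesis


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def expansion_sequence(
    length: int, gc: float, repeat_spec: dict | None, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]]]:
    """An expansion insert: GC-biased background with planted repeats.

    ``repeat_spec`` gives expected arrays per kb for "tandem", "dispersed"
    and "ssr".  Returns (sequence, planted) where planted lists
    (kind, start, end) relative to the insert.  Raises when the requested
    repeat load cannot fit.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    spec = repeat_spec or {}
    seq = np.frombuffer(_random_dna(rng, length, gc).encode(), dtype=np.uint8).copy()
    planted: list[tuple[str, int, int]] = []
    occupied: list[tuple[int, int]] = []

    def reserve(ln: int) -> int | None:
        for _ in range(50):
            s = int(rng.integers(0, max(1, length - ln)))
            if all(s + ln <= a or s >= b for a, b in occupied):
                occupied.append((s, s + ln))
                return s
        return None

    def plant(kind: str, s: int, block: str):
        seq[s : s + len(block)] = np.frombuffer(block.encode(), dtype=np.uint8)
        planted.append((kind, s, s + len(block)))

    n_tandem = rng.poisson(spec.get("tandem", 0.0) * length / 1000)
    n_disp = rng.poisson(spec.get("dispersed", 0.0) * length / 1000)
    n_ssr = rng.poisson(spec.get("ssr", 0.0) * length / 1000)
    demand = n_tandem * 180 + n_disp * 200 + n_ssr * 20
    if demand > 0.8 * length:
        raise ValueError("repeat densities exceed sequence capacity")

    for _ in range(n_tandem):
        unit = _random_dna(rng, int(rng.integers(10, 61)), gc)
        copies = int(rng.integers(2, 5))
        s = reserve(len(unit) * copies)
        if s is not None:
            plant("tandem", s, unit * copies)
    for _ in range(n_disp):
        block = _random_dna(rng, int(rng.integers(30, 81)), gc)
        s1 = reserve(len(block))
        s2 = reserve(len(block))
        if s1 is not None and s2 is not None:
            plant("dispersed", s1, block)
            plant("dispersed", s2, block)
    for _ in range(n_ssr):
        u = int(rng.integers(1, 4))
        unit = _random_dna(rng, u, gc)
        copies = {1: 12, 2: 7, 3: 5}[u] + int(rng.integers(0, 4))
        s = reserve(u * copies)
        if s is not None:
            plant("ssr", s, unit * copies)
    return seq.tobytes().decode(), planted


# ---------------------------------------------------------------------------
# Cohort assembly

_TRAILING = {"trn": "tRNA", "rrn": "rRNA"}


def _gene_kinds(name: str) -> list[str]:
    kinds = ["gene"]
    for prefix, kind in _TRAILING.items():
        if name.startswith(prefix):
            kinds.append(kind)
    return kinds


@dataclass
class _Igs:
    seq: str
    expansions: list  # (rel_start, delta, planted) within this element


@dataclass
class _Gene:
    name: str
    strand: str
    seq: str


def _mirror_elements(elems: list) -> list:
    out = []
    for e in reversed(elems):
        if isinstance(e, _Gene):
            out.append(
                _Gene(e.name, "-" if e.strand == "+" else "+", e.seq.translate(_COMP)[::-1])
            )
        else:
            exp = []
            for rel, delta, planted in e.expansions:
                new_rel = len(e.seq) - (rel + delta)
                exp.append((new_rel, delta, [
                    (k, delta - b, delta - a) for k, a, b in planted
                ]))
            out.append(_Igs(e.seq.translate(_COMP)[::-1], exp))
    return out


def _merge_igs(a: _Igs, b: _Igs) -> _Igs:
    off = len(a.seq)
    exps = list(a.expansions) + [(rel + off, d, pl) for rel, d, pl in b.expansions]
    return _Igs(a.seq + b.seq, exps)


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[Plastome], TruthManifest]:
    """Deterministic synthetic cohort plus its ground-truth manifest."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    template = cfg.gene_template
    by_comp = {"LSC": [], "IR": [], "SSC": []}
    for name, ln, strand, comp in template:
        by_comp[comp].append((name, ln, strand))

    # cohort-wide shared material
    gene_seq = {name: _random_dna(rng, ln, cfg.gc_background) for name, ln, _, _ in template}

    def draw_len() -> int:
        return int(rng.integers(cfg.baseline_igs[0], cfg.baseline_igs[1] + 1))

    # internal cells per compartment; boundary cells split into two halves
    internal_len = {
        comp: [draw_len() for _ in range(len(genes) - 1)] for comp, genes in by_comp.items()
    }
    half_len = {}
    for tag in ("lsc_head", "lsc_tail", "ir_head", "ir_tail", "ssc_head", "ssc_tail"):
        total = draw_len()
        half_len[tag] = max(25, total // 2)
    cell_seq = {
        (comp, i): _random_dna(rng, ln, cfg.gc_background)
        for comp, lens in internal_len.items()
        for i, ln in enumerate(lens)
    }
    half_seq = {tag: _random_dna(rng, ln, cfg.gc_background) for tag, ln in half_len.items()}

    plastomes: list[Plastome] = []
    manifest = TruthManifest(config=cfg)

    # per-species structural decisions, drawn up front so the expansion plan
    # below knows which spacers exist in which species
    sp_rngs = [
        np.random.default_rng([cfg.seed % (2**31), 1 + s]) for s in range(cfg.n_species)
    ]
    lost_by_sp = [
        [g for g in cfg.losable_genes if sp_rngs[s].random() < cfg.p_gene_loss]
        for s in range(cfg.n_species)
    ]
    inverted_by_sp = [
        bool(sp_rngs[s].random() < cfg.p_ssc_invert) for s in range(cfg.n_species)
    ]

    # cohort-level expansion plan: per internal spacer cell, draw which
    # species expand it and by how much.  Within one cell the deltas are
    # redrawn until the smallest exceeds the cell's mean expansion load over
    # the species carrying it — this is what makes every expanded copy
    # strictly exceed the cross-species mean length (the overlong rule) by
    # construction.
    plan_rng = np.random.default_rng([cfg.seed % (2**31), 7919])
    expansion_plan: dict[tuple[str, int], dict[int, int]] = {}
    for comp in ("LSC", "IR", "SSC"):
        genes = by_comp[comp]
        for i in range(len(genes) - 1):
            flanks = (genes[i][0], genes[i + 1][0])
            present = [
                s
                for s in range(cfg.n_species)
                if not any(g in flanks for g in lost_by_sp[s])
            ]
            expanders = [s for s in present if plan_rng.random() < cfg.p_expand]
            if not expanders:
                continue
            for _ in range(200):
                deltas = plan_rng.integers(
                    cfg.expand_delta[0], cfg.expand_delta[1] + 1, size=len(expanders)
                )
                if deltas.min() > deltas.sum() / len(present):
                    break
            else:  # astronomically rare: equalize, which always separates
                deltas = np.full(len(expanders), sum(cfg.expand_delta) // 2)
            expansion_plan[(comp, i)] = dict(zip(expanders, (int(d) for d in deltas)))

    for s_idx in range(cfg.n_species):
        sp_rng = sp_rngs[s_idx]
        acc = f"SYN{s_idx + 1:04d}"
        species = f"Synthetica species{s_idx + 1}"

        lost = lost_by_sp[s_idx]
        inverted = inverted_by_sp[s_idx]

        def jitter(seq: str) -> str:
            if not cfg.baseline_jitter:
                return seq
            d = int(sp_rng.integers(-cfg.baseline_jitter, cfg.baseline_jitter + 1))
            if d >= 0:
                return seq + _random_dna(sp_rng, d, cfg.gc_background)
            return seq[: len(seq) + d] if len(seq) + d > 10 else seq

        # build per-compartment element lists (IR elements in IRb orientation),
        # inserting planned expansions into their spacers as we go
        comp_elems: dict[str, list] = {}
        for comp, genes in by_comp.items():
            elems: list = []
            for i, (name, ln, strand) in enumerate(genes):
                if i > 0:
                    e = _Igs(jitter(cell_seq[(comp, i - 1)]), [])
                    delta = expansion_plan.get((comp, i - 1), {}).get(s_idx)
                    if delta is not None:
                        ins, planted = expansion_sequence(
                            delta, cfg.gc_expansion, cfg.repeat_injection, sp_rng
                        )
                        rel = len(e.seq) // 2
                        e.seq = e.seq[:rel] + ins + e.seq[rel:]
                        e.expansions.append((rel, delta, planted))
                    elems.append(e)
                elems.append(_Gene(name, strand, gene_seq[name]))
            comp_elems[comp] = elems

        # gene losses: remove the gene, fuse its flanking spacer elements
        for comp in ("LSC", "IR", "SSC"):
            elems = comp_elems[comp]
            for g in lost:
                idx = next(
                    (i for i, e in enumerate(elems) if isinstance(e, _Gene) and e.name == g),
                    None,
                )
                if idx is None:
                    continue
                left = elems[idx - 1] if idx > 0 and isinstance(elems[idx - 1], _Igs) else None
                right = (
                    elems[idx + 1]
                    if idx + 1 < len(elems) and isinstance(elems[idx + 1], _Igs)
                    else None
                )
                if left is not None and right is not None:
                    elems[idx - 1 : idx + 2] = [_merge_igs(left, right)]
                else:
                    # gene at a compartment edge: its surviving neighbour
                    # joins a boundary cell (never an expansion target — the
                    # cohort expansion plan only covers intact internal cells)
                    del elems[idx]
            comp_elems[comp] = elems

        # assemble: LSC | IRb | SSC | IRa, boundary halves around each block
        lsc_block = [_Igs(half_seq["lsc_head"], [])] + comp_elems["LSC"] + [
            _Igs(half_seq["lsc_tail"], [])
        ]
        irb_block = [_Igs(half_seq["ir_head"], [])] + comp_elems["IR"] + [
            _Igs(half_seq["ir_tail"], [])
        ]
        ssc_block = [_Igs(half_seq["ssc_head"], [])] + comp_elems["SSC"] + [
            _Igs(half_seq["ssc_tail"], [])
        ]
        if inverted:
            ssc_block = _mirror_elements(ssc_block)
        ira_block = _mirror_elements(irb_block)

        blocks = {"LSCb": lsc_block, "IRb": irb_block, "SSCb": ssc_block, "IRa": ira_block}
        seq_parts: list[str] = []
        annotations: list[Annotation] = []
        injected: list[tuple[str, int, int]] = []
        offset = 0
        elem_layout: list[tuple[str, object, int]] = []  # (block, element, start)
        block_bounds = {}
        for bname, elems in blocks.items():
            bstart = offset
            for e in elems:
                elem_layout.append((bname, e, offset))
                if isinstance(e, _Gene):
                    iv = GenomicInterval(offset, offset + len(e.seq))
                    for kind in _gene_kinds(e.name):
                        annotations.append(Annotation(e.name, kind, e.strand, (iv,)))
                else:
                    for rel, delta, planted in e.expansions:
                        for kind, a, b in planted:
                            injected.append((kind, offset + rel + a, offset + rel + b))
                seq_parts.append(e.seq)
                offset += len(e.seq)
            block_bounds[bname] = (bstart, offset)
        seq = "".join(seq_parts)
        n = len(seq)

        # break inverted-repeat extension into the SSC so detection is exact
        b_end = block_bounds["IRb"][1]  # first SSC base
        c_end = block_bounds["SSCb"][1]  # one past last SSC base
        comp_last = seq[c_end - 1].translate(_COMP)
        if seq[b_end] == comp_last:
            repl = next(b for b in "ACGT" if b != comp_last and b != seq[b_end])
            seq = seq[:b_end] + repl + seq[b_end + 1 :]

        # realized spacer cells: circular walk grouping igs runs between genes
        gene_positions = [
            (i, e, start) for i, (bn, e, start) in enumerate(elem_layout) if isinstance(e, _Gene)
        ]
        cells: dict[str, dict] = {}
        m = len(elem_layout)
        for gi, (i_idx, gene, _) in enumerate(gene_positions):
            nxt_idx, nxt_gene, _ = gene_positions[(gi + 1) % len(gene_positions)]
            # igs elements strictly between this gene and the next (circular)
            length = 0
            expanded = False
            delta_sum = 0
            j = (i_idx + 1) % m
            while j != nxt_idx:
                _, e, start = elem_layout[j]
                length += len(e.seq)
                if isinstance(e, _Igs) and e.expansions:
                    expanded = True
                    delta_sum += sum(d for _, d, _ in e.expansions)
                j = (j + 1) % m
            if length == 0:
                continue
            key = "|".join(sorted((gene.name, nxt_gene.name)))
            if key in cells:  # mirrored IR copy of an already-seen spacer
                cells[key]["copies"] += 1
            else:
                cells[key] = {
                    "length": length,
                    "expanded": expanded,
                    "delta": delta_sum,
                    "flanks": [gene.name, nxt_gene.name],
                    "copies": 1,
                }

        lsc_len = block_bounds["LSCb"][1] - block_bounds["LSCb"][0]
        ssc_len = block_bounds["SSCb"][1] - block_bounds["SSCb"][0]
        A, B = block_bounds["IRb"]
        C, L = block_bounds["IRa"]
        if lsc_len >= ssc_len:
            part = {
                "LSC": [0, A], "IRb": [A, B], "SSC": [B, C], "IRa": [C, L],
            }
        else:  # the designed SSC came out longer: labels follow length
            part = {
                "LSC": [B, C], "IRb": [C, L], "SSC": [0, A], "IRa": [A, B],
            }

        p = Plastome(acc, species, seq, annotations)
        plastomes.append(p)
        manifest.species[acc] = SpeciesTruth(
            accession=acc,
            species=species,
            genome_length=n,
            partition=part,
            lost_genes=lost,
            ssc_inverted=inverted,
            cells=cells,
            injected_repeats=sorted(injected),
        )
    return plastomes, manifest


# ---------------------------------------------------------------------------
# GenBank output


def write_genbank(p: Plastome, path: str | Path) -> None:
    """Serialize a plastome as a circular GenBank flat file.

    Round-trips through :func:`plastigs.genome.read_genbank` with identical
    sequence and annotation names/strands/parts.  The LOCUS date is pinned so
    identical inputs give byte-identical files.
    """
    rec = SeqRecord(
        Seq(p.sequence),
        id=p.accession,
        name=p.accession[:16],
        description=f"{p.species} chloroplast, complete genome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    rec.annotations["organism"] = p.species
    rec.annotations["date"] = "01-JAN-2000"
    for a in p.annotations:
        strand = -1 if a.strand == "-" else 1
        locs = [FeatureLocation(iv.start, iv.end, strand=strand) for iv in a.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        rec.features.append(SeqFeature(loc, type=a.kind, qualifiers={"gene": [a.name]}))
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")


def write_cohort(cohort: list[Plastome], manifest: TruthManifest, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        write_genbank(p, outdir / f"{p.accession}.gb")
    (outdir / "manifest.json").write_text(manifest.to_json())
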