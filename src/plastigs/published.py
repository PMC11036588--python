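"""Packaged transcriptions of the published cohort tables.

Two fixtures ship with the package:

* the per-genome feature table of the 41 fern plastomes (size, GC%, region
  lengths, accession) — the "IR" column is the *combined* length of both
  inverted-repeat copies, so LSC + IR + SSC equals the genome size;
* the cross-species overlong-spacer matrix for the six recurrently expanded
  spacers (``-`` marks a flank-gene loss; ``*`` marks cells the publication
  typeset as overlong).

The spacer names in the matrix abbreviate tRNA isoforms; ``expand_symbol``
restores the full anticodon form (trnD = trnD-GUC, trnY = trnY-GUA,
trnV = trnV-UAC).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .features import HomologousIgsGroup

__all__ = [
    "load_cohort_features",
    "load_overlong_matrix",
    "matrix_to_groups",
    "compare_with_published_bold",
    "expand_symbol",
]

_TRN_FULL = {"trnD": "trnD-GUC", "trnY": "trnY-GUA", "trnV": "trnV-UAC"}


def expand_symbol(sym: str) -> str:
    return _TRN_FULL.get(sym, sym)


def _data(name: str):
    return resources.files("plastigs.data").joinpath(name)


def load_cohort_features() -> pd.DataFrame:
    """The 41-genome feature table (sizes in bp, GC in percent)."""
    with resources.as_file(_data("table1_cohort_features.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_overlong_matrix() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(lengths, bold) of the published overlong-spacer matrix.

    ``lengths`` holds spacer lengths in bp indexed by species (NaN where the
    flanking gene is lost); ``bold`` is the boolean mask of cells typeset as
    overlong in the publication.
    """
    with resources.as_file(_data("table2_overlong_igs.tsv")) as path:
        raw = pd.read_csv(path, sep="\t", dtype=str).set_index("species")
    raw = raw.drop(columns=["cpdna_size"])
    bold = raw.map(lambda v: isinstance(v, str) and v.endswith("*"))
    lengths = raw.map(
        lambda v: float(v.rstrip("*")) if isinstance(v, str) and v != "-" else float("nan")
    )
    return lengths, bold


def matrix_to_groups(lengths: pd.DataFrame) -> list[HomologousIgsGroup]:
    """Each matrix column becomes a homologous spacer group (species keyed)."""
    groups = []
    for col in lengths.columns:
        left, right = col.split("-")
        left, right = expand_symbol(left), expand_symbol(right)
        g = HomologousIgsGroup(key=tuple(sorted((left, right))), display_name=col)
        for sp, v in lengths[col].items():
            if pd.notna(v):
                g.lengths[sp] = int(v)
        groups.append(g)
    return groups


def compare_with_published_bold(calls, bold: pd.DataFrame) -> pd.DataFrame:
    """Cells where the strict mean rule and the published typesetting differ.

    Returns a data frame (species, igs, length, group_mean, rule_overlong,
    published_bold); empty when the two agree everywhere.  Discrepancies are
    reported, never silently reconciled.
    """
    name_by_key = {}
    for col in bold.columns:
        left, right = (expand_symbol(s) for s in col.split("-"))
        name_by_key[tuple(sorted((left, right)))] = col
    rows = []
    for c in calls:
        col = name_by_key.get(c.key)
        if col is None:
            continue
        published = bool(bold.loc[c.accession, col])
        if published != c.is_overlong:
            rows.append(
                {
                    "species": c.accession,
                    "igs": col,
                    "length": c.length,
                    "group_mean": round(c.group_mean, 1),
                    "rule_overlong": c.is_overlong,
                    "published_bold": published,
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "igs", "length", "group_mean", "rule_overlong", "published_bold"]
    )
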