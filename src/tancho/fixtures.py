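"""Bundled study data: the 11-marker panel, the two published genotype
tables (39 non-kin chicks; 39 individuals of 12 known families) and the
pedigree derived from the family annotations.

The two tables overlap in 12 individuals; their union is the 66-sample set
used for individual identification.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io import parse_genotype_table, read_marker_panel, read_pedigree
from .model import GenotypeTable, Marker, Pedigree

__all__ = [
    "load_marker_panel",
    "load_nonkin_table",
    "load_kin_table",
    "load_kin_pedigree",
    "select_dataset",
]

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def load_marker_panel() -> list[Marker]:
    with (_DATA / "markers.tsv").open() as fh:
        return read_marker_panel(fh)


def load_nonkin_table() -> GenotypeTable:
    """The 39 non-kin chicks (13 each from Kushiro, Nemuro, Tokachi)."""
    with (_DATA / "nonkin_genotypes.tsv").open() as fh:
        return parse_genotype_table(fh, panel=load_marker_panel())


def load_kin_table() -> GenotypeTable:
    """The 39 individuals of the 12 known families."""
    with (_DATA / "kin_genotypes.tsv").open() as fh:
        return parse_genotype_table(fh, panel=load_marker_panel())


def load_kin_pedigree() -> Pedigree:
    ped_path = _DATA / "kin_pedigree.tsv"
    with ped_path.open() as fh:
        ped = read_pedigree(fh)
    return ped


def select_dataset(which: str) -> GenotypeTable:
    """Select the analysis sample set: ``non_kin``, ``kin`` or ``union``.

    ``union`` merges the two tables and deduplicates the 12 overlapping
    individuals by sample id (keeping the non-kin copy), yielding the
    66 unique individuals used for exhaustive identity matching.
    """
    if which == "non_kin":
        return load_nonkin_table()
    if which == "kin":
        return load_kin_table()
    if which == "union":
        return union_tables(load_nonkin_table(), load_kin_table())
    raise ValueError(f"unknown dataset selector {which!r}")


def union_tables(first: GenotypeTable, second: GenotypeTable) -> GenotypeTable:
    """Union of two tables over the same panel, deduplicated by sample id."""
    if first.marker_ids != second.marker_ids:
        raise ValueError("tables use different panels")
    individuals = list(first.individuals)
    calls = [first.calls]
    seen = set(first.sample_ids)
    extra = [i for i, ind in enumerate(second.individuals) if ind.sample_id not in seen]
    individuals += [second.individuals[i] for i in extra]
    calls.append(second.calls[extra])
    return GenotypeTable(
        panel=list(first.panel),
        individuals=individuals,
        calls=np.concatenate(calls, axis=0),
    )
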