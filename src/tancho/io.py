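"""Reading and writing the genotype-table text dialect, marker panels and
pedigree edge lists.

The genotype dialect is the vocabulary used in the printed tables:
``W Homo`` (wild homozygote), ``D Homo`` / ``I Homo`` (variant homozygote),
``WD Hetero`` / ``WI Hetero`` (heterozygote).  The published tables also
contain the typographic variants ``WD Heter``, ``W Heter`` and ``W Hetero``;
these normalize to the heterozygote call with a recorded warning, because
every such cell sits in a heterozygote context and the legend defines no
other state they could denote.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    GenotypeCall,
    GenotypeTable,
    Individual,
    Marker,
    Pedigree,
    VariantType,
)

__all__ = [
    "CANONICAL_TOKENS",
    "VARIANT_TOKENS",
    "parse_genotype_table",
    "write_genotype_table",
    "read_marker_panel",
    "read_pedigree",
    "write_pedigree",
]

CANONICAL_TOKENS: dict[str, int] = {
    "W Homo": 0,
    "D Homo": 2,
    "I Homo": 2,
    "WD Hetero": 1,
    "WI Hetero": 1,
}

#: non-canonical spellings found in the published tables -> normalized call
VARIANT_TOKENS: dict[str, int] = {
    "WD Heter": 1,
    "W Heter": 1,
    "W Hetero": 1,
}

MISSING_TOKENS = {"", "-", "NA", "missing"}

_METADATA_FIELDS = {
    "crane": "sample_id",
    "sample_id": "sample_id",
    "banding_no": "sample_id",
    "sex": "sex",
    "haplotype": "haplotype",
    "region": "region",
    "area": "region",
    "family": "family_id",
    "family_id": "family_id",
    "relationship": None,  # carried through but not a typed field
}


def _canonical_token(call: int, marker: Marker) -> str:
    letter = "I" if marker.variant_type is VariantType.INSERTION else "D"
    return {0: "W Homo", 1: f"W{letter} Hetero", 2: f"{letter} Homo"}[call]


def parse_genotype_table(
    source,
    panel: Sequence[Marker] | None = None,
    id_column: str | None = None,
) -> GenotypeTable:
    """Parse a TSV genotype table in the published text dialect.

    ``source`` is a path, file object or literal TSV string.  Columns whose
    header matches a marker id of ``panel`` (or, without a panel, columns
    starting with ``Id-``) are genotype columns; everything else is
    per-individual metadata.  Normalized non-canonical cells are recorded in
    ``table.warnings``, one entry per cell.
    """
    if isinstance(source, str) and "\t" in source:
        buf = _io.StringIO(source)
    else:
        buf = source
    df = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False)

    if panel is not None:
        marker_cols = [m.marker_id for m in panel]
        missing_cols = [c for c in marker_cols if c not in df.columns]
        if missing_cols:
            raise ValueError(f"genotype columns missing from header: {missing_cols}")
        panel = list(panel)
    else:
        marker_cols = [c for c in df.columns if c.lower() not in _METADATA_FIELDS]
        if not marker_cols:
            raise ValueError("no genotype columns found (header names no markers)")
        # placeholder loci: arbitrary but valid deletion markers
        panel = [
            Marker(marker_id=c, variant_type=VariantType.DELETION,
                   indel_size=30, amplicon_size_wild=200)
            for c in marker_cols
        ]

    meta_cols = [c for c in df.columns if c not in marker_cols]
    if id_column is None:
        id_column = next(
            (c for c in meta_cols if _METADATA_FIELDS.get(c.lower()) == "sample_id"),
            meta_cols[0] if meta_cols else None,
        )
    if id_column is None:
        raise ValueError("no identifier column found")

    individuals = []
    for _, row in df.iterrows():
        fields = {"sample_id": row[id_column].strip()}
        for col in meta_cols:
            target = _METADATA_FIELDS.get(col.lower())
            if target and target != "sample_id":
                value = row[col].strip()
                fields[target] = "unknown" if value in MISSING_TOKENS else value
        individuals.append(Individual(**fields))

    warnings: list[str] = []
    calls = np.full((len(df), len(marker_cols)), -1, dtype=np.int8)
    for j, col in enumerate(marker_cols):
        for i, raw in enumerate(df[col]):
            token = str(raw).strip()
            if token in CANONICAL_TOKENS:
                calls[i, j] = CANONICAL_TOKENS[token]
            elif token in VARIANT_TOKENS:
                calls[i, j] = VARIANT_TOKENS[token]
                warnings.append(
                    f"normalized non-canonical cell {token!r} -> heterozygote "
                    f"(sample {individuals[i].sample_id}, locus {col})"
                )
            elif token in MISSING_TOKENS:
                calls[i, j] = -1
            else:
                raise ValueError(
                    f"unknown genotype token {token!r} at row "
                    f"{individuals[i].sample_id!r}, column {col!r}"
                )

    table = GenotypeTable(panel=list(panel), individuals=individuals, calls=calls)
    table.warnings = warnings
    return table


def write_genotype_table(
    table: GenotypeTable,
    path=None,
    typo_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Serialize ``table`` to the TSV dialect; returns the text.

    ``typo_rate`` re-spells that fraction of heterozygote cells with the
    published tables' non-canonical variants (exercises the parser).
    """
    if typo_rate and rng is None:
        raise ValueError("typo_rate requires an rng")
    header = ["crane", "sex", "haplotype", "region", "family"]
    lines = ["\t".join(header + table.marker_ids)]
    for i, ind in enumerate(table.individuals):
        cells = [ind.sample_id, ind.sex, ind.haplotype, ind.region,
                 ind.family_id or ""]
        for j, marker in enumerate(table.panel):
            call = int(table.calls[i, j])
            if call == -1:
                cells.append("-")
                continue
            token = _canonical_token(call, marker)
            if call == 1 and typo_rate and rng.random() < typo_rate:
                token = "WD Heter" if "D" in token else "W Hetero"
            cells.append(token)
        lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_marker_panel(source) -> list[Marker]:
    """Read a marker-panel TSV (marker_id, variant_type, indel_size, product_bp, ...)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    markers = []
    for _, row in df.iterrows():
        span = None
        if "span_start" in df.columns and "span_end" in df.columns:
            span = (int(row["span_start"]), int(row["span_end"]))
        markers.append(
            Marker(
                marker_id=row["marker_id"],
                variant_type=VariantType(row["variant_type"].lower()),
                indel_size=int(row["indel_size"]),
                amplicon_size_wild=int(row["product_bp"]),
                chromosome=row.get("chromosome", ""),
                span=span,
                forward_primer=row.get("forward_primer", ""),
                reverse_primer=row.get("reverse_primer", ""),
            )
        )
    return markers


_RELATIONS = {"parent_offspring", "full_sibling", "twin", "grandparent"}


def read_pedigree(source) -> Pedigree:
    """Read an edge-list TSV with columns (relation, id1, id2)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    ped = Pedigree()
    for _, row in df.iterrows():
        rel, a, b = row["relation"].strip(), row["id1"].strip(), row["id2"].strip()
        if rel not in _RELATIONS:
            raise ValueError(f"unknown relation {rel!r}")
        if rel == "parent_offspring":
            ped.parent_offspring.add((a, b))
        elif rel == "grandparent":
            ped.grandparent.add((a, b))
        elif rel == "full_sibling":
            ped.full_sibling_pairs.add(frozenset((a, b)))
        else:
            ped.twin_pairs.add(frozenset((a, b)))
    ped._check_acyclic()
    return ped


def write_pedigree(ped: Pedigree, path=None) -> str:
    lines = ["relation\tid1\tid2"]
    for a, b in sorted(ped.parent_offspring):
        lines.append(f"parent_offspring\t{a}\t{b}")
    for pair in sorted(ped.full_sibling_pairs, key=sorted):
        a, b = sorted(pair)
        lines.append(f"full_sibling\t{a}\t{b}")
    for pair in sorted(ped.twin_pairs, key=sorted):
        a, b = sorted(pair)
        lines.append(f"twin\t{a}\t{b}")
    for a, b in sorted(ped.grandparent):
        lines.append(f"grandparent\t{a}\t{b}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
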