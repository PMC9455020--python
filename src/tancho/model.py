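"""Domain types for biallelic InDel marker panels.

A panel is a set of loci at which one *wild* (W) allele segregates against a
single *variant* (V) allele, the variant being either an insertion or a
deletion of a few tens of base pairs.  Because each locus is strictly
biallelic, every genotype call is one of ``WW``, ``WV``, ``VV`` or missing,
and a call can be stored as the count of variant alleles (the "dosage").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VariantType",
    "GenotypeCall",
    "Marker",
    "Individual",
    "GenotypeTable",
    "Pedigree",
    "BandPattern",
    "predict_band_pattern",
]


class VariantType(str, enum.Enum):
    INSERTION = "insertion"
    DELETION = "deletion"


class GenotypeCall(enum.IntEnum):
    """Unordered biallelic genotype, coded as the variant-allele dosage."""

    MISSING = -1
    WW = 0
    WV = 1
    VV = 2


@dataclass(frozen=True)
class Marker:
    """One InDel locus and the PCR amplicon that detects it.

    ``amplicon_size_wild`` is the product length of the W allele; the V
    allele's product differs from it by ``indel_size`` base pairs in the
    direction given by ``variant_type``.
    """

    marker_id: str
    variant_type: VariantType
    indel_size: int
    amplicon_size_wild: int
    chromosome: str = ""
    span: tuple[int, int] | None = None  # 1-based inclusive, metadata only
    forward_primer: str = ""
    reverse_primer: str = ""

    def __post_init__(self) -> None:
        if self.indel_size <= 0:
            raise ValueError(f"{self.marker_id}: indel_size must be positive")
        if self.amplicon_size_wild <= self.indel_size:
            raise ValueError(
                f"{self.marker_id}: amplicon must be longer than the InDel"
            )


@dataclass(frozen=True)
class Individual:
    sample_id: str
    sex: str = "unknown"            # male / female / unknown
    haplotype: str = "unknown"      # mitochondrial lineage label (Gj1, Gj2, ...)
    region: str = "unknown"         # sampling region (Kushiro, Nemuro, Tokachi)
    family_id: str | None = None


@dataclass
class GenotypeTable:
    """Individuals x markers matrix of unordered biallelic calls.

    ``calls`` holds variant-allele dosages (0, 1, 2) with -1 for missing,
    shape ``(n_individuals, n_markers)``.
    """

    panel: list[Marker]
    individuals: list[Individual]
    calls: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.panel)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.panel)} markers"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} for sample "
                f"{self.individuals[i].sample_id} at {self.panel[j].marker_id}"
            )
        ids = [ind.sample_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")
        mids = [m.marker_id for m in self.panel]
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate marker_id in panel")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    @property
    def sample_ids(self) -> list[str]:
        return [ind.sample_id for ind in self.individuals]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.panel]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def individual_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def locus_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        idx = [self.individual_index(s) for s in sample_ids]
        return GenotypeTable(
            panel=list(self.panel),
            individuals=[self.individuals[i] for i in idx],
            calls=self.calls[idx].copy(),
        )

    def by_region(self, region: str) -> "GenotypeTable":
        keep = [ind.sample_id for ind in self.individuals if ind.region == region]
        if not keep:
            raise KeyError(f"no individuals in region {region!r}")
        return self.subset(keep)

    def regions(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            if ind.region not in seen:
                seen.append(ind.region)
        return seen


@dataclass
class Pedigree:
    """Known relationships over sample identifiers.

    Parent->offspring and grandparent->grandchild edges are ordered
    (ancestor first); sibling and twin pairs are unordered.
    """

    parent_offspring: set[tuple[str, str]] = field(default_factory=set)
    full_sibling_pairs: set[frozenset[str]] = field(default_factory=set)
    twin_pairs: set[frozenset[str]] = field(default_factory=set)
    grandparent: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in list(self.full_sibling_pairs) + list(self.twin_pairs):
            if len(pair) != 2:
                raise ValueError(f"sibling/twin pair must have 2 members: {set(pair)}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: dict[str, set[str]] = {}
        for p, o in self.parent_offspring | self.grandparent:
            children.setdefault(p, set()).add(o)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for ch in children.get(node, ()):
                if state.get(ch) == 1:
                    raise ValueError(f"pedigree cycle through {node!r}")
                if state.get(ch, 0) == 0:
                    visit(ch)
            state[node] = 2

        for node in list(children):
            if state.get(node, 0) == 0:
                visit(node)

    def all_ids(self) -> set[str]:
        ids: set[str] = set()
        for p, o in self.parent_offspring | self.grandparent:
            ids.update((p, o))
        for pair in self.full_sibling_pairs | self.twin_pairs:
            ids.update(pair)
        return ids

    def full_sibling_groups(self) -> list[set[str]]:
        """Connected components of the sibling-pair graph."""
        adj: dict[str, set[str]] = {}
        for pair in self.full_sibling_pairs:
            a, b = sorted(pair)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        seen: set[str] = set()
        groups = []
        for start in sorted(adj):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                stack.extend(adj[node] - comp)
            seen |= comp
            groups.append(comp)
        return groups

    def relation(self, id_a: str, id_b: str) -> str | None:
        """Most specific declared relation of a pair, or None."""
        pair = frozenset((id_a, id_b))
        if pair in self.twin_pairs:
            return "twin"
        if (id_a, id_b) in self.parent_offspring or (id_b, id_a) in self.parent_offspring:
            return "parent_offspring"
        if (id_a, id_b) in self.grandparent or (id_b, id_a) in self.grandparent:
            return "grandparent_grandchild"
        if pair in self.full_sibling_pairs:
            return "full_sibling"
        return None


@dataclass(frozen=True)
class BandPattern:
    """Predicted homoduplex fragment lengths on an agarose gel.

    Heterozygote PCR products frequently show an extra slow band caused by
    a heteroduplex mobility shift; the flag marks where that may appear.
    """

    fragment_lengths: tuple[int, ...]
    heteroduplex_possible: bool

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")
        if tuple(sorted(self.fragment_lengths)) != self.fragment_lengths:
            raise ValueError("fragment lengths must be sorted")


def predict_band_pattern(
    marker: Marker,
    call: GenotypeCall | int,
    product_is_wild: bool = True,
) -> BandPattern:
    """Predict homoduplex band lengths for a call at ``marker``.

    The W allele amplifies at ``amplicon_size_wild``; the variant allele is
    longer by ``indel_size`` for insertions and shorter for deletions.  Set
    ``product_is_wild=False`` if the recorded product size refers to the
    variant allele instead (the alternative reading of the panel table for
    insertion markers), in which case the roles are swapped.
    """
    call = GenotypeCall(call)
    if call is GenotypeCall.MISSING:
        raise ValueError("cannot predict bands for a missing call")
    shift = marker.indel_size if marker.variant_type is VariantType.INSERTION else -marker.indel_size
    if product_is_wild:
        w_len = marker.amplicon_size_wild
        v_len = marker.amplicon_size_wild + shift
    else:
        v_len = marker.amplicon_size_wild
        w_len = marker.amplicon_size_wild - shift
    lengths = {GenotypeCall.WW: (w_len,), GenotypeCall.VV: (v_len,),
               GenotypeCall.WV: tuple(sorted((w_len, v_len)))}[call]
    return BandPattern(lengths, heteroduplex_possible=(call is GenotypeCall.WV))
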