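"""Non-exclusion probabilities for identity and parentage.

All formulas are closed-form functions of the allele-frequency power sums
a_m = sum_i p_i^m (m = 2..6) and assume Hardy-Weinberg genotype
proportions (test HWE first).  Per-locus values:

    identity      Q_I  = 2 a2^2 - a4
                  (probability two random individuals share a genotype)
    first parent  1 - E1,  E1 = 1 - 4 a2 + 2 a2^2 + 4 a3 - 3 a4
                  (E1 = power to exclude a random non-parent when the other
                  parent is unknown; biallelic: E1 = 2 p^2 q^2)
    second parent 1 - E2,  E2 = 1 - 2 a2 + a3 + 3 (a2 a3 - a5) - 2 (a2^2 - a4)
                  (other parent's genotype known)
    parent pair   1 - E3,  E3 = 1 + 4 a4 - 4 a5 - 3 a6 - 8 a2^2 + 8 a2 a3 + 2 a3^2
                  (candidate couple vs their putative offspring)

Multi-locus values multiply across independent loci, so every added
polymorphic locus strictly decreases the combined non-exclusion
probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .locus_stats import AlleleFrequencies, allele_frequencies
from .model import GenotypeTable

__all__ = [
    "MomentSet",
    "ExclusionSummary",
    "ne_identity",
    "ne_first_parent",
    "ne_second_parent",
    "ne_parent_pair",
    "combine",
    "summarize_exclusion",
]


@dataclass(frozen=True)
class MomentSet:
    """Allele-frequency power sums a_m = sum_i p_i^m for m = 2..6."""

    a2: float
    a3: float
    a4: float
    a5: float
    a6: float

    @classmethod
    def from_frequencies(cls, freqs: Iterable[float]) -> "MomentSet":
        ps = list(freqs)
        if not ps or any(p < 0 or p > 1 for p in ps):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not math.isclose(sum(ps), 1.0, abs_tol=1e-9):
            raise ValueError("allele frequencies must sum to 1")
        return cls(*(sum(p**m for p in ps) for m in range(2, 7)))


def _moments(freqs: AlleleFrequencies | MomentSet) -> MomentSet:
    if isinstance(freqs, MomentSet):
        return freqs
    return MomentSet.from_frequencies((freqs.p_w, freqs.p_v))


def ne_identity(freqs: AlleleFrequencies | MomentSet) -> float:
    """Probability that two random HWE individuals share a genotype."""
    m = _moments(freqs)
    return 2.0 * m.a2**2 - m.a4


def ne_first_parent(freqs: AlleleFrequencies | MomentSet) -> float:
    """Non-exclusion probability for the first candidate parent."""
    m = _moments(freqs)
    e1 = 1.0 - 4.0 * m.a2 + 2.0 * m.a2**2 + 4.0 * m.a3 - 3.0 * m.a4
    return 1.0 - e1


def ne_second_parent(freqs: AlleleFrequencies | MomentSet) -> float:
    """Non-exclusion probability for a candidate parent when the other
    parent's genotype is known (not a headline statistic of the study)."""
    m = _moments(freqs)
    e2 = (
        1.0
        - 2.0 * m.a2
        + m.a3
        + 3.0 * (m.a2 * m.a3 - m.a5)
        - 2.0 * (m.a2**2 - m.a4)
    )
    return 1.0 - e2


def ne_parent_pair(freqs: AlleleFrequencies | MomentSet) -> float:
    """Non-exclusion probability for a candidate parent pair."""
    m = _moments(freqs)
    e3 = (
        1.0
        + 4.0 * m.a4
        - 4.0 * m.a5
        - 3.0 * m.a6
        - 8.0 * m.a2**2
        + 8.0 * m.a2 * m.a3
        + 2.0 * m.a3**2
    )
    return 1.0 - e3


def combine(per_locus: Sequence[float]) -> float:
    """Combined non-exclusion probability over independent loci (product)."""
    values = list(per_locus)
    if not values:
        raise ValueError("empty per-locus list")
    if any(v <= 0 or v > 1 for v in values):
        raise ValueError("per-locus values must lie in (0, 1]")
    return math.prod(values)


@dataclass(frozen=True)
class ExclusionSummary:
    marker_ids: tuple[str, ...]
    per_locus_ne_identity: tuple[float, ...]
    per_locus_ne_1p: tuple[float, ...]
    per_locus_ne_pp: tuple[float, ...]
    combined_ne_identity: float
    combined_ne_1p: float
    combined_ne_pp: float


def summarize_exclusion(table: GenotypeTable) -> ExclusionSummary:
    """Per-locus and combined non-exclusion probabilities for a panel.

    Frequencies are taken from ``table`` itself, so pass the non-kin sample
    set: family-based sampling biases allele frequencies.
    """
    ids, nei, ne1, nepp = [], [], [], []
    for marker in table.panel:
        freqs = allele_frequencies(table, marker.marker_id)
        ids.append(marker.marker_id)
        nei.append(ne_identity(freqs))
        ne1.append(ne_first_parent(freqs))
        nepp.append(ne_parent_pair(freqs))
    return ExclusionSummary(
        marker_ids=tuple(ids),
        per_locus_ne_identity=tuple(nei),
        per_locus_ne_1p=tuple(ne1),
        per_locus_ne_pp=tuple(nepp),
        combined_ne_identity=combine(nei),
        combined_ne_1p=combine(ne1),
        combined_ne_pp=combine(nepp),
    )
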