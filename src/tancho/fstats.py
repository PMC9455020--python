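"""Weir & Cockerham (1984) ANOVA F-statistic estimators with permutation
tests.

For each locus and allele the observed variance in allele frequency is
partitioned into components among populations (a), among individuals within
populations (b) and within individuals (c).  Multi-locus estimates follow
the ratio-of-sums convention:

    theta (FST) = sum a / sum (a + b + c)
    f     (FIS) = sum b / sum (b + c)

summed over loci and alleles.  Negative estimates are reported as computed.
Significance is assessed by permutation: individuals among groups for FST,
gene copies among individuals within each group for FIS, with the add-one
p-value (1 + #{|perm| >= |obs|}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import GenotypeTable

__all__ = ["FStatResult", "wc_components", "multilocus_fstat", "permutation_test"]


@dataclass(frozen=True)
class FStatResult:
    statistic: str                       # "f_is" or "f_st"
    estimate: float
    per_locus_components: tuple[tuple[str, float, float, float], ...]
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def _groups_from_spec(table: GenotypeTable, grouping) -> list[np.ndarray]:
    """Resolve a grouping spec into per-group row-index arrays.

    Accepts "region" (group by individual metadata), a list of sample-id
    lists, or a dict sample_id -> group label.
    """
    if grouping == "region":
        labels = [ind.region for ind in table.individuals]
        keys = list(dict.fromkeys(labels))
        return [np.array([i for i, l in enumerate(labels) if l == k]) for k in keys]
    if isinstance(grouping, dict):
        keys = list(dict.fromkeys(grouping.values()))
        return [
            np.array([table.individual_index(s) for s, g in grouping.items() if g == k])
            for k in keys
        ]
    return [np.array([table.individual_index(s) for s in grp]) for grp in grouping]


def _components_from_calls(group_calls: list[np.ndarray]) -> tuple[float, float, float]:
    """W&C components for one locus from per-group dosage vectors.

    Missing calls are dropped per group (complete-case per locus); the two
    alleles of a biallelic locus contribute symmetrically, so the summed
    components are twice those of the variant allele.
    """
    groups = [g[g >= 0] for g in group_calls]
    groups = [g for g in groups if len(g) > 0]
    r = len(groups)
    if r == 0:
        return 0.0, 0.0, 0.0
    ni = np.array([len(g) for g in groups], dtype=float)
    pi = np.array([(2 * (g == 2).sum() + (g == 1).sum()) / (2 * len(g)) for g in groups])
    hi = np.array([(g == 1).mean() for g in groups])
    nbar = ni.mean()
    if nbar <= 1:
        raise ValueError("groups must contain >= 2 typed individuals on average")
    pbar = float((ni * pi).sum() / (r * nbar))
    hbar = float((ni * hi).sum() / (r * nbar))
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0  # monomorphic across all groups
    if r > 1:
        nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1)
        s2 = float((ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar))
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    else:
        a = 0.0
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    # both alleles of the biallelic locus
    return 2 * a, 2 * b, 2 * c


def wc_components(
    table: GenotypeTable, marker_id: str, grouping
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one locus under a grouping."""
    idx_groups = _groups_from_spec(table, grouping)
    j = table.marker_index(marker_id)
    return _components_from_calls([table.calls[idx, j] for idx in idx_groups])


def _multilocus_estimate(
    table: GenotypeTable, statistic: str, idx_groups: list[np.ndarray]
) -> tuple[float, list[tuple[str, float, float, float]]]:
    num = den = 0.0
    per_locus = []
    for j, marker in enumerate(table.panel):
        a, b, c = _components_from_calls([table.calls[idx, j] for idx in idx_groups])
        per_locus.append((marker.marker_id, a, b, c))
        if statistic == "f_st":
            num += a
            den += a + b + c
        else:
            num += b
            den += b + c
    if den == 0.0:
        raise ValueError("undefined-fstat: zero denominator (all loci monomorphic?)")
    return num / den, per_locus


def multilocus_fstat(table: GenotypeTable, statistic: str, grouping) -> FStatResult:
    """Multi-locus ratio-of-sums FIS or FST estimate.

    ``grouping`` partitions individuals into populations (see
    ``_groups_from_spec``); FST needs >= 2 groups, FIS accepts one.
    """
    if statistic not in ("f_is", "f_st"):
        raise ValueError(f"unknown statistic {statistic!r}")
    idx_groups = _groups_from_spec(table, grouping)
    if statistic == "f_st" and len(idx_groups) < 2:
        raise ValueError("f_st requires >= 2 groups")
    est, per_locus = _multilocus_estimate(table, statistic, idx_groups)
    return FStatResult(statistic=statistic, estimate=est,
                       per_locus_components=tuple(per_locus))


def permutation_test(
    table: GenotypeTable,
    statistic: str,
    grouping,
    n_perm: int,
    seed: int,
) -> FStatResult:
    """Permutation significance for FIS/FST against zero.

    FST: individuals are permuted among groups (group sizes kept).  FIS:
    within each group and locus, gene copies are permuted among individuals
    and re-paired into genotypes.  Two-sided via absolute value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    idx_groups = _groups_from_spec(table, grouping)
    if statistic == "f_st" and len(idx_groups) < 2:
        raise ValueError("f_st requires >= 2 groups")
    observed, per_locus = _multilocus_estimate(table, statistic, idx_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    if statistic == "f_st":
        pooled = np.concatenate(idx_groups)
        sizes = [len(g) for g in idx_groups]
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            bounds = np.cumsum(sizes)[:-1]
            new_groups = np.split(perm, bounds)
            est, _ = _multilocus_estimate(table, statistic, new_groups)
            if abs(est) >= abs(observed) - 1e-15:
                exceed += 1
    else:
        base = table.calls
        for _ in range(n_perm):
            calls = base.copy()
            for idx in idx_groups:
                for j in range(table.n_markers):
                    col = calls[idx, j]
                    typed = np.where(col >= 0)[0]
                    if len(typed) == 0:
                        continue
                    # expand genotypes into gene copies, shuffle, re-pair
                    copies = np.concatenate([
                        np.array(([0, 0], [0, 1], [1, 1])[c]) for c in col[typed]
                    ])
                    rng.shuffle(copies)
                    col[typed] = copies.reshape(-1, 2).sum(axis=1)
                    calls[idx, j] = col
            perm_table = GenotypeTable(
                panel=table.panel, individuals=table.individuals, calls=calls
            )
            est, _ = _multilocus_estimate(perm_table, statistic, idx_groups)
            if abs(est) >= abs(observed) - 1e-15:
                exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return FStatResult(
        statistic=statistic, estimate=observed,
        per_locus_components=tuple(per_locus),
        p_value=p, n_permutations=n_perm, seed=seed,
    )
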