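"""Identity matching, genotype concordance and kinship screening.

The concordance rate of a pair of individuals is
100 * (loci with identical genotype) / (loci compared); loci missing in
either member are excluded from both numerator and denominator.  Matching
is at the level of genotype state (WW = WW, WV = WV, VV = VV), not allele
sharing.  Pairs are screened against empirical (or normal-theory) 5%
points of the concordance distributions of known kin classes, and kin
classes are compared by a Wilcoxon rank-sum test with midranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .model import GenotypeTable, Pedigree

__all__ = [
    "PairComparison",
    "ThresholdSet",
    "RankSumResult",
    "concordance",
    "find_identical_pairs",
    "classify_pairs",
    "thresholds",
    "rank_sum_test",
    "concordance_histogram",
]

KIN_CLASSES = (
    "twin",
    "parent_offspring",
    "grandparent_grandchild",
    "full_sibling",
    "non_kin",
    "unknown",
)


@dataclass(frozen=True)
class PairComparison:
    id_a: str
    id_b: str
    n_compared_loci: int
    n_matching_loci: int
    kin_class: str = "unknown"

    @property
    def concordance(self) -> float:
        return 100.0 * self.n_matching_loci / self.n_compared_loci

    @property
    def exact_match(self) -> bool:
        return self.n_matching_loci == self.n_compared_loci


@dataclass(frozen=True)
class ThresholdSet:
    upper5_nonkin: float
    lower5_parent_offspring: float
    lower5_full_sibling: float
    method: str
    quantile_convention: str


@dataclass(frozen=True)
class RankSumResult:
    w_statistic: float
    n1: int
    n2: int
    p_value: float
    sidedness: str
    method: str


def _pair_counts(table: GenotypeTable, i: int, j: int) -> tuple[int, int]:
    a, b = table.calls[i], table.calls[j]
    both = (a >= 0) & (b >= 0)
    return int(both.sum()), int(((a == b) & both).sum())


def concordance(
    table: GenotypeTable,
    id_a: str,
    id_b: str,
    pedigree: Pedigree | None = None,
) -> PairComparison:
    """Concordance of one pair; kin class filled from ``pedigree`` if given."""
    i, j = table.individual_index(id_a), table.individual_index(id_b)
    n_comp, n_match = _pair_counts(table, i, j)
    if n_comp == 0:
        raise ValueError(f"no mutually typed loci for pair ({id_a}, {id_b})")
    kin_class = "unknown"
    if pedigree is not None:
        kin_class = pedigree.relation(id_a, id_b) or "unknown"
    return PairComparison(id_a, id_b, n_comp, n_match, kin_class)


def find_identical_pairs(
    table: GenotypeTable, max_mismatch: int = 0
) -> list[PairComparison]:
    """All unordered pairs mismatching at <= ``max_mismatch`` compared loci."""
    if table.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    out = []
    for i, j in itertools.combinations(range(table.n_individuals), 2):
        n_comp, n_match = _pair_counts(table, i, j)
        if n_comp > 0 and n_comp - n_match <= max_mismatch:
            out.append(
                PairComparison(
                    table.individuals[i].sample_id,
                    table.individuals[j].sample_id,
                    n_comp,
                    n_match,
                )
            )
    return out


def classify_pairs(
    table: GenotypeTable, pedigree: Pedigree
) -> list[PairComparison]:
    """Concordance of every unordered pair with its pedigree kin class.

    Pairs with a declared relation get that class (twin taking precedence);
    undeclared pairs from different families are non_kin; undeclared pairs
    within the same family are unknown (excluded from class comparisons).
    """
    dangling = pedigree.all_ids() - set(table.sample_ids)
    if dangling:
        raise ValueError(f"pedigree ids not in table: {sorted(dangling)}")
    family = {ind.sample_id: ind.family_id for ind in table.individuals}
    out = []
    for i, j in itertools.combinations(range(table.n_individuals), 2):
        id_a = table.individuals[i].sample_id
        id_b = table.individuals[j].sample_id
        n_comp, n_match = _pair_counts(table, i, j)
        rel = pedigree.relation(id_a, id_b)
        if rel is None:
            fam_a, fam_b = family[id_a], family[id_b]
            if fam_a is not None and fam_a == fam_b:
                rel = "unknown"
            else:
                rel = "non_kin"
        out.append(PairComparison(id_a, id_b, n_comp, n_match, rel))
    return out


def _class_values(
    comparisons: Sequence[PairComparison], kin_class: str
) -> np.ndarray:
    return np.array(
        [c.concordance for c in comparisons if c.kin_class == kin_class]
    )


def thresholds(
    comparisons: Sequence[PairComparison],
    method: str = "empirical_quantile",
    quantile_convention: str = "linear",
) -> ThresholdSet:
    """5% screening thresholds from classified pair concordances.

    ``empirical_quantile`` takes the 95th percentile of non_kin and the 5th
    percentiles of parent_offspring and full_sibling concordances under a
    numpy interpolation convention (default ``linear``, i.e. R type 7 /
    spreadsheet PERCENTILE).  ``normal_theory`` uses mean -/+ 1.645 sd.
    """
    values = {
        k: _class_values(comparisons, k)
        for k in ("non_kin", "parent_offspring", "full_sibling")
    }
    for k, v in values.items():
        if len(v) == 0:
            raise ValueError(f"no pairs in class {k!r}")
    if method == "empirical_quantile":
        up = float(np.quantile(values["non_kin"], 0.95, method=quantile_convention))
        lo_po = float(
            np.quantile(values["parent_offspring"], 0.05, method=quantile_convention)
        )
        lo_fs = float(
            np.quantile(values["full_sibling"], 0.05, method=quantile_convention)
        )
    elif method == "normal_theory":
        for k, v in values.items():
            if len(v) < 2:
                raise ValueError(f"normal_theory needs >= 2 pairs in class {k!r}")
        z = 1.645
        nk, po, fs = (values[k] for k in ("non_kin", "parent_offspring", "full_sibling"))
        up = float(nk.mean() + z * nk.std(ddof=1))
        lo_po = float(po.mean() - z * po.std(ddof=1))
        lo_fs = float(fs.mean() - z * fs.std(ddof=1))
        quantile_convention = "z=1.645"
    else:
        raise ValueError(f"unknown method {method!r}")
    return ThresholdSet(up, lo_po, lo_fs, method, quantile_convention)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by enumeration of group-1 position choices."""
    pooled = np.concatenate([x, y])
    ranks = _stats.rankdata(pooled)
    n1 = len(x)
    total = 0
    extreme = 0
    mean_w = ranks.sum() * n1 / len(pooled)
    dev_obs = abs(w_obs - mean_w)
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def rank_sum_test(
    group1: Sequence[float],
    group2: Sequence[float],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Wilcoxon rank-sum test; W is the midrank sum of ``group1``.

    Exact enumeration for n1 + n2 <= 12, otherwise the normal approximation
    with tie correction (no continuity correction).
    """
    x = np.asarray(list(group1), dtype=float)
    y = np.asarray(list(group2), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = _stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    if n <= 12 and alternative == "two-sided":
        p = _exact_rank_sum_p(x, y, w)
        return RankSumResult(w, n1, n2, p, alternative, "exact")
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        p = 1.0
    else:
        z = (w - mean_w) / math.sqrt(var_w)
        if alternative == "two-sided":
            p = 2.0 * _stats.norm.sf(abs(z))
        elif alternative == "greater":
            p = float(_stats.norm.sf(z))
        elif alternative == "less":
            p = float(_stats.norm.cdf(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return RankSumResult(w, n1, n2, min(1.0, p), alternative, "normal")


def concordance_histogram(
    comparisons: Sequence[PairComparison],
    classes: Sequence[str] = ("parent_offspring", "full_sibling", "non_kin"),
    n_loci: int = 11,
) -> dict[str, dict[float, int]]:
    """Counts of pairs per class at each attainable concordance level."""
    levels = [round(100.0 * k / n_loci, 1) for k in range(n_loci + 1)]
    out: dict[str, dict[float, int]] = {}
    for cls in classes:
        counts = dict.fromkeys(levels, 0)
        for c in comparisons:
            if c.kin_class == cls:
                counts[round(c.concordance, 1)] += 1
        out[cls] = counts
    return out
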