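"""Per-locus diversity statistics and Hardy-Weinberg testing.

Conventions follow the parentage-analysis tradition for small samples:
expected heterozygosity uses the unbiased estimator He = 2n/(2n-1) * (1 -
sum p_i^2) and polymorphic information content (PIC) is 1 - sum p_i^2 -
sum_{i<j} 2 p_i^2 p_j^2.  The Hardy-Weinberg test is the conditional exact
test for a biallelic locus (all heterozygote counts compatible with the
observed allele counts are enumerated); a seeded Monte-Carlo chain with the
classical dememorization/batch parameters is available as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "LocusSummary",
    "PanelSummary",
    "allele_frequencies",
    "genotype_counts",
    "heterozygosities",
    "pic",
    "hwe_exact",
    "hwe_mcmc",
    "hwe_test",
    "bonferroni",
    "summarize_panel",
]


@dataclass(frozen=True)
class AlleleFrequencies:
    p_w: float
    p_v: float
    n_typed: int

    def __post_init__(self) -> None:
        if not math.isclose(self.p_w + self.p_v, 1.0, abs_tol=1e-9):
            raise ValueError("allele frequencies must sum to 1")
        if min(self.p_w, self.p_v) < -1e-12 or self.n_typed < 0:
            raise ValueError("invalid allele frequencies")


@dataclass(frozen=True)
class LocusSummary:
    marker_id: str
    freqs: AlleleFrequencies
    ho: float
    he: float
    pic: float
    hwe_p: float
    hwe_degenerate: bool = False


@dataclass(frozen=True)
class PanelSummary:
    per_locus: tuple[LocusSummary, ...]
    mean_ho: float
    mean_he: float
    mean_pic: float


def genotype_counts(table: GenotypeTable, marker_id: str) -> tuple[int, int, int]:
    """(n_WW, n_WV, n_VV) over non-missing calls at a locus."""
    calls = table.locus_calls(marker_id)
    return int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())


def allele_frequencies(table: GenotypeTable, marker_id: str) -> AlleleFrequencies:
    n_ww, n_wv, n_vv = genotype_counts(table, marker_id)
    n = n_ww + n_wv + n_vv
    if n == 0:
        raise ValueError(f"monomorphic-undefined: no typed calls at {marker_id}")
    p_v = (2 * n_vv + n_wv) / (2 * n)
    return AlleleFrequencies(p_w=1.0 - p_v, p_v=p_v, n_typed=n)


def heterozygosities(
    table: GenotypeTable, marker_id: str, unbiased: bool = True
) -> tuple[float, float]:
    """Observed and expected heterozygosity (Ho, He) at one locus."""
    n_ww, n_wv, n_vv = genotype_counts(table, marker_id)
    n = n_ww + n_wv + n_vv
    if n < 2:
        raise ValueError(f"need >= 2 typed individuals at {marker_id}")
    freqs = allele_frequencies(table, marker_id)
    ho = n_wv / n
    gene_diversity = 1.0 - freqs.p_w**2 - freqs.p_v**2
    he = gene_diversity * (2 * n / (2 * n - 1) if unbiased else 1.0)
    return ho, he


def pic(freqs: AlleleFrequencies) -> float:
    ps = (freqs.p_w, freqs.p_v)
    value = 1.0 - sum(p * p for p in ps)
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            value -= 2.0 * ps[i] ** 2 * ps[j] ** 2
    return value


# -- Hardy-Weinberg ------------------------------------------------------

def _het_weights(n: int, n_v: int) -> tuple[np.ndarray, np.ndarray]:
    """Attainable heterozygote counts and their conditional weights.

    Conditional on n individuals carrying n_v copies of the variant allele,
    P(n_WV = h) is proportional to n! / (n_WW! h! n_VV!) * 2^h.
    """
    hs = np.arange(n_v % 2, min(n_v, 2 * n - n_v) + 1, 2)
    logw = np.array([
        math.lgamma(n + 1)
        - math.lgamma((n_v - h) // 2 + 1)
        - math.lgamma(h + 1)
        - math.lgamma(n - h - (n_v - h) // 2 + 1)
        + h * math.log(2.0)
        for h in hs
    ])
    w = np.exp(logw - logw.max())
    return hs, w / w.sum()


def hwe_exact(n_ww: int, n_wv: int, n_vv: int) -> float:
    """Conditional exact Hardy-Weinberg p-value for a biallelic locus.

    Sums the probabilities of all heterozygote counts no more probable than
    the observed one, conditional on the allele counts.
    """
    n = n_ww + n_wv + n_vv
    n_v = 2 * n_vv + n_wv
    if n == 0:
        raise ValueError("no typed individuals")
    if n_v in (0, 2 * n):
        return 1.0
    hs, probs = _het_weights(n, n_v)
    p_obs = probs[hs == n_wv][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_mcmc(
    n_ww: int,
    n_wv: int,
    n_vv: int,
    seed: int,
    dememorization: int = 1000,
    batches: int = 100,
    iterations_per_batch: int = 1000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the exact p-value with batch standard error.

    A Metropolis chain over heterozygote counts (proposals h -> h +/- 2)
    with the conditional distribution as its target; the estimate is the
    visit fraction of configurations no more probable than the observed one,
    averaged over batches after a dememorization burn-in.
    """
    n = n_ww + n_wv + n_vv
    n_v = 2 * n_vv + n_wv
    if n_v in (0, 2 * n):
        return 1.0, 0.0
    hs, probs = _het_weights(n, n_v)
    weight = dict(zip(hs.tolist(), probs.tolist()))
    p_obs = weight[n_wv]
    rng = np.random.default_rng(seed)
    h = int(n_wv)
    h_min, h_max = int(hs[0]), int(hs[-1])

    def step(h: int) -> int:
        prop = h + int(rng.choice((-2, 2)))
        if prop < h_min or prop > h_max:
            return h
        if rng.random() < weight[prop] / weight[h]:
            return prop
        return h

    for _ in range(dememorization):
        h = step(h)
    batch_means = np.empty(batches)
    tol = p_obs * (1 + 1e-12)
    for b in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            h = step(h)
            hits += weight[h] <= tol
        batch_means[b] = hits / iterations_per_batch
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return float(batch_means.mean()), se


def hwe_test(
    table: GenotypeTable,
    marker_id: str,
    method: str = "exact_enumeration",
    seed: int | None = None,
) -> tuple[float, bool]:
    """Hardy-Weinberg p-value at a locus; returns (p, degenerate_flag).

    A locus monomorphic in the sample has a single attainable configuration;
    p = 1 with the degenerate flag set.
    """
    n_ww, n_wv, n_vv = genotype_counts(table, marker_id)
    n = n_ww + n_wv + n_vv
    if n < 2:
        raise ValueError(f"need >= 2 typed individuals at {marker_id}")
    n_v = 2 * n_vv + n_wv
    if n_v in (0, 2 * n):
        return 1.0, True
    if method == "exact_enumeration":
        return hwe_exact(n_ww, n_wv, n_vv), False
    if method == "mcmc":
        if seed is None:
            raise ValueError("mcmc method requires a seed")
        p, _se = hwe_mcmc(n_ww, n_wv, n_vv, seed=seed)
        return p, False
    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values) -> list[float]:
    """Bonferroni adjustment: min(1, p * m), order preserved."""
    ps = list(p_values)
    if not ps:
        raise ValueError("empty p-value list")
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]


def summarize_panel(table: GenotypeTable, unbiased: bool = True) -> PanelSummary:
    """Per-locus summaries plus panel means (arithmetic means over loci)."""
    rows = []
    for marker in table.panel:
        freqs = allele_frequencies(table, marker.marker_id)
        ho, he = heterozygosities(table, marker.marker_id, unbiased=unbiased)
        p, degen = hwe_test(table, marker.marker_id)
        rows.append(
            LocusSummary(
                marker_id=marker.marker_id, freqs=freqs, ho=ho, he=he,
                pic=pic(freqs), hwe_p=p, hwe_degenerate=degen,
            )
        )
    return PanelSummary(
        per_locus=tuple(rows),
        mean_ho=float(np.mean([r.ho for r in rows])),
        mean_he=float(np.mean([r.he for r in rows])),
        mean_pic=float(np.mean([r.pic for r in rows])),
    )
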