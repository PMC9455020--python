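"""Synthetic genotype data with the structure the analyses assume.

Populations: locus frequencies per population are drawn from the
Balding-Nichols law around a base frequency p, Beta(p (1-F)/F,
(1-p)(1-F)/F) with F the target FST (F = 0 means shared frequencies), and
genotypes follow the inbreeding law P(WV) = 2 p q (1 - f) with the
homozygotes adjusted accordingly.  Pedigrees: founders are drawn the same
way and offspring receive one uniformly random allele from each parent per
locus; twins are dizygotic (independent meioses from the same parents).
All randomness flows from the config seed, so equal seeds give bit-equal
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import GenotypeTable, Individual, Marker, Pedigree, VariantType

__all__ = ["PedigreeSpec", "SimulationConfig", "mendelian_offspring", "simulate_population", "simulate_pedigree"]


@dataclass(frozen=True)
class PedigreeSpec:
    """Family templates: each family has two founder parents and
    ``offspring_per_family`` chicks; optionally a grandparent couple (the
    father's parents) and one dizygotic twin pair appended per family."""

    n_families: int = 1
    offspring_per_family: int = 2
    with_grandparents: bool = False
    with_twins: bool = False

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.offspring_per_family < 0:
            raise ValueError("invalid pedigree template")


@dataclass
class SimulationConfig:
    n_loci: int
    seed: int
    allele_freqs: Sequence[float] | None = None  # base variant frequencies; None -> Uniform(0.05, 0.5)
    inbreeding_f: float = 0.0
    n_populations: int = 1
    target_fst: float = 0.0
    population_sizes: Sequence[int] = (50,)
    pedigree_spec: PedigreeSpec = field(default_factory=PedigreeSpec)
    missing_rate: float = 0.0
    typo_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for rate in (self.missing_rate, self.typo_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must lie in [0, 1)")
        if not -1 <= self.inbreeding_f <= 1:
            raise ValueError("inbreeding_f must lie in [-1, 1]")
        if len(self.population_sizes) not in (1, self.n_populations):
            raise ValueError("population_sizes must match n_populations")

    def resolved_sizes(self) -> list[int]:
        sizes = list(self.population_sizes)
        if len(sizes) == 1 and self.n_populations > 1:
            sizes = sizes * self.n_populations
        return sizes

    def base_frequencies(self, rng: np.random.Generator) -> np.ndarray:
        if self.allele_freqs is not None:
            p = np.asarray(self.allele_freqs, dtype=float)
            if len(p) != self.n_loci:
                raise ValueError("allele_freqs length must equal n_loci")
            if ((p <= 0) | (p >= 1)).any():
                raise ValueError("base frequencies must lie in (0, 1)")
            return p
        return rng.uniform(0.05, 0.5, size=self.n_loci)


def _panel(n_loci: int) -> list[Marker]:
    return [
        Marker(
            marker_id=f"Sim-{k + 1:02d}",
            variant_type=VariantType.DELETION,
            indel_size=30,
            amplicon_size_wild=200,
        )
        for k in range(n_loci)
    ]


def _population_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_populations, n_loci) variant frequencies under Balding-Nichols."""
    base = config.base_frequencies(rng)
    if config.target_fst == 0.0 or config.n_populations == 1:
        return np.tile(base, (config.n_populations, 1))
    f = config.target_fst
    alpha = base * (1 - f) / f
    beta = (1 - base) * (1 - f) / f
    return rng.beta(alpha, beta, size=(config.n_populations, config.n_loci))


def _draw_genotypes(
    p: np.ndarray, n: int, inbreeding_f: float, rng: np.random.Generator
) -> np.ndarray:
    """n individuals x loci dosages under HWE with inbreeding f."""
    q = 1.0 - p
    p_wv = 2 * p * q * (1 - inbreeding_f)
    p_vv = p**2 + inbreeding_f * p * q
    p_ww = q**2 + inbreeding_f * p * q
    probs = np.stack([p_ww, p_wv, p_vv])
    if (probs < -1e-12).any():
        raise ValueError("inbreeding_f makes a genotype probability negative")
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=0)
    u = rng.random((n, len(p)))
    return (u > probs[0]).astype(np.int8) + (u > probs[0] + probs[1]).astype(np.int8)


def _inject_missing(calls: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate > 0:
        calls[rng.random(calls.shape) < rate] = -1


def simulate_population(config: SimulationConfig) -> GenotypeTable:
    """Independent individuals in one or more structured populations."""
    rng = np.random.default_rng(config.seed)
    freqs = _population_frequencies(config, rng)
    sizes = config.resolved_sizes()
    individuals: list[Individual] = []
    blocks = []
    for k, (size, p) in enumerate(zip(sizes, freqs)):
        blocks.append(_draw_genotypes(p, size, config.inbreeding_f, rng))
        individuals.extend(
            Individual(sample_id=f"P{k + 1}-{i + 1:03d}", region=f"pop{k + 1}")
            for i in range(size)
        )
    calls = np.concatenate(blocks, axis=0)
    _inject_missing(calls, config.missing_rate, rng)
    return GenotypeTable(panel=_panel(config.n_loci), individuals=individuals, calls=calls)


def mendelian_offspring(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring dosage vector: a uniformly random allele from each
    parent per locus."""
    from_mother = (rng.random(mother.shape) < mother / 2.0).astype(np.int8)
    from_father = (rng.random(father.shape) < father / 2.0).astype(np.int8)
    return from_mother + from_father


def simulate_pedigree(config: SimulationConfig) -> tuple[GenotypeTable, Pedigree]:
    """Families with Mendelian transmission; returns (table, pedigree).

    Each family: two founder parents, ``offspring_per_family`` chicks (full
    siblings), optionally the father's parents (adding grandparent edges to
    every chick) and one dizygotic twin pair appended to the brood.
    """
    spec = config.pedigree_spec
    rng = np.random.default_rng(config.seed)
    p = config.base_frequencies(rng)

    def founder() -> np.ndarray:
        return _draw_genotypes(p, 1, config.inbreeding_f, rng)[0]

    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    ped = Pedigree()

    def add(sample_id: str, family: str, calls: np.ndarray) -> None:
        individuals.append(Individual(sample_id=sample_id, family_id=family))
        rows.append(calls)

    for fam in range(1, spec.n_families + 1):
        fid = f"F{fam:02d}"
        if spec.with_grandparents:
            gm, gf = founder(), founder()
            add(f"{fid}-GM", fid, gm)
            add(f"{fid}-GF", fid, gf)
            father = mendelian_offspring(gm, gf, rng)
        else:
            father = founder()
        mother = founder()
        add(f"{fid}-dam", fid, mother)
        add(f"{fid}-sire", fid, father)
        brood: list[str] = []
        for c in range(spec.offspring_per_family):
            cid = f"{fid}-c{c + 1}"
            add(cid, fid, mendelian_offspring(mother, father, rng))
            brood.append(cid)
        if spec.with_twins:
            t1, t2 = f"{fid}-t1", f"{fid}-t2"
            add(t1, fid, mendelian_offspring(mother, father, rng))
            add(t2, fid, mendelian_offspring(mother, father, rng))
            ped.twin_pairs.add(frozenset((t1, t2)))
            brood.extend((t1, t2))
        for cid in brood:
            ped.parent_offspring.add((f"{fid}-dam", cid))
            ped.parent_offspring.add((f"{fid}-sire", cid))
            if spec.with_grandparents:
                ped.grandparent.add((f"{fid}-GM", cid))
                ped.grandparent.add((f"{fid}-GF", cid))
        for i, a in enumerate(brood):
            for b in brood[i + 1:]:
                ped.full_sibling_pairs.add(frozenset((a, b)))
        if spec.with_grandparents:
            ped.parent_offspring.add((f"{fid}-GM", f"{fid}-sire"))
            ped.parent_offspring.add((f"{fid}-GF", f"{fid}-sire"))

    calls = np.array(rows, dtype=np.int8)
    _inject_missing(calls, config.missing_rate, rng)
    table = GenotypeTable(panel=_panel(config.n_loci), individuals=individuals, calls=calls)
    return table, ped
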