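"""Synthetic population and pedigree generator."""

import itertools

import numpy as np
import pytest

from tancho import (
    PedigreeSpec,
    mendelian_offspring,
    SimulationConfig,
    multilocus_fstat,
    parse_genotype_table,
    simulate_pedigree,
    simulate_population,
    write_genotype_table,
)


def po_pairs_share_allele(table, ped):
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    for parent, child in ped.parent_offspring:
        gp = table.calls[idx[parent]]
        gc = table.calls[idx[child]]
        both = (gp >= 0) & (gc >= 0)
        # dosage pairs (0,2) and (2,0) are the only allele-sharing violations
        if np.any((np.abs(gp - gc) == 2) & both):
            return False
    return True


class TestPopulation:
    def test_same_seed_bit_identical(self):
        cfg = dict(n_loci=20, seed=99, n_populations=2, target_fst=0.1,
                   population_sizes=(30, 30), missing_rate=0.05)
        t1 = simulate_population(SimulationConfig(**cfg))
        t2 = simulate_population(SimulationConfig(**cfg))
        assert np.array_equal(t1.calls, t2.calls)
        assert t1.sample_ids == t2.sample_ids

    def test_full_inbreeding_removes_heterozygotes(self):
        cfg = SimulationConfig(n_loci=30, seed=5, inbreeding_f=1.0,
                               population_sizes=(80,))
        table = simulate_population(cfg)
        assert not (table.calls == 1).any()

    def test_negative_inbreeding_can_be_infeasible(self):
        cfg = SimulationConfig(n_loci=5, seed=5, inbreeding_f=-0.9,
                               allele_freqs=[0.05] * 5, population_sizes=(10,))
        with pytest.raises(ValueError, match="negative"):
            simulate_population(cfg)

    def test_zero_fst_shares_frequencies(self):
        cfg = SimulationConfig(n_loci=8, seed=17, n_populations=2,
                               target_fst=0.0, population_sizes=(400, 400),
                               allele_freqs=[0.3] * 8)
        table = simulate_population(cfg)
        p1 = table.calls[:400].mean() / 2
        p2 = table.calls[400:].mean() / 2
        assert abs(p1 - p2) < 0.05  # same law, sampling noise only

    def test_frequency_convergence(self):
        target = [0.25] * 50
        cfg = SimulationConfig(n_loci=50, seed=23, allele_freqs=target,
                               population_sizes=(2000,))
        table = simulate_population(cfg)
        emp = table.calls.mean(axis=0) / 2
        se = np.sqrt(0.25 * 0.75 / (2 * 2000))
        assert np.abs(emp - 0.25).mean() < 3 * se

    def test_missing_rate_applied(self):
        cfg = SimulationConfig(n_loci=50, seed=3, missing_rate=0.2,
                               population_sizes=(100,))
        table = simulate_population(cfg)
        rate = (table.calls == -1).mean()
        assert 0.15 < rate < 0.25

    def test_seed_is_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            SimulationConfig(n_loci=5, seed=None)


class TestPedigree:
    def test_certain_cross_gives_all_heterozygotes(self):
        # WW x VV parents: every offspring must be WV at every locus
        rng = np.random.default_rng(1)
        mother = np.zeros(200, dtype=np.int8)
        father = np.full(200, 2, dtype=np.int8)
        for _ in range(10):
            child = mendelian_offspring(mother, father, rng)
            assert (child == 1).all()

    def test_parent_offspring_always_share_an_allele(self):
        cfg = SimulationConfig(
            n_loci=25, seed=42,
            pedigree_spec=PedigreeSpec(n_families=6, offspring_per_family=4,
                                       with_grandparents=True, with_twins=True),
        )
        table, ped = simulate_pedigree(cfg)
        assert po_pairs_share_allele(table, ped)

    def test_same_seed_bit_identical(self):
        cfg = dict(
            n_loci=12, seed=8,
            pedigree_spec=PedigreeSpec(n_families=3, offspring_per_family=2),
        )
        t1, p1 = simulate_pedigree(SimulationConfig(**cfg))
        t2, p2 = simulate_pedigree(SimulationConfig(**cfg))
        assert np.array_equal(t1.calls, t2.calls)
        assert p1.parent_offspring == p2.parent_offspring

    def test_twins_are_dizygotic(self):
        cfg = SimulationConfig(
            n_loci=60, seed=12, allele_freqs=[0.5] * 60,
            pedigree_spec=PedigreeSpec(n_families=1, offspring_per_family=0,
                                       with_twins=True),
        )
        table, ped = simulate_pedigree(cfg)
        idx = {s: i for i, s in enumerate(table.sample_ids)}
        (pair,) = ped.twin_pairs
        a, b = sorted(pair)
        assert (table.calls[idx[a]] != table.calls[idx[b]]).any()

    def test_grandparent_edges_recorded(self):
        cfg = SimulationConfig(
            n_loci=5, seed=2,
            pedigree_spec=PedigreeSpec(n_families=2, offspring_per_family=1,
                                       with_grandparents=True),
        )
        _, ped = simulate_pedigree(cfg)
        assert len(ped.grandparent) == 2 * 2  # two grandparents x one chick x two families

    def test_sibling_concordance_exceeds_nonkin_enumeration(self):
        """Full sibs beat non-kin in expected genotype concordance; the
        sibling expectation is checked against exact enumeration of the
        joint sibling genotype distribution at p = 0.3."""
        p = 0.3
        q = 1 - p
        gf = {0: q * q, 1: 2 * p * q, 2: p * p}
        gam = {0: [0], 1: [0, 1], 2: [1]}

        def sib_match_prob():
            match = 0.0
            for gm, pm in gf.items():
                for gsire, ps in gf.items():
                    joint = pm * ps
                    kids = {}
                    for a1 in gam[gm]:
                        for b1 in gam[gsire]:
                            kids[a1 + b1] = kids.get(a1 + b1, 0) + 1 / (
                                len(gam[gm]) * len(gam[gsire])
                            )
                    match += joint * sum(v * v for v in kids.values())
            return match

        exact_sib = sib_match_prob()
        exact_nonkin = sum(v * v for v in gf.values())
        assert exact_sib > exact_nonkin

        cfg = SimulationConfig(
            n_loci=500, seed=606, allele_freqs=[p] * 500,
            pedigree_spec=PedigreeSpec(n_families=25, offspring_per_family=2),
        )
        table, ped = simulate_pedigree(cfg)
        idx = {s: i for i, s in enumerate(table.sample_ids)}
        rates = []
        for pair in ped.full_sibling_pairs:
            a, b = sorted(pair)
            rates.append((table.calls[idx[a]] == table.calls[idx[b]]).mean())
        # 25 families x 500 loci = 12500 locus pairs
        assert np.mean(rates) == pytest.approx(exact_sib, abs=0.02)

    def test_roundtrip_through_dialect_with_typos(self):
        cfg = SimulationConfig(
            n_loci=10, seed=77,
            pedigree_spec=PedigreeSpec(n_families=2, offspring_per_family=3),
        )
        table, _ = simulate_pedigree(cfg)
        rng = np.random.default_rng(1)
        text = write_genotype_table(table, typo_rate=0.5, rng=rng)
        back = parse_genotype_table(text, panel=table.panel)
        assert np.array_equal(back.calls, table.calls)
        n_het = int((table.calls == 1).sum())
        assert 0 < len(back.warnings) <= n_het


class TestRecoverySmall:
    def test_fis_near_zero_without_inbreeding(self, nonkin):
        from tancho.locus_stats import allele_frequencies

        freqs = [allele_frequencies(nonkin, m).p_v for m in nonkin.marker_ids]
        ests = []
        for rep in range(60):
            cfg = SimulationConfig(n_loci=11, seed=1000 + rep,
                                   allele_freqs=freqs, population_sizes=(39,))
            t = simulate_population(cfg)
            ests.append(multilocus_fstat(t, "f_is", [t.sample_ids]).estimate)
        assert abs(np.mean(ests)) < 3 * np.std(ests) / np.sqrt(len(ests)) + 0.02
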