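"""Identity matching, concordance, pedigree classes, thresholds, rank sums."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from tancho import (
    classify_pairs,
    concordance,
    find_identical_pairs,
    rank_sum_test,
    thresholds,
)
from tancho.kinship import concordance_histogram
from tancho.model import GenotypeTable, Individual, Marker, Pedigree, VariantType


def table_from_rows(rows, ids=None, families=None):
    calls = np.asarray(rows, dtype=np.int8)
    n, m = calls.shape
    ids = ids or [f"s{i}" for i in range(n)]
    fams = families or [None] * n
    return GenotypeTable(
        panel=[Marker(f"L{j}", VariantType.DELETION, 30, 200) for j in range(m)],
        individuals=[
            Individual(sample_id=i, family_id=f) for i, f in zip(ids, fams)
        ],
        calls=calls,
    )


class TestConcordance:
    def test_self_pair_is_100(self, kin):
        pair = concordance(kin, "207", "207")
        assert pair.concordance == 100.0 and pair.exact_match

    def test_father_207_vs_chick_352_match_10_of_11(self, kin):
        pair = concordance(kin, "207", "352")
        assert (pair.n_compared_loci, pair.n_matching_loci) == (11, 10)
        assert pair.concordance == pytest.approx(100 * 10 / 11)

    def test_symmetry_and_locus_order_invariance(self, kin):
        ab = concordance(kin, "207", "387")
        ba = concordance(kin, "387", "207")
        assert ab.concordance == ba.concordance
        shuffled = kin.subset(kin.sample_ids)
        shuffled.calls = shuffled.calls[:, ::-1].copy()
        shuffled.panel = list(reversed(shuffled.panel))
        assert (
            concordance(shuffled, "207", "387").concordance == ab.concordance
        )

    def test_fully_discordant_pair_is_zero(self):
        table = table_from_rows([[0, 0, 0], [1, 2, 1]])
        assert concordance(table, "s0", "s1").concordance == 0.0

    def test_missing_loci_removed_pairwise(self):
        table = table_from_rows([[0, -1, 1], [0, 2, -1]])
        pair = concordance(table, "s0", "s1")
        assert pair.n_compared_loci == 1 and pair.concordance == 100.0

    def test_no_shared_loci_is_an_error(self):
        table = table_from_rows([[0, -1], [-1, 2]])
        with pytest.raises(ValueError):
            concordance(table, "s0", "s1")


class TestIdentityMatching:
    def test_nonkin_has_exactly_the_89_127_pair(self, nonkin):
        pairs = find_identical_pairs(nonkin)
        assert [(p.id_a, p.id_b) for p in pairs] == [("89", "127")]

    def test_union_has_exactly_two_pairs_among_2145(self, union):
        pairs = find_identical_pairs(union)
        assert {frozenset((p.id_a, p.id_b)) for p in pairs} == {
            frozenset(("89", "127")),
            frozenset(("331", "388")),
        }
        n = union.n_individuals
        assert n * (n - 1) // 2 == 2145

    def test_duplicated_rows_are_reported(self, nonkin):
        sub = nonkin.subset(nonkin.sample_ids[:3])
        dup = table_from_rows(
            np.vstack([sub.calls, sub.calls[:1]]), ids=["a", "b", "c", "a2"]
        )
        pairs = find_identical_pairs(dup)
        assert {frozenset((p.id_a, p.id_b)) for p in pairs} == {frozenset(("a", "a2"))}

    def test_max_mismatch_widens_the_net(self, nonkin):
        strict = len(find_identical_pairs(nonkin, max_mismatch=0))
        loose = len(find_identical_pairs(nonkin, max_mismatch=1))
        assert loose > strict


class TestClassification:
    def test_kin_table_pair_class_counts(self, kin, pedigree):
        comps = classify_pairs(kin, pedigree)
        assert len(comps) == 39 * 38 // 2
        by_class = {}
        for c in comps:
            by_class.setdefault(c.kin_class, []).append(c)
        assert len(by_class["parent_offspring"]) == 25
        assert len(by_class["twin"]) == 2
        assert len(by_class["grandparent_grandchild"]) == 4

    def test_twin_pair_classified_as_twin(self, kin, pedigree):
        comps = {frozenset((c.id_a, c.id_b)): c for c in classify_pairs(kin, pedigree)}
        assert comps[frozenset(("315", "316"))].kin_class == "twin"
        # 244/245 are both twins and declared siblings; twin takes precedence
        assert comps[frozenset(("244", "245"))].kin_class == "twin"

    def test_empty_pedigree_makes_cross_family_pairs_nonkin(self, kin):
        comps = classify_pairs(kin, Pedigree())
        fam = {i.sample_id: i.family_id for i in kin.individuals}
        for c in comps:
            expected = "unknown" if fam[c.id_a] == fam[c.id_b] else "non_kin"
            assert c.kin_class == expected

    def test_dangling_pedigree_id_rejected(self, kin):
        ped = Pedigree(parent_offspring={("ghost", "207")})
        with pytest.raises(ValueError, match="ghost"):
            classify_pairs(kin, ped)


class TestThresholds:
    def test_constant_class_gives_that_value(self):
        table = table_from_rows(
            [[0, 0], [0, 0], [1, 1], [1, 1]],
            ids=list("abcd"),
            families=["f1", "f1", "f2", "f2"],
        )
        ped = Pedigree(
            parent_offspring={("a", "b"), ("c", "d")},
            full_sibling_pairs={frozenset(("a", "c"))},
        )
        comps = classify_pairs(table, ped)
        thr = thresholds(comps, method="empirical_quantile")
        po_values = {c.concordance for c in comps if c.kin_class == "parent_offspring"}
        assert po_values == {100.0}
        assert thr.lower5_parent_offspring == 100.0

    def test_normal_theory_zero_sd_gives_mean(self):
        table = table_from_rows(
            [[0, 0], [0, 0], [0, 0], [1, 1], [1, 1], [1, 1]],
            ids=list("abcdef"),
            families=["f1", "f1", "f1", "f2", "f2", "f2"],
        )
        ped = Pedigree(
            parent_offspring={("a", "b"), ("a", "c")},
            full_sibling_pairs={frozenset(("d", "e")), frozenset(("d", "f"))},
        )
        thr = thresholds(classify_pairs(table, ped), method="normal_theory")
        assert thr.lower5_parent_offspring == pytest.approx(100.0)

    def test_fixture_parent_offspring_quantile_matches_enumeration(self, kin, pedigree):
        comps = classify_pairs(kin, pedigree)
        po = sorted(c.concordance for c in comps if c.kin_class == "parent_offspring")
        assert len(po) == 25
        thr = thresholds(comps, method="empirical_quantile", quantile_convention="linear")
        assert thr.lower5_parent_offspring == pytest.approx(
            float(np.quantile(po, 0.05, method="linear"))
        )

    def test_unknown_class_pairs_are_excluded_from_thresholds(self, kin, pedigree):
        comps = [c for c in classify_pairs(kin, pedigree) if c.kin_class != "unknown"]
        full = classify_pairs(kin, pedigree)
        assert thresholds(comps) == thresholds(full)


class TestRankSum:
    def test_maximal_separation_w(self):
        res = rank_sum_test([10, 11, 12], [1, 2, 3, 4])
        n1, n2 = 3, 4
        assert res.w_statistic == n1 * n2 + n1 * (n1 + 1) / 2

    def test_identical_small_groups_exact_p_is_one(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0)

    def test_exact_against_scipy_mannwhitney(self):
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        res = rank_sum_test(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_against_scipy(self):
        rng = np.random.default_rng(77)
        x = rng.normal(0.4, 1, size=20).tolist()
        y = rng.normal(0.0, 1, size=25).tolist()
        res = rank_sum_test(x, y)
        ref = sstats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_w_bounds_for_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n1, n2 = rng.integers(1, 15, size=2)
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            res = rank_sum_test(x.tolist(), y.tolist())
            assert n1 * (n1 + 1) / 2 <= res.w_statistic <= n1 * n2 + n1 * (n1 + 1) / 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestHistogram:
    def test_histogram_counts_match_class_sizes(self, kin, pedigree):
        comps = classify_pairs(kin, pedigree)
        hist = concordance_histogram(comps, n_loci=11)
        for cls, counts in hist.items():
            assert sum(counts.values()) == sum(
                1 for c in comps if c.kin_class == cls
            )
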