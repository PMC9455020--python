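# tancho

Population-genetic analysis and individual identification with small
panels of gel-resolvable biallelic InDel markers, built around the
11-marker panel developed for the red-crowned crane (*Grus japonensis*,
"tancho") island population of eastern Hokkaido.

Long (≥ 30 bp) insertion/deletion polymorphisms can be typed on an
ordinary agarose gel: each locus has a wild allele W and one variant
allele V, so every bird is WW, WV or VV and a panel of a dozen loci gives
a cheap multilocus fingerprint. This package implements the complete
statistical toolchain such a panel needs, and ships the published crane
genotype tables (39 unrelated chicks from three regions; 39 members of 12
known families; 66 unique birds in their union) as bundled fixtures:

- **Locus statistics** — allele frequencies, observed heterozygosity
  `Ho = n_WV / n`, unbiased expected heterozygosity
  `He = 2n/(2n−1) · (1 − Σ pᵢ²)`, polymorphic information content
  `PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²`, the conditional exact
  Hardy–Weinberg test (plus a seeded Monte-Carlo variant) and Bonferroni
  correction.
- **F-statistics** — Weir & Cockerham (1984) ANOVA components (a, b, c)
  per locus, multi-locus ratio-of-sums estimates
  `θ = Σa / Σ(a+b+c)` (F<sub>ST</sub>) and `f = Σb / Σ(b+c)`
  (F<sub>IS</sub>), with permutation tests.
- **Non-exclusion probabilities** — closed-form per-locus and combined
  probabilities that the panel fails to distinguish two individuals
  (`Q_I = 2a₂² − a₄`), a wrong first parent, a wrong second parent, or a
  wrong parent pair, from allele-frequency power sums `aₘ = Σ pᵢᵐ` under
  HWE; each closed form is validated against an exhaustive Mendelian
  enumeration oracle.
- **Identity & kinship** — exhaustive pairwise identity matching, the
  concordance rate `100 · (matching loci) / (compared loci)`,
  pedigree-based pair classification, empirical and normal-theory 5%
  screening thresholds, and Wilcoxon rank-sum comparisons (midranks,
  exact for small samples).
- **PCA** — genotype-dosage principal components with deterministic signs
  and per-component contribution ratios.
- **Simulation** — Balding–Nichols population structure with tunable
  F<sub>ST</sub>, inbreeding-adjusted HWE genotypes, Mendelian pedigrees
  with twins and grandparents, missingness and dialect-typo noise; fully
  seeded.

## Worked example

```python
>>> from tancho import select_dataset, summarize_panel, summarize_exclusion, find_identical_pairs
>>> nonkin = select_dataset("non_kin")
>>> s = summarize_panel(nonkin)
>>> round(s.mean_ho, 3), round(s.mean_he, 3)
(0.284, 0.315)
>>> excl = summarize_exclusion(nonkin)
>>> round(excl.combined_ne_identity, 3)
0.001
>>> [(p.id_a, p.id_b) for p in find_identical_pairs(select_dataset("union"))]
[('89', '127'), ('331', '388')]
```

Mean He ≈ 0.31 over the 11 loci confirms the island population's low
genetic diversity; the combined non-exclusion probability of identity,
0.001, means two random cranes share a full 11-locus genotype about once
in a thousand pairs — and indeed exactly two of the 2145 pairs among the
66 bundled birds match at every locus. The `examples/` directory has one
narrative script per capability (`python examples/locus_summary.py`, …),
and the same analyses are exposed as a thin CLI
(`tancho stats|fstats|exclusion|identity|kinship|pca|simulate|reproduce`).

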