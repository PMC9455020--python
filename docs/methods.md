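# Methods

## Data model

A marker panel is a list of strictly biallelic InDel loci; genotypes are
stored as variant-allele dosages (0 = WW, 1 = WV, 2 = VV, −1 = missing)
in an individuals × loci matrix. The bundled fixtures transcribe the
published crane tables token-for-token, including their typographic cell
variants ("WD Heter", "W Heter", "W Hetero"), which the parser normalizes
to the heterozygote call with one recorded warning per cell — every such
cell sits in a heterozygote-dialect column and the table legend defines
no other state they could denote. The two tables overlap in 12 birds;
`select_dataset("union")` keeps the non-kin copy of each duplicate
(the overlapping rows agree genotype-for-genotype) and yields the
66-sample identification set.

The kin table's family annotations are read as: "Sibling of X" = chick of
X; "Father of 116–390" = father of the seven listed chicks 116…390;
"Grandsibling of T73" = grandchild of T73. This yields 25 parent–offspring
pairs, 4 grandparent–grandchild pairs and 2 twin pairs, with full-sibling
pairs declared within each brood. The pedigree is an editable TSV
fixture, not hard-coded.

## Estimators and conventions

**Heterozygosity and PIC.** He uses the small-sample unbiased estimator
2n/(2n−1)·(1 − Σpᵢ²) (the convention of the standard parentage software
family); the biased variant is available via `unbiased=False`. Panel
means are arithmetic means over loci, not pooled counts. Missing data are
handled per locus (complete case), so n may differ across loci.
Monomorphic loci get Ho = He = PIC = 0 rather than NaN.

**Hardy–Weinberg.** The default test is the conditional exact test for a
biallelic locus: given n individuals and the observed variant-allele
count, all attainable heterozygote counts h (same parity) are enumerated
with weights n!/(n_WW! h! n_VV!)·2ʰ, and the p-value is the total
probability of configurations no more probable than the observed one
(tolerance 1+1e−12 on the probability comparison to absorb float ties).
A Metropolis chain over h with the classical parameters (dememorization
1000, 100 batches × 1000 iterations, caller seed, batch standard error)
is provided as a cross-check; for biallelic loci the exact enumeration is
always feasible and is the default.

**F-statistics.** Per locus and allele the Weir–Cockerham (1984) variance
components a (among populations), b (among individuals within
populations) and c (within individuals) are computed from sample sizes,
allele frequencies and heterozygote frequencies; the two alleles of a
biallelic locus contribute symmetrically. Multi-locus estimates are
ratios of summed components (never means of per-locus ratios), making
them invariant to duplicating a locus. Negative estimates are reported
as computed. With a single population the θ terms vanish and f reduces to
the one-level ANOVA; the package's headline F<sub>IS</sub> for the 39
non-kin birds uses this single-population convention because the
per-region rows of the published diversity table reproduce exactly under
it; the regions-as-subpopulations variant is one argument away.
Permutation nulls: for θ, individuals are permuted among groups; for f,
gene copies are permuted among individuals within each group and
re-paired. p = (1 + #{|perm| ≥ |obs|})/(1 + n_perm) — two-sided by
absolute value, never exactly zero; the scheme behind the study's printed
permutation p-values is not recoverable, so permutation machinery is
validated by null calibration on exchangeable synthetic data instead of
against printed p-values.

**Non-exclusion probabilities.** All four statistics are closed forms in
the frequency power sums a₂…a₆ assuming HWE and locus independence
(identity: 2a₂²−a₄; first parent, second parent and parent pair via the
classical exclusion-power polynomials; combined values are products over
loci). The test suite proves each closed form equal (≤ 1e−12) to an
exhaustive enumeration over parental/candidate genotypes and Mendelian
gametes on a frequency grid, and checks the identity formula against
10⁵-pair simulation. Frequencies feeding these formulas come from the
non-kin sample only, because family-based sampling biases allele
frequencies.

**Concordance and thresholds.** Genotype match is state-level equality;
loci missing in either member are excluded from numerator and
denominator. Empirical 5% screening points use interpolated order
statistics, default `numpy` method `linear` (R type 7, the convention of
the spreadsheet tools the study names); the printed threshold triple does
not discriminate between interpolation families (see Reproduction notes),
so the default was fixed on provenance rather than fit. The
normal-theory variant uses mean ± 1.645·sd. The rank-sum statistic W is
the midrank sum of the kin group; p is exact (full enumeration) for
n₁+n₂ ≤ 12 and the tie-corrected normal approximation otherwise. The
non-kin pair set defaults to cross-family pairs of the kin table (652
pairs), and the "known full-sibling" set defaults to T73's brood of
seven (21 pairs), with the all-declared-groups variant available —
neither the published N₂ = 366 non-kin pairs nor the exact sibling set
could be reconstructed from the published table, so pair-set sizes are
always logged in reports.

**PCA.** Dosage encoding (WW→0, WV→1, VV→2) with optional per-locus mean
imputation; column-centered (optionally unit-scaled) SVD; constant
columns are dropped with a warning because near-monomorphic loci go
constant in subgroups. Contribution ratio of component i is λᵢ/Σλ.
Signs are fixed by making each component's largest-magnitude loading
positive, so score tables are reproducible run-to-run and under row
permutation.

## Synthetic data

The generator emulates exactly the structure the estimators assume:
per-population allele frequencies from the Balding–Nichols Beta law
(parameterized directly by the target F<sub>ST</sub>; F<sub>ST</sub> = 0
shares frequencies), genotypes from the inbreeding-adjusted HWE law
P(WV) = 2pq(1−F) (an F making a genotype probability negative is an
error), Mendelian pedigrees (one uniformly random allele per parent per
locus) with dizygotic twins — matching the observed non-identical crane
twins — optional grandparent couples, uniform missingness, and
dialect-typo noise at serialization to exercise the parser. A single
seed drives everything; equal seeds give bit-identical tables. Base
frequencies default to Uniform(0.05, 0.5) per locus, the range spanned by
the real panel. What the generator does *not* emulate: linkage between
loci, genotyping error correlated with genotype, null alleles, or any
demographic history — passing calibration tests therefore shows estimator
correctness under the model's own assumptions, not robustness to real
data pathologies.

Calibration suites (sized to run comfortably on one CPU): exact-HWE
type-I error over 1000 replicates at n = 39; F<sub>IS</sub> null recovery
over 500 replicates at the panel's own frequencies; θ recovery of
F<sub>ST</sub> ∈ {0.05, 0.1, 0.2} within ±0.02 over 200 replicates of
two populations of 50 × 100 loci; permutation-p uniformity over 200
exchangeable datasets.

## Reproduction notes and known limitations

The published genotype tables are internally inconsistent with several of
the published summary numbers, and the package reports what the tables
yield rather than the printed figures:

- The Nemuro column of the diversity table (Ho 0.294 / He 0.320 / FIS
  0.085) is not reproducible from the printed Nemuro genotypes (which
  give 0.287 / 0.316 / 0.096); adding a single extra Id-05 heterozygote
  to any Nemuro bird reconciles that entire row and the Total Ho/He,
  strongly suggesting a one-cell difference between the printed table and
  the data actually analysed. The Total FIS (printed 0.095; computed
  0.098 single-population, 0.090 three-region), global F<sub>ST</sub>
  (0.013 vs computed 0.012), Kushiro–Nemuro F<sub>ST</sub> (0.009 vs
  0.008) and the parentage non-exclusion products (0.518/0.077 vs
  computed 0.522/0.080) shift accordingly. Kushiro He is exactly
  212/715 = 0.29650, which prints as 0.297 at three decimals against the
  published 0.296.
- The published lower 5% point of parent–offspring concordance (72.7%)
  is unattainable from the printed kin table: 9 of the 25 pairs lie below
  72.7%, so every standard quantile convention puts the 5th percentile
  near 45.5%. The published grandparent summary (45.5–72.7%, mean 56.8)
  likewise disagrees with the four printed grandchild rows
  (45.5–63.6%, mean 52.3).
- Values that do reproduce exactly from the same fixtures: the Tokachi
  and Kushiro diversity rows, pairwise F<sub>ST</sub> Tokachi–Kushiro
  (−0.006) and Tokachi–Nemuro (0.033), the Id-03 Hardy–Weinberg result,
  the combined identity non-exclusion probability (0.001), and both
  identity-matching results ((89,127); plus (331,388) among the 2145
  union pairs).

The corresponding acceptance tests assert the printed values at printed
precision and are left failing where the fixtures cannot yield them; the
package never substitutes printed figures for computed ones.

Other limitations: the panel model is strictly biallelic (no multiallelic
loci, no null alleles); identity matching has no genotyping-error model
beyond the `max_mismatch` knob; exclusion probabilities assume HWE and
independent loci (test HWE first; the bundled panel passes after
Bonferroni); band prediction is fragment-length arithmetic only, with the
heteroduplex extra band flagged but not sized, and the reading of the
recorded product size for the insertion marker (wild vs variant allele)
is switchable because the source table does not disambiguate it.
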