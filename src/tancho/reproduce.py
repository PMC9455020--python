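"""End-to-end reproduction of the study's statistical analysis on the
bundled genotype tables, emitting TSV reports with run manifests.

Stages, in order: per-locus diversity summary, F-statistics with
permutation p-values, non-exclusion probabilities, exhaustive identity
matching, kinship concordance analysis (thresholds and rank-sum tests) and
genotype PCA.  Deterministic stages are byte-reproducible; stochastic
stages record seed and replicate counts in the manifest.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exclusion import summarize_exclusion
from .fixtures import load_kin_pedigree, select_dataset
from .fstats import multilocus_fstat, permutation_test
from .kinship import (
    classify_pairs,
    concordance_histogram,
    find_identical_pairs,
    rank_sum_test,
    thresholds,
)
from .locus_stats import bonferroni, summarize_panel
from .pca import encode_dosage, run_pca

__all__ = ["RunManifest", "run_full_reproduction"]

#: T73's brood: the one sibling set whose pair count matches the study's
#: known full-sibling comparison (C(7,2) = 21 pairs).
T73_BROOD = ("116", "204", "261", "312", "313", "353", "390")


@dataclass
class RunManifest:
    subcommand: str
    inputs: list[str]
    outputs: list[str]
    seed: int | None
    package_version: str = __version__
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir: Path) -> None:
        path = out_dir / f"{self.subcommand}.manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sibling_values(comparisons, table, which: str):
    if which == "t73_brood":
        brood = set(T73_BROOD)
        return [
            c.concordance
            for c in comparisons
            if c.kin_class == "full_sibling" and {c.id_a, c.id_b} <= brood
        ]
    if which == "all_groups":
        return [c.concordance for c in comparisons if c.kin_class == "full_sibling"]
    raise ValueError(f"unknown sibling set {which!r}")


def run_full_reproduction(
    out_dir,
    seed: int = 0,
    n_perm: int = 999,
    sibling_set: str = "t73_brood",
) -> dict:
    """Run the complete analysis chain on the bundled tables.

    Writes one TSV (plus manifest) per stage into ``out_dir`` and returns
    the headline numbers as a nested dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nonkin = select_dataset("non_kin")
    kin = select_dataset("kin")
    union = select_dataset("union")
    pedigree = load_kin_pedigree()
    results: dict = {}

    # -- per-locus summary ------------------------------------------------
    summary = summarize_panel(nonkin)
    adj = bonferroni([r.hwe_p for r in summary.per_locus])
    rows = [
        {
            "marker_id": r.marker_id, "n": r.freqs.n_typed,
            "p_v": r.freqs.p_v, "ho": r.ho, "he": r.he, "pic": r.pic,
            "hwe_p": r.hwe_p, "hwe_p_bonferroni": a,
        }
        for r, a in zip(summary.per_locus, adj)
    ]
    regional = {}
    for region in nonkin.regions():
        sub = nonkin.by_region(region)
        s = summarize_panel(sub)
        fis = multilocus_fstat(sub, "f_is", [sub.sample_ids]).estimate
        regional[region] = {"n": sub.n_individuals, "mean_ho": s.mean_ho,
                            "mean_he": s.mean_he, "f_is": fis}
    pd.DataFrame(rows).to_csv(out / "locus_summary.tsv", sep="\t", index=False)
    RunManifest("stats", ["bundled:non_kin"], ["locus_summary.tsv"], None,
                parameters={"he": "unbiased"},
                warnings=list(nonkin.warnings)).write(out)
    results["locus_summary"] = {
        "mean_ho": summary.mean_ho, "mean_he": summary.mean_he,
        "mean_pic": summary.mean_pic, "regional": regional,
    }

    # -- F-statistics ------------------------------------------------------
    fis_single = multilocus_fstat(nonkin, "f_is", [nonkin.sample_ids])
    fis_regional = multilocus_fstat(nonkin, "f_is", "region")
    fst_global = permutation_test(nonkin, "f_st", "region", n_perm=n_perm, seed=seed)
    regions = nonkin.regions()
    frows = [
        {"pop1": "all", "pop2": "(single population)", "statistic": "f_is",
         "estimate": fis_single.estimate, "p": ""},
        {"pop1": "all", "pop2": "(regions as subpopulations)", "statistic": "f_is",
         "estimate": fis_regional.estimate, "p": ""},
        {"pop1": "global", "pop2": "-", "statistic": "f_st",
         "estimate": fst_global.estimate, "p": fst_global.p_value},
    ]
    pairwise = {}
    for r1, r2 in itertools.combinations(regions, 2):
        ids = [s for s in nonkin.sample_ids
               if nonkin.individuals[nonkin.individual_index(s)].region in (r1, r2)]
        sub = nonkin.subset(ids)
        res = permutation_test(sub, "f_st", "region", n_perm=n_perm, seed=seed + 1)
        pairwise[f"{r1}-{r2}"] = {"f_st": res.estimate, "p": res.p_value}
        frows.append({"pop1": r1, "pop2": r2, "statistic": "f_st",
                      "estimate": res.estimate, "p": res.p_value})
    pd.DataFrame(frows).to_csv(out / "fstatistics.tsv", sep="\t", index=False)
    RunManifest("fstats", ["bundled:non_kin"], ["fstatistics.tsv"], seed,
                parameters={"n_perm": n_perm}).write(out)
    results["fstats"] = {
        "fis_single_population": fis_single.estimate,
        "fis_regions": fis_regional.estimate,
        "fst_global": fst_global.estimate,
        "fst_global_p": fst_global.p_value,
        "pairwise": pairwise,
    }

    # -- exclusion probabilities ------------------------------------------
    excl = summarize_exclusion(nonkin)
    erows = [
        {"marker_id": m, "ne_identity": a, "ne_first_parent": b, "ne_parent_pair": c}
        for m, a, b, c in zip(excl.marker_ids, excl.per_locus_ne_identity,
                              excl.per_locus_ne_1p, excl.per_locus_ne_pp)
    ]
    erows.append({"marker_id": "combined", "ne_identity": excl.combined_ne_identity,
                  "ne_first_parent": excl.combined_ne_1p,
                  "ne_parent_pair": excl.combined_ne_pp})
    pd.DataFrame(erows).to_csv(out / "exclusion.tsv", sep="\t", index=False)
    RunManifest("exclusion", ["bundled:non_kin"], ["exclusion.tsv"], None).write(out)
    results["exclusion"] = {
        "combined_ne_identity": excl.combined_ne_identity,
        "combined_ne_first_parent": excl.combined_ne_1p,
        "combined_ne_parent_pair": excl.combined_ne_pp,
    }

    # -- identity matching -------------------------------------------------
    irows = []
    for label, table in (("non_kin", nonkin), ("union", union)):
        for pair in find_identical_pairs(table):
            irows.append({"dataset": label, "id_a": pair.id_a, "id_b": pair.id_b,
                          "n_loci": pair.n_compared_loci})
    pd.DataFrame(irows).to_csv(out / "identity_pairs.tsv", sep="\t", index=False)
    RunManifest("identity", ["bundled:non_kin", "bundled:union"],
                ["identity_pairs.tsv"], None).write(out)
    results["identity"] = {
        "nonkin_matches": [(r["id_a"], r["id_b"]) for r in irows
                           if r["dataset"] == "non_kin"],
        "union_matches": [(r["id_a"], r["id_b"]) for r in irows
                          if r["dataset"] == "union"],
        "union_n_pairs": union.n_individuals * (union.n_individuals - 1) // 2,
    }

    # -- kinship concordance ----------------------------------------------
    comparisons = classify_pairs(kin, pedigree)
    pd.DataFrame(
        [{"id_a": c.id_a, "id_b": c.id_b, "kin_class": c.kin_class,
          "n_compared": c.n_compared_loci, "n_matching": c.n_matching_loci,
          "concordance": c.concordance} for c in comparisons]
    ).to_csv(out / "kinship_pairs.tsv", sep="\t", index=False)
    po = [c.concordance for c in comparisons if c.kin_class == "parent_offspring"]
    nk = [c.concordance for c in comparisons if c.kin_class == "non_kin"]
    sib = _sibling_values(comparisons, kin, sibling_set)
    gp = [c.concordance for c in comparisons
          if c.kin_class == "grandparent_grandchild"]
    thr_emp = thresholds(comparisons, method="empirical_quantile")
    thr_norm = thresholds(comparisons, method="normal_theory")
    rs_po = rank_sum_test(po, nk)
    rs_sib = rank_sum_test(sib, nk)
    hist = concordance_histogram(comparisons, n_loci=kin.n_markers)
    pd.DataFrame(hist).to_csv(out / "kinship_histogram.tsv", sep="\t")
    report = {
        "n_parent_offspring": len(po), "n_non_kin": len(nk),
        "n_full_sibling": len(sib), "sibling_set": sibling_set,
        "thresholds_empirical": asdict(thr_emp),
        "thresholds_normal": asdict(thr_norm),
        "rank_sum_po_vs_nonkin": asdict(rs_po),
        "rank_sum_sib_vs_nonkin": asdict(rs_sib),
        "grandparent_concordances": sorted(gp),
        "grandparent_mean": float(np.mean(gp)) if gp else None,
        "grandparent_sd": float(np.std(gp, ddof=1)) if len(gp) > 1 else None,
    }
    (out / "kinship_report.json").write_text(json.dumps(report, indent=2) + "\n")
    RunManifest("kinship", ["bundled:kin", "bundled:pedigree"],
                ["kinship_pairs.tsv", "kinship_report.json", "kinship_histogram.tsv"],
                None, parameters={"sibling_set": sibling_set},
                warnings=list(kin.warnings)).write(out)
    results["kinship"] = report

    # -- PCA ---------------------------------------------------------------
    pca = run_pca(encode_dosage(nonkin))
    scores = pd.DataFrame(
        pca.scores[:, :4], columns=[f"PC{k}" for k in range(1, 5)]
    )
    scores.insert(0, "sample_id", nonkin.sample_ids)
    scores.insert(1, "region", [ind.region for ind in nonkin.individuals])
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    RunManifest("pca", ["bundled:non_kin"], ["pca_scores.tsv"], None,
                parameters={"center": True, "scale": False}).write(out)
    results["pca"] = {
        "contribution_ratios": pca.contribution_ratios[:4].tolist(),
    }
    return results
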