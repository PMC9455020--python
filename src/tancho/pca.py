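"""Principal component analysis of genotype dosages.

Genotypes are encoded as variant-allele counts (WW=0, WV=1, VV=2); missing
calls can be mean-imputed per locus.  The decomposition is a column-centered
(optionally unit-scaled) SVD; the contribution ratio of component i is its
eigenvalue share lambda_i / sum lambda.  Component signs are fixed so the
largest-magnitude loading of each component is positive, making score
tables reproducible run-to-run.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .model import GenotypeTable

__all__ = ["PcaResult", "encode_dosage", "run_pca"]


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray                 # individuals x components
    loadings: np.ndarray               # retained loci x components
    contribution_ratios: np.ndarray    # fractions summing to 1
    retained_columns: tuple[int, ...]  # indices of non-constant input columns
    encoding: str = "dosage"
    centered: bool = True
    scaled: bool = False


def encode_dosage(table: GenotypeTable, impute: str = "mean") -> np.ndarray:
    """Individuals x loci matrix of variant-allele dosages.

    ``impute="mean"`` replaces missing calls by the locus mean dosage;
    ``impute="error"`` refuses missing data.  A locus with no typed calls is
    always an error.
    """
    m = table.calls.astype(float)
    missing = m < 0
    if missing.any():
        if impute == "error":
            raise ValueError("missing calls present and impute='error'")
        if impute != "mean":
            raise ValueError(f"unknown imputation policy {impute!r}")
        for j in range(m.shape[1]):
            col = m[:, j]
            typed = col[~missing[:, j]]
            if typed.size == 0:
                raise ValueError(
                    f"locus {table.panel[j].marker_id} has no typed calls"
                )
            col[missing[:, j]] = typed.mean()
    return m


def run_pca(matrix: np.ndarray, center: bool = True, scale: bool = False) -> PcaResult:
    """Column-centered SVD of a numeric matrix with deterministic signs.

    Constant columns are dropped with a warning (they carry no variance and
    would break unit scaling).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    sd = x.std(axis=0, ddof=1)
    keep = np.where(sd > 0)[0]
    if keep.size < x.shape[1]:
        dropped = sorted(set(range(x.shape[1])) - set(keep.tolist()))
        _warnings.warn(f"dropping constant column(s) {dropped} before PCA")
    if keep.size == 0:
        raise ValueError("fewer than 2 distinct rows (all columns constant)")
    x = x[:, keep]
    if center:
        x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2
    if eig.sum() == 0:
        raise ValueError("fewer than 2 distinct rows")
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return PcaResult(
        scores=u * s,
        loadings=vt.T,
        contribution_ratios=eig / eig.sum(),
        retained_columns=tuple(int(j) for j in keep),
        centered=center,
        scaled=scale,
    )
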