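"""Genotype standardization and principal components analysis.

The standardization follows the smartpca convention: with c_il the
reference-allele count of individual i at locus l and p_l the allele
frequency estimated from non-missing genotypes, non-missing entries become

    y_il = (c_il - 2 p_l) / sqrt(2 p_l (1 - p_l)),

monomorphic columns (p in {0, 1}) are set wholly to zero, and missing
entries are set to zero.  PCA eigendecomposes the n x n matrix Y Y^T; the
k-th PC coordinates are sqrt(lambda_k) * u_k, so each PC's variance reflects
its share of the total (the convention in which PC axes are *not* rescaled
to equal variance).  Y has rank at most n-1 because every standardized
column sums to zero, hence n-1 components are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype import GenotypeMatrix

__all__ = ["StandardizedMatrix", "PCAResult", "standardize", "run_pca"]


@dataclass
class StandardizedMatrix:
    """Standardized genotype matrix Y with allele-frequency bookkeeping."""

    values: np.ndarray            # (n, L) float
    allele_freqs: np.ndarray      # (L,) estimated reference-allele frequencies
    monomorphic_mask: np.ndarray  # (L,) bool; True where the column was zeroed
    individual_ids: list[str]
    populations: list[str]


@dataclass
class PCAResult:
    """Eigenvalue-scaled PC scores with variance-explained accounting."""

    scores: np.ndarray             # (n, n-1); column k is sqrt(lambda_k) * u_k
    eigenvalues: np.ndarray        # (n-1,), non-increasing
    variance_explained: np.ndarray  # eigenvalues / sum(eigenvalues)
    individual_ids: list[str]

    @property
    def pc12(self) -> np.ndarray:
        """The first two PC coordinates, the map used for Procrustes fits."""
        return self.scores[:, :2]


def standardize(G: GenotypeMatrix) -> StandardizedMatrix:
    """Standardize reference-allele counts column by column.

    Allele frequency at each locus is the plain mean of non-missing
    genotypes divided by 2.  Loci with no observed genotypes are treated as
    monomorphic (zero column).
    """
    values = G.values.astype(np.float64)
    miss = G.missing
    obs = ~miss
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(miss, 0, values).sum(axis=0) / (2 * np.maximum(n_obs, 1)), 0.0)
    mono = (p <= 0.0) | (p >= 1.0)
    denom = np.sqrt(2 * p * (1 - p))
    denom[mono] = 1.0  # placeholder; columns zeroed below
    Y = (values - 2 * p) / denom
    Y[miss] = 0.0
    Y[:, mono] = 0.0
    return StandardizedMatrix(
        values=Y,
        allele_freqs=p,
        monomorphic_mask=mono,
        individual_ids=list(G.individual_ids),
        populations=list(G.populations),
    )


def run_pca(S: StandardizedMatrix) -> PCAResult:
    """Eigendecompose Y Y^T and return sqrt(lambda)-scaled PC scores.

    Exactly n-1 components are kept (the standardized matrix has rank at
    most n-1).  Eigenvalues more negative than -1e-8 * lambda_1 raise; tiny
    negative values from round-off are clipped to zero.
    """
    Y = S.values
    n = Y.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 individuals")
    M = Y @ Y.T
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order][: n - 1]
    eigvecs = eigvecs[:, order][:, : n - 1]
    lam1 = max(eigvals[0], 0.0)
    if (eigvals < -1e-8 * max(lam1, 1.0)).any():
        raise ValueError("eigendecomposition produced a significantly negative eigenvalue")
    eigvals = np.clip(eigvals, 0.0, None)
    scores = eigvecs * np.sqrt(eigvals)
    total = eigvals.sum()
    if total == 0:
        raise ValueError("standardized matrix is identically zero")
    return PCAResult(
        scores=scores,
        eigenvalues=eigvals,
        variance_explained=eigvals / total,
        individual_ids=list(S.individual_ids),
    )
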