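"""Population-structure covariates: genotype PCA and soft cluster memberships.

The dosage matrix is mean-imputed, centered by twice the estimated allele
frequency and scaled by ``sqrt(2 p (1-p))`` (Patterson-style) before the
eigendecomposition; a flag switches to empirical unit-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from geascan.genotype_io import MISSING, GenotypeMatrix


class StructureError(ValueError):
    pass


@dataclass
class PopStructure:
    """PCA scores plus optional cluster memberships.

    ``scores``: samples x k; ``varexp``: fraction of total variance per kept
    component (non-increasing, sums to <= 1); ``memberships``: samples x K
    rows summing to 1; ``centroids``: K x k in score space.
    """

    samples: list
    scores: np.ndarray
    varexp: np.ndarray
    memberships: np.ndarray | None = None
    centroids: np.ndarray | None = None


def _standardize(g: GenotypeMatrix, scaling: str = "patterson"):
    x = g.calls.astype(float)
    x[g.calls == MISSING] = np.nan
    p = np.nanmean(x, axis=0) / 2.0
    # monomorphic columns carry no information and break the scaling
    keep = (p > 0) & (p < 1)
    x = x[:, keep]
    p = p[keep]
    col_mean = 2.0 * p
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= col_mean
    if scaling == "patterson":
        x /= np.sqrt(2.0 * p * (1.0 - p))
    elif scaling == "unit":
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x /= sd
    else:
        raise StructureError(f"unknown scaling {scaling!r}")
    return x


def pca_structure(g: GenotypeMatrix, n_components: int,
                  scaling: str = "patterson") -> PopStructure:
    """Project samples on the top principal components of the standardized
    dosage matrix.

    ``varexp`` is each eigenvalue over the sum of all eigenvalues of the
    sample covariance.  ``n_components`` above ``min(n-1, n_snps)`` is fatal.
    """
    max_k = min(g.n_samples - 1, g.n_snps)
    if n_components < 1 or n_components > max_k:
        raise StructureError(
            f"n_components must be in [1, {max_k}] for {g.n_samples} samples "
            f"x {g.n_snps} SNPs"
        )
    x = _standardize(g, scaling)
    x = x - x.mean(axis=0)  # eigenvectors of the sample covariance
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (g.n_samples - 1)
    total = eigvals.sum()
    scores = u[:, :n_components] * s[:n_components]
    varexp = eigvals[:n_components] / total if total > 0 else np.zeros(n_components)
    return PopStructure(samples=list(g.samples), scores=scores, varexp=varexp)


def cluster_memberships(ps: PopStructure, K: int, seed: int) -> PopStructure:
    """k-means on the PCA scores (10 restarts, fixed seed) plus
    inverse-squared-distance membership coefficients.

    ``m_ik = (1/d_ik^2) / sum_j (1/d_ij^2)``; a sample coincident with a
    centroid gets membership 1 for it.
    """
    from sklearn.cluster import KMeans

    n = ps.scores.shape[0]
    if K < 2:
        raise StructureError("K must be >= 2")
    if K > n:
        raise StructureError(f"K={K} exceeds sample count {n}")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(ps.scores)
    centroids = km.cluster_centers_
    memberships = membership_coefficients(ps.scores, centroids)
    return PopStructure(
        samples=list(ps.samples),
        scores=ps.scores,
        varexp=ps.varexp,
        memberships=memberships,
        centroids=centroids,
    )


def membership_coefficients(scores: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Inverse-squared-Euclidean-distance soft assignments to centroids."""
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    memberships = np.zeros_like(d2)
    zero = d2 <= 0
    has_zero = zero.any(axis=1)
    if has_zero.any():
        rows = np.where(has_zero)[0]
        memberships[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    inv = 1.0 / d2[~has_zero]
    memberships[~has_zero] = inv / inv.sum(axis=1, keepdims=True)
    return memberships
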