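"""Variant filtering, PCA, kinship and subpopulation assignment.

These are the shared substrate of every downstream stage: association
models take the principal components as fixed covariates and the kinship
matrix as the covariance of the random polygenic effect, and the
bulked-segregant screen draws its "typical" subpopulation members from the
PC1 axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


class DegenerateInputError(ValueError):
    """No usable variance left in the genotype matrix."""


@dataclass
class StructureResult:
    """Principal components, kinship and subpopulation labels of a panel."""

    accessions: list[str]
    pcs: np.ndarray  # (n_accessions, k) PC scores
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # fraction per reported PC
    kinship: np.ndarray | None = None
    labels: np.ndarray | None = None
    typical: np.ndarray | None = None


def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.5
) -> GenotypeMatrix:
    """Keep SNPs with MAF > ``maf_min`` and missing fraction < ``missing_max``.

    MAF is computed from non-missing calls.  An empty survivor set is
    returned (with a warning), not raised.
    """
    import warnings

    maf = gm.maf()
    miss = gm.missing_fraction()
    with np.errstate(invalid="ignore"):
        keep = (maf > maf_min) & (miss < missing_max)
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("no SNPs survive the MAF/missingness filter", stacklevel=2)
    return gm.subset(snp_idx=keep)


def _imputed_standardized(gm: GenotypeMatrix, scale: bool):
    """Mean-imputed dosage matrix, centered at 2p (and optionally scaled)."""
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    d = np.where(np.isnan(d), 2.0 * p, d)
    z = d - 2.0 * p
    var = 2.0 * p * (1.0 - p)
    poly = var > 0
    z = z[:, poly]
    var = var[poly]
    if not z.size:
        raise DegenerateInputError("all SNPs are monomorphic after imputation")
    if scale:
        z = z / np.sqrt(var)
    return z, var


def compute_pca(gm: GenotypeMatrix, k: int = 3) -> StructureResult:
    """PC scores from standardized dosages.

    Missing calls are mean-imputed; columns are centered and scaled by
    sqrt(2p(1-p)).  Signs follow a fixed convention (the largest-magnitude
    loading of each component is positive) so results are reproducible
    across runs and LAPACK builds.
    """
    if gm.n_accessions < k + 1:
        raise DegenerateInputError(f"need at least {k + 1} accessions for {k} PCs")
    z, _ = _imputed_standardized(gm, scale=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    total = np.sum(s**2)
    k = min(k, len(s))
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    return StructureResult(
        accessions=list(gm.accessions),
        pcs=scores,
        eigenvalues=(s[:k] ** 2) / max(gm.n_accessions - 1, 1),
        variance_explained=(s[:k] ** 2) / total,
    )


def compute_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """Centered cross-product (VanRaden) kinship: K = ZZ' / sum 2p(1-p).

    Missing calls are mean-imputed.  Under full homozygosity (dosage 0/2)
    the diagonal averages about 2, i.e. 1 + f with inbreeding f = 1.
    """
    z, var = _imputed_standardized(gm, scale=False)
    return (z @ z.T) / np.sum(var)


def assign_subpopulations(
    structure: StructureResult,
    mode: str = "quantile",
    cutoffs: tuple[float, float] | None = None,
    quantiles: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
) -> StructureResult:
    """Two-way subpopulation labels plus "typical" membership flags from PC1.

    Modes
    -----
    ``threshold``
        User-supplied PC1 cutoffs ``(lower, upper)``: typical-pop1 below the
        lower cutoff, typical-pop2 above the upper, intermediate accessions
        flagged atypical.  Matches panels where the raw PC1 scale is known.
    ``quantile``
        Scale-free version with cutoffs at the stated PC1 quantiles.
    ``kmeans2``
        Seeded 2-means on PC1; every accession is typical of its cluster.
    """
    pc1 = structure.pcs[:, 0]
    if mode == "threshold":
        if cutoffs is None:
            raise ValueError("threshold mode requires cutoffs=(lower, upper)")
        lower, upper = cutoffs
        if lower >= upper:
            raise ValueError(f"lower cutoff {lower} must be below upper {upper}")
    elif mode == "quantile":
        q1, q2 = quantiles
        if q1 >= q2:
            raise ValueError("quantiles must be increasing")
        lower, upper = np.quantile(pc1, q1), np.quantile(pc1, q2)
    elif mode == "kmeans2":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pc1.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        remap = {int(order[0]): "pop1", int(order[1]): "pop2"}
        labels = np.array([remap[int(c)] for c in km.labels_], dtype=object)
        structure.labels = labels
        structure.typical = np.ones(len(labels), dtype=bool)
        return structure
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mid = 0.5 * (lower + upper)
    structure.labels = np.where(pc1 <= mid, "pop1", "pop2").astype(object)
    structure.typical = (pc1 < lower) | (pc1 > upper)
    return structure
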