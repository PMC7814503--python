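"""Population structure (PCA, kinship), linkage disequilibrium and LD decay,
and neighbor-joining clustering on identity-by-state distances.

PCA runs on centered, unscaled alt-allele dosages with per-SNP mean
imputation of missing calls.  LD is the squared Pearson correlation r^2 of
dosage vectors over accessions non-missing at both SNPs.  The LD-decay
distance is where a locally weighted (LOESS) fit of r^2 on physical
distance first falls to the 99th percentile of r^2 among unlinked
(inter-chromosomal) marker pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import GenotypeMatrix

#: Sentinel returned when the smoothed LD curve never reaches the threshold.
NO_DECAY = None


@dataclass
class StructureModel:
    """PCA scores and (optionally) a genomic kinship matrix."""

    pc_scores: np.ndarray  # (n_accessions, n_pcs)
    variance_explained: np.ndarray  # fraction per PC, non-increasing
    kinship: np.ndarray | None = None


@dataclass
class LDProfile:
    """Pairwise r^2 against distance plus its smoothed decay curve."""

    distances: np.ndarray
    r2: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    unlinked_threshold: float
    decay_distance: float | None


def _imputed_centered(gm: GenotypeMatrix) -> np.ndarray:
    """Dosages with per-SNP mean imputation, centered per SNP; shape (m, n)."""
    d = gm.dosage_float()
    mu = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mu, d)
    return d - mu


def pca(gm: GenotypeMatrix, n_pcs: int = 3) -> StructureModel:
    """Principal components of the centered (unscaled) genotype matrix.

    Missing calls are mean-imputed per SNP before centering, the common
    GWAS practice.  Raises on a constant matrix (no variance to decompose).
    """
    if gm.n_accessions < 2 or gm.n_snps < 2:
        raise ValueError("PCA needs at least 2 accessions and 2 SNPs")
    X = _imputed_centered(gm).T  # accessions x SNPs
    if not np.any(X):
        raise ValueError("constant genotype matrix: no variance for PCA")
    n_pcs = min(n_pcs, gm.n_accessions - 1, gm.n_snps)
    model = PCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(X)
    return StructureModel(
        pc_scores=scores, variance_explained=model.explained_variance_ratio_
    )


def kinship(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Missing calls are imputed with twice the alt-allele frequency; the
    centered cross-product is scaled by 2*sum p(1-p) over polymorphic SNPs,
    so the diagonal averages about 1 on an unstructured panel.
    """
    if gm.n_accessions < 2 or gm.n_snps < 2:
        raise ValueError("kinship needs at least 2 accessions and 2 SNPs")
    d = gm.dosage_float()
    p = np.nanmean(d, axis=1) / 2.0
    if np.all((p == 0) | (p == 1) | np.isnan(p)):
        raise ValueError("all SNPs monomorphic: kinship undefined")
    Z = np.where(np.isnan(d), 0.0, d - 2.0 * p[:, None])
    Z[np.isnan(p)] = 0.0
    denom = 2.0 * np.nansum(p * (1.0 - p))
    return (Z.T @ Z) / denom


def ibs_distance(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """1 - proportion of alleles shared, pairwise-complete over accessions.

    Allele sharing between dosages a and b is ``1 - |a - b| / 2`` (1 for
    identical genotypes, 0.5 when one allele differs, 0 for opposite
    homozygotes).  Pairs of calls with either member missing are ignored.
    """
    d = gm.dosage_float()
    V = (~np.isnan(d)).astype(float)
    I = [((d == c) & ~np.isnan(d)).astype(float) for c in (0.0, 1.0, 2.0)]
    S = (
        I[0].T @ I[0]
        + I[1].T @ I[1]
        + I[2].T @ I[2]
        + 0.5 * (I[0].T @ I[1] + I[1].T @ I[0] + I[1].T @ I[2] + I[2].T @ I[1])
    )
    N = V.T @ V
    with np.errstate(invalid="ignore"):
        D = 1.0 - S / N
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        raise ValueError("accession pair with no shared non-missing calls")
    return D, list(gm.accessions)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _pairwise_r2_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs r^2 with pairwise-complete observations; NaN where a member
    of the pair is monomorphic on the shared accessions."""
    V = (~np.isnan(X)).astype(float)
    Xz = np.nan_to_num(X)
    X2 = Xz * Xz
    N = V @ V.T
    Sx = Xz @ V.T  # sum of x_i over samples where both i and j observed
    Sxx = X2 @ V.T
    Sxy = Xz @ Xz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        varx = N * Sxx - Sx * Sx
        denom = varx * varx.T
        r2 = np.where(denom > 0, (cov * cov) / denom, np.nan)
    return r2


def ld_r2(
    gm: GenotypeMatrix, chrom: str, max_dist: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Within-chromosome pairwise (distance, r^2) for placed SNPs.

    Pairs involving a SNP that is monomorphic on the shared accessions are
    skipped (their correlation is undefined).
    """
    idx = [
        i for i, s in enumerate(gm.snps) if s.chrom == chrom and s.placed
    ]
    if len(idx) < 2:
        raise ValueError(f"need >= 2 placed SNPs on chromosome {chrom!r}")
    sub = gm.take_snps(np.asarray(idx))
    X = sub.dosage_float()
    pos = np.asarray([s.pos for s in sub.snps], dtype=np.int64)
    r2 = _pairwise_r2_matrix(X)
    iu, ju = np.triu_indices(len(idx), k=1)
    dist = np.abs(pos[iu] - pos[ju])
    vals = r2[iu, ju]
    keep = ~np.isnan(vals)
    if max_dist is not None:
        keep &= dist <= max_dist
    return dist[keep], vals[keep]


def unlinked_r2(
    gm: GenotypeMatrix, n_pairs: int = 50_000, seed: int = 0
) -> np.ndarray:
    """r^2 for a random sample of inter-chromosomal ("unlinked") SNP pairs."""
    chroms = np.asarray([s.chrom for s in gm.snps])
    rng = np.random.default_rng(seed)
    X = gm.dosage_float()
    m = gm.n_snps
    out = np.empty(0)
    # rejection-sample index pairs on different chromosomes
    while out.size < n_pairs:
        need = n_pairs - out.size
        i = rng.integers(0, m, size=2 * need + 16)
        j = rng.integers(0, m, size=2 * need + 16)
        ok = chroms[i] != chroms[j]
        i, j = i[ok][:need], j[ok][:need]
        if i.size == 0:
            raise ValueError("genotype matrix has a single chromosome")
        A, B = X[i], X[j]
        both = ~np.isnan(A) & ~np.isnan(B)
        A = np.where(both, A, np.nan)
        B = np.where(both, B, np.nan)
        n = both.sum(axis=1)
        sa, sb = np.nansum(A, 1), np.nansum(B, 1)
        saa, sbb = np.nansum(A * A, 1), np.nansum(B * B, 1)
        sab = np.nansum(A * B, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sab - sa * sb
            denom = (n * saa - sa * sa) * (n * sbb - sb * sb)
            r2 = np.where(denom > 0, cov * cov / denom, np.nan)
        out = np.concatenate([out, r2[~np.isnan(r2)]])
    return out[:n_pairs]


def ld_decay(
    distances: np.ndarray,
    r2: np.ndarray,
    unlinked: np.ndarray,
    span: float = 0.3,
    grid_points: int = 512,
) -> LDProfile:
    """Smooth r^2 against distance and find where it meets the unlinked
    background.

    Fits a locally weighted regression (tricube weights, degree 1, span as
    a fraction of pairs) of r^2 on distance, evaluates it on a uniform
    grid, and reports the smallest grid distance at which the fitted curve
    first falls to or below the 99th percentile of r^2 among unlinked
    pairs.  ``decay_distance`` is the :data:`NO_DECAY` sentinel if the
    curve never reaches the threshold within the observed range.
    """
    distances = np.asarray(distances, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    unlinked = np.asarray(unlinked, dtype=float)
    if distances.size < 100 or unlinked.size < 100:
        raise ValueError("need >= 100 within-chromosome and >= 100 unlinked pairs")
    threshold = float(np.percentile(unlinked, 99))
    sm = lowess(r2, distances, frac=span, return_sorted=True)
    grid = np.linspace(distances.min(), distances.max(), grid_points)
    fitted = np.interp(grid, sm[:, 0], sm[:, 1])
    below = np.flatnonzero(fitted <= threshold)
    decay = float(grid[below[0]]) if below.size else NO_DECAY
    return LDProfile(
        distances=distances,
        r2=r2,
        grid=grid,
        fitted=fitted,
        unlinked_threshold=threshold,
        decay_distance=decay,
    )


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(distance_matrix: np.ndarray, labels: list[str]):
    """Saitou-Nei neighbor-joining on a symmetric distance matrix.

    Returns an unrooted scikit-bio ``TreeNode``.  Negative branch lengths
    produced by the algorithm are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(distance_matrix, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape[0] != D.shape[1] or D.shape[0] < 3:
        raise ValueError("need a square matrix with n >= 3 taxa")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("matrix must be symmetric, zero-diagonal, non-negative")
    return nj(DistanceMatrix(D, ids=labels), neg_as_zero=True)
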