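"""Per-environment single-marker association scans with structure correction.

Two models are available per scan:

``lm``
    Ordinary least squares of the phenotype on [intercept, PCs, dosage]
    with a two-sided t-test on the dosage coefficient.

``mlm``
    A kinship mixed model in the P3D/EMMAX style: the variance ratio
    lambda = sigma2_g / sigma2_e is estimated once by REML on the null
    model (covariates only), and every marker is then tested by
    generalized least squares under that fixed covariance.  This is the
    standard fast approximation to per-marker REML used by TASSEL-class
    mixed-model software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeMatrix, PhenotypeTable
from .structure_ld import kinship as marker_kinship
from .structure_ld import pca as structure_pca

#: Lower floor applied to p-values so downstream logs stay finite.
P_FLOOR = 1e-300

_SCAN_COLUMNS = ["snp_id", "chrom", "pos", "beta", "se", "stat", "p", "n_used"]


@dataclass
class AssociationScan:
    """Single-environment scan results.

    ``results`` has one row per tested SNP (columns: snp_id, chrom, pos,
    beta, se, stat, p, n_used); ``skipped`` maps snp_id -> reason for SNPs
    that could not be tested (monomorphic after drops, too few samples).
    """

    environment: str
    results: pd.DataFrame
    model: str
    skipped: dict[str, str]

    def pvalues(self) -> pd.Series:
        return self.results.set_index("snp_id")["p"]


@dataclass
class NullModelFit:
    """REML fit of the covariates-only mixed model, with the kinship
    eigen-decomposition retained so every marker test can reuse it."""

    lambda_: float
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray


def _reml_loglik(log_lambda, s, y_rot, X_rot, n, p):
    lam = np.exp(log_lambda)
    w = lam * s + 1.0
    Xw = X_rot / w[:, None]
    XtWX = X_rot.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y_rot)
    resid = y_rot - X_rot @ beta
    rss = float(resid @ (resid / w))
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return -np.inf
    df = n - p
    return -0.5 * (
        df * np.log(2 * np.pi * rss / df)
        + df
        + np.sum(np.log(w))
        + logdet_XtWX
    )


def fit_null_mlm(
    y: np.ndarray, covariates: np.ndarray, K: np.ndarray
) -> NullModelFit:
    """REML estimate of the variance ratio lambda on the kinship eigenbasis.

    One-dimensional optimization over log lambda (EMMA-style), deterministic
    given the inputs.  lambda is clamped to [1e-6, 1e6]; hitting either
    boundary raises a warning via the returned value only (no exception).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError(
            "kinship is not positive semi-definite; add a small diagonal jitter"
        )
    s = np.clip(s, 0.0, None)
    y_rot = U.T @ y
    X_rot = U.T @ X
    p = X.shape[1]

    lo, hi = np.log(1e-6), np.log(1e6)
    grid = np.linspace(lo, hi, 61)
    vals = np.array([_reml_loglik(g, s, y_rot, X_rot, n, p) for g in grid])
    best = int(np.argmax(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, s, y_rot, X_rot, n, p),
        bounds=(a, b),
        method="bounded",
    )
    lam = float(np.clip(np.exp(res.x), 1e-6, 1e6))
    ll = _reml_loglik(np.log(lam), s, y_rot, X_rot, n, p)
    return NullModelFit(lambda_=lam, loglik=float(ll), eigvals=s, eigvecs=U)


def _marker_tests(G: np.ndarray, y: np.ndarray, X0: np.ndarray):
    """Vectorized per-marker t-tests of y on [X0, g] for complete-data G.

    Residualizes y and every dosage row on X0, then tests the marker
    coefficient; algebraically identical to the full OLS fit by the
    Frisch-Waugh-Lovell theorem.
    """
    n, p0 = X0.shape
    Q, _ = np.linalg.qr(X0)
    yr = y - Q @ (Q.T @ y)
    Gr = G - (G @ Q) @ Q.T
    gss = np.einsum("ij,ij->i", Gr, Gr)
    gy = Gr @ yr
    yss = float(yr @ yr)
    df = n - p0 - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gss
        rss = yss - beta * gy
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / df / gss)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, P_FLOOR, 1.0)
    return beta, se, tstat, p, df


def scan_environment(
    gm: GenotypeMatrix,
    y: pd.Series,
    pcs: np.ndarray | None,
    model: str = "lm",
    null_fit: NullModelFit | None = None,
    K: np.ndarray | None = None,
    environment: str = "",
) -> AssociationScan:
    """Scan every SNP for association with one environment's phenotype.

    ``y`` is indexed by accession id; accessions with missing phenotype are
    dropped, and ``pcs`` rows must align with ``gm.accessions``.  For the
    lm model, per-SNP missing genotypes are dropped pairwise.  For the mlm
    model, missing dosages are mean-imputed so the one-time kinship
    rotation stays valid for every marker.
    """
    if model not in ("lm", "mlm"):
        raise ValueError(f"unknown model {model!r}")
    y = y.dropna()
    used = [a for a in gm.accessions if a in y.index]
    if len(used) == 0:
        raise ValueError("no accessions shared between genotypes and phenotype")
    acc_idx = np.asarray([gm.accessions.index(a) for a in used])
    yv = y.loc[used].to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("phenotype is constant")

    if pcs is not None:
        X0 = np.column_stack([np.ones(len(used)), np.asarray(pcs)[acc_idx]])
    else:
        X0 = np.ones((len(used), 1))
    G = gm.dosage_float()[:, acc_idx]

    if model == "mlm":
        if null_fit is None:
            if K is None:
                raise ValueError("mlm requires a kinship matrix or a null fit")
            null_fit = fit_null_mlm(yv, X0, K[np.ix_(acc_idx, acc_idx)])
        w = null_fit.lambda_ * null_fit.eigvals + 1.0
        A = null_fit.eigvecs.T / np.sqrt(w)[:, None]
        mu = np.nanmean(G, axis=1)
        G = np.where(np.isnan(G), mu[:, None], G)
        yv = A @ yv
        X0 = A @ X0
        G = G @ A.T

    n, p0 = X0.shape
    skipped: dict[str, str] = {}
    rows = np.arange(gm.n_snps)
    complete = ~np.isnan(G).any(axis=1)
    poly = np.nanstd(G, axis=1) > 0

    beta = np.full(gm.n_snps, np.nan)
    se = np.full(gm.n_snps, np.nan)
    stat = np.full(gm.n_snps, np.nan)
    pval = np.full(gm.n_snps, np.nan)
    n_used = np.full(gm.n_snps, n)

    do_vec = complete & poly
    if do_vec.any():
        b, s_, t_, p_, _ = _marker_tests(G[do_vec], yv, X0)
        beta[do_vec], se[do_vec], stat[do_vec], pval[do_vec] = b, s_, t_, p_

    for i in rows[~do_vec]:
        g = G[i]
        ok = ~np.isnan(g)
        n_i = int(ok.sum())
        n_used[i] = n_i
        if n_i < p0 + 2:
            skipped[gm.snps[i].snp_id] = f"too few samples (n={n_i})"
            continue
        gi = g[ok]
        if np.ptp(gi) == 0:
            skipped[gm.snps[i].snp_id] = "monomorphic after missing-data drop"
            continue
        b, s_, t_, p_, _ = _marker_tests(gi[None, :], yv[ok], X0[ok])
        beta[i], se[i], stat[i], pval[i] = b[0], s_[0], t_[0], p_[0]

    mono = complete & ~poly
    for i in rows[mono]:
        skipped[gm.snps[i].snp_id] = "monomorphic"

    tested = ~np.isnan(pval)
    results = pd.DataFrame(
        {
            "snp_id": np.asarray(gm.snp_ids())[tested],
            "chrom": [s.chrom for s, t in zip(gm.snps, tested) if t],
            "pos": [s.pos for s, t in zip(gm.snps, tested) if t],
            "beta": beta[tested],
            "se": se[tested],
            "stat": stat[tested],
            "p": pval[tested],
            "n_used": n_used[tested],
        }
    )
    return AssociationScan(
        environment=environment, results=results, model=model, skipped=skipped
    )


def scan_all(
    gm: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    model: str = "mlm",
    n_pcs: int = 3,
    min_n: int = 30,
    use_kinship: bool = True,
) -> tuple[list[AssociationScan], dict[str, str]]:
    """One structure-corrected scan per usable environment.

    Environments with fewer than ``min_n`` non-missing phenotypes or with
    no phenotypic variance are excluded and reported, mirroring the
    field-trial practice of analysing only sites with differential
    survival.  PCs (default 3) and the marker kinship are computed once on
    the full panel.
    """
    pcs = structure_pca(gm, n_pcs=n_pcs).pc_scores if n_pcs > 0 else None
    K = marker_kinship(gm) if (model == "mlm" and use_kinship) else None
    if model == "mlm" and not use_kinship:
        K = np.eye(gm.n_accessions)

    scans: list[AssociationScan] = []
    excluded: dict[str, str] = {}
    for env in phenotypes.environments:
        y = phenotypes.data[f"ws_{env}"].dropna()
        if len(y) < min_n:
            excluded[env] = f"only {len(y)} non-missing phenotypes (< {min_n})"
            continue
        if np.ptp(y.to_numpy(dtype=float)) == 0:
            excluded[env] = "no phenotypic variance"
            continue
        scans.append(
            scan_environment(
                gm, y, pcs, model=model, K=K, environment=env
            )
        )
    if not scans:
        raise ValueError("no usable environments")
    return scans, excluded
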