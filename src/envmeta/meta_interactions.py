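"""Fisher combined-probability meta-analysis across environments with
Benjamini-Hochberg FDR control, and the two-locus likelihood-ratio
interaction test.

Fisher's method pools k independent per-environment p-values for a marker
into ``X2 = -2 * sum(ln p_i)``, referred to a chi-square distribution with
2k degrees of freedom; a marker only needs a modest signal in several
environments to reach combined significance, which is how loci invisible
in every single-environment scan surface in the meta-analysis.

The interaction test compares, by a likelihood ratio, a Gaussian model
with both markers, their product term, and structure covariates (PCs)
against the PCs-only model; the statistic is referred to chi-square with
3 degrees of freedom (the two marginal terms plus one additive-by-additive
interaction term).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import P_FLOOR, AssociationScan
from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FdrVerdict:
    """Outcome of a Benjamini-Hochberg step-up pass at level q."""

    q: float
    n_rejected: int
    critical_p: float | None  # largest rejected p; None when nothing rejected

    @property
    def threshold_minus_log10(self) -> float | None:
        if self.critical_p is None:
            return None
        return -np.log10(self.critical_p)


@dataclass
class InteractionTest:
    marker1: str
    marker2: str
    trait: str
    lrt: float
    df: int
    p: float


def fisher_combine(p_list) -> tuple[float, float]:
    """Fisher's combined probability: ``X2 = -2 sum ln p_i`` against
    chi-square with 2k degrees of freedom.

    With a single study the combined p equals the input p.  Inputs must be
    in (0, 1]; values below 1e-300 are clamped there before the log.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]; floor zeros before calling")
    p = np.clip(p, 1e-300, 1.0)
    x2 = float(-2.0 * np.log(p).sum())
    p_fisher = float(stats.chi2.sf(x2, df=2 * p.size))
    return x2, max(p_fisher, P_FLOOR)


def fisher_sf_even_df(x2: float, k: int) -> float:
    """Closed-form chi-square survival function for even df = 2k:
    ``exp(-x/2) * sum_{j<k} (x/2)^j / j!``.  An independent cross-check of
    :func:`fisher_combine`'s tail probability."""
    h = x2 / 2.0
    term = 1.0
    total = 1.0
    for j in range(1, k):
        term *= h / j
        total += term
    return float(np.exp(-h) * total)


def bh_fdr(p_vector, q: float) -> FdrVerdict:
    """Benjamini-Hochberg step-up at level q.

    Rejects every p at or below the largest p_(i) with
    ``p_(i) <= i * q / m``; ties are rejected together.  An empty vector
    yields zero rejections with an undefined critical p.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        return FdrVerdict(q=q, n_rejected=0, critical_p=None)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    order = np.sort(p)
    m = p.size
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(order <= thresh)
    if passing.size == 0:
        return FdrVerdict(q=q, n_rejected=0, critical_p=None)
    crit = order[passing[-1]]
    return FdrVerdict(q=q, n_rejected=int(np.sum(p <= crit)), critical_p=float(crit))


def fisher_combine_matrix(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Fisher combination of an (m, k) p-value matrix with NaN for
    missing entries; returns (X2, p_fisher) arrays.  Vectorized counterpart
    of :func:`fisher_combine` (which remains the scalar reference)."""
    P = np.asarray(P, dtype=float)
    valid = ~np.isnan(P)
    if np.any((P <= 0) | (P > 1), where=valid):
        raise ValueError("p-values must be in (0, 1]")
    k = valid.sum(axis=1)
    if np.any(k == 0):
        raise ValueError("every row must contribute at least one p-value")
    logs = np.where(valid, np.log(np.clip(P, 1e-300, 1.0)), 0.0)
    x2 = -2.0 * logs.sum(axis=1)
    pf = stats.chi2.sf(x2, df=2 * k)
    return x2, np.clip(pf, P_FLOOR, 1.0)


def bh_adjusted(p_vector) -> np.ndarray:
    """BH-adjusted p-values (the conservative, estimator-free reading of a
    per-marker q-value)."""
    p = np.asarray(p_vector, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def meta_scan(
    scans: list[AssociationScan], q: float = 0.01
) -> tuple[pd.DataFrame, FdrVerdict]:
    """Combine per-environment scans marker by marker with Fisher's method,
    then control the FDR over all scored markers at level q.

    Markers missing from some environments are combined over the
    environments where they were tested, with the per-marker k recorded.
    ``envs_significant`` counts the individual environments where the
    marker passed that scan's own BH pass at the same q.  Markers absent
    from every scan are omitted with a log entry.
    """
    if not scans:
        raise ValueError("need at least one scan")
    frames = []
    for s in scans:
        f = s.results[["snp_id", "chrom", "pos", "p"]].copy()
        f["env"] = s.environment
        padj = bh_adjusted(f["p"].to_numpy())
        f["env_significant"] = padj <= q
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)

    wide = long.pivot(index="snp_id", columns="env", values="p")
    x2, pf = fisher_combine_matrix(wide.to_numpy())
    first = long.drop_duplicates("snp_id").set_index("snp_id")
    meta = pd.DataFrame(
        {
            "snp_id": wide.index,
            "chrom": first.loc[wide.index, "chrom"].to_numpy(),
            "pos": first.loc[wide.index, "pos"].to_numpy(),
            "k": (~np.isnan(wide.to_numpy())).sum(axis=1),
            "X2": x2,
            "p_fisher": pf,
            "minus_log10_p": -np.log10(pf),
            "envs_significant": long.groupby("snp_id", sort=False)[
                "env_significant"
            ].sum().loc[wide.index].to_numpy(),
        }
    ).reset_index(drop=True)
    all_ids = {sid for s in scans for sid in s.skipped}
    omitted = all_ids - set(meta["snp_id"])
    if omitted:
        logger.info("%d SNPs absent from every scan were omitted", len(omitted))
    verdict = bh_fdr(meta["p_fisher"].to_numpy(), q=q)
    crit = verdict.critical_p if verdict.critical_p is not None else -np.inf
    meta["significant"] = meta["p_fisher"] <= crit
    meta = meta.sort_values("p_fisher", kind="mergesort").reset_index(drop=True)
    return meta, verdict


def _gaussian_ml_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Maximized Gaussian log-likelihood of an OLS fit (ML variance)."""
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    if rss <= 0:
        rss = np.finfo(float).tiny
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def lrt_interaction(
    y: np.ndarray,
    dosage1: np.ndarray,
    dosage2: np.ndarray,
    pcs: np.ndarray | None,
    trait: str = "",
    marker1: str = "m1",
    marker2: str = "m2",
) -> InteractionTest:
    """Two-locus likelihood-ratio test.

    Full model: y ~ 1 + PCs + m1 + m2 + m1*m2 (Gaussian ML); reduced
    model: y ~ 1 + PCs.  The statistic 2*(l_full - l_reduced) is referred
    to chi-square with 3 degrees of freedom.  Pairs with fewer complete
    cases than parameters are rejected, as are collinear marker pairs.
    """
    y = np.asarray(y, dtype=float)
    d1 = np.asarray(dosage1, dtype=float)
    d2 = np.asarray(dosage2, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(d1) | np.isnan(d2))
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        ok &= ~np.isnan(pcs).any(axis=1)
    y, d1, d2 = y[ok], d1[ok], d2[ok]
    P = pcs[ok] if pcs is not None else np.empty((ok.sum(), 0))
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        raise ValueError(
            f"marker {marker1 if np.ptp(d1) == 0 else marker2} is constant "
            "on the complete cases"
        )
    r = np.corrcoef(d1, d2)[0, 1]
    if abs(r) > 1 - 1e-12:
        raise ValueError(f"markers {marker1} and {marker2} are collinear")
    n = y.size
    n_params = 4 + P.shape[1]
    if n < n_params + 2:
        raise ValueError(f"too few complete cases (n={n})")
    X_red = np.column_stack([np.ones(n), P])
    X_full = np.column_stack([X_red, d1, d2, d1 * d2])
    lrt = 2.0 * (_gaussian_ml_loglik(y, X_full) - _gaussian_ml_loglik(y, X_red))
    lrt = max(lrt, 0.0)
    p = max(float(stats.chi2.sf(lrt, df=3)), P_FLOOR)
    return InteractionTest(
        marker1=marker1, marker2=marker2, trait=trait, lrt=lrt, df=3, p=p
    )


def interaction_screen(
    gm: GenotypeMatrix,
    trait: pd.Series,
    pcs: np.ndarray | None,
    candidate_snps: list[str],
    trait_label: str = "",
) -> list[InteractionTest]:
    """LRT every unordered pair of candidate markers against the trait.

    ``candidate_snps`` is typically the set of markers with BH-adjusted
    p <= 0.1 from a prior single-marker scan of the trait.  Pairs that
    fail the test's preconditions (collinear, too few cases) are skipped.
    Results are sorted by p-value.
    """
    if len(candidate_snps) < 2:
        logger.warning("fewer than 2 candidate SNPs: nothing to test")
        return []
    trait = trait.dropna()
    used = [a for a in gm.accessions if a in trait.index]
    idx = {a: i for i, a in enumerate(gm.accessions)}
    acc_idx = np.asarray([idx[a] for a in used])
    y = trait.loc[used].to_numpy(dtype=float)
    D = gm.dosage_float()[:, acc_idx]
    P = np.asarray(pcs)[acc_idx] if pcs is not None else None
    sid = {s: i for i, s in enumerate(gm.snp_ids())}

    out: list[InteractionTest] = []
    for m1, m2 in combinations(candidate_snps, 2):
        try:
            out.append(
                lrt_interaction(
                    y, D[sid[m1]], D[sid[m2]], P,
                    trait=trait_label, marker1=m1, marker2=m2,
                )
            )
        except ValueError as exc:
            logger.info("pair (%s, %s) skipped: %s", m1, m2, exc)
    out.sort(key=lambda t: t.p)
    return out


def prescreen_candidates(
    scan: AssociationScan, q: float = 0.1
) -> list[str]:
    """Markers with BH-adjusted p <= q from a single-marker scan; the first
    stage of the two-stage interaction screen."""
    padj = bh_adjusted(scan.results["p"].to_numpy())
    return list(scan.results["snp_id"][padj <= q])
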