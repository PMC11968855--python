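"""Linear association scan and a simple SNP heritability estimator.

A desk-scale stand-in for a mixed-model GWAS on related samples: an
unrelated-samples OLS scan (per-SNP regression of the phenotype on dosage
plus age, sex and genetic principal components) and Haseman-Elston
regression of phenotype cross-products on genomic-relationship entries for
heritability, with a delete-one jackknife SE.  Genomic inflation reuses the
EWAS definition; tiers are 5e-8 (genome-wide) and 1e-5 (suggestive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .marginal import genomic_inflation

logger = logging.getLogger(__name__)

__all__ = [
    "compute_pcs",
    "gwas_scan",
    "he_regression",
    "compare_phenotype_scans",
    "GWAS_GENOME_WIDE_P",
    "GWAS_SUGGESTIVE_P",
]

GWAS_GENOME_WIDE_P = 5e-8
GWAS_SUGGESTIVE_P = 1e-5


def _standardized_dosages(genotypes: pd.DataFrame) -> np.ndarray:
    g = genotypes.to_numpy(dtype=float)
    col_mean = np.nanmean(g, axis=0)
    nan = np.isnan(g)
    if nan.any():
        g = np.where(nan, col_mean[None, :], g)
    g -= col_mean
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return g / sd


def compute_pcs(genotypes: pd.DataFrame, k: int = 20) -> np.ndarray:
    """Top-k principal component scores of the standardized dosage matrix.

    Sign convention: within each component, the largest-magnitude SNP
    loading is made positive, so repeated runs agree.
    """
    n, p = genotypes.shape
    if k >= min(n, p):
        raise ValueError(f"k={k} must be below min(n, p)={min(n, p)}")
    z = _standardized_dosages(genotypes)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def gwas_scan(
    genotypes: pd.DataFrame,
    y: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP least squares of y on dosage + covariates (via FWL projection).

    Returns a frame (snp_id, beta, se, p, n) with the scan-level inflation
    factor in ``attrs['lambda']``.  Monomorphic SNPs produce NA rows.
    """
    y = np.asarray(y, dtype=float)
    n, p = genotypes.shape
    if len(y) != n:
        raise ValueError("phenotype length mismatch")
    if covariates is None:
        design = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        design = np.column_stack([np.ones(n), cov])
    k_cov = design.shape[1]
    if n <= k_cov + 2:
        raise ValueError("too few samples for the covariate set")

    q, _ = np.linalg.qr(design)
    y_r = y - q @ (q.T @ y)

    g = genotypes.to_numpy(dtype=float)
    col_mean = np.nanmean(g, axis=0)
    nan = np.isnan(g)
    if nan.any():
        g = np.where(nan, col_mean[None, :], g)
    mono = g.std(axis=0) == 0
    g_r = g - q @ (q.T @ g)

    gg = (g_r**2).sum(axis=0)
    gg_safe = np.where(gg == 0, 1.0, gg)
    beta = (g_r * y_r[:, None]).sum(axis=0) / gg_safe
    df = n - k_cov - 1
    rss = (y_r**2).sum() - beta**2 * gg_safe
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)

    dead = mono | (gg == 0)
    beta[dead] = np.nan
    se[dead] = np.nan
    pval[dead] = np.nan
    if dead.any():
        logger.info("gwas_scan: %d monomorphic SNPs skipped", int(dead.sum()))

    out = pd.DataFrame(
        {
            "snp_id": list(genotypes.columns),
            "beta": beta,
            "se": se,
            "p": pval,
            "n": n,
        }
    )
    out.attrs["lambda"] = genomic_inflation(pval[np.isfinite(pval)])
    out.attrs["genome_wide_p"] = GWAS_GENOME_WIDE_P
    out.attrs["suggestive_p"] = GWAS_SUGGESTIVE_P
    return out


def he_regression(
    genotypes: pd.DataFrame, y: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Haseman-Elston heritability: regress y_i y_j on GRM entries (i < j).

    y is standardized internally (population variance).  The slope of the
    with-intercept regression over off-diagonal pairs estimates h2; the SE
    is a delete-one-individual jackknife.
    """
    y = np.asarray(y, dtype=float)
    n, p = genotypes.shape
    if n < 30:
        raise ValueError("need at least 30 individuals for HE regression")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    y = (y - y.mean()) / y.std()

    z = _standardized_dosages(genotypes)
    grm = (z @ z.T) / p
    yy = np.outer(y, y)

    mask = ~np.eye(n, dtype=bool)
    # per-row sums over j != i (each unordered pair counted twice; slope unaffected)
    sx_row = np.where(mask, grm, 0.0).sum(axis=1)
    sy_row = np.where(mask, yy, 0.0).sum(axis=1)
    sxx_row = np.where(mask, grm**2, 0.0).sum(axis=1)
    sxy_row = np.where(mask, grm * yy, 0.0).sum(axis=1)
    m_row = np.full(n, n - 1, dtype=float)

    def slope(sx, sy, sxx, sxy, m):
        denom = sxx - sx * sx / m
        if denom <= 0:
            raise ValueError("degenerate relatedness distribution")
        return (sxy - sx * sy / m) / denom

    sx, sy, sxx, sxy, m = (sx_row.sum(), sy_row.sum(), sxx_row.sum(),
                           sxy_row.sum(), m_row.sum())
    h2 = slope(sx, sy, sxx, sxy, m)

    # delete individual i: remove its row and column pairs (row sums count
    # each of its pairs twice across i and j, so subtract row i once from
    # totals, then the symmetric half remaining)
    jack = np.empty(n)
    for i in range(n):
        jack[i] = slope(
            sx - 2 * sx_row[i],
            sy - 2 * sy_row[i],
            sxx - 2 * sxx_row[i],
            sxy - 2 * sxy_row[i],
            m - 2 * m_row[i],
        )
    se = float(np.sqrt((n - 1) / n * ((jack - jack.mean()) ** 2).sum()))
    return float(h2), se


def compare_phenotype_scans(
    result_a: pd.DataFrame,
    result_b: pd.DataFrame,
    tiers: tuple[float, ...] = (GWAS_GENOME_WIDE_P, GWAS_SUGGESTIVE_P),
) -> dict:
    """Per-tier hit overlap and effect-sign concordance on shared SNPs."""
    shared = result_a.merge(result_b, on="snp_id", suffixes=("_a", "_b"))
    if shared.empty:
        raise ValueError("no shared SNP ids between scans")
    out: dict = {"n_shared_snps": len(shared)}
    for tier in tiers:
        hit_a = set(result_a.loc[result_a["p"] < tier, "snp_id"])
        hit_b = set(result_b.loc[result_b["p"] < tier, "snp_id"])
        both = sorted(hit_a & hit_b)
        entry = {
            "n_a": len(hit_a),
            "n_b": len(hit_b),
            "n_overlap": len(both),
        }
        if both:
            sub = shared[shared["snp_id"].isin(both)]
            entry["sign_concordance"] = float(
                (np.sign(sub["beta_a"]) == np.sign(sub["beta_b"])).mean()
            )
        else:
            entry["sign_concordance"] = float("nan")
        out[f"tier_{tier:g}"] = entry
    ok = shared[np.isfinite(shared["beta_a"]) & np.isfinite(shared["beta_b"])]
    out["overall_sign_concordance"] = float(
        (np.sign(ok["beta_a"]) == np.sign(ok["beta_b"])).mean()
    ) if len(ok) else float("nan")
    return out
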