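"""Per-CpG linear-model EWAS and genomic inflation.

The model direction follows the sequencing analyses: methylation at each
site is the outcome, regressed on the smoking phenotype (binary, ordinal or
continuous) plus age and sex.  Two-sided p-values use the t reference at
the exact residual degrees of freedom.  Hits are tiered at a genome-wide
threshold of 3.6e-8 and a suggestive threshold of 1e-5 (strict <).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceTiers",
    "ewas_lm",
    "genomic_inflation",
    "tier_hits",
    "cross_platform_overlap",
]

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

_SITE_RE = re.compile(r"^(\w+)-(\d+)-(\d+)$")


class SignificanceTiers:
    """Thresholds for hit calling; genome-wide must be the stricter one."""

    def __init__(self, genome_wide_p: float = 3.6e-8, suggestive_p: float = 1e-5):
        if not genome_wide_p < suggestive_p:
            raise ValueError("genome_wide_p must be below suggestive_p")
        self.genome_wide_p = genome_wide_p
        self.suggestive_p = suggestive_p


def _parse_site_ids(site_ids) -> pd.DataFrame:
    chrom, start, end = [], [], []
    for sid in site_ids:
        m = _SITE_RE.match(str(sid))
        if m:
            chrom.append(m.group(1))
            start.append(int(m.group(2)))
            end.append(int(m.group(3)))
        else:
            chrom.append(None)
            start.append(-1)
            end.append(-1)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": end})


def ewas_lm(
    methylation: pd.DataFrame,
    phenotype: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series | None = None,
    sex: np.ndarray | pd.Series | None = None,
    build: str = "GRCh38",
) -> pd.DataFrame:
    """OLS of each methylation column on phenotype (+ age, sex).

    ``methylation`` is samples x sites and may contain NaN; sites with
    missing entries are fit on complete cases.  Constant sites yield NA
    rows.  Returns a frame with columns site_id, chrom, start, end, beta,
    se, p, n (beta = phenotype coefficient), with the build stamped into
    ``attrs``.
    """
    pheno = np.asarray(phenotype, dtype=float)
    n = len(pheno)
    if len(methylation) != n:
        raise ValueError("methylation and phenotype lengths differ")
    if np.ptp(pheno[np.isfinite(pheno)]) == 0:
        raise ValueError("phenotype does not vary")
    cols = [np.ones(n), pheno]
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
    if sex is not None:
        s = pd.Series(sex).astype(str)
        cols.append(s.map({"F": 0.0, "M": 1.0, "0": 0.0, "1": 1.0}).to_numpy())
    design = np.column_stack(cols)
    k = design.shape[1]
    if n <= k + 1:
        raise ValueError("too few samples for the covariate set")

    values = methylation.to_numpy(dtype=float)
    p_sites = values.shape[1]
    beta = np.full(p_sites, np.nan)
    se = np.full(p_sites, np.nan)
    pval = np.full(p_sites, np.nan)
    n_used = np.zeros(p_sites, dtype=np.int64)

    has_nan = np.isnan(values).any()
    complete = ~np.isnan(values).any(axis=0) if has_nan else np.ones(p_sites, bool)

    def _fit_block(d: np.ndarray, block: np.ndarray, idx: np.ndarray) -> None:
        nn = d.shape[0]
        df = nn - d.shape[1]
        if df < 1:
            return
        dtd = d.T @ d
        dtd_inv = np.linalg.inv(dtd)
        coef = dtd_inv @ (d.T @ block)
        resid = block - d @ coef
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / df
        se_block = np.sqrt(dtd_inv[1, 1] * sigma2)
        const = block.std(axis=0) == 0
        b = coef[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = b / se_block
        pv = 2.0 * stats.t.sf(np.abs(tstat), df)
        pv = np.clip(pv, np.finfo(float).tiny, 1.0)
        b[const] = np.nan
        se_block[const] = np.nan
        pv[const] = np.nan
        beta[idx] = b
        se[idx] = se_block
        pval[idx] = pv
        n_used[idx] = nn

    idx_c = np.flatnonzero(complete)
    if idx_c.size:
        _fit_block(design, values[:, idx_c], idx_c)
    for j in np.flatnonzero(~complete):
        keep = ~np.isnan(values[:, j])
        if keep.sum() <= k + 1:
            continue
        sub = design[keep]
        if np.ptp(sub[:, 1]) == 0:
            continue
        _fit_block(sub, values[keep][:, [j]].reshape(-1, 1), np.array([j]))

    n_skipped = int(np.isnan(beta).sum())
    if n_skipped:
        logger.info("ewas_lm: %d sites skipped (constant or too missing)", n_skipped)

    coords = _parse_site_ids(methylation.columns)
    out = pd.DataFrame(
        {
            "site_id": list(methylation.columns),
            "chrom": coords["chrom"],
            "start": coords["start"],
            "end": coords["end"],
            "beta": beta,
            "se": se,
            "p": pval,
            "n": n_used,
        }
    )
    out.attrs["build"] = build
    return out


def genomic_inflation(pvalues: np.ndarray | pd.Series) -> float:
    """lambda = median observed 1-df chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def tier_hits(
    result: pd.DataFrame, tiers: SignificanceTiers | None = None
) -> dict[str, list[str]]:
    """Strictly-below-threshold hit lists; genome-wide is a subset of suggestive."""
    tiers = tiers or SignificanceTiers()
    p = result["p"].to_numpy(dtype=float)
    ids = result["site_id"].to_numpy()
    ok = np.isfinite(p)
    return {
        "genome_wide": list(ids[ok & (p < tiers.genome_wide_p)]),
        "suggestive": list(ids[ok & (p < tiers.suggestive_p)]),
    }


def cross_platform_overlap(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    tier_p: float = 3.6e-8,
) -> dict:
    """Overlap of tiered hits across two platforms sharing a coordinate scheme.

    Sites match on exact identifier (interval) equality.  Reports per-platform
    hit counts, the intersection count, and effect-sign concordance among
    shared hits.
    """
    build_a = results_a.attrs.get("build", "GRCh38")
    build_b = results_b.attrs.get("build", "GRCh38")
    if build_a != build_b:
        raise ValueError(f"mixed genome builds: {build_a} vs {build_b}")
    hits_a = results_a[np.isfinite(results_a["p"]) & (results_a["p"] < tier_p)]
    hits_b = results_b[np.isfinite(results_b["p"]) & (results_b["p"] < tier_p)]
    ids_a = set(hits_a["site_id"])
    ids_b = set(hits_b["site_id"])
    shared = sorted(ids_a & ids_b)
    if shared:
        sa = hits_a.set_index("site_id").loc[shared, "beta"]
        sb = hits_b.set_index("site_id").loc[shared, "beta"]
        concordance = float((np.sign(sa.to_numpy()) == np.sign(sb.to_numpy())).mean())
    else:
        concordance = float("nan")
    return {
        "n_a": len(ids_a),
        "n_b": len(ids_b),
        "n_shared": len(shared),
        "shared_sites": shared,
        "sign_concordance": concordance,
    }
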