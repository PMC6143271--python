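"""Univariate linear-mixed-model association with a standardized GRM.

The model per SNP is y = W g + g_snp b + u + e with u ~ N(0, sg2 K) and
e ~ N(0, se2 I), K the standardized genetic relatedness matrix.  The
variance-component ratio is estimated once per phenotype on the
covariate-only model via an eigendecomposition of K and one-dimensional
likelihood optimization; each SNP is then tested by generalized least
squares with a 1-df likelihood-ratio test.  With K = I this reduces
exactly to ordinary least squares.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import KinshipMatrix

logger = logging.getLogger("altadapt")

#: diagonal ridge applied when K's smallest eigenvalue is negative
KINSHIP_RIDGE = 1e-6


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def standardize_genotypes(genotypes: np.ndarray, maf_min: float = 0.05,
                          allele_freqs: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Center genotype columns by 2*p_hat and scale by sqrt(2*p_hat*(1-p_hat)).

    p_hat is estimated from the sample unless reference ``allele_freqs``
    are supplied (useful for very small cohorts, where sample estimates
    degenerate).  Missing genotypes (NaN) are mean-imputed per SNP.
    Returns the standardized matrix restricted to SNPs with
    maf >= maf_min, plus the boolean keep-mask over input columns.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 individuals")
    if allele_freqs is not None:
        p_hat = np.asarray(allele_freqs, dtype=float)
        if p_hat.shape != (g.shape[1],):
            raise ValueError("allele_freqs must have one entry per SNP")
    else:
        p_hat = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = (maf >= maf_min) & (p_hat > 0) & (p_hat < 1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluding %d SNP(s) with maf < %.3g", n_drop, maf_min)
    g = g[:, keep]
    p = p_hat[keep]
    col_mean = 2.0 * p
    if np.any(np.isnan(g)):
        nan_mask = np.isnan(g)
        g = np.where(nan_mask, np.broadcast_to(col_mean, g.shape), g)
    x = (g - col_mean) / np.sqrt(2.0 * p * (1.0 - p))
    return x, keep


def compute_grm(genotypes: np.ndarray, ids: list[str] | None = None,
                maf_min: float = 0.05,
                allele_freqs: np.ndarray | None = None) -> KinshipMatrix:
    """Standardized genetic covariance matrix K = X X' / M."""
    x, keep = standardize_genotypes(genotypes, maf_min=maf_min,
                                    allele_freqs=allele_freqs)
    m = x.shape[1]
    if m == 0:
        raise ValueError("no SNPs left after the maf filter")
    k = x @ x.T / m
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(x.shape[0])]
    return KinshipMatrix(values=k, ids=list(ids), n_snps_used=m,
                         n_snps_excluded=int((~keep).sum()))


# ---------------------------------------------------------------------------
# LMM
# ---------------------------------------------------------------------------

def _null_loglik(log_lambda: float, d: np.ndarray, yr: np.ndarray,
                 wr: np.ndarray) -> float:
    """Profiled ML log-likelihood of the covariate-only model at variance
    ratio lambda = sg2/se2, in the eigenbasis of K (d = eigenvalues)."""
    lam = np.exp(log_lambda)
    v = lam * d + 1.0
    wts = 1.0 / v
    xtx = (wr * wts[:, None]).T @ wr
    xty = (wr * wts[:, None]).T @ yr
    beta = np.linalg.solve(xtx, xty)
    resid = yr - wr @ beta
    rss = float(resid @ (wts * resid))
    n = yr.size
    return -0.5 * (n * np.log(rss / n) + np.log(v).sum())


def lmm_assoc(phenotype: np.ndarray, covariates: np.ndarray | None,
              genotypes: np.ndarray, kinship: KinshipMatrix,
              snp_ids: list[str] | None = None,
              effect_alleles: np.ndarray | None = None,
              other_alleles: np.ndarray | None = None,
              maf_min: float = 0.05) -> pd.DataFrame:
    """Per-SNP mixed-model association.

    Returns a DataFrame with columns snp, effect_allele, other_allele,
    maf, beta, se, p_lrt.  SNPs that are monomorphic (or below the maf
    filter) in the analysis sample are skipped.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] != n or kinship.values.shape[0] != n:
        raise ValueError("dimension mismatch between phenotype, genotypes, kinship")
    if covariates is None:
        w = np.ones((n, 1))
    else:
        w = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])

    k = kinship.values
    d, u = np.linalg.eigh(k)
    if d.min() < 0:
        logger.info("kinship not PSD (min eigenvalue %.3g); adding ridge", d.min())
        d, u = np.linalg.eigh(k + KINSHIP_RIDGE * np.eye(n))
        if d.min() < -1e-8:
            raise ValueError("kinship matrix not PSD after ridge")
        d = np.maximum(d, 0.0)

    yr, wr = u.T @ y, u.T @ w
    opt = optimize.minimize_scalar(lambda ll: -_null_loglik(ll, d, yr, wr),
                                   bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(opt.x))
    wts = 1.0 / (lam * d + 1.0)
    sw = np.sqrt(wts)

    # null weighted RSS for the LRT
    w_w = wr * sw[:, None]
    y_w = yr * sw
    beta0, rss0_arr = np.linalg.lstsq(w_w, y_w, rcond=None)[:2]
    rss0 = float(rss0_arr[0]) if rss0_arr.size else float(
        np.sum((y_w - w_w @ beta0) ** 2))

    p_hat = np.nanmean(g, axis=0) / 2.0
    maf_all = np.minimum(p_hat, 1.0 - p_hat)

    rows = []
    gr_all = u.T @ np.where(np.isnan(g), 2.0 * p_hat, g)
    n_cov = w.shape[1]
    for j in range(g.shape[1]):
        snp = snp_ids[j] if snp_ids is not None else f"snp{j + 1}"
        if maf_all[j] < maf_min or np.nanstd(g[:, j]) == 0:
            logger.debug("skipping SNP %s (maf %.3g)", snp, maf_all[j])
            continue
        x_w = np.column_stack([w_w, gr_all[:, j] * sw])
        beta, rss_arr = np.linalg.lstsq(x_w, y_w, rcond=None)[:2]
        rss1 = float(rss_arr[0]) if rss_arr.size else float(
            np.sum((y_w - x_w @ beta) ** 2))
        lrt = max(n * np.log(rss0 / rss1), 0.0)
        p_lrt = float(stats.chi2.sf(lrt, df=1))
        sigma2 = rss1 / (n - n_cov - 1)
        xtx_inv = np.linalg.inv(x_w.T @ x_w)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        rows.append({
            "snp": snp,
            "effect_allele": (effect_alleles[j] if effect_alleles is not None
                              else "G"),
            "other_allele": (other_alleles[j] if other_alleles is not None
                             else "A"),
            "maf": float(maf_all[j]),
            "beta": float(beta[-1]),
            "se": se,
            "p_lrt": max(p_lrt, np.nextafter(0, 1)),
        })
    out = pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele",
                                      "maf", "beta", "se", "p_lrt"])
    out.attrs["lambda_ratio"] = lam
    return out


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median-based inflation factor of a set of association p-values."""
    chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
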