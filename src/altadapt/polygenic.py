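"""Matched-control resampling and polygenic adaptation tests.

The machinery: GWAS-ascertained SNPs are compared with random panel SNPs
matched one-to-one by minor-allele-frequency bin (width 0.02) and
optionally by background-selection B-value bin (width 100).  Three tests
are built on this null:

* the *frequency-difference* test - is the mean frequency of
  trait-increasing alleles more different between two populations than in
  matched random sets (one-sided empirical p);
* the *overdispersion* (Q_X-style) test - do per-population genetic
  values Z_m = 2 * sum_l alpha_l p_ml disperse across populations more
  than the neutral drift covariance F predicts (chi^2_{M-1}
  parametrically, and empirically against matched null sets);
* the *outlier* test - is a population's (or regional group's) genetic
  value away from its conditional expectation given the other
  populations, under the multivariate-normal drift model.

Empirical p-values use the plus-one rule (r+1)/(B+1), so a reported
0.0000 means p < 1/B, never literal zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (AscertainedSet, FrequencyPanel, PopulationCovariance,
                   TestResult, maf_bin_of)

logger = logging.getLogger("altadapt")

#: relative eigenvalue tolerance of the pseudo-inverse of F
PINV_RCOND = 1e-8


# ---------------------------------------------------------------------------
# orientation helpers
# ---------------------------------------------------------------------------

def _source_freq(panel: FrequencyPanel, maf_source: str) -> np.ndarray:
    """Alt-allele frequency used for maf binning / minor-allele calls."""
    if maf_source == "mean":
        return panel.mean_freq()
    if maf_source in panel.populations:
        return panel.table[maf_source].to_numpy(dtype=float)
    raise KeyError(f"maf_source must be 'mean' or a population name, "
                   f"got {maf_source!r}")


def inc_allele_freqs(ascertained: AscertainedSet, panel: FrequencyPanel,
                     populations: list[str]) -> np.ndarray:
    """Trait-increasing allele frequencies, shape (n_snps, n_populations)."""
    idx = panel.index_of(ascertained.table["snp"])
    f_alt = panel.freqs(populations)[idx]
    inc_is_alt = (ascertained.table["inc_allele"].to_numpy()
                  == panel.table["alt"].to_numpy()[idx])
    return np.where(inc_is_alt[:, None], f_alt, 1.0 - f_alt)


# ---------------------------------------------------------------------------
# matched controls
# ---------------------------------------------------------------------------

@dataclass
class ControlSets:
    """B random SNP sets matched one-to-one to an ascertained set.

    ``indices`` holds panel row positions, shape (n_sets, n_ascertained),
    column l matched to ascertained SNP l by maf bin (and optionally
    B-value bin).  ``inc_is_minor`` records, per ascertained SNP, whether
    its trait-increasing allele is the minor allele under ``maf_source``;
    control SNPs inherit this orientation (minor matched to minor).
    """

    indices: np.ndarray
    ascertained_snps: list[str]
    match_bvalue: bool
    maf_source: str
    inc_is_minor: np.ndarray
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return self.indices.shape[0]


def sample_matched_controls(ascertained: AscertainedSet, panel: FrequencyPanel,
                            n_sets: int = 10_000, match_bvalue: bool = False,
                            maf_source: str = "mean",
                            rng: np.random.Generator | None = None,
                            seed: int | None = None) -> ControlSets:
    """Draw matched random SNP sets from the panel.

    For each set and each ascertained SNP one panel SNP is drawn uniformly
    from the SNPs sharing its maf bin (width 0.02 under ``maf_source``)
    and, when ``match_bvalue``, its B-value bin (width 100).  Ascertained
    SNPs themselves are excluded; duplicates are disallowed within a set
    and allowed across sets.  An empty matching cell is an error (no
    silent bin-widening).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(ascertained) == 0:
        raise ValueError("cannot sample controls for an empty ascertained set")
    f_src = _source_freq(panel, maf_source)
    maf = np.minimum(f_src, 1.0 - f_src)
    bins = maf_bin_of(maf)
    if match_bvalue:
        keys = bins * 100 + panel.table["bvalue_bin"].to_numpy()
    else:
        keys = bins

    asc_idx = panel.index_of(ascertained.table["snp"])
    eligible = np.ones(panel.n_snps, dtype=bool)
    eligible[asc_idx] = False

    indices = np.empty((n_sets, len(ascertained)), dtype=np.int64)
    asc_keys = keys[asc_idx]
    for cell in np.unique(asc_keys):
        members = np.flatnonzero(asc_keys == cell)  # positions in ascertained set
        pool = np.flatnonzero((keys == cell) & eligible)
        k = members.size
        if pool.size < k:
            snps = list(ascertained.table["snp"].iloc[members])
            raise ValueError(
                f"matching cell {cell} has {pool.size} eligible SNP(s) for "
                f"{k} ascertained SNP(s) {snps}: cannot sample without "
                f"within-set duplicates")
        if pool.size <= k:
            logger.warning("low control diversity: cell %s has exactly %d "
                           "eligible SNP(s) for %d ascertained SNP(s)",
                           cell, pool.size, k)
        if k == 1:
            draw = pool[rng.integers(pool.size, size=n_sets)][:, None]
        elif n_sets * pool.size <= 2e8:
            u = rng.random((n_sets, pool.size))
            draw = pool[np.argpartition(u, k - 1, axis=1)[:, :k]]
        else:  # pragma: no cover - very large pools
            draw = np.stack([pool[rng.choice(pool.size, size=k, replace=False)]
                             for _ in range(n_sets)])
        indices[:, members] = draw
    # orientation under maf_source: is the increasing allele the minor one?
    inc_is_alt = (ascertained.table["inc_allele"].to_numpy()
                  == panel.table["alt"].to_numpy()[asc_idx])
    f_inc_src = np.where(inc_is_alt, f_src[asc_idx], 1.0 - f_src[asc_idx])
    inc_is_minor = f_inc_src < 0.5
    return ControlSets(indices=indices,
                       ascertained_snps=list(ascertained.table["snp"]),
                       match_bvalue=match_bvalue, maf_source=maf_source,
                       inc_is_minor=inc_is_minor, seed=seed)


def oriented_control_freqs(controls: ControlSets, panel: FrequencyPanel,
                           populations: list[str]) -> np.ndarray:
    """Null-set frequencies oriented like their ascertained partners.

    Each control SNP's "trait-increasing" allele is its minor allele when
    the partner's increasing allele is minor (major otherwise), minor
    status judged under the matching ``maf_source``.  Shape
    (n_sets, n_ascertained, n_populations).
    """
    f_src = _source_freq(panel, controls.maf_source)
    minor_is_alt = f_src < 0.5
    f_alt = panel.freqs(populations)
    f_sel = f_alt[controls.indices]                  # (B, L, M)
    take_alt = minor_is_alt[controls.indices] == controls.inc_is_minor[None, :]
    return np.where(take_alt[:, :, None], f_sel, 1.0 - f_sel)


# ---------------------------------------------------------------------------
# population covariance and genetic values
# ---------------------------------------------------------------------------

def estimate_population_covariance(panel: FrequencyPanel,
                                   populations: list[str] | None = None,
                                   exclude_snps=None) -> PopulationCovariance:
    """Across-SNP covariance F of standardized frequency deviations.

    Per SNP l the deviation vector is
    y_ml = (p_ml - pbar_l) / sqrt(pbar_l (1 - pbar_l)) with pbar the
    unweighted across-population mean; F = mean_l y_l y_l'.  Built from
    control SNPs only when ``exclude_snps`` names the ascertained set.
    """
    pops = panel.populations if populations is None else list(populations)
    f = panel.freqs(pops)
    keep = np.ones(panel.n_snps, dtype=bool)
    if exclude_snps is not None:
        keep[panel.index_of(exclude_snps)] = False
    f = f[keep]
    pbar = f.mean(axis=1)
    ok = (pbar > 0) & (pbar < 1)
    f, pbar = f[ok], pbar[ok]
    y = (f - pbar[:, None]) / np.sqrt(pbar * (1.0 - pbar))[:, None]
    mat = y.T @ y / len(y)
    return PopulationCovariance(matrix=mat, populations=pops, n_snps=len(y))


@dataclass
class GeneticValues:
    """Effect-weighted allele-frequency sums per population.

    Z_m = 2 * sum_l alpha_l * p_ml on the trait-increasing orientation
    (the factor 2 is the diploid convention; it cancels in all
    standardized statistics).  V_A = 4 * sum_l alpha_l^2 pbar_l(1-pbar_l)
    is the drift-scaling additive variance.
    """

    populations: list[str]
    z: np.ndarray
    v_a: float

    def standardized(self) -> np.ndarray:
        """Mean-centered Z in drift-SD units: (Z - Zbar) / sqrt(V_A)."""
        if self.v_a <= 0:
            raise ValueError("degenerate variance: all effect sizes are zero")
        return (self.z - self.z.mean()) / np.sqrt(self.v_a)


def genetic_values(ascertained: AscertainedSet, panel: FrequencyPanel,
                   populations: list[str] | None = None) -> GeneticValues:
    """Compute per-population genetic values for an ascertained set."""
    pops = panel.populations if populations is None else list(populations)
    alpha = ascertained.table["alpha"].to_numpy(dtype=float)
    if np.any(~np.isfinite(alpha)):
        raise ValueError("missing effect size for an ascertained SNP")
    f_inc = inc_allele_freqs(ascertained, panel, pops)   # (L, M)
    z = 2.0 * alpha @ f_inc
    pbar = f_inc.mean(axis=1)
    v_a = float(4.0 * np.sum(alpha ** 2 * pbar * (1.0 - pbar)))
    return GeneticValues(populations=pops, z=z, v_a=v_a)


def _null_genetic_values(controls: ControlSets, panel: FrequencyPanel,
                         alpha: np.ndarray,
                         populations: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Z and V_A for every null set; shapes (B, M) and (B,)."""
    f = oriented_control_freqs(controls, panel, populations)   # (B, L, M)
    z = 2.0 * np.einsum("l,blm->bm", alpha, f)
    pbar = f.mean(axis=2)                                      # (B, L)
    v_a = 4.0 * np.einsum("l,bl->b", alpha ** 2, pbar * (1.0 - pbar))
    return z, v_a


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _plus_one_p(r: int, b: int) -> float:
    return (r + 1) / (b + 1)


def freq_diff_test(ascertained: AscertainedSet, panel: FrequencyPanel,
                   pop_a: str, pop_b: str, controls: ControlSets,
                   direction: str = "lower") -> TestResult:
    """One-sided empirical test of the mean trait-increasing-allele
    frequency difference between two populations.

    statistic = mean_l (p_inc(pop_a) - p_inc(pop_b)); the empirical p is
    the (plus-one) proportion of matched null sets at least as extreme in
    ``direction`` ("lower" or "higher").
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    f_inc = inc_allele_freqs(ascertained, panel, [pop_a, pop_b])
    observed = float(np.mean(f_inc[:, 0] - f_inc[:, 1]))
    f_null = oriented_control_freqs(controls, panel, [pop_a, pop_b])
    null_means = (f_null[:, :, 0] - f_null[:, :, 1]).mean(axis=1)
    if direction == "lower":
        r = int(np.sum(null_means <= observed))
    else:
        r = int(np.sum(null_means >= observed))
    return TestResult(name="freq_diff", statistic=observed,
                      p_empirical=_plus_one_p(r, controls.n_sets),
                      n_sets=controls.n_sets, direction=direction,
                      extra={"null_means": null_means,
                             "pop_a": pop_a, "pop_b": pop_b})


def _pinv_quadratic(fmat: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Q = z' F+ z with the pseudo-inverse restricted to the mean-centered
    (M-1)-dimensional subspace; z may be (M,) or (B, M)."""
    m = fmat.shape[0]
    center = np.eye(m) - np.ones((m, m)) / m
    fc = center @ fmat @ center
    fpinv = np.linalg.pinv(fc, rcond=PINV_RCOND, hermitian=True)
    z = np.atleast_2d(z) @ center
    return np.einsum("bi,ij,bj->b", z, fpinv, z)


def overdispersion_test(ascertained: AscertainedSet, panel: FrequencyPanel,
                        fcov: PopulationCovariance, controls: ControlSets,
                        populations: list[str] | None = None) -> TestResult:
    """Q_X-style overdispersion of genetic values across populations.

    Q = Z'^T F+ Z' with Z' the standardized genetic values and F+ the
    pseudo-inverse of the drift covariance on the mean-centered subspace;
    chi^2_{M-1} upper tail parametrically, and the same statistic on each
    matched null set empirically (upper tail, plus-one rule).
    """
    pops = fcov.populations if populations is None else list(populations)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    gv = genetic_values(ascertained, panel, pops)
    zp = gv.standardized()
    q = float(_pinv_quadratic(fcov.matrix, zp)[0])
    dof = len(pops) - 1
    p_par = float(stats.chi2.sf(q, df=dof))

    alpha = ascertained.table["alpha"].to_numpy(dtype=float)
    z_null, va_null = _null_genetic_values(controls, panel, alpha, pops)
    if np.any(va_null <= 0):
        raise ValueError("degenerate variance in a null set")
    zp_null = (z_null - z_null.mean(axis=1, keepdims=True)) \
        / np.sqrt(va_null)[:, None]
    q_null = _pinv_quadratic(fcov.matrix, zp_null)
    r = int(np.sum(q_null >= q))
    return TestResult(name="overdispersion", statistic=q,
                      p_empirical=_plus_one_p(r, controls.n_sets),
                      p_parametric=p_par, n_sets=controls.n_sets,
                      extra={"dof": dof, "null_q": q_null})


def _conditional_stat(zp: np.ndarray, fmat: np.ndarray,
                      s_idx: np.ndarray, r_idx: np.ndarray) -> np.ndarray:
    """Conditional z-score of the subset mean given the rest, under
    N(0, F); zp may be (M,) or (B, M).

    Centered genetic values sum to zero exactly, so F is singular with
    null vector 1 and conditioning on *all* remaining populations would
    be degenerate.  One non-focal population is therefore dropped from
    the conditioning set (the constraint absorbs it), which makes the
    MVN conditional proper; with M = 2 the subset is conditioned on
    nothing (unconditional variance).
    """
    zp = np.atleast_2d(zp)
    w = np.full(s_idx.size, 1.0 / s_idx.size)
    r_use = r_idx[:-1]
    f_ss = fmat[np.ix_(s_idx, s_idx)]
    if r_use.size == 0:
        cond_var = float(w @ f_ss @ w)
        if cond_var <= 0:
            raise ValueError("singular conditioning covariance")
        return (zp[:, s_idx] @ w) / np.sqrt(cond_var)
    f_sr = fmat[np.ix_(s_idx, r_use)]
    f_rr = fmat[np.ix_(r_use, r_use)]
    f_rr_inv = np.linalg.pinv(f_rr, rcond=PINV_RCOND, hermitian=True)
    coef = f_sr @ f_rr_inv
    cond_var = float(w @ (f_ss - coef @ f_sr.T) @ w)
    if cond_var <= 0:
        raise ValueError("singular conditioning covariance")
    cond_mean = zp[:, r_use] @ coef.T @ w
    observed = zp[:, s_idx] @ w
    return (observed - cond_mean) / np.sqrt(cond_var)


def outlier_test(ascertained: AscertainedSet, panel: FrequencyPanel,
                 subset: list[str], fcov: PopulationCovariance,
                 controls: ControlSets,
                 populations: list[str] | None = None) -> TestResult:
    """Conditional-expectation outlier test for a population subset.

    Under the MVN drift model the statistic is the subset's mean
    standardized genetic value minus its conditional expectation given
    the remaining populations, in conditional-SD units; the empirical p
    is two-sided over matched null sets.
    """
    pops = fcov.populations if populations is None else list(populations)
    subset = list(subset)
    if not subset or set(subset) >= set(pops):
        raise ValueError("subset must be a non-empty strict subset")
    unknown = [s for s in subset if s not in pops]
    if unknown:
        raise KeyError(f"unknown subset population(s): {unknown}")
    s_idx = np.array([pops.index(s) for s in subset])
    r_idx = np.array([i for i in range(len(pops)) if i not in s_idx])

    gv = genetic_values(ascertained, panel, pops)
    stat = float(_conditional_stat(gv.standardized(), fcov.matrix,
                                   s_idx, r_idx)[0])

    alpha = ascertained.table["alpha"].to_numpy(dtype=float)
    z_null, va_null = _null_genetic_values(controls, panel, alpha, pops)
    zp_null = (z_null - z_null.mean(axis=1, keepdims=True)) \
        / np.sqrt(va_null)[:, None]
    stat_null = _conditional_stat(zp_null, fcov.matrix, s_idx, r_idx)
    r = int(np.sum(np.abs(stat_null) >= abs(stat)))
    return TestResult(name="outlier", statistic=stat,
                      p_empirical=_plus_one_p(r, controls.n_sets),
                      n_sets=controls.n_sets,
                      extra={"subset": subset, "null_stats": stat_null})


# ---------------------------------------------------------------------------
# single-SNP bookkeeping
# ---------------------------------------------------------------------------

def single_snp_value_gap(beta: float, freq_diff: float) -> float:
    """Between-population genetic-value gap contributed by one SNP.

    A diploid carries two alleles, so a per-allele effect ``beta`` and an
    allele-frequency difference ``freq_diff`` contribute
    2 * beta * freq_diff to the expected phenotype difference between the
    two populations (trait units).
    """
    return 2.0 * beta * freq_diff


def explained_gap_fraction(beta: float, freq_diff: float,
                           observed_gap: float) -> float:
    """Fraction of an observed between-population phenotype difference
    explained by one SNP's frequency differentiation."""
    if observed_gap == 0:
        raise ValueError("observed gap must be non-zero")
    return single_snp_value_gap(beta, freq_diff) / observed_gap
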