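"""Reduction of association output to independent, polarized SNP sets.

Two ascertainment routes: distance-based peak lumping of a cohort GWAS
(significant SNPs chained while neighbours are within a maximum gap, one
representative per peak), and greedy LD pruning of an external GWAS table
against a reference genotype panel.  Both polarize effects so that alpha
is the (non-negative) effect of the trait-increasing allele.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ASCERTAINED_COLUMNS, AscertainedSet

logger = logging.getLogger("altadapt")


def _polarize(df: pd.DataFrame) -> pd.DataFrame:
    """Make effects non-negative by swapping effect/non-effect alleles.

    Idempotent: rows with beta >= 0 are unchanged.
    """
    out = df.copy()
    flip = out["beta"] < 0
    inc = np.where(flip, out["other_allele"], out["effect_allele"])
    out["inc_allele"] = inc
    out["alpha"] = out["beta"].abs()
    return out


def lump_peaks(assoc: pd.DataFrame, p_threshold: float = 1e-4,
               max_gap: int = 200_000) -> AscertainedSet:
    """Lump significant SNPs into distance-chained peaks.

    SNPs with p <= p_threshold on the same chromosome belong to one peak
    while each adjacent pair is <= max_gap apart (single-linkage on
    neighbours).  The minimum-p SNP represents each peak; ties break to
    the smaller genomic position.

    ``assoc`` needs columns snp, chrom, pos, effect_allele, other_allele,
    beta, p_lrt.  Empty input (or no significant SNP) yields an empty set.
    """
    sig = assoc.loc[assoc["p_lrt"] <= p_threshold].copy()
    if sig.empty:
        return AscertainedSet(pd.DataFrame(columns=ASCERTAINED_COLUMNS))
    sig = sig.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_peak = (sig["chrom"] != sig["chrom"].shift()) | \
               (sig["pos"] - sig["pos"].shift() > max_gap)
    sig["peak_id"] = new_peak.cumsum().astype(int)

    reps = []
    for peak, grp in sig.groupby("peak_id", sort=True):
        best = grp.sort_values(["p_lrt", "pos"], kind="mergesort").iloc[0]
        reps.append(best)
    rep = pd.DataFrame(reps).reset_index(drop=True)
    rep = _polarize(rep)
    rep["peak_id"] = [f"peak{i + 1}" for i in range(len(rep))]
    out = rep[["snp", "chrom", "pos", "inc_allele", "alpha", "peak_id"]].copy()
    out["p"] = rep["p_lrt"].to_numpy()
    return AscertainedSet(out[ASCERTAINED_COLUMNS])


def dosage_r2(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of genotype dosage columns."""
    g = np.asarray(genotypes, dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.atleast_2d(np.corrcoef(g, rowvar=False))
    return np.nan_to_num(r, nan=0.0) ** 2


def ld_prune_external(snps: pd.DataFrame, reference_genotypes: np.ndarray,
                      reference_snp_ids: list[str],
                      r2_threshold: float = 0.2,
                      p_threshold: float = 1e-5,
                      column_map: dict[str, str] | None = None) -> AscertainedSet:
    """Greedy LD pruning of an external GWAS table.

    Candidates are restricted to SNPs present in the reference panel and
    with p <= p_threshold.  Pairs are visited in order of descending r^2
    (dosage correlation in the reference); whenever r^2 > r2_threshold the
    larger-p member is dropped.  The surviving set is pairwise
    r^2 <= r2_threshold.

    ``column_map`` renames external columns onto the expected
    snp/chrom/pos/effect_allele/other_allele/beta/p_lrt schema.
    """
    df = snps.rename(columns=column_map or {}).copy()
    needed = ["snp", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "p_lrt"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"external GWAS table missing columns: {missing}")

    df = df.loc[df["p_lrt"] <= p_threshold].reset_index(drop=True)
    ref_index = pd.Index(reference_snp_ids)
    pos_in_ref = ref_index.get_indexer(df["snp"])
    absent = pos_in_ref < 0
    if absent.any():
        logger.warning("dropping %d candidate SNP(s) missing from the "
                       "reference panel", int(absent.sum()))
    df = df.loc[~absent].reset_index(drop=True)
    pos_in_ref = pos_in_ref[~absent]
    if df.empty:
        return AscertainedSet(pd.DataFrame(columns=ASCERTAINED_COLUMNS))

    r2 = dosage_r2(np.asarray(reference_genotypes, dtype=float)[:, pos_in_ref])
    m = len(df)
    iu = np.triu_indices(m, k=1)
    order = np.argsort(-r2[iu], kind="mergesort")
    removed = np.zeros(m, dtype=bool)
    pvals = df["p_lrt"].to_numpy()
    for k in order:
        i, j = iu[0][k], iu[1][k]
        if r2[i, j] <= r2_threshold:
            break
        if removed[i] or removed[j]:
            continue
        # drop the larger-p member; ties break to the later row
        removed[j if pvals[j] >= pvals[i] else i] = True

    kept = df.loc[~removed].reset_index(drop=True)
    kept = _polarize(kept)
    kept["peak_id"] = [f"ext{i + 1}" for i in range(len(kept))]
    out = kept[["snp", "chrom", "pos", "inc_allele", "alpha", "peak_id"]].copy()
    out["p"] = kept["p_lrt"].to_numpy()
    return AscertainedSet(out[ASCERTAINED_COLUMNS])
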