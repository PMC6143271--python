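"""Per-SNP F_ST, the population branch statistic and a window scan.

PBS compares the log-transformed branch lengths T = -log(1 - F_ST) of
three populations: PBS = (T_tc + T_to - T_co) / 2 for target t,
comparison c and outgroup o.  Large values flag allele-frequency change
specific to the target branch.  Hudson's estimator is the default;
Reynolds' is available behind a switch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import FrequencyPanel

logger = logging.getLogger("altadapt")

#: F_ST is capped at 1 - FST_CAP_EPS before the log so T stays finite
FST_CAP_EPS = 1e-12


def pairwise_fst(p1, p2, n1=None, n2=None, estimator: str = "hudson"):
    """Pairwise F_ST from allele frequencies.

    With haploid sample counts (n1, n2) the sample-size-corrected Hudson
    estimator is used; without them the uncorrected form
    (p1-p2)^2 / (p1(1-p2) + p2(1-p1)).  Negative estimates are clamped to
    0 and results are capped just below 1.  Both populations fixed for the
    same allele give F_ST = 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    scalar = p1.ndim == 0 and p2.ndim == 0
    p1, p2 = np.atleast_1d(p1), np.atleast_1d(p2)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")

    if estimator == "hudson":
        num = (p1 - p2) ** 2
        if n1 is not None and n2 is not None:
            if n1 < 2 or n2 < 2:
                raise ValueError("haploid sample counts must be >= 2")
            num = num - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "reynolds":
        # Reynolds, Weir & Cockerham (1983) for two populations of equal
        # weight, frequency-level form
        num = (p1 - p2) ** 2 / 2.0
        den = num + p1 * (1 - p2) + p2 * (1 - p1)
        if n1 is not None and n2 is not None:
            # sample-size-corrected coancestry form
            h1 = p1 * (1 - p1) * (2 * n1) / (n1 - 1)
            h2 = p2 * (1 - p2) * (2 * n2) / (n2 - 1)
            al = (p1 - p2) ** 2 - (h1 / (2 * n1) + h2 / (2 * n2)) / 2.0
            num = al / 2.0
            den = al / 2.0 + (h1 + h2) / 4.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0 - FST_CAP_EPS)
    return float(fst[0]) if scalar else fst


def branch_length(fst):
    """Additive branch-length transform T = -log(1 - F_ST)."""
    fst = np.asarray(fst, dtype=float)
    if np.any(fst >= 1):
        raise ValueError("F_ST must be < 1")
    return -np.log1p(-fst)


def pbs(fst_tc, fst_to, fst_co):
    """Population branch statistic from three pairwise F_ST values.

    PBS = (T_tc + T_to - T_co) / 2 with T = -log(1 - F_ST).  May be
    negative (the target branch shorter than drift predicts).
    """
    t_tc = branch_length(fst_tc)
    t_to = branch_length(fst_to)
    t_co = branch_length(fst_co)
    return (t_tc + t_to - t_co) / 2.0


def pbs_scan(panel: FrequencyPanel, target: str, comparison: str,
             outgroup: str, top_quantile: float = 0.999,
             window_bp: int = 500_000,
             estimator: str = "hudson") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP PBS over a panel plus a window-enrichment scan.

    SNPs above the empirical ``top_quantile`` of PBS are flagged;
    non-overlapping windows of ``window_bp`` are then scored by a binomial
    tail test of their flagged-SNP count against the genome-wide flag
    rate.  Returns (per-SNP table, per-window table).
    """
    for pop in (target, comparison, outgroup):
        if pop not in panel.populations:
            raise KeyError(f"population {pop!r} not in panel")
    if panel.n_snps < 1000:
        logger.warning("PBS scan on %d SNPs: the top quantile is unstable",
                       panel.n_snps)
    pt = panel.table[target].to_numpy(dtype=float)
    pc = panel.table[comparison].to_numpy(dtype=float)
    po = panel.table[outgroup].to_numpy(dtype=float)
    fst_tc = pairwise_fst(pt, pc, estimator=estimator)
    fst_to = pairwise_fst(pt, po, estimator=estimator)
    fst_co = pairwise_fst(pc, po, estimator=estimator)
    values = pbs(fst_tc, fst_to, fst_co)

    cutoff = np.quantile(values, top_quantile)
    flags = values > cutoff
    snp_table = pd.DataFrame({
        "snp": panel.table["snp"],
        "chrom": panel.table["chrom"],
        "pos": panel.table["pos"],
        "fst_tc": fst_tc, "fst_to": fst_to, "fst_co": fst_co,
        "pbs": values, "top_flag": flags,
    })

    rate = flags.mean()
    windows = []
    if rate > 0:
        for chrom, grp in snp_table.groupby("chrom", sort=False):
            win = (grp["pos"].to_numpy() - 1) // window_bp
            for w in np.unique(win):
                sel = win == w
                n, k = int(sel.sum()), int(grp["top_flag"].to_numpy()[sel].sum())
                p_tail = stats.binom.sf(k - 1, n, rate) if k > 0 else 1.0
                windows.append({"chrom": chrom, "start": int(w) * window_bp + 1,
                                "end": (int(w) + 1) * window_bp,
                                "n_snps": n, "n_flagged": k,
                                "p_binomial": float(p_tail)})
    window_table = pd.DataFrame(
        windows, columns=["chrom", "start", "end", "n_snps", "n_flagged",
                          "p_binomial"])
    return snp_table, window_table
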