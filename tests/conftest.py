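import numpy as np
import pandas as pd
import pytest

from altadapt.core import AscertainedSet, FrequencyPanel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_panel(freqs: dict[str, list[float]], positions=None,
               chrom="1") -> FrequencyPanel:
    """Build a small frequency panel from per-population frequency lists."""
    pops = list(freqs)
    n = len(freqs[pops[0]])
    table = pd.DataFrame({
        "snp": [f"s{i + 1}" for i in range(n)],
        "chrom": chrom,
        "pos": positions if positions is not None
        else (np.arange(n) + 1) * 10_000,
        "ref": "A",
        "alt": "G",
    })
    for pop in pops:
        table[pop] = np.asarray(freqs[pop], dtype=float)
    panel = FrequencyPanel(table, pops)
    panel.annotate_bins(rng=np.random.default_rng(0))
    return panel


def make_ascertained(snp_ids, alphas, inc_alleles=None, positions=None,
                     pvals=None, chrom="1") -> AscertainedSet:
    n = len(snp_ids)
    return AscertainedSet(pd.DataFrame({
        "snp": snp_ids,
        "chrom": chrom,
        "pos": positions if positions is not None else np.arange(n) + 1,
        "inc_allele": inc_alleles if inc_alleles is not None else ["G"] * n,
        "alpha": np.asarray(alphas, dtype=float),
        "p": pvals if pvals is not None else [1e-5] * n,
        "peak_id": [f"peak{i + 1}" for i in range(n)],
    }))


def random_ascertained(panel: FrequencyPanel, n: int,
                       rng: np.random.Generator,
                       alpha_scale: float = 0.3) -> AscertainedSet:
    """Random panel SNPs with random effect sizes and orientations —
    a null 'GWAS hit list' for calibration studies."""
    idx = rng.choice(panel.n_snps, size=n, replace=False)
    sub = panel.table.iloc[idx]
    inc = np.where(rng.random(n) < 0.5, sub["alt"], sub["ref"])
    return AscertainedSet(pd.DataFrame({
        "snp": sub["snp"].to_numpy(),
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
        "inc_allele": inc,
        "alpha": np.abs(rng.normal(0.0, alpha_scale, size=n)),
        "p": 1e-5,
        "peak_id": [f"peak{i + 1}" for i in range(n)],
    }))
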