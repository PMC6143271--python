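"""Shared domain containers for the adaptation-testing pipeline.

The in-memory lingua franca is the pandas DataFrame; the light wrappers
here exist to pin column contracts and invariants that every stage relies
on (frequency panels, ascertained SNP sets, test results).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("altadapt")

#: width of the minor-allele-frequency matching bins
MAF_BIN_WIDTH = 0.02
#: width of the background-selection (B-value) matching bins; B in [0, 1000]
BVALUE_BIN_WIDTH = 100

#: columns of a frequency panel table, before the per-population columns
PANEL_FIXED_COLUMNS = ["snp", "chrom", "pos", "ref", "alt"]
#: columns of an ascertained SNP-set table
ASCERTAINED_COLUMNS = ["snp", "chrom", "pos", "inc_allele", "alpha", "p", "peak_id"]


def maf_bin_of(maf: np.ndarray) -> np.ndarray:
    """Bin minor-allele frequencies into width-0.02 bins (0..24)."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 0.5 + 1e-12)):
        raise ValueError("minor allele frequencies must lie in [0, 0.5]")
    return np.minimum((maf / MAF_BIN_WIDTH).astype(int), 24)


def bvalue_bin_of(bvalue: np.ndarray) -> np.ndarray:
    """Bin B-values (0-1000) into width-100 bins (0..9)."""
    b = np.asarray(bvalue)
    if np.any((b < 0) | (b > 1000)):
        raise ValueError("B-values must lie in [0, 1000]")
    return np.minimum(b // BVALUE_BIN_WIDTH, 9).astype(int)


@dataclass
class FrequencyPanel:
    """Per-SNP alternate-allele frequencies across populations.

    ``table`` holds one row per SNP with columns ``snp, chrom, pos, ref,
    alt``, one frequency column per population (alt-allele frequency in
    [0, 1]), plus ``maf_bin`` (computed on the mean minor-allele frequency
    across populations), ``bvalue`` and ``bvalue_bin`` annotations.
    """

    table: pd.DataFrame
    populations: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_FIXED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        for pop in self.populations:
            if pop not in self.table.columns:
                raise ValueError(f"panel table missing population column {pop!r}")
            f = self.table[pop].to_numpy(dtype=float)
            if np.any((f < 0) | (f > 1)) or not np.all(np.isfinite(f)):
                raise ValueError(f"frequencies for {pop!r} outside [0, 1]")
        self.table = self.table.reset_index(drop=True)
        if "maf_bin" not in self.table.columns:
            self.annotate_bins()

    # -- frequency access -------------------------------------------------

    def freqs(self, populations: list[str] | None = None) -> np.ndarray:
        """Alt-allele frequency matrix, shape (n_snps, n_populations)."""
        pops = self.populations if populations is None else list(populations)
        unknown = [p for p in pops if p not in self.populations]
        if unknown:
            raise KeyError(f"unknown population(s): {unknown}")
        return self.table[pops].to_numpy(dtype=float)

    def mean_freq(self) -> np.ndarray:
        """Mean alt-allele frequency across populations, per SNP."""
        return self.freqs().mean(axis=1)

    def mean_maf(self) -> np.ndarray:
        """Mean minor-allele frequency across populations, per SNP."""
        f = self.mean_freq()
        return np.minimum(f, 1.0 - f)

    def annotate_bins(self, bvalues: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> None:
        """(Re)annotate maf bins and, if absent, B-values and their bins.

        B-values are uniform random integers in [0, 1000] unless supplied.
        """
        self.table["maf_bin"] = maf_bin_of(self.mean_maf())
        if bvalues is not None:
            self.table["bvalue"] = np.asarray(bvalues, dtype=int)
        elif "bvalue" not in self.table.columns:
            if rng is None:
                rng = np.random.default_rng(0)
            self.table["bvalue"] = rng.integers(0, 1001, size=len(self.table))
        self.table["bvalue_bin"] = bvalue_bin_of(self.table["bvalue"].to_numpy())

    def index_of(self, snp_ids) -> np.ndarray:
        """Row positions of the given SNP ids; raises on absence."""
        lookup = pd.Index(self.table["snp"])
        idx = lookup.get_indexer(pd.Index(snp_ids))
        if np.any(idx < 0):
            missing = list(np.asarray(snp_ids)[idx < 0][:5])
            raise KeyError(f"SNPs absent from panel: {missing}")
        return idx

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def copy(self) -> "FrequencyPanel":
        return FrequencyPanel(self.table.copy(), list(self.populations))


@dataclass
class AscertainedSet:
    """Independent trait-associated SNPs polarized to trait-increasing alleles.

    ``table`` columns: snp, chrom, pos, inc_allele, alpha (>= 0, phenotype
    units per trait-increasing allele), p (source association p-value),
    peak_id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ASCERTAINED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ascertained table missing columns: {missing}")
        if np.any(self.table["alpha"].to_numpy(dtype=float) < 0):
            raise ValueError("effect sizes must be polarized (alpha >= 0)")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def drop_snps(self, snp_ids) -> "AscertainedSet":
        """Return a copy without the named SNPs (e.g. a dominant-locus rerun)."""
        keep = ~self.table["snp"].isin(list(np.atleast_1d(snp_ids)))
        return AscertainedSet(self.table.loc[keep].reset_index(drop=True))


@dataclass
class KinshipMatrix:
    """Standardized genetic covariance among cohort individuals."""

    values: np.ndarray
    ids: list[str]
    n_snps_used: int = 0
    n_snps_excluded: int = 0

    def __post_init__(self) -> None:
        k = np.asarray(self.values, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = k


@dataclass
class PopulationCovariance:
    """Across-SNP covariance F of standardized allele-frequency deviations."""

    matrix: np.ndarray
    populations: list[str]
    n_snps: int

    def __post_init__(self) -> None:
        f = np.asarray(self.matrix, dtype=float)
        if f.shape != (len(self.populations), len(self.populations)):
            raise ValueError("covariance shape does not match population count")
        self.matrix = 0.5 * (f + f.T)


@dataclass
class TestResult:
    """A statistic with its empirical (and optionally parametric) p-value."""

    name: str
    statistic: float
    p_empirical: float
    n_sets: int
    p_parametric: float | None = None
    direction: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sets > 0:
            lo = 1.0 / (self.n_sets + 1)
            if not (lo - 1e-12 <= self.p_empirical <= 1.0 + 1e-12):
                raise ValueError("empirical p outside [1/(B+1), 1]")
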