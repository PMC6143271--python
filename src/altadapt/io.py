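"""File formats: frequency panels, genotype tables, VCF, phenotype TSVs.

TSV dialect: tab-separated with a header row; '.' and 'NA' are both read
as missing and 'NA' is written.  Coordinates are 1-based inclusive (VCF
convention); BED-like B-value inputs are converted on read (0-based
half-open) with a logged note.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PANEL_FIXED_COLUMNS, FrequencyPanel

logger = logging.getLogger("altadapt")

_NA_VALUES = [".", "NA"]
_ANNOTATION_COLUMNS = {"maf_bin", "bvalue", "bvalue_bin", "boundary"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=_NA_VALUES,
                       keep_default_na=False)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# frequency panels
# ---------------------------------------------------------------------------

def write_frequency_panel(panel: FrequencyPanel, path) -> None:
    _write_tsv(panel.table, path)


def read_frequency_panel(path, populations: list[str] | None = None
                         ) -> FrequencyPanel:
    """Read a frequency panel TSV.

    Population columns are inferred as all columns that are neither the
    fixed SNP columns nor bin annotations, unless given explicitly.
    Round-trips with :func:`write_frequency_panel` byte-identically on
    the frequency columns.
    """
    table = _read_tsv(path)
    if populations is None:
        populations = [c for c in table.columns
                       if c not in PANEL_FIXED_COLUMNS
                       and c not in _ANNOTATION_COLUMNS]
    return FrequencyPanel(table, list(populations))


def read_frequency_panel_vcf(vcf_path, population_map) -> FrequencyPanel:
    """Build a frequency panel from a VCF and a sample->population map.

    Frequencies are alt-allele dosage means over called alleles; missing
    genotypes ('./.') are excluded from the denominator.  ``population_map``
    is a path to a 2-column TSV (sample, population) or a dict.  Any
    population with fewer than 2 haplotypes is an error.
    """
    from cyvcf2 import VCF  # deferred: only needed on the VCF path

    if not isinstance(population_map, dict):
        pm = pd.read_csv(population_map, sep="\t", header=None,
                         names=["sample", "population"])
        population_map = dict(zip(pm["sample"], pm["population"]))
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        if s in population_map:
            pops.setdefault(population_map[s], []).append(i)
    if not pops:
        raise ValueError("no VCF sample matches the population map")
    for pop, idx in pops.items():
        if 2 * len(idx) < 2:
            raise ValueError(f"population {pop!r} has < 2 haplotypes")

    rows = []
    for n_rec, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            logger.warning("skipping non-biallelic record at %s:%d",
                           variant.CHROM, variant.POS)
            continue
        gts = np.array(variant.genotypes, dtype=int)[:, :2]  # (n_samples, 2)
        row = {
            "snp": variant.ID or f"{variant.CHROM}:{variant.POS}",
            "chrom": str(variant.CHROM), "pos": int(variant.POS),
            "ref": variant.REF, "alt": variant.ALT[0],
        }
        for pop, idx in pops.items():
            alleles = gts[idx].ravel()
            called = alleles[alleles >= 0]
            if called.size == 0:
                row[pop] = np.nan
            else:
                row[pop] = float((called == 1).sum() / called.size)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.isna().any().any():
        n_bad = int(table.isna().any(axis=1).sum())
        logger.warning("dropping %d record(s) with no called genotypes "
                       "in some population", n_bad)
        table = table.dropna().reset_index(drop=True)
    return FrequencyPanel(table, sorted(pops))


def read_bvalues_bed(path) -> pd.DataFrame:
    """Read BED-like B-value annotations (chrom, start, end, bvalue).

    BED is 0-based half-open; intervals are converted to 1-based
    inclusive coordinates on read.
    """
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "bvalue"])
    logger.info("converting BED 0-based half-open intervals to 1-based "
                "inclusive")
    bed["start"] = bed["start"] + 1
    bed["chrom"] = bed["chrom"].astype(str)
    return bed


def assign_bvalues(panel: FrequencyPanel, bed: pd.DataFrame) -> None:
    """Annotate panel SNPs with B-values from interval annotations."""
    bvals = np.full(panel.n_snps, -1, dtype=int)
    chrom = panel.table["chrom"].astype(str).to_numpy()
    pos = panel.table["pos"].to_numpy()
    for _, iv in bed.iterrows():
        hit = (chrom == str(iv["chrom"])) & (pos >= iv["start"]) \
            & (pos <= iv["end"])
        bvals[hit] = int(iv["bvalue"])
    if np.any(bvals < 0):
        raise ValueError(f"{int((bvals < 0).sum())} SNP(s) not covered by "
                         "the B-value annotation")
    panel.annotate_bins(bvalues=bvals)


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def write_genotype_tsv(genotypes: np.ndarray, ids: list[str],
                       snp_ids: list[str], path) -> None:
    """Genotype matrix as TSV: one row per individual, one column per SNP."""
    df = pd.DataFrame(genotypes, columns=snp_ids)
    df.insert(0, "id", ids)
    _write_tsv(df, path)


def read_genotype_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = _read_tsv(path)
    ids = list(df["id"])
    snps = [c for c in df.columns if c != "id"]
    return df[snps].to_numpy(dtype=float), ids, snps


def write_vcf(path, genotypes: np.ndarray, ids: list[str],
              sites: pd.DataFrame) -> None:
    """Write hard-call genotypes as an uncompressed VCF v4.2.

    ``sites`` needs columns snp, chrom, pos, ref, alt (one row per SNP,
    same order as the genotype columns).
    """
    g = np.asarray(genotypes)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j in range(len(sites)):
            row = sites.iloc[j]
            calls = [gt_strings.get(int(x), "./.") if np.isfinite(x) else "./."
                     for x in g[:, j].astype(float)]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf_genotypes(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read hard-call dosages from a VCF; missing calls become NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps, cols = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        gts = np.array(variant.genotypes, dtype=float)[:, :2]
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
        snps.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    return np.column_stack(cols), ids, snps


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path)


def write_pedigree(ped: pd.DataFrame, path) -> None:
    _write_tsv(ped[["id", "family", "role"]], path)


def write_association(assoc: pd.DataFrame, path) -> None:
    _write_tsv(assoc, path)


def read_association(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_snp_set(ascertained, path) -> None:
    _write_tsv(ascertained.table, path)


def read_snp_set(path):
    from .core import AscertainedSet

    return AscertainedSet(_read_tsv(path))


def write_results(results: list, path, seed=None) -> None:
    """Write test results as a TSV (test, statistic, p_empirical, ...)."""
    rows = []
    for res in results:
        rows.append({
            "test": res.name,
            "statistic": res.statistic,
            "p_empirical": res.p_empirical,
            "p_parametric": res.p_parametric,
            "n_sets": res.n_sets,
            "direction": res.direction,
            "seed": seed,
        })
    _write_tsv(pd.DataFrame(rows), path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
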