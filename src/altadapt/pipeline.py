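"""End-to-end pipeline driver and flat key-value configuration.

Stage order: simulate (optional) -> phenotype construction -> association
-> ascertainment -> PBS -> matched controls -> adaptation tests -> power
analysis.  All randomness flows from one global seed through named
per-stage substreams (numpy SeedSequence), so any stage re-run with its
logged substream reproduces its output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .ascertainment import lump_peaks
from .association import compute_grm, lmm_assoc
from .core import AscertainedSet
from .differentiation import pbs_scan
from .phenotypes import binomial_residual_phenotype
from .polygenic import (estimate_population_covariance, freq_diff_test,
                        genetic_values, outlier_test, overdispersion_test,
                        sample_matched_controls)
from .power import SelectionModel, min_detectable_s, power_grid
from .simulate import PopulationTree, SimulationConfig, simulate_cohort, \
    simulate_frequency_panel

logger = logging.getLogger("altadapt")

#: stage names, in execution order; also the substream labels
STAGES = ["simulate", "phenotypes", "association", "ascertainment", "pbs",
          "controls", "adaptation_tests", "power"]


@dataclass
class PipelineConfig:
    """Flat configuration of the pipeline driver.

    File paths may be empty when ``simulate`` is on; thresholds default to
    the standard analysis choices (ascertainment p <= 1e-4 with 200 kb
    lumping, maf filter 0.05, 10,000 frequency-difference null sets and
    5,000 genetic-value null sets).
    """

    # inputs (all optional when simulating)
    panel_file: str = ""
    genotype_file: str = ""
    phenotype_file: str = ""
    bvalue_file: str = ""
    # simulation
    simulate: bool = True
    tree: str = "default"
    n_snps: int = 2000
    n_individuals: int = 200
    n_relative_pairs: int = 0
    n_causal: int = 20
    effect_scale: float = 0.4
    noise_sd: float = 1.0
    family: str = "continuous"
    delta: float = 0.0
    # roles
    target: str = "TARGET"
    comparison: str = "LOW1"
    outgroup: str = "OUTGRP"
    subset: str = "TARGET"
    # thresholds
    phenotype_column: str = "phenotype"
    covariate_columns: str = "age"
    maf_min: float = 0.05
    ascertain_p: float = 1e-4
    max_gap: int = 200_000
    fallback_top_k: int = 0
    n_sets_freq: int = 10_000
    n_sets_gv: int = 5_000
    match_bvalue: bool = True
    window_bp: int = 500_000
    # power analysis
    power_wm: float = 5.67
    power_sd: float = 2.87
    power_p: float = 0.248
    power_n: int = 991
    power_alpha: float = 0.05
    power_target: float = 0.8
    # global
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` file ('#' starts a comment)."""
        values: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        kwargs = {}
        by_name = {f.name: f for f in fields(cls)}
        for key, val in values.items():
            if key not in by_name:
                raise ValueError(f"unknown config key {key!r}")
            typ = by_name[key].type
            if typ == "bool":
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif typ == "int":
                kwargs[key] = int(val)
            elif typ == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("panel_file", "genotype_file", "phenotype_file",
                     "bvalue_file"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if not self.simulate and not self.panel_file:
            raise ValueError("need a panel_file when not simulating")
        if not (0 < self.ascertain_p <= 1):
            raise ValueError("ascertain_p must lie in (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")


def _tree_from_config(config: PipelineConfig) -> PopulationTree:
    if config.tree == "default":
        return PopulationTree.default()
    if config.tree == "small":
        parent = {"root": None, "OUTGRP": "root", "ASIA": "root",
                  "LOW1": "ASIA", "HIGH": "ASIA",
                  "TARGET": "HIGH", "SISTER": "HIGH"}
        drift = {"OUTGRP": 0.04, "ASIA": 0.02, "LOW1": 0.01, "HIGH": 0.006,
                 "TARGET": 0.004, "SISTER": 0.004}
        return PopulationTree(parent=parent, drift=drift, target="TARGET",
                              comparison="LOW1", outgroup="OUTGRP",
                              groups={"highland": ["TARGET", "SISTER"]})
    raise ValueError(f"unknown tree {config.tree!r}")


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir=None,
                 timestamp: bool = True) -> dict:
    """Execute the full inference chain; returns a results bundle dict.

    Every stage's seed substream, inputs and row counts are logged;
    outputs are written as TSVs into ``out_dir`` (a timestamped directory
    under the current directory by default).
    """
    config.validate()
    if out_dir is None:
        stamp = time.strftime("%Y%m%d-%H%M%S") if timestamp else "run"
        out_dir = Path(f"altadapt-{stamp}")
    out_dir = aio.ensure_dir(out_dir)
    streams = {name: np.random.default_rng(ss) for name, ss in
               zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))}
    bundle: dict = {"out_dir": out_dir, "seed": config.seed}

    def stage(name):
        logger.info("stage %s (seed substream %s)", name, config.seed)

        def wrap(fn):
            def inner(*args, **kwargs):
                try:
                    return fn(*args, **kwargs)
                except StageFailure:
                    raise
                except Exception as err:
                    raise StageFailure(name, err) from err
            return inner
        return wrap

    # -- simulate / load ----------------------------------------------------
    run = stage("simulate")
    if config.simulate:
        tree = _tree_from_config(config)
        sim = SimulationConfig(
            n_snps=config.n_snps, n=config.n_individuals,
            n_relative_pairs=config.n_relative_pairs,
            n_causal=config.n_causal, effect_scale=config.effect_scale,
            noise_sd=config.noise_sd, family=config.family,
            delta=config.delta, seed=config.seed)
        panel = run(simulate_frequency_panel)(tree, sim,
                                              rng=streams["simulate"])
        cohort = run(simulate_cohort)(panel, config.target, sim,
                                      rng=streams["simulate"])
        aio.write_frequency_panel(panel, out_dir / "panel.tsv")
        aio.write_genotype_tsv(cohort["genotypes"], cohort["ids"],
                               cohort["snp_ids"], out_dir / "genotypes.tsv")
        aio.write_phenotypes(cohort["phenotypes"], out_dir / "phenotypes.tsv")
        aio.write_pedigree(cohort["pedigree"], out_dir / "pedigree.tsv")
    else:
        panel = run(aio.read_frequency_panel)(config.panel_file)
        geno, ids, snps = run(aio.read_genotype_tsv)(config.genotype_file)
        cohort = {"genotypes": geno, "ids": ids, "snp_ids": snps,
                  "phenotypes": run(aio.read_phenotypes)(config.phenotype_file)}
    if config.bvalue_file:
        bed = run(aio.read_bvalues_bed)(config.bvalue_file)
        run(aio.assign_bvalues)(panel, bed)
    bundle["panel"] = panel
    logger.info("panel: %d SNPs x %d populations", panel.n_snps,
                len(panel.populations))

    # -- phenotype construction --------------------------------------------
    run = stage("phenotypes")
    pheno_table = cohort["phenotypes"]
    covars = [c.strip() for c in config.covariate_columns.split(",") if c.strip()]
    if config.family == "binomial":
        resid = run(binomial_residual_phenotype)(
            pheno_table["successes"], pheno_table["trials"],
            pheno_table[covars] if covars else None)
        pheno_table = pheno_table.assign(phenotype=resid)
        y_col = "phenotype"
    else:
        y_col = config.phenotype_column
    y = pheno_table[y_col].to_numpy(dtype=float)
    w = pheno_table[covars].to_numpy(dtype=float) if covars else None

    # -- association --------------------------------------------------------
    run = stage("association")
    geno = np.asarray(cohort["genotypes"], dtype=float)
    kinship = run(compute_grm)(geno, ids=cohort["ids"], maf_min=config.maf_min)
    assoc = run(lmm_assoc)(y, w, geno, kinship, snp_ids=cohort["snp_ids"],
                           maf_min=config.maf_min)
    site_cols = panel.table.set_index("snp").loc[assoc["snp"],
                                                 ["chrom", "pos"]]
    assoc.insert(1, "chrom", site_cols["chrom"].to_numpy())
    assoc.insert(2, "pos", site_cols["pos"].to_numpy())
    aio.write_association(assoc, out_dir / "association.tsv")
    bundle["association"] = assoc
    logger.info("association: %d records", len(assoc))

    # -- ascertainment -------------------------------------------------------
    run = stage("ascertainment")
    ascertained = run(lump_peaks)(assoc, p_threshold=config.ascertain_p,
                                  max_gap=config.max_gap)
    if len(ascertained) < config.fallback_top_k:
        # greedy top-k by p with the same independence gap, so the
        # adaptation tests always have a working SNP set on small runs
        logger.warning("only %d SNP(s) at p <= %g; topping up to %d "
                       "distance-separated SNPs by smallest p",
                       len(ascertained), config.ascertain_p,
                       config.fallback_top_k)
        chosen: list[int] = []
        taken = ascertained.table[["chrom", "pos"]]
        occupied = list(zip(taken["chrom"], taken["pos"]))
        for row in assoc.sort_values("p_lrt").itertuples():
            if len(occupied) >= config.fallback_top_k:
                break
            if all(c != row.chrom or abs(p - row.pos) > config.max_gap
                   for c, p in occupied):
                occupied.append((row.chrom, row.pos))
                chosen.append(row.Index)
        if chosen:
            extra = assoc.loc[chosen].copy()
            extra = extra.rename(columns={"p_lrt": "p"})
            from .ascertainment import _polarize
            extra["p_lrt"] = extra["p"]
            extra = _polarize(extra)
            extra["peak_id"] = [f"topup{i + 1}" for i in range(len(extra))]
            cols = ["snp", "chrom", "pos", "inc_allele", "alpha", "p",
                    "peak_id"]
            merged = pd.concat([ascertained.table, extra[cols]],
                               ignore_index=True)
            ascertained = AscertainedSet(merged)
    aio.write_snp_set(ascertained, out_dir / "ascertained.tsv")
    bundle["ascertained"] = ascertained
    logger.info("ascertained: %d independent SNP(s)", len(ascertained))

    # -- PBS -----------------------------------------------------------------
    run = stage("pbs")
    pbs_table, windows = run(pbs_scan)(panel, config.target,
                                       config.comparison, config.outgroup,
                                       window_bp=config.window_bp)
    aio.write_association(pbs_table, out_dir / "pbs.tsv")
    aio.write_association(windows, out_dir / "pbs_windows.tsv")
    bundle["pbs"] = pbs_table

    # -- adaptation tests ----------------------------------------------------
    results = []
    if len(ascertained) > 0:
        run = stage("controls")
        seed_freq = int(streams["controls"].integers(2 ** 31))
        seed_gv = int(streams["controls"].integers(2 ** 31))
        controls_freq = run(sample_matched_controls)(
            ascertained, panel, n_sets=config.n_sets_freq,
            match_bvalue=False, maf_source="mean", seed=seed_freq)
        controls_gv = run(sample_matched_controls)(
            ascertained, panel, n_sets=config.n_sets_gv,
            match_bvalue=config.match_bvalue, maf_source=config.target,
            seed=seed_gv)
        logger.info("controls: %d + %d matched sets (seeds %d, %d)",
                    config.n_sets_freq, config.n_sets_gv, seed_freq, seed_gv)

        run = stage("adaptation_tests")
        fcov = run(estimate_population_covariance)(
            panel, exclude_snps=ascertained.table["snp"])
        results.append(run(freq_diff_test)(
            ascertained, panel, config.target, config.comparison,
            controls_freq, direction="lower"))
        results.append(run(overdispersion_test)(
            ascertained, panel, fcov, controls_gv))
        subset = [s.strip() for s in config.subset.split(",") if s.strip()]
        results.append(run(outlier_test)(
            ascertained, panel, subset, fcov, controls_gv))
        bundle["genetic_values"] = run(genetic_values)(ascertained, panel)
        aio.write_results(results, out_dir / "adaptation_tests.tsv",
                          seed=config.seed)
        null_dump = pd.DataFrame({
            "freq_diff_null": pd.Series(results[0].extra["null_means"]),
            "overdispersion_null": pd.Series(results[1].extra["null_q"]),
            "outlier_null": pd.Series(results[2].extra["null_stats"]),
        })
        null_dump.to_csv(out_dir / "null_distributions.tsv", sep="\t",
                         index=False, na_rep="NA")
    else:
        logger.warning("empty ascertained set: adaptation tests skipped")
    bundle["tests"] = results

    # -- power ---------------------------------------------------------------
    run = stage("power")
    model = SelectionModel(p=config.power_p, w_m=config.power_wm,
                           sd=config.power_sd, n=config.power_n,
                           alpha_level=config.power_alpha)
    s_min = run(min_detectable_s)(model, target_power=config.power_target)
    grid = run(power_grid)(model, np.linspace(0.0, max(2 * s_min, 0.01), 21))
    grid.to_csv(out_dir / "power.tsv", sep="\t", index=False)
    bundle["min_detectable_s"] = s_min
    logger.info("minimum detectable s at %.0f%% power: %.4f",
                100 * config.power_target, s_min)
    return bundle
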