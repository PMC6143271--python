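"""Synthetic frequency panels, cohorts and phenotypes.

The generator emulates the data structure the downstream tests assume:
populations related by a drift tree (with a high-altitude pair nested in a
regional group), biallelic SNP panels with maf structure, a cohort with
cryptic relatedness, and continuous / count / binomial-proportion
phenotypes, plus an optional directional selection shift on one branch.

Drift is modelled per branch as a truncated Gaussian perturbation with
variance c * p(1-p), matching the multivariate-normal null of the
genetic-value machinery: for leaves i, j the covariance of standardized
frequency deviations equals the summed drift c over their shared branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import AscertainedSet, FrequencyPanel

logger = logging.getLogger("altadapt")

_MAX_PANEL_RETRIES = 50


# ---------------------------------------------------------------------------
# population tree
# ---------------------------------------------------------------------------

@dataclass
class PopulationTree:
    """Populations related by a rooted drift tree.

    ``parent`` maps node label -> parent label (root maps to None);
    ``drift`` maps node label -> the drift amount c (>= 0) on the branch
    above it.  ``target``, ``comparison`` and ``outgroup`` designate the
    leaf roles used by the branch statistic; ``groups`` optionally names
    regional leaf groupings (e.g. a high-altitude pair).
    """

    parent: dict[str, str | None]
    drift: dict[str, float]
    target: str
    comparison: str
    outgroup: str
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        for n, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"unknown parent {p!r} for node {n!r}")
        for n in self.parent:
            c = self.drift.get(n, 0.0)
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"branch drift for {n!r} must be finite and >= 0")
        leaves = self.leaves
        for role, name in (("target", self.target), ("comparison", self.comparison),
                           ("outgroup", self.outgroup)):
            if name not in leaves:
                raise ValueError(f"{role} {name!r} is not a leaf")
        if len({self.target, self.comparison, self.outgroup}) != 3:
            raise ValueError("target/comparison/outgroup must be distinct leaves")

    @property
    def leaves(self) -> list[str]:
        parents = {p for p in self.parent.values() if p is not None}
        return [n for n in self.parent if n not in parents]

    def path_to_root(self, node: str) -> list[str]:
        path = []
        while node is not None:
            path.append(node)
            node = self.parent[node]
        return path

    def traversal_order(self) -> list[str]:
        """Nodes ordered parent-before-child."""
        order, seen = [], set()
        pending = list(self.parent)
        while pending:
            nxt = [n for n in pending
                   if self.parent[n] is None or self.parent[n] in seen]
            if not nxt:
                raise ValueError("cyclic parent links")
            order.extend(nxt)
            seen.update(nxt)
            pending = [n for n in pending if n not in seen]
        return order

    def shared_drift_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Closed-form leaf covariance of standardized frequency deviations.

        Entry (i, j) is the total drift c on branches shared by the
        root-to-leaf paths of leaves i and j.
        """
        leaves = self.leaves
        paths = {lf: set(self.path_to_root(lf)) - {self.root} for lf in leaves}
        cov = np.zeros((len(leaves), len(leaves)))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                cov[i, j] = sum(self.drift.get(n, 0.0)
                                for n in paths[a] & paths[b])
        return cov, leaves

    @classmethod
    def default(cls, c_scale: float = 1.0) -> "PopulationTree":
        """Six-leaf tree: an outgroup, three lowland populations, and a
        high-altitude pair nested inside the regional (Asian-like) clade."""
        parent = {
            "root": None,
            "OUTGRP": "root",
            "ASIA": "root",
            "LOW1": "ASIA", "LOW2": "ASIA", "LOW3": "ASIA",
            "HIGH": "ASIA",
            "TARGET": "HIGH", "SISTER": "HIGH",
        }
        drift = {
            "OUTGRP": 0.04 * c_scale,
            "ASIA": 0.02 * c_scale,
            "LOW1": 0.008 * c_scale, "LOW2": 0.008 * c_scale,
            "LOW3": 0.008 * c_scale,
            "HIGH": 0.006 * c_scale,
            "TARGET": 0.004 * c_scale, "SISTER": 0.004 * c_scale,
        }
        return cls(parent=parent, drift=drift, target="TARGET",
                   comparison="LOW1", outgroup="OUTGRP",
                   groups={"highland": ["TARGET", "SISTER"]})


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator.

    Panel: ``n_snps`` SNPs, ancestral frequencies Uniform(anc_low,
    anc_high) (defaults keep most SNPs past a maf >= 0.05 filter), SNPs on
    one synthetic chromosome at uniform ``spacing_bp``.  Selection:
    ``delta`` (>= 0) is the per-unit-effect frequency displacement on
    ``selected_branch``.  Cohort: ``n`` individuals of which
    ``n_relative_pairs`` pairs share a parent; phenotype with ``n_causal``
    causal SNPs, per-allele effects of scale ``effect_scale``, covariate
    effects and Gaussian noise of SD ``noise_sd``; family one of
    continuous | count | binomial.
    """

    n_snps: int = 20_000
    anc_low: float = 0.05
    anc_high: float = 0.95
    maf_floor: float = 0.0
    spacing_bp: int = 5_000
    chrom: str = "1"
    delta: float = 0.0
    selected_branch: str | None = None
    n: int = 500
    n_relative_pairs: int = 0
    n_causal: int = 40
    effect_scale: float = 0.25
    covariate_effects: tuple[float, ...] = (0.02, 0.0)
    noise_sd: float = 1.0
    family: str = "continuous"
    binomial_trials_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.delta < 0:
            raise ValueError("selection shift delta must be >= 0")
        if not (0 <= self.anc_low < self.anc_high <= 1):
            raise ValueError("ancestral frequency range invalid")
        if self.family not in ("continuous", "count", "binomial"):
            raise ValueError(f"unknown phenotype family {self.family!r}")


# ---------------------------------------------------------------------------
# frequency panel
# ---------------------------------------------------------------------------

def _drift_once(tree: PopulationTree, anc: np.ndarray,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    freqs = {tree.root: anc}
    for node in tree.traversal_order():
        if node == tree.root:
            continue
        p = freqs[tree.parent[node]]
        c = tree.drift.get(node, 0.0)
        if c == 0.0:
            freqs[node] = p.copy()
        else:
            sd = np.sqrt(c * p * (1.0 - p))
            freqs[node] = np.clip(p + rng.normal(0.0, 1.0, size=p.shape) * sd,
                                  0.0, 1.0)
    return freqs


def simulate_frequency_panel(tree: PopulationTree, config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             bvalues: np.ndarray | None = None) -> FrequencyPanel:
    """Simulate a frequency panel under the tree's truncated-Gaussian drift.

    Ancestral frequencies are drawn uniformly, then perturbed branch by
    branch with variance c * p(1-p).  SNPs fixed in every leaf (and SNPs
    below ``maf_floor`` on the across-leaf mean maf) are dropped and
    resampled until ``n_snps`` segregating SNPs exist.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    leaves = tree.leaves
    kept: list[np.ndarray] = []
    n_kept = 0
    for attempt in range(_MAX_PANEL_RETRIES):
        need = config.n_snps - n_kept
        if need <= 0:
            break
        # oversample to absorb the (rare) fixed-everywhere losses
        n_draw = max(int(need * 1.1) + 10, need)
        anc = rng.uniform(config.anc_low, config.anc_high, size=n_draw)
        freqs = _drift_once(tree, anc, rng)
        leaf_mat = np.column_stack([freqs[lf] for lf in leaves])
        segregating = ~(np.all(leaf_mat == 0.0, axis=1)
                        | np.all(leaf_mat == 1.0, axis=1))
        if config.maf_floor > 0:
            mean = leaf_mat.mean(axis=1)
            segregating &= np.minimum(mean, 1 - mean) >= config.maf_floor
        block = leaf_mat[segregating]
        kept.append(block)
        n_kept += len(block)
    else:
        raise RuntimeError("could not obtain the requested number of "
                           "segregating SNPs within the retry budget")
    mat = np.concatenate(kept, axis=0)[: config.n_snps]
    pos = (np.arange(config.n_snps) + 1) * config.spacing_bp
    table = pd.DataFrame({
        "snp": [f"snp{i + 1}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos": pos,
        "ref": "A",
        "alt": "G",
    })
    for j, lf in enumerate(leaves):
        table[lf] = mat[:, j]
    panel = FrequencyPanel(table, leaves)
    panel.annotate_bins(bvalues=bvalues, rng=rng)
    return panel


def inject_selection_shift(panel: FrequencyPanel, effects: AscertainedSet,
                           branch: str, delta: float) -> FrequencyPanel:
    """Shift trait-increasing allele frequencies on one leaf.

    Each effect SNP's trait-increasing allele frequency on ``branch`` moves
    by +delta * |alpha| / max|alpha|, clipped to [0, 1]; clipped SNPs are
    flagged in a ``boundary`` column.  All other SNPs and leaves are
    untouched.  ``delta = 0`` is the identity.
    """
    if branch not in panel.populations:
        raise KeyError(f"unknown leaf {branch!r}")
    out = panel.copy()
    if delta == 0 or len(effects) == 0:
        return out
    idx = out.index_of(effects.table["snp"])
    alpha = effects.table["alpha"].to_numpy(dtype=float)
    amax = np.max(np.abs(alpha))
    scale = np.abs(alpha) / amax if amax > 0 else np.zeros_like(alpha)
    disp = delta * scale
    f = out.table[branch].to_numpy(dtype=float)
    inc_is_alt = (effects.table["inc_allele"].to_numpy()
                  == out.table["alt"].to_numpy()[idx])
    signed = np.where(inc_is_alt, disp, -disp)
    shifted = f[idx] + signed
    clipped = (shifted < 0.0) | (shifted > 1.0)
    f[idx] = np.clip(shifted, 0.0, 1.0)
    out.table[branch] = f
    boundary = np.zeros(out.n_snps, dtype=bool)
    boundary[idx[clipped]] = True
    out.table["boundary"] = boundary
    if np.any(clipped):
        logger.info("selection shift clipped %d SNP(s) at a frequency boundary",
                    int(clipped.sum()))
    # shifted SNPs may have changed maf bin; keep annotations consistent
    out.table["maf_bin"] = out.table["maf_bin"].astype(int)
    out.annotate_bins(bvalues=out.table["bvalue"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _draw_genotypes(freq: np.ndarray, n: int, n_relative_pairs: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Genotypes for n individuals; the first 2*k individuals form k
    relative pairs sharing a parent (half-sib style: each member receives
    one allele transmitted from the common parent, chosen independently
    per SNP, expected standardized-GRM entry 0.25)."""
    n_snps = freq.shape[0]
    if 2 * n_relative_pairs > n:
        raise ValueError("more relative pairs than individuals allow")
    geno = np.empty((n, n_snps), dtype=np.int8)
    ped = pd.DataFrame({"id": [f"ind{i + 1}" for i in range(n)],
                        "family": ["-"] * n, "role": ["unrelated"] * n})
    for k in range(n_relative_pairs):
        parent_hap = rng.random((2, n_snps)) < freq  # the shared parent's alleles
        for member in range(2):
            pick = rng.integers(0, 2, size=n_snps)
            transmitted = parent_hap[pick, np.arange(n_snps)]
            other = rng.random(n_snps) < freq
            geno[2 * k + member] = transmitted.astype(np.int8) + other.astype(np.int8)
            ped.loc[2 * k + member, ["family", "role"]] = [f"fam{k + 1}", "pair"]
    n_rel = 2 * n_relative_pairs
    if n > n_rel:
        draws = rng.random((n - n_rel, n_snps, 2)) < freq[None, :, None]
        geno[n_rel:] = draws.sum(axis=2, dtype=np.int8)
    return geno, ped


def simulate_cohort(panel: FrequencyPanel, focal_population: str,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> dict:
    """Simulate genotypes, pedigree, phenotypes and covariates.

    Returns a dict with keys ``genotypes`` (n x n_snps int array),
    ``ids``, ``snp_ids``, ``pedigree``, ``phenotypes`` (DataFrame with the
    phenotype, covariates and, for the binomial family, successes/trials)
    and ``true_effects`` (the generating per-allele effects, for recovery
    tests).
    """
    if focal_population not in panel.populations:
        raise KeyError(f"unknown focal population {focal_population!r}")
    if config.n < 2:
        raise ValueError("cohort size must be >= 2")
    if config.n_causal > panel.n_snps:
        raise ValueError("more causal SNPs than panel SNPs")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freq = panel.table[focal_population].to_numpy(dtype=float)
    geno, ped = _draw_genotypes(freq, config.n, config.n_relative_pairs, rng)

    causal_idx = (rng.choice(panel.n_snps, size=config.n_causal, replace=False)
                  if config.n_causal > 0 else np.array([], dtype=int))
    alpha = rng.normal(0.0, config.effect_scale, size=config.n_causal)

    age = rng.normal(55.0, 10.0, size=config.n)
    altitude = rng.normal(3600.0, 250.0, size=config.n)
    covs = np.column_stack([age, altitude])
    gamma = np.asarray(config.covariate_effects, dtype=float)[: covs.shape[1]]
    linpred = covs[:, : gamma.size] @ gamma
    if config.n_causal > 0:
        linpred = linpred + geno[:, causal_idx].astype(float) @ alpha

    pheno = pd.DataFrame({"id": ped["id"], "age": age, "altitude": altitude})
    if config.family == "continuous":
        pheno["phenotype"] = linpred + rng.normal(0.0, config.noise_sd, config.n)
    elif config.family == "count":
        y = linpred + rng.normal(0.0, config.noise_sd, config.n)
        pheno["phenotype"] = np.maximum(np.round(y), 0.0)
    else:  # binomial
        trials = 1 + rng.poisson(config.binomial_trials_mean, size=config.n)
        center = linpred - linpred.mean()
        prob = expit(center / max(config.noise_sd, 1e-12))
        successes = rng.binomial(trials, prob)
        pheno["trials"] = trials
        pheno["successes"] = successes
        pheno["phenotype"] = successes / trials

    true_effects = pd.DataFrame({
        "snp": panel.table["snp"].to_numpy()[causal_idx],
        "alpha": alpha,
    })
    return {
        "genotypes": geno,
        "ids": list(ped["id"]),
        "snp_ids": list(panel.table["snp"]),
        "pedigree": ped,
        "phenotypes": pheno,
        "true_effects": true_effects,
    }
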