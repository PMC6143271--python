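"""Selection coefficients, effect sizes and association power.

Under an additive fitness model, genotypes with 0, 1 and 2 copies of an
adaptive allele at population frequency p have mean fitness W0, W0(1+s)
and W0(1+2s).  Given the observed mean of a fitness-proxy phenotype W_m,
the per-allele phenotype effect implied by selection coefficient s is

    s W0 = s W_m / (1 + 2 s p).

Standardizing by the phenotype SD and using the Hardy-Weinberg genotype
variance 2p(1-p) gives the genotype-phenotype correlation
r = (effect / SD) * sqrt(2p(1-p)), whose two-sided correlation-test power
at sample size n is computed with the bias-corrected Fisher-z
approximation (a noncentral-t variant is available).  Inverting the
forward map yields the minimum selection coefficient detectable at a
target power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class SelectionModel:
    """Inputs of the selection-to-power mapping.

    p: adaptive allele frequency; w_m: observed phenotype mean (fitness
    proxy, phenotype units); sd: phenotype SD (same units); n: sample
    size; alpha_level: test size.
    """

    p: float
    w_m: float
    sd: float
    n: int
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("allele frequency must lie in [0, 1]")
        if self.sd <= 0:
            raise ValueError("phenotype SD must be positive")
        if self.n < 3:
            raise ValueError("sample size must be >= 3")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")


def selection_to_effect(s: float, model: SelectionModel) -> float:
    """Per-allele phenotype effect s * W_m / (1 + 2 s p)."""
    denom = 1.0 + 2.0 * s * model.p
    if denom <= 0:
        raise ValueError("1 + 2 s p must be positive")
    return s * model.w_m / denom


def correlation_power(r: float, n: int, alpha_level: float = 0.05,
                      method: str = "fisher-z") -> float:
    """Power of the two-sided test of zero correlation at true r.

    ``fisher-z`` (default) uses the bias-corrected Fisher transform of
    the critical correlation; ``noncentral-t`` evaluates the noncentral-t
    tail of the t-statistic of r.
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    df = n - 2
    t_crit = stats.t.isf(alpha_level / 2.0, df)
    if method == "fisher-z":
        r_crit = np.sqrt(t_crit ** 2 / (t_crit ** 2 + df))
        zr = np.arctanh(r) + r / (2.0 * (n - 1))
        zc = np.arctanh(r_crit)
        scale = np.sqrt(n - 3)
        return float(stats.norm.cdf((zr - zc) * scale)
                     + stats.norm.cdf((-zr - zc) * scale))
    if method == "noncentral-t":
        ncp = r * np.sqrt(n) / np.sqrt(1.0 - r ** 2)
        return float(stats.nct.sf(t_crit, df, ncp)
                     + stats.nct.cdf(-t_crit, df, ncp))
    raise ValueError(f"unknown method {method!r}")


def effect_to_power(effect: float, model: SelectionModel,
                    method: str = "fisher-z") -> float:
    """Power to detect a per-allele effect in a correlation test.

    The standardized effect effect/SD implies a genotype-phenotype
    correlation r = (effect/SD) * sqrt(2p(1-p)) under Hardy-Weinberg.
    """
    beta_std = effect / model.sd
    r = beta_std * np.sqrt(2.0 * model.p * (1.0 - model.p))
    return correlation_power(r, model.n, model.alpha_level, method=method)


def selection_to_power(s: float, model: SelectionModel,
                       method: str = "fisher-z") -> float:
    """Forward map: selection coefficient -> association-test power."""
    return effect_to_power(selection_to_effect(s, model), model, method=method)


def min_detectable_s(model: SelectionModel, target_power: float = 0.8,
                     method: str = "fisher-z", s_max: float = 10.0) -> float:
    """Smallest s >= 0 whose implied association power reaches the target.

    Found by bracketed root finding on the (monotone) forward power curve
    to relative tolerance 1e-6; deterministic.
    """
    if not model.alpha_level < target_power < 1:
        raise ValueError("target power must lie in (alpha_level, 1)")

    def gap(s: float) -> float:
        try:
            pw = selection_to_power(s, model, method=method)
        except ValueError:
            pw = 1.0  # |r| >= 1: the association is deterministic
        return pw - target_power

    if gap(s_max) < 0:
        raise ValueError(f"target power unreachable within s in [0, {s_max}]")
    if gap(0.0) >= 0:
        return 0.0
    return float(optimize.brentq(gap, 0.0, s_max, rtol=1e-10, xtol=1e-12))


def power_grid(model: SelectionModel, s_values,
               method: str = "fisher-z"):
    """Tabulate (s, per-allele effect, power) over a grid of s values."""
    import pandas as pd

    rows = []
    for s in np.asarray(s_values, dtype=float):
        eff = selection_to_effect(float(s), model)
        rows.append({"s": float(s), "effect": eff,
                     "power": effect_to_power(eff, model, method=method)})
    return pd.DataFrame(rows)
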