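"""Composite and residualized phenotype construction.

Two constructions: the oxygenated/deoxygenated hemoglobin split
(oxyHb = Hb * SaO2 / 100, deoxyHb = Hb - oxyHb, both in g/dL), and the
log-odds residual phenotype for binomial proportion traits (e.g. the
proportion of live births among pregnancies), where a binomial GLM with a
logit link is fitted on covariates and each woman's residual is her
observed log-odds minus the fitted log-odds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("altadapt")

#: Haldane-Anscombe continuity correction applied to observed odds so that
#: all-success and all-failure proportions stay finite
CONTINUITY_CORRECTION = 0.5


def derive_oxy_deoxy(hb, sao2, ids=None):
    """Split total hemoglobin into oxygenated and deoxygenated parts.

    oxyHb = hb * sao2 / 100 and deoxyHb = hb - oxyHb, so that
    oxyHb + deoxyHb == hb exactly.  Records with hb < 0 or sao2 outside
    [0, 100] are rejected (NaN in the output) and logged by identifier.

    Parameters
    ----------
    hb : array-like
        Total hemoglobin concentration, g/dL.
    sao2 : array-like
        Percent arterial oxygen saturation, in [0, 100].
    ids : array-like, optional
        Record identifiers used in rejection log messages.

    Returns
    -------
    (oxyhb, deoxyhb) : pair of ndarrays, g/dL.
    """
    hb = np.asarray(hb, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    scalar = hb.ndim == 0
    hb, sao2 = np.atleast_1d(hb), np.atleast_1d(sao2)
    bad = (hb < 0) | (sao2 < 0) | (sao2 > 100) | ~np.isfinite(hb) | ~np.isfinite(sao2)
    if np.any(bad):
        labels = (np.asarray(ids)[bad] if ids is not None
                  else np.flatnonzero(bad))
        for lab in np.atleast_1d(labels):
            logger.warning("rejected out-of-range Hb/SaO2 record %s", lab)
    oxy = hb * sao2 / 100.0
    deoxy = hb - oxy
    oxy[bad] = np.nan
    deoxy[bad] = np.nan
    if scalar:
        return float(oxy[0]), float(deoxy[0])
    return oxy, deoxy


def _drop_collinear(design: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that are linear combinations of earlier ones."""
    x = design.to_numpy(dtype=float)
    keep, rank = [], 0
    for j in range(x.shape[1]):
        if np.linalg.matrix_rank(x[:, keep + [j]], tol=1e-8) > rank:
            keep.append(j)
            rank += 1
        else:
            logger.warning("dropping collinear covariate column %r",
                           design.columns[j])
    return design.iloc[:, keep]


def binomial_residual_phenotype(successes, trials, covariates=None,
                                add_intercept: bool = True) -> np.ndarray:
    """Log-odds-scale residuals of a binomial regression on covariates.

    A binomial GLM (logit link, per-individual trials as the binomial
    denominator) of successes/trials on the covariates is fitted; the
    residual is the observed log-odds minus the fitted log-odds, with a
    0.5 continuity correction on observed counts so boundary proportions
    (0% and 100%) remain finite.  Individuals with trials = 0 must be
    excluded beforehand.

    Categorical covariate columns are one-hot expanded; collinear columns
    are dropped with a warning.

    Returns the residual vector (log-odds units); its mean is ~0.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if np.any(t <= 0):
        raise ValueError("individuals with trials = 0 must be excluded")
    if np.any(s < 0) or np.any(s > t):
        raise ValueError("need 0 <= successes <= trials")

    if covariates is None:
        design = pd.DataFrame(index=np.arange(len(s)))
    else:
        design = pd.DataFrame(covariates).reset_index(drop=True)
        design = pd.get_dummies(design, drop_first=True, dtype=float)
    if add_intercept:
        design.insert(0, "const", 1.0)
    if design.shape[1] == 0:
        raise ValueError("empty design: need an intercept or covariates")
    design = _drop_collinear(design)

    if np.allclose(s / t, (s / t)[0]):
        logger.warning("all outcomes identical: residuals have zero variance")

    endog = np.column_stack([s, t - s])
    model = sm.GLM(endog, design.to_numpy(dtype=float),
                   family=sm.families.Binomial())
    try:
        fit = model.fit()
    except Exception as err:  # pragma: no cover - statsmodels-internal failures
        raise RuntimeError(f"binomial regression did not converge: {err}")
    if not fit.converged:
        raise RuntimeError("binomial regression did not converge")

    c = CONTINUITY_CORRECTION
    observed_logodds = np.log((s + c) / (t - s + c))
    fitted_logodds = design.to_numpy(dtype=float) @ fit.params
    return observed_logodds - fitted_logodds
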