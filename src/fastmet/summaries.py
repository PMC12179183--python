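"""Genetic-parameter summaries: heritability, CV, correlations, crossover G x E.

Per-environment precision statistics come from single-trial fits
(generalized heritability in the Cullis sense, and the residual
coefficient of variation); between-environment structure comes from the
selected multi-environment FA fit (genetic correlations and the crossover
share of the G x E interaction against a compound-symmetry baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fa import CSFit, SingleEnvFit, fit_single_env_lmm

__all__ = [
    "cullis_h2", "env_cv", "genetic_correlations", "crossover_share",
    "environment_summary", "GeneticCorrelationMatrix", "CrossoverDecomposition",
]


def cullis_h2(fit: SingleEnvFit) -> float:
    """Generalized heritability H2 = 1 - vbar_Delta / (2 sigma2_g).

    ``vbar_Delta`` is the mean prediction error variance of BLUP
    differences over all genotype pairs, which stays valid under
    unbalance.  Requires a random-genotype single-trial fit; a zero
    genetic variance returns 0 by convention.
    """
    if fit.genotype_role != "random":
        raise ValueError("cullis_h2 needs a random-genotype fit")
    s2g = fit.sigma2_g or 0.0
    if s2g <= 0:
        warnings.warn("zero genetic variance: H2 = 0 by convention")
        return 0.0
    P = fit.pev
    v = P.shape[0]
    diag = np.diag(P)
    # mean over pairs of PEV(u_i - u_j) = P_ii + P_jj - 2 P_ij
    vbar = 2.0 * (v * diag.sum() - P.sum()) / (v * (v - 1))
    return float(np.clip(1.0 - vbar / (2.0 * s2g), 0.0, 1.0))


def env_cv(fit: SingleEnvFit) -> float:
    """Residual coefficient of variation sigma_e / mu of one trial."""
    if fit.mu_hat == 0:
        raise ValueError("environment mean is zero; CV undefined")
    return float(np.sqrt(fit.sigma2_e) / fit.mu_hat)


@dataclass
class GeneticCorrelationMatrix:
    """Between-environment genetic correlations from an FA fit."""

    matrix: pd.DataFrame          # t x t, unit diagonal
    env_stats: pd.DataFrame       # per-environment mean and SD of off-diagonals

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="environment")


def genetic_correlations(rotated) -> GeneticCorrelationMatrix:
    """Correlation matrix D G D with D = diag(1/sqrt(diag G)).

    ``G`` is the implied genetic covariance of the rotated FA solution.
    Also reports each environment's mean and SD of its correlations with
    the other environments — a quick screen for trials driving crossover
    interaction.
    """
    G = np.asarray(rotated.genetic_covariance, dtype=float)
    d = np.diag(G)
    if np.any(d <= 0):
        raise ValueError("zero or negative genetic variance in some environment")
    Dm = 1.0 / np.sqrt(d)
    rho = G * Dm[:, None] * Dm[None, :]
    np.fill_diagonal(rho, 1.0)
    envs = list(rotated.env_codes)
    mat = pd.DataFrame(rho, index=envs, columns=envs)
    t = len(envs)
    off = rho.copy()
    np.fill_diagonal(off, np.nan)
    stats = pd.DataFrame({
        "mean_corr": np.nanmean(off, axis=1),
        "sd_corr": np.nanstd(off, axis=1, ddof=1) if t > 2 else np.full(t, np.nan),
    }, index=envs)
    return GeneticCorrelationMatrix(matrix=mat, env_stats=stats)


@dataclass
class CrossoverDecomposition:
    """Split of the G x E variance into heterogeneity and crossover parts."""

    sigma2_ge: float
    heterogeneity: float          # dispersion of per-environment genetic scale
    crossover_share: float        # in [0, 1]
    heterogeneity_of: str         # "sd" or "variance"


def crossover_share(fa_env_variances: np.ndarray, cs_fit: CSFit,
                    heterogeneity: str = "sd", ddof: int = 1) -> CrossoverDecomposition:
    """Crossover share of G x E: 1 - dispersion(scale_t) / sigma2_ge.

    The G x E variance ``sigma2_ge`` comes from the compound-symmetry
    baseline; the heterogeneity term is the dispersion across environments
    of the per-environment genetic scale — by default the variance of the
    genetic standard deviations ``sqrt(sigma2_gt)`` (the scale on which
    the classical heterogeneity / lack-of-correlation decomposition
    operates), with ``heterogeneity="variance"`` switching to the variance
    of the variances.  Sample (n-1) dispersion by default.  The share is
    clamped to [0, 1]: equal genetic variances give exactly 1 (pure
    crossover), heterogeneity exceeding sigma2_ge clamps to 0.
    """
    s2_ge = float(cs_fit.gxe_variance)
    if s2_ge <= 0:
        raise ValueError("sigma2_ge must be positive")
    s2_gt = np.asarray(fa_env_variances, dtype=float)
    if s2_gt.ndim != 1 or len(s2_gt) < 2:
        raise ValueError("need per-environment genetic variances for >= 2 environments")
    if heterogeneity == "sd":
        het = float(np.var(np.sqrt(s2_gt), ddof=ddof))
    elif heterogeneity == "variance":
        het = float(np.var(s2_gt, ddof=ddof))
    else:
        raise ValueError("heterogeneity must be 'sd' or 'variance'")
    share = 1.0 - het / s2_ge
    if share < 0:
        warnings.warn("heterogeneity exceeds sigma2_ge; crossover share clamped to 0")
    return CrossoverDecomposition(
        sigma2_ge=s2_ge, heterogeneity=het,
        crossover_share=float(np.clip(share, 0.0, 1.0)),
        heterogeneity_of=heterogeneity,
    )


def environment_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-environment mean yield, Cullis H2, CV and variance components.

    Fits the random-genotype single-trial model in every environment;
    trials that cannot be fitted (e.g. a single block) are excluded with a
    warning.
    """
    rows = {}
    for env, sub in table.groupby("environment", sort=True):
        try:
            fit = fit_single_env_lmm(sub, genotype_role="random")
        except ValueError as err:
            warnings.warn(f"environment {env} excluded: {err}")
            continue
        rows[env] = {
            "mean_yield": fit.mu_hat,
            "h2": cullis_h2(fit),
            "cv": env_cv(fit),
            "sigma2_g": fit.sigma2_g,
            "sigma2_e": fit.sigma2_e,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "environment"
    return out
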