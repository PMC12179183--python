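"""Two-stage regression of environment mean yield on environmental features.

Stage one fits each trial separately (genotype fixed, replication random)
and averages the genotype eBLUEs into an environment-level adjusted mean;
stage two regresses those adjusted means on standardized environmental
features by ordinary least squares, ranking features by the size and
significance of their coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fa import fit_single_env_lmm

__all__ = ["env_adjusted_means", "fit_env_regression", "EnvYieldRegression"]


def env_adjusted_means(table: pd.DataFrame) -> pd.Series:
    """Environment-level adjusted mean yields.

    For each environment the single-trial model (genotype fixed,
    replication random) is fitted and the mean of the genotype eBLUEs is
    taken as the adjusted mean.  Environments that cannot be fitted (e.g.
    a single replicate) are excluded with a warning.
    """
    means = {}
    for env, sub in table.groupby("environment", sort=True):
        try:
            fit = fit_single_env_lmm(sub, genotype_role="fixed")
        except ValueError as err:
            warnings.warn(f"environment {env} excluded from adjusted means: {err}")
            continue
        means[env] = float(fit.effects.mean())
    if not means:
        raise ValueError("no environment could be fitted")
    out = pd.Series(means, name="adjusted_mean")
    out.index.name = "environment"
    return out


@dataclass
class EnvYieldRegression:
    """OLS fit of environment mean yield on environmental features."""

    intercept: float
    coefficients: pd.DataFrame    # beta, se, t, p, significant per feature
    residuals: pd.Series
    response: pd.Series
    r_squared: float
    model: object                 # statsmodels results, for diagnostics

    def ranked(self) -> pd.DataFrame:
        """Features ordered by absolute coefficient size."""
        return self.coefficients.reindex(
            self.coefficients["beta"].abs().sort_values(ascending=False).index)


def fit_env_regression(adjusted_means: pd.Series, features: pd.DataFrame,
                       feature_subset: list[str] | None = None,
                       alpha: float = 0.05,
                       collinearity_threshold: float | None = 0.9
                       ) -> EnvYieldRegression:
    """Multiple linear regression of adjusted environment means on features.

    ``features`` should be standardized (see
    :func:`fastmet.enviro.zscore_standardize`); rows are aligned to the
    response by environment code.  Collinear features are removed first
    (|r| > ``collinearity_threshold``; pass ``None`` to skip), which keeps
    a full feature set fittable with modest environment counts.  Raises on
    rank-deficient designs, naming the aliased features.
    """
    X = features if feature_subset is None else features[list(feature_subset)]
    common = adjusted_means.index.intersection(X.index)
    if len(common) == 0:
        raise ValueError("no overlapping environments between means and features")
    y = adjusted_means.loc[common].astype(float)
    X = X.loc[common].astype(float)
    if collinearity_threshold is not None:
        from .enviro import filter_collinear

        X, _ = filter_collinear(X, collinearity_threshold)
    if len(common) <= X.shape[1] + 1:
        raise ValueError(
            f"{len(common)} environments cannot support {X.shape[1]} features; "
            "filter features first")

    Xd = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        aliased = _aliased_columns(Xd)
        raise ValueError(f"rank-deficient design; aliased features: {aliased}")

    res = sm.OLS(y, Xd).fit()
    coefs = pd.DataFrame({
        "beta": res.params.drop("const"),
        "se": res.bse.drop("const"),
        "t": res.tvalues.drop("const"),
        "p": res.pvalues.drop("const"),
    })
    coefs["significant"] = coefs["p"] < alpha
    return EnvYieldRegression(
        intercept=float(res.params["const"]),
        coefficients=coefs,
        residuals=res.resid,
        response=y,
        r_squared=float(res.rsquared),
        model=res,
    )


def _aliased_columns(Xd: pd.DataFrame) -> list[str]:
    """Columns that add no rank beyond the preceding ones."""
    out = []
    M = Xd.to_numpy()
    rank = 0
    for j, name in enumerate(Xd.columns):
        r = np.linalg.matrix_rank(M[:, :j + 1])
        if r == rank:
            out.append(name)
        rank = r
    return out
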