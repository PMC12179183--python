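"""Comparing FA(k) fits: deviance, parameter counts, explained variance, ASVR.

The working rule for choosing the factor order balances explanatory power
and parsimony: the smallest k whose overall explained variance and average
semi-variance ratio (ASVR) both reach a threshold (80% by default) is
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "deviance", "count_fa_parameters", "explained_variance", "asvr",
    "select_model", "ModelSelectionSummary", "summarize_models",
]


def deviance(loglik: float) -> float:
    """Deviance D = -2 log L."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    return -2.0 * float(loglik)


def count_fa_parameters(t: int, k: int) -> int:
    """Number of genetic variance parameters of an FA(k) model for t environments.

    ``t*k`` loadings minus ``k(k-1)/2`` rotational constraints plus ``t``
    specific variances.  ``k = 0`` counts the diagonal model (variances only).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if not (0 <= k < t):
        raise ValueError(f"need 0 <= k < t, got k={k}, t={t}")
    return t * k - k * (k - 1) // 2 + t


def explained_variance(rotated) -> tuple[pd.DataFrame, float]:
    """Per-environment per-factor explained genetic variance, in percent.

    For rotated loadings ``lambda_kt`` with factor variances ``d_k`` and
    specific variances ``psi_t``::

        v_kt = 100 * lambda_kt^2 d_k / (sum_k lambda_kt^2 d_k + psi_t)

    Returns the t x K table of ``v_kt`` and the overall percentage — the
    unweighted mean over environments of the per-environment totals.
    """
    U = np.asarray(rotated.U, dtype=float)
    L = np.asarray(rotated.L, dtype=float)
    psi = np.asarray(rotated.psi, dtype=float)
    if np.any(psi < 0):
        raise ValueError("specific variances must be non-negative")
    num = U**2 * L[None, :]                       # t x K
    denom = num.sum(axis=1) + psi                 # t
    with np.errstate(invalid="ignore", divide="ignore"):
        vkt = 100.0 * num / denom[:, None]
    vkt = np.where(denom[:, None] > 0, vkt, 0.0)
    table = pd.DataFrame(vkt, index=list(rotated.env_codes),
                         columns=[f"factor_{j + 1}" for j in range(U.shape[1])])
    overall = float(table.sum(axis=1).mean())
    return table, overall


def _avg_semivariance(mat: np.ndarray) -> float:
    """Average pairwise semi-variance 0.5*(m_tt + m_t't') - m_tt' over pairs."""
    t = mat.shape[0]
    diag = np.diag(mat)
    iu = np.triu_indices(t, 1)
    vals = 0.5 * (diag[iu[0]] + diag[iu[1]]) - mat[iu]
    return float(vals.mean())


def asvr(rotated) -> float:
    """Average semi-variance ratio, percent.

    Share of the average pairwise semi-variance of the implied genetic
    covariance captured by its low-rank (common-factor) part.
    """
    U = np.asarray(rotated.U, dtype=float)
    L = np.asarray(rotated.L, dtype=float)
    psi = np.asarray(rotated.psi, dtype=float)
    t = U.shape[0]
    if t < 2:
        raise ValueError("ASVR needs at least 2 environments")
    B = (U * L[None, :]) @ U.T
    G = B + np.diag(psi)
    den = _avg_semivariance(G)
    if den == 0:
        raise ValueError("degenerate genetic covariance: zero average semi-variance")
    return 100.0 * _avg_semivariance(B) / den


@dataclass
class ModelSelectionSummary:
    """Per-k fit summaries plus the selected factor order."""

    table: pd.DataFrame            # rows per k: loglik, deviance, n_params, var_pct, asvr_pct
    selected_k: int
    var_threshold: float
    asvr_threshold: float
    warning: str | None = None

    def to_frame(self) -> pd.DataFrame:
        """Summary shaped like a model-comparison report table."""
        out = self.table.copy()
        out.insert(0, "model", [f"M{k}" for k in out.index])
        return out


def select_model(summaries: pd.DataFrame | dict, var_threshold: float = 80.0,
                 asvr_threshold: float = 80.0) -> ModelSelectionSummary:
    """Select the most parsimonious FA order meeting both thresholds.

    ``summaries`` maps k to at least ``var_pct`` and ``asvr_pct`` (extra
    columns such as ``loglik``/``deviance``/``n_params`` are carried
    through).  Returns the smallest k whose explained variance and ASVR
    both reach their thresholds; if none qualifies, the largest k is
    returned with a warning.
    """
    if isinstance(summaries, dict):
        table = pd.DataFrame(summaries).T
    else:
        table = summaries.copy()
    if len(table) == 0:
        raise ValueError("no model summaries given")
    table = table.sort_index()
    ok = (table["var_pct"] >= var_threshold) & (table["asvr_pct"] >= asvr_threshold)
    warning = None
    if ok.any():
        selected = int(table.index[ok][0])
    else:
        selected = int(table.index[-1])
        warning = (f"no model reached var% >= {var_threshold} and "
                   f"ASVR% >= {asvr_threshold}; returning largest k={selected}")
        warnings.warn(warning)
    return ModelSelectionSummary(table=table, selected_k=selected,
                                 var_threshold=var_threshold,
                                 asvr_threshold=asvr_threshold, warning=warning)


def summarize_models(fits: dict, rotations: dict | None = None) -> pd.DataFrame:
    """Build the model-comparison table from FA fits keyed by k.

    Explained variance and ASVR are computed from each fit's rotated form
    (rotating on the fly when not supplied).
    """
    from .fast import rotate_loadings

    rows = {}
    for k, fit in sorted(fits.items()):
        rot = (rotations or {}).get(k) or rotate_loadings(fit)
        _, var_pct = explained_variance(rot)
        rows[k] = {
            "loglik": fit.loglik,
            "deviance": deviance(fit.loglik),
            "n_params": count_fa_parameters(len(fit.env_order), k),
            "var_pct": var_pct,
            "asvr_pct": asvr(rot),
        }
    return pd.DataFrame(rows).T
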