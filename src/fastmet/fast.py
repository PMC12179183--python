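"""Factor Analytic Selection Tools (FAST).

The constrained FA solution is rotated by SVD into loadings ``Lambda = U``
(orthonormal columns) with factor variances ``D = L`` sorted decreasing;
the first factor then carries the genotype main effects (overall
performance, OP) and the remaining factors carry the G x E deviations that
feed the stability (RMSD), responsiveness and reliability statistics, and
finally the combined FAST index used to rank genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fa import FAFit

__all__ = [
    "RotatedFA", "FASTResult", "rotate_loadings", "overall_performance",
    "stability_rmsd", "responsiveness", "reliability", "fast_index",
    "fast_summary",
]


@dataclass
class RotatedFA:
    """SVD-rotated FA solution: Lambda* = U L^(1/2) V'.

    ``U`` (t x k) holds the rotated loadings, ``L`` the factor variances
    (squared singular values, decreasing), ``rotated_scores`` (v x k) the
    correspondingly transformed score BLUPs.  The first loading column's
    sign is chosen so its mean is non-negative (an overall-performance
    factor).  ``beta_tilde`` is the genetic fit from all factors except the
    first — the deviations from the first-factor latent regression.
    """

    U: np.ndarray
    L: np.ndarray
    V: np.ndarray
    rotated_scores: np.ndarray
    psi: np.ndarray
    env_codes: list[str]
    genotype_ids: list[str]
    delta: np.ndarray                  # v x t lack-of-fit BLUPs
    fitted_genetic: np.ndarray         # v x t: rotated factors + delta
    beta_tilde: np.ndarray             # v x t: factors 2..K (delta optional)
    include_delta_in_beta: bool = False

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def genetic_covariance(self) -> np.ndarray:
        return (self.U * self.L[None, :]) @ self.U.T + np.diag(self.psi)


def rotate_loadings(fit: FAFit, include_delta_in_beta: bool = False) -> RotatedFA:
    """Rotate a constrained FA fit to the orthonormal-loading form.

    The rotation preserves the implied genetic covariance and the fitted
    genetic effects exactly; it only re-parameterizes loadings and scores.
    """
    lam = np.asarray(fit.loadings_constrained, dtype=float)
    t, k = lam.shape
    if k < 1:
        raise ValueError("rotation needs at least one factor")
    U, s, Vt = np.linalg.svd(lam, full_matrices=False)
    V = Vt.T
    if s[0] > 0 and np.any(s < 1e-10 * s[0]):
        eff = int(np.sum(s >= 1e-10 * s[0]))
        warnings.warn(f"loading matrix is rank deficient: effective k = {eff}")
    L = s**2
    scores = np.asarray(fit.scores_constrained, dtype=float) @ V * s[None, :]
    if U[:, 0].mean() < 0:
        U = U.copy()
        V = V.copy()
        U[:, 0] *= -1
        V[:, 0] *= -1
        scores[:, 0] *= -1
    delta = np.asarray(fit.lack_of_fit, dtype=float)
    fitted = scores @ U.T + delta
    beta = scores[:, 1:] @ U[:, 1:].T
    if include_delta_in_beta:
        beta = beta + delta
    return RotatedFA(
        U=U, L=L, V=V, rotated_scores=scores,
        psi=np.asarray(fit.specific_variances, dtype=float),
        env_codes=list(fit.env_order), genotype_ids=list(fit.genotype_order),
        delta=delta, fitted_genetic=fitted, beta_tilde=beta,
        include_delta_in_beta=include_delta_in_beta,
    )


def overall_performance(rotated: RotatedFA) -> pd.Series:
    """OP_v: mean first-factor loading times the genotype's first-factor score."""
    op = rotated.U[:, 0].mean() * rotated.rotated_scores[:, 0]
    return pd.Series(op, index=rotated.genotype_ids, name="OP")


def stability_rmsd(rotated: RotatedFA, method: str = "rms") -> pd.Series:
    """RMSD_v: size of the deviations from the first-factor latent regression.

    ``method="rms"`` (default) is the root mean square of the deviations —
    the quantity the name defines; ``method="literal"`` reproduces the
    plain mean of the deviations for audit purposes.
    """
    dev = rotated.beta_tilde
    if method == "rms":
        vals = np.sqrt(np.mean(dev**2, axis=1))
    elif method == "literal":
        vals = np.mean(dev, axis=1)
    else:
        raise ValueError("method must be 'rms' or 'literal'")
    return pd.Series(vals, index=rotated.genotype_ids, name="RMSD")


def responsiveness(rotated: RotatedFA, factor_k: int) -> pd.Series:
    """RE_vk: spread between positive- and negative-loading environments
    on factor k, times the genotype's score on that factor.

    ``factor_k`` is 1-based and must be at least 2 (the first factor is
    overall performance).  An empty sign group contributes zero.
    """
    if factor_k < 2 or factor_k > rotated.k:
        raise ValueError(f"factor_k must be in 2..{rotated.k}")
    lam = rotated.U[:, factor_k - 1]
    pos = lam[lam > 0]
    neg = lam[lam < 0]
    spread = (pos.mean() if pos.size else 0.0) - (neg.mean() if neg.size else 0.0)
    re = spread * rotated.rotated_scores[:, factor_k - 1]
    return pd.Series(re, index=rotated.genotype_ids, name=f"RE_{factor_k}")


def reliability(fit: FAFit, rotated: RotatedFA | None = None) -> pd.Series:
    """R_v = 1 - PEV_v / mean genetic variance, clamped to [0, 1].

    ``PEV_v`` is the mean over environments of the genotype's prediction
    error variance.
    """
    sigma2_g_bar = float(np.mean(fit.env_genetic_variances))
    if sigma2_g_bar <= 0:
        raise ValueError("mean genetic variance must be positive")
    pev_v = fit.pev_mean_by_genotype()
    r = np.clip(1.0 - pev_v / sigma2_g_bar, 0.0, 1.0)
    return pd.Series(r, index=fit.genotype_order, name="reliability")


def fast_index(op: pd.Series, rmsd: pd.Series, rel: pd.Series) -> pd.Series:
    """FAST_v = (2 z(OP_v) - z(RMSD_v)) * R_v.

    OP and RMSD are standardized across genotypes; performance gets twice
    the weight of stability, and the whole contrast is discounted by the
    reliability of the genotype's predictions.
    """
    if len(op) < 2:
        raise ValueError("need at least 2 genotypes")
    sd_op = float(op.std(ddof=1))
    sd_rmsd = float(rmsd.std(ddof=1))
    if sd_op == 0 or sd_rmsd == 0:
        raise ValueError("zero spread in OP or RMSD across genotypes")
    z_op = (op - op.mean()) / sd_op
    z_rmsd = (rmsd - rmsd.mean()) / sd_rmsd
    out = (2.0 * z_op - z_rmsd) * rel
    out.name = "FAST"
    return out


@dataclass
class FASTResult:
    """Per-genotype FAST selection statistics."""

    table: pd.DataFrame          # OP, RMSD, RE_2..RE_K, reliability, FAST
    deviations: pd.DataFrame     # v x t deviations from the first-factor regression

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("FAST", ascending=False).head(n)


def fast_summary(fit: FAFit, rotated: RotatedFA | None = None,
                 rmsd_method: str = "rms") -> FASTResult:
    """Compute all FAST statistics for a fitted FA model."""
    rot = rotated or rotate_loadings(fit)
    op = overall_performance(rot)
    rmsd = stability_rmsd(rot, method=rmsd_method)
    rel = reliability(fit, rot)
    cols = {"OP": op, "RMSD": rmsd}
    for j in range(2, rot.k + 1):
        cols[f"RE_{j}"] = responsiveness(rot, j)
    cols["reliability"] = rel
    cols["FAST"] = fast_index(op, rmsd, rel)
    table = pd.DataFrame(cols)
    table.index.name = "genotype"
    dev = pd.DataFrame(rot.beta_tilde, index=rot.genotype_ids,
                       columns=rot.env_codes)
    return FASTResult(table=table, deviations=dev)
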