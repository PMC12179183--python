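"""REML machinery for MET mixed models with genotype-in-environment effects.

The model is ``y = X tau + Z g + eps`` where the fixed part holds an
intercept, environment effects and block-within-environment effects, ``g``
stacks one random effect per genotype-in-environment cell with covariance
``G (x) I_v`` (``G`` any positive-definite t x t matrix: factor analytic,
compound symmetry or diagonal), and residuals are independent with a
per-environment variance.

Likelihood evaluations exploit the structure heavily: the coefficient
matrix of the absorbed mixed-model equations is block diagonal by genotype
(one t x t block each), so a REML log-likelihood costs
``O(v t^3 + v t p^2)`` rather than anything cubic in the number of plots.
All quantities needed (log-determinants, the profiled quadratic form,
BLUPs, prediction error variances) come from the same decomposition:

``-2 l_R = (n-p) log 2 pi + log|R| + v log|G| + log|M| + log|S| + y' P y``

with ``M`` the block-diagonal absorbed random-effect matrix and
``S = X' V^-1 X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = ["METDesign", "neg2_reml", "solve_mme", "MMESolution"]

_LOG2PI = float(np.log(2.0 * np.pi))

REQUIRED_COLUMNS = ("environment", "genotype", "block", "yield")


class METDesign:
    """Pre-digested design arrays for a long-format trial table.

    Rows with missing yield are dropped (REML handles unbalance natively).
    Environment and genotype levels are taken in sorted order so that every
    downstream estimate is invariant to the row order of the input table.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"trial table lacks columns: {missing}")
        tab = table.loc[np.isfinite(pd.to_numeric(table["yield"], errors="coerce"))]
        if len(tab) == 0:
            raise ValueError("no observations with finite yield")

        self.env_codes = np.unique(tab["environment"].astype(str))
        self.genotype_ids = np.unique(tab["genotype"].astype(str))
        self.t = len(self.env_codes)
        self.v = len(self.genotype_ids)
        env_idx = pd.Categorical(tab["environment"].astype(str),
                                 categories=self.env_codes).codes.astype(np.intp)
        gen_idx = pd.Categorical(tab["genotype"].astype(str),
                                 categories=self.genotype_ids).codes.astype(np.intp)
        y = tab["yield"].to_numpy(dtype=float)
        block = tab["block"].to_numpy()
        self.n = len(y)
        self.y = y
        self.env_idx = env_idx
        self.gen_idx = gen_idx

        for j in range(self.t):
            sel = env_idx == j
            if len(np.unique(gen_idx[sel])) < 2:
                raise ValueError(
                    f"environment {self.env_codes[j]} has fewer than 2 genotypes")

        # fixed-effect design: intercept + env (drop first) + block-in-env (drop first)
        cols: list[np.ndarray] = [np.ones(self.n)]
        names: list[str] = ["intercept"]
        for j in range(1, self.t):
            cols.append((env_idx == j).astype(float))
            names.append(f"env[{self.env_codes[j]}]")
        for j in range(self.t):
            sel = env_idx == j
            blocks = np.unique(block[sel])
            for b in blocks[1:]:
                cols.append((sel & (block == b)).astype(float))
                names.append(f"block[{self.env_codes[j]}:{b}]")
        X = np.column_stack(cols)
        self.X = X
        self.fixed_names = names
        self.p = X.shape[1]

        # per-environment sufficient statistics
        self.n_env = np.bincount(env_idx, minlength=self.t).astype(float)
        self.XtX_env = np.empty((self.t, self.p, self.p))
        self.Xty_env = np.empty((self.t, self.p))
        self.yty_env = np.empty(self.t)
        for j in range(self.t):
            sel = env_idx == j
            Xe, ye = X[sel], y[sel]
            self.XtX_env[j] = Xe.T @ Xe
            self.Xty_env[j] = Xe.T @ ye
            self.yty_env[j] = ye @ ye

        # per-cell (genotype x environment) sufficient statistics
        v, t, p = self.v, self.t, self.p
        self.counts = np.zeros((v, t))
        self.ysum = np.zeros((v, t))
        self.y2sum = np.zeros((v, t))
        self.Xsum = np.zeros((v, t, p))
        np.add.at(self.counts, (gen_idx, env_idx), 1.0)
        np.add.at(self.ysum, (gen_idx, env_idx), y)
        np.add.at(self.y2sum, (gen_idx, env_idx), y * y)
        np.add.at(self.Xsum, (gen_idx, env_idx), X)

    def cell_means(self) -> np.ndarray:
        """v x t matrix of raw genotype-in-environment means (NaN if unobserved)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.ysum / self.counts, np.nan)

    def connected_components(self) -> list[np.ndarray]:
        """Groups of environments linked by shared genotypes."""
        occ = self.counts > 0
        adj = occ.T @ occ > 0
        seen = np.zeros(self.t, dtype=bool)
        comps = []
        for s in range(self.t):
            if seen[s]:
                continue
            stack, comp = [s], []
            seen[s] = True
            while stack:
                i = stack.pop()
                comp.append(i)
                nxt = np.where(adj[i] & ~seen)[0]
                seen[nxt] = True
                stack.extend(nxt.tolist())
            comps.append(np.sort(np.asarray(comp)))
        return comps


def _chol_logdet(a: np.ndarray) -> tuple[np.ndarray, float]:
    c = np.linalg.cholesky(a)
    return c, 2.0 * float(np.sum(np.log(np.diagonal(c, axis1=-2, axis2=-1))))


def neg2_reml(design: METDesign, G: np.ndarray | None,
              sigma2_eps: np.ndarray) -> float:
    """-2 x REML log-likelihood of the MET model.

    ``G`` is the t x t between-environment genetic covariance (``None`` or a
    zero matrix means no genetic effects, i.e. a fixed-effects-only model);
    ``sigma2_eps`` holds the per-environment residual variances.  Raises
    ``np.linalg.LinAlgError`` if ``G`` is not positive definite.
    """
    d = design
    sigma2_eps = np.broadcast_to(np.asarray(sigma2_eps, dtype=float), (d.t,))
    if np.any(sigma2_eps <= 0):
        raise ValueError("residual variances must be positive")
    w = 1.0 / sigma2_eps

    yRy = float(w @ d.yty_env)
    XtRX = np.tensordot(w, d.XtX_env, axes=1)
    XtRy = w @ d.Xty_env
    logdetR = float(np.sum(d.n_env * np.log(sigma2_eps)))

    if G is not None and not np.any(np.abs(G) > 0):
        G = None
    if G is None:
        cS, logdetS = _chol_logdet(XtRX)
        beta = sla.cho_solve((cS, True), XtRy)
        yPy = yRy - XtRy @ beta
        return ((d.n - d.p) * _LOG2PI + logdetR + logdetS + yPy)

    cG, logdetG = _chol_logdet(G)
    Ginv = sla.cho_solve((cG, True), np.eye(d.t))

    D = d.counts * w                                  # (v, t)
    M = np.broadcast_to(Ginv, (d.v, d.t, d.t)).copy()
    idx = np.arange(d.t)
    M[:, idx, idx] += D
    cM, logdetM = _chol_logdet(M)

    b = d.ysum * w                                    # (v, t)
    A = d.Xsum * w[None, :, None]                     # (v, t, p)
    rhs = np.concatenate([b[:, :, None], A], axis=2)  # (v, t, p+1)
    Minv = np.linalg.inv(M)                           # batched; faster than solve
    sol = Minv @ rhs
    Mib, MiA = sol[:, :, 0], sol[:, :, 1:]

    p = d.p
    S = XtRX - A.reshape(-1, p).T @ MiA.reshape(-1, p)
    u = XtRy - A.reshape(-1, p).T @ Mib.reshape(-1)
    q = yRy - float(b.ravel() @ Mib.ravel())

    cS, logdetS = _chol_logdet(S)
    beta = sla.cho_solve((cS, True), u)
    yPy = q - float(u @ beta)

    return ((d.n - d.p) * _LOG2PI + logdetR + d.v * logdetG
            + logdetM + logdetS + yPy)


def neg2_reml_grad(design: METDesign, G: np.ndarray,
                   sigma2_eps: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """-2 REML log-likelihood with its exact derivatives.

    Returns ``(value, Q, resid_grad)`` where ``Q`` (t x t) gives the
    gradient with respect to any parameterization of ``G`` via
    ``d(-2l)/d alpha = tr(Q dG/d alpha)``, and ``resid_grad`` holds
    ``d(-2l)/d sigma2_eps_t``.  Uses the standard REML derivative
    ``tr(P dV) - y'P dV P y`` evaluated through the genotype-block
    structure, so the gradient costs about one extra likelihood
    evaluation.
    """
    d = design
    sigma2_eps = np.broadcast_to(np.asarray(sigma2_eps, dtype=float), (d.t,))
    if np.any(sigma2_eps <= 0):
        raise ValueError("residual variances must be positive")
    w = 1.0 / sigma2_eps

    yRy = float(w @ d.yty_env)
    XtRX = np.tensordot(w, d.XtX_env, axes=1)
    XtRy = w @ d.Xty_env
    logdetR = float(np.sum(d.n_env * np.log(sigma2_eps)))

    cG, logdetG = _chol_logdet(G)
    Ginv = sla.cho_solve((cG, True), np.eye(d.t))
    D = d.counts * w                                   # (v, t)
    M = np.broadcast_to(Ginv, (d.v, d.t, d.t)).copy()
    idx = np.arange(d.t)
    M[:, idx, idx] += D
    cM, logdetM = _chol_logdet(M)
    Minv = np.linalg.inv(M)

    b = d.ysum * w
    A = d.Xsum * w[None, :, None]
    Mib = np.einsum("vij,vj->vi", Minv, b)
    MiA = Minv @ A

    p = d.p
    S = XtRX - A.reshape(-1, p).T @ MiA.reshape(-1, p)
    u = XtRy - A.reshape(-1, p).T @ Mib.reshape(-1)
    q = yRy - float(b.ravel() @ Mib.ravel())
    cS, logdetS = _chol_logdet(S)
    Sinv = sla.cho_solve((cS, True), np.eye(p))
    beta = Sinv @ u
    yPy = q - float(u @ beta)
    value = ((d.n - d.p) * _LOG2PI + logdetR + d.v * logdetG
             + logdetM + logdetS + yPy)

    # --- gradient pieces ---------------------------------------------------
    # blocks of Z'V^-1 Z, Z'V^-1 X and Z'P y per genotype, in the
    # cancellation-free forms  D M^-1 G^-1,  G^-1 M^-1 A  and  G^-1 ghat
    ghat = Mib - np.einsum("vtp,p->vt", MiA, beta)
    W_sum = np.einsum("vt,vts->ts", D, Minv) @ Ginv    # sum_v D_v M_v^-1 G^-1
    F = Ginv @ MiA                                     # (v, t, p)
    e = ghat @ Ginv                                    # (v, t) blocks of Z'Py

    FS = F @ Sinv                                      # (v, t, p)
    T = W_sum - np.einsum("vtp,vsp->ts", FS, F, optimize=True)
    Q = T - e.T @ e                                    # tr(Q dG) gives G-gradients
    Q = 0.5 * (Q + Q.T)

    # residual-variance gradients
    resid = d.y - d.X @ beta - ghat[d.gen_idx, d.env_idx]
    rss_env = np.bincount(d.env_idx, weights=resid**2, minlength=d.t)

    minv_diag = Minv[:, idx, idx]                      # (v, t)
    tr_vinv = d.n_env * w - w**2 * (d.counts * minv_diag).sum(axis=0)
    # sum over observations in each environment of x~' S^-1 x~
    xsx = np.einsum("tij,ij->t", d.XtX_env, Sinv)
    SMiA = MiA @ Sinv                                  # (v, t, p)
    cross = np.einsum("vtp,vtp->t", d.Xsum, SMiA)
    quad_cell = np.einsum("vtp,vtp->vt", MiA, SMiA)
    xsx = xsx - 2.0 * cross + (d.counts * quad_cell).sum(axis=0)
    resid_grad = tr_vinv - w**2 * xsx - w**2 * rss_env

    return value, Q, resid_grad


@dataclass
class MMESolution:
    """Solved mixed-model equations at fixed variance parameters."""

    beta: np.ndarray              # fixed-effect estimates (p,)
    beta_cov: np.ndarray          # (X' V^-1 X)^-1
    ghat: np.ndarray              # BLUPs of genotype-in-environment effects (v, t)
    pev: np.ndarray               # per-genotype PEV blocks (v, t, t)
    neg2_loglik: float
    fixed_names: list[str] = field(default_factory=list)


def solve_mme(design: METDesign, G: np.ndarray,
              sigma2_eps: np.ndarray) -> MMESolution:
    """BLUPs and prediction error variances at given variance parameters.

    The PEV blocks are the genotype-wise t x t diagonal blocks of the
    inverse mixed-model coefficient matrix, i.e. they account for the
    uncertainty in the fixed effects.
    """
    d = design
    sigma2_eps = np.broadcast_to(np.asarray(sigma2_eps, dtype=float), (d.t,))
    w = 1.0 / sigma2_eps

    yRy = float(w @ d.yty_env)
    XtRX = np.tensordot(w, d.XtX_env, axes=1)
    XtRy = w @ d.Xty_env
    logdetR = float(np.sum(d.n_env * np.log(sigma2_eps)))

    cG, logdetG = _chol_logdet(G)
    Ginv = sla.cho_solve((cG, True), np.eye(d.t))
    D = d.counts * w
    M = np.broadcast_to(Ginv, (d.v, d.t, d.t)).copy()
    idx = np.arange(d.t)
    M[:, idx, idx] += D
    cM, logdetM = _chol_logdet(M)
    Minv = np.linalg.inv(M)

    b = d.ysum * w
    A = d.Xsum * w[None, :, None]
    Mib = np.einsum("vij,vj->vi", Minv, b)
    MiA = Minv @ A

    S = XtRX - A.reshape(-1, d.p).T @ MiA.reshape(-1, d.p)
    u = XtRy - A.reshape(-1, d.p).T @ Mib.reshape(-1)
    q = yRy - float(b.ravel() @ Mib.ravel())

    cS, logdetS = _chol_logdet(S)
    beta = sla.cho_solve((cS, True), u)
    Sinv = sla.cho_solve((cS, True), np.eye(d.p))
    yPy = q - float(u @ beta)

    ghat = Mib - np.einsum("vtp,p->vt", MiA, beta)
    pev = Minv + np.einsum("vip,pq,vjq->vij", MiA, Sinv, MiA, optimize=True)

    neg2 = ((d.n - d.p) * _LOG2PI + logdetR + d.v * logdetG
            + logdetM + logdetS + yPy)
    return MMESolution(beta=beta, beta_cov=Sinv, ghat=ghat, pev=pev,
                       neg2_loglik=neg2, fixed_names=list(design.fixed_names))
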