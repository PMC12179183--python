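"""Fitting factor analytic, compound-symmetry and single-trial mixed models.

All fits use REML.  The multi-environment fitters share the structured
likelihood in :mod:`fastmet.reml` and maximize it with a bounded
quasi-Newton optimizer over log-variances and free loadings; loadings are
started from an eigen-decomposition of the genotype-mean covariance and
variances from per-cell moments, which puts the optimizer close to the
optimum on typical trial data.

Identifiability follows the usual constrained parameterization: for k > 1
the upper triangle of the loading matrix is fixed at zero and factor
scores have identity prior covariance; the rotated (SVD) parameterization
is recovered afterwards by :func:`fastmet.fast.rotate_loadings`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize

from .reml import METDesign, neg2_reml, neg2_reml_grad, solve_mme

__all__ = [
    "FAParams", "FAFit", "CSFit", "SingleEnvFit", "FitOptions",
    "reml_loglik", "fit_fa_model", "fit_cs_model", "fit_single_env_lmm",
]

_PSI_MIN = 1e-8          # lower bound on specific variances (keeps G invertible)
_LOGV_LO, _LOGV_HI = -40.0, 30.0


@dataclass
class FitOptions:
    """Optimizer controls for the MET fitters."""

    max_iter: int = 500
    ftol: float = 1e-11          # relative log-likelihood change
    gtol: float = 1e-6
    maxcor: int = 60             # L-BFGS memory; high values pay off here
    restarts: int = 2            # extra optimizer runs from the last solution
    psi_min: float = _PSI_MIN    # on the standardized-data scale
    rescale: bool = True         # standardize yields internally


@dataclass
class FAParams:
    """A complete variance-parameter set for the FA MET model."""

    loadings: np.ndarray            # t x k
    specific_variances: np.ndarray  # (t,)
    residual_variances: np.ndarray  # (t,)

    def genetic_covariance(self) -> np.ndarray:
        lam = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if lam.size == 0:
            lam = np.zeros((len(self.specific_variances), 0))
        return lam @ lam.T + np.diag(np.asarray(self.specific_variances, float))


def reml_loglik(table: pd.DataFrame | METDesign, params: FAParams,
                k: int | None = None) -> float:
    """REML log-likelihood of the MET model at the given parameters.

    The fixed effects (intercept, environments, blocks-in-environments) are
    profiled out by the REML criterion itself.  ``params`` may describe a
    model with zero genetic variance (all loadings and specific variances
    zero), in which case the value reduces to the fixed-effects-only REML
    log-likelihood.
    """
    design = table if isinstance(table, METDesign) else METDesign(table)
    lam = np.atleast_2d(np.asarray(params.loadings, dtype=float))
    if lam.size and lam.shape[0] != design.t:
        raise ValueError("loadings rows must match number of environments")
    if k is not None and lam.size and lam.shape[1] != k:
        raise ValueError("loadings columns must match k")
    psi = np.asarray(params.specific_variances, dtype=float)
    G = params.genetic_covariance()
    if not np.any(np.abs(G) > 0):
        G = None
    elif np.any(psi < 0):
        raise ValueError("specific variances must be non-negative")
    return -0.5 * neg2_reml(design, G, params.residual_variances)


# ---------------------------------------------------------------------------
# FA(k) model


@dataclass
class FAFit:
    """A converged (or flagged) FA(k) REML fit of a MET trial table."""

    k: int
    env_order: list[str]
    genotype_order: list[str]
    loadings_constrained: np.ndarray     # t x k, upper triangle zero for k > 1
    specific_variances: np.ndarray       # (t,)
    residual_variances: np.ndarray       # (t,)
    fixed_effects: pd.Series
    scores_constrained: np.ndarray       # v x k BLUPs of factor scores
    lack_of_fit: np.ndarray              # v x t BLUPs of delta
    blups: np.ndarray                    # v x t BLUPs of genetic effects g
    pev: np.ndarray                      # v x t PEV of genotype-in-env effects
    pev_blocks: np.ndarray               # v x t x t PEV blocks
    loglik: float
    n_params: int                        # estimated variance parameters (incl. residuals)
    converged: bool
    n_iter: int
    message: str = ""
    opt_trace: list[float] = field(default_factory=list)
    disconnected_groups: list[list[str]] = field(default_factory=list)

    @property
    def genetic_covariance(self) -> np.ndarray:
        """Implied G = Lambda* Lambda*' + diag(Psi)."""
        return (self.loadings_constrained @ self.loadings_constrained.T
                + np.diag(self.specific_variances))

    @property
    def env_genetic_variances(self) -> np.ndarray:
        return np.diag(self.genetic_covariance)

    def pev_mean_by_genotype(self) -> np.ndarray:
        """Mean over environments of each genotype's prediction error variance."""
        return self.pev.mean(axis=1)

    def to_json(self, path) -> None:
        """Serialize the fit (arrays as nested lists; PEV blocks omitted)."""
        import json

        d = {
            "k": self.k, "env_order": self.env_order,
            "genotype_order": self.genotype_order,
            "loadings_constrained": self.loadings_constrained.tolist(),
            "specific_variances": self.specific_variances.tolist(),
            "residual_variances": self.residual_variances.tolist(),
            "fixed_effects": self.fixed_effects.to_dict(),
            "scores_constrained": self.scores_constrained.tolist(),
            "lack_of_fit": self.lack_of_fit.tolist(),
            "blups": self.blups.tolist(),
            "pev": self.pev.tolist(),
            "loglik": self.loglik, "n_params": self.n_params,
            "converged": self.converged, "n_iter": self.n_iter,
            "message": self.message,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "FAFit":
        import json

        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        fx = d.pop("fixed_effects")
        arrays = ["loadings_constrained", "specific_variances",
                  "residual_variances", "scores_constrained", "lack_of_fit",
                  "blups", "pev"]
        for key in arrays:
            d[key] = np.asarray(d[key], dtype=float)
        v, t = d["blups"].shape
        return cls(fixed_effects=pd.Series(fx),
                   pev_blocks=np.zeros((v, t, t)), **d)


def _loading_mask(t: int, k: int) -> np.ndarray:
    """Boolean mask of free loading entries (column index <= row index)."""
    rows = np.arange(t)[:, None]
    cols = np.arange(k)[None, :]
    return cols <= rows


def _lower_triangularize(lam: np.ndarray) -> np.ndarray:
    """Rotate a t x k loading matrix so its top k x k block is lower triangular."""
    t, k = lam.shape
    if k <= 1:
        out = lam.copy()
    else:
        q, _ = np.linalg.qr(lam[:k, :].T)
        out = lam @ q
        out[~_loading_mask(t, k)] = 0.0
    # sign convention: non-negative diagonal of the top block
    for j in range(k):
        if out[j, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _start_values(design: METDesign, k: int, psi_min: float):
    """Eigen-based starts: loadings from the genotype-mean covariance,
    residual variances from within-cell replicate variation."""
    d = design
    ybar = d.cell_means()
    reps = d.counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        within_ss = d.y2sum - np.where(reps > 0, d.ysum**2 / np.maximum(reps, 1), 0.0)
    df = np.maximum((reps - 1).clip(min=0).sum(axis=0), 1.0)
    resid0 = within_ss.sum(axis=0) / df
    resid0 = np.clip(resid0, 1e-12, None)
    if np.all((reps <= 1) | (reps == 0)):  # no replication: fall back to total variance
        resid0 = np.full(d.t, np.nanvar(ybar, axis=0).mean() or 1.0)

    C = pd.DataFrame(ybar).cov(min_periods=2).to_numpy()
    C = np.where(np.isfinite(C), C, 0.0)
    mean_reps = np.where(reps > 0, reps, np.nan)
    nb = np.nanmean(mean_reps) if np.isfinite(np.nanmean(mean_reps)) else 1.0
    C_adj = C - np.diag(resid0 / max(nb, 1.0))
    diag = np.clip(np.diag(C_adj), 1e-6, None)
    np.fill_diagonal(C_adj, diag)

    if k > 0:
        w, E = np.linalg.eigh(C_adj)
        order = np.argsort(w)[::-1][:k]
        lam0 = E[:, order] * np.sqrt(np.clip(w[order], 1e-8, None))
        lam0 = _lower_triangularize(lam0)
        psi0 = np.clip(diag - np.sum(lam0**2, axis=1), 1e-3 * diag, None)
    else:
        lam0 = np.zeros((d.t, 0))
        psi0 = diag
    psi0 = np.clip(psi0, psi_min * 10, None)
    return lam0, psi0, resid0


def fit_fa_model(table: pd.DataFrame | METDesign, k: int,
                 opts: FitOptions | None = None) -> FAFit:
    """Fit the FA(k) MET mixed model by REML.

    ``k = 0`` fits the diagonal model (independent environments,
    heterogeneous genetic and residual variances).  Non-convergence within
    the iteration budget is flagged on the returned fit, not raised.
    """
    opts = opts or FitOptions()
    design = table if isinstance(table, METDesign) else METDesign(table)
    t, v = design.t, design.v
    if not (0 <= k < t):
        raise ValueError(f"need 0 <= k < t environments, got k={k}, t={t}")

    comps = design.connected_components()
    disconnected = []
    if len(comps) > 1:
        disconnected = [[design.env_codes[i] for i in comp] for comp in comps]
        warnings.warn(
            "environments form disconnected genotype groups; "
            "between-group genetic correlations are not estimable")

    scale = float(np.std(design.y)) or 1.0
    if not opts.rescale:
        scale = 1.0
    sdesign = _scaled_design(design, scale)

    lam0, psi0, resid0 = _start_values(sdesign, k, opts.psi_min)
    mask = _loading_mask(t, k)
    n_free = int(mask.sum())

    def unpack(theta):
        lam = np.zeros((t, k))
        lam[mask] = theta[:n_free]
        psi = np.exp(theta[n_free:n_free + t])
        sig = np.exp(theta[n_free + t:])
        return lam, psi, sig

    def objective(theta):
        lam, psi, sig = unpack(theta)
        G = lam @ lam.T + np.diag(psi)
        try:
            val, Q, rg = neg2_reml_grad(sdesign, G, sig)
        except np.linalg.LinAlgError:
            trace.append(1e10)
            return 1e10, np.zeros_like(theta)
        grad = np.concatenate([
            2.0 * (Q @ lam)[mask] if k > 0 else np.empty(0),
            np.diag(Q) * psi,            # chain rule for log psi
            rg * sig,                    # chain rule for log sigma2
        ])
        trace.append(val)
        return val, grad

    theta0 = np.concatenate([
        lam0[mask],
        np.log(np.clip(psi0, opts.psi_min, None)),
        np.log(np.clip(resid0, 1e-10, None)),
    ])
    bounds = ([(None, None)] * n_free
              + [(np.log(opts.psi_min), _LOGV_HI)] * t
              + [(_LOGV_LO, _LOGV_HI)] * t)

    trace: list[float] = []
    res = None
    x0 = theta0
    total_iter = 0
    stalled = False
    for _ in range(opts.restarts + 1):
        prev = res.fun if res is not None else np.inf
        res = minimize(objective, x0, method="L-BFGS-B", jac=True, bounds=bounds,
                       options={"maxiter": opts.max_iter, "ftol": opts.ftol,
                                "gtol": opts.gtol, "maxcor": opts.maxcor,
                                "maxfun": 500_000})
        total_iter += int(res.nit)
        x0 = res.x
        # a fresh L-BFGS memory often finishes off stiff problems
        stalled = prev - res.fun <= 1e-6 * max(abs(res.fun), 1.0)
        if res.success and stalled:
            break
    converged = bool(res.success) or stalled
    lam, psi, sig = unpack(res.x)
    lam = _lower_triangularize(lam) if k > 1 else _sign_fix(lam)
    G = lam @ lam.T + np.diag(psi)
    mme = solve_mme(sdesign, G, sig)

    # scores and lack of fit from the genetic-effect BLUPs
    Ginv = np.linalg.inv(G)
    if k > 0:
        scores = mme.ghat @ Ginv @ lam          # v x k
        delta = mme.ghat - scores @ lam.T
    else:
        scores = np.zeros((v, 0))
        delta = mme.ghat.copy()

    loglik = -0.5 * mme.neg2_loglik - (design.n - design.p) * np.log(scale)
    idxt = np.arange(t)
    fit = FAFit(
        k=k,
        env_order=list(design.env_codes),
        genotype_order=list(design.genotype_ids),
        loadings_constrained=lam * scale,
        specific_variances=psi * scale**2,
        residual_variances=sig * scale**2,
        fixed_effects=pd.Series(mme.beta * scale, index=mme.fixed_names),
        scores_constrained=scores,
        lack_of_fit=delta * scale,
        blups=mme.ghat * scale,
        pev=mme.pev[:, idxt, idxt] * scale**2,
        pev_blocks=mme.pev * scale**2,
        loglik=float(loglik),
        n_params=n_free + 2 * t,
        converged=converged,
        n_iter=total_iter,
        message=str(res.message),
        opt_trace=trace,
        disconnected_groups=disconnected,
    )
    if not converged:
        warnings.warn(f"FA({k}) fit did not converge: {res.message}")
    return fit


def _sign_fix(lam: np.ndarray) -> np.ndarray:
    out = lam.copy()
    for j in range(out.shape[1]):
        if out[min(j, out.shape[0] - 1), j] < 0:
            out[:, j] = -out[:, j]
    return out


def _scaled_design(design: METDesign, scale: float) -> METDesign:
    """A shallow copy of the design with yields divided by ``scale``."""
    if scale == 1.0:
        return design
    import copy

    d = copy.copy(design)
    d.y = design.y / scale
    d.yty_env = design.yty_env / scale**2
    d.Xty_env = design.Xty_env / scale
    d.ysum = design.ysum / scale
    d.y2sum = design.y2sum / scale**2
    return d


# ---------------------------------------------------------------------------
# compound-symmetry baseline


@dataclass
class CSFit:
    """Compound-symmetry MET fit: common genetic covariance across environments."""

    genetic_variance: float      # sigma2_g (between-environment covariance)
    gxe_variance: float          # sigma2_ge (environment-specific genetic variance)
    residual_variance: float
    loglik: float
    converged: bool
    n_iter: int = 0


def fit_cs_model(table: pd.DataFrame | METDesign,
                 opts: FitOptions | None = None) -> CSFit:
    """REML fit of the compound-symmetry baseline.

    Genetic effects have covariance ``sigma2_g J + sigma2_ge I`` across
    environments (equal variances, equal covariances) and the residual
    variance is homogeneous — the neutral baseline from which the crossover
    share of the G x E interaction is computed.
    """
    opts = opts or FitOptions()
    design = table if isinstance(table, METDesign) else METDesign(table)
    t = design.t
    if t < 2:
        raise ValueError("compound-symmetry model needs >= 2 environments")
    if design.v < 2:
        raise ValueError("need >= 2 genotypes")

    scale = float(np.std(design.y)) or 1.0
    if not opts.rescale:
        scale = 1.0
    sdesign = _scaled_design(design, scale)

    _, psi0, resid0 = _start_values(sdesign, 0, opts.psi_min)
    v0 = float(np.mean(psi0))
    theta0 = np.log(np.clip([v0 / 2, v0 / 2, float(np.mean(resid0))], 1e-6, None))
    J = np.ones((t, t))
    I = np.eye(t)

    def objective(theta):
        sg, sge, se = np.exp(theta)
        G = sg * J + sge * I
        try:
            val, Q, rg = neg2_reml_grad(sdesign, G, np.full(t, se))
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(3)
        grad = np.array([Q.sum() * sg, np.trace(Q) * sge, rg.sum() * se])
        return val, grad

    bounds = [(np.log(_PSI_MIN), _LOGV_HI)] * 3
    res = None
    x0 = theta0
    total_iter = 0
    stalled = False
    for _ in range(opts.restarts + 1):
        prev = res.fun if res is not None else np.inf
        res = minimize(objective, x0, method="L-BFGS-B", jac=True, bounds=bounds,
                       options={"maxiter": opts.max_iter, "ftol": opts.ftol,
                                "gtol": opts.gtol})
        total_iter += int(res.nit)
        x0 = res.x
        stalled = prev - res.fun <= 1e-6 * max(abs(res.fun), 1.0)
        if res.success and stalled:
            break
    converged = bool(res.success) or stalled
    sg, sge, se = np.exp(res.x)
    loglik = -0.5 * objective(res.x)[0] - (design.n - design.p) * np.log(scale)
    if not converged:
        warnings.warn(f"CS fit did not converge: {res.message}")
    return CSFit(
        genetic_variance=float(sg * scale**2),
        gxe_variance=float(sge * scale**2),
        residual_variance=float(se * scale**2),
        loglik=float(loglik),
        converged=converged,
        n_iter=total_iter,
    )


# ---------------------------------------------------------------------------
# single-environment linear mixed models


@dataclass
class SingleEnvFit:
    """Per-trial LMM fit used for adjusted means and Cullis heritability."""

    environment: str
    genotype_role: str                   # "fixed" or "random"
    genotypes: list[str]
    effects: pd.Series                   # eBLUEs (fixed) or BLUPs (random)
    mu_hat: float
    sigma2_g: float | None               # genetic variance (random role)
    sigma2_block: float | None           # replicate variance (fixed role)
    sigma2_e: float
    pev: np.ndarray | None               # v x v PEV matrix of BLUPs (random role)
    se: np.ndarray | None                # SEs of eBLUEs (fixed role)
    loglik: float
    converged: bool


def _one_random_effect_reml(y, X, zidx, q, fix_sigma2_u=None,
                            max_iter=200):
    """REML for ``y = X b + Z u + e`` with one iid random effect.

    ``zidx`` maps each observation to its random-effect level, so Z'Z is
    diagonal and everything reduces to per-level sums.  Returns estimates,
    BLUPs with their full PEV matrix, and the REML log-likelihood.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    counts = np.bincount(zidx, minlength=q).astype(float)
    Zy = np.bincount(zidx, weights=y, minlength=q)
    ZX = np.zeros((q, p))
    np.add.at(ZX, zidx, X)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    if np.linalg.matrix_rank(XtX) < p:
        raise np.linalg.LinAlgError("singular fixed-effect design")

    def neg2(log_su, log_se):
        su, se = np.exp(log_su), np.exp(log_se)
        if su < 1e-10:
            cS = np.linalg.cholesky(XtX / se)
            beta = sla.cho_solve((cS, True), Xty / se)
            yPy = yty / se - (Xty / se) @ beta
            logdetS = 2 * np.sum(np.log(np.diag(cS)))
            return (n - p) * np.log(2 * np.pi) + n * np.log(se) + logdetS + yPy
        m = counts / se + 1.0 / su
        b = Zy / se
        A = ZX / se
        Mib = b / m
        MiA = A / m[:, None]
        S = XtX / se - A.T @ MiA
        u_ = Xty / se - A.T @ Mib
        cS = np.linalg.cholesky(S)
        beta = sla.cho_solve((cS, True), u_)
        yPy = yty / se - b @ Mib - u_ @ beta
        logdetS = 2 * np.sum(np.log(np.diag(cS)))
        return ((n - p) * np.log(2 * np.pi) + n * np.log(se) + q * np.log(su)
                + np.sum(np.log(m)) + logdetS + yPy)

    v0 = max(np.var(y), 1e-8)

    def guarded(log_su, log_se):
        try:
            return neg2(log_su, log_se)
        except np.linalg.LinAlgError:
            return 1e10

    bounds_v = (np.log(1e-8 * v0), np.log(1e6 * v0))
    if fix_sigma2_u is None:
        obj = lambda th: guarded(th[0], th[1])
        th0 = np.log([v0 / 2, v0 / 2])
        res = minimize(obj, th0, method="L-BFGS-B", bounds=[bounds_v] * 2,
                       options={"maxiter": max_iter, "ftol": 1e-12})
        su, se = np.exp(res.x)
        converged = bool(res.success)
        n2 = res.fun
    else:
        su = float(fix_sigma2_u)
        log_su = np.log(su) if su > 0 else np.log(v0) - 60.0
        obj = lambda th: guarded(log_su, th[0])
        res = minimize(obj, [np.log(v0)], method="L-BFGS-B", bounds=[bounds_v],
                       options={"maxiter": max_iter, "ftol": 1e-12})
        se = float(np.exp(res.x[0]))
        converged = bool(res.success)
        n2 = res.fun

    # solve at the optimum
    if su <= 1e-10 * v0 or (fix_sigma2_u is not None and fix_sigma2_u == 0):
        cS = np.linalg.cholesky(XtX / se)
        Sinv = sla.cho_solve((cS, True), np.eye(p))
        beta = Sinv @ (Xty / se)
        uhat = np.zeros(q)
        pev = np.zeros((q, q))
        su = 0.0 if fix_sigma2_u == 0 else su
    else:
        m = counts / se + 1.0 / su
        b, A = Zy / se, ZX / se
        Mib, MiA = b / m, A / m[:, None]
        S = XtX / se - A.T @ MiA
        cS = np.linalg.cholesky(S)
        Sinv = sla.cho_solve((cS, True), np.eye(p))
        beta = Sinv @ (Xty / se - A.T @ Mib)
        uhat = Mib - MiA @ beta
        pev = np.diag(1.0 / m) + MiA @ Sinv @ MiA.T
    return {
        "beta": beta, "beta_cov": Sinv, "uhat": uhat, "pev": pev,
        "sigma2_u": float(su), "sigma2_e": float(se),
        "loglik": -0.5 * float(n2), "converged": converged,
    }


def fit_single_env_lmm(table: pd.DataFrame, genotype_role: str = "fixed",
                       fix_sigma2_g: float | None = None) -> SingleEnvFit:
    """Fit one trial's RCBD mixed model.

    ``genotype_role="fixed"`` estimates genotype eBLUEs with replication
    random (the adjusted-means stage); ``genotype_role="random"`` gives
    genotype BLUPs with their PEV matrix and variance components, block
    taken as fixed (the heritability stage).  ``fix_sigma2_g`` pins the
    genetic variance (e.g. to zero) in the random-genotype model.
    """
    envs = np.unique(table["environment"].astype(str))
    if len(envs) != 1:
        raise ValueError("fit_single_env_lmm expects exactly one environment")
    env = str(envs[0])
    tab = table.loc[np.isfinite(pd.to_numeric(table["yield"], errors="coerce"))]
    y = tab["yield"].to_numpy(dtype=float)
    gens = np.unique(tab["genotype"].astype(str))
    blocks = np.unique(tab["block"].to_numpy())
    if len(blocks) < 2:
        raise ValueError(f"environment {env}: fewer than 2 blocks (factor 'block')")
    if len(gens) < 2:
        raise ValueError(f"environment {env}: fewer than 2 genotypes (factor 'genotype')")
    gidx = pd.Categorical(tab["genotype"].astype(str), categories=gens).codes
    bidx = pd.Categorical(tab["block"], categories=blocks).codes

    if genotype_role == "fixed":
        # cell-means coding for genotype, blocks random
        X = np.zeros((len(y), len(gens)))
        X[np.arange(len(y)), gidx] = 1.0
        try:
            sol = _one_random_effect_reml(y, X, bidx, len(blocks))
        except np.linalg.LinAlgError:
            raise ValueError(
                f"environment {env}: singular design for factor 'genotype'")
        eblues = pd.Series(sol["beta"], index=list(gens), name="eBLUE")
        return SingleEnvFit(
            environment=env, genotype_role="fixed", genotypes=list(gens),
            effects=eblues, mu_hat=float(eblues.mean()),
            sigma2_g=None, sigma2_block=sol["sigma2_u"],
            sigma2_e=sol["sigma2_e"], pev=None,
            se=np.sqrt(np.diag(sol["beta_cov"])),
            loglik=sol["loglik"], converged=sol["converged"],
        )
    if genotype_role == "random":
        # intercept + block (fixed), genotype random
        cols = [np.ones(len(y))]
        for b in range(1, len(blocks)):
            cols.append((bidx == b).astype(float))
        X = np.column_stack(cols)
        try:
            sol = _one_random_effect_reml(y, X, gidx, len(gens),
                                          fix_sigma2_u=fix_sigma2_g)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"environment {env}: singular design for factor 'block'")
        blups = pd.Series(sol["uhat"], index=list(gens), name="BLUP")
        mu_hat = float(np.mean(X @ sol["beta"]))
        return SingleEnvFit(
            environment=env, genotype_role="random", genotypes=list(gens),
            effects=blups, mu_hat=mu_hat,
            sigma2_g=sol["sigma2_u"], sigma2_block=None,
            sigma2_e=sol["sigma2_e"], pev=sol["pev"], se=None,
            loglik=sol["loglik"], converged=sol["converged"],
        )
    raise ValueError("genotype_role must be 'fixed' or 'random'")
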