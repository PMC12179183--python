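"""Synthetic multi-environment trial (MET) data with known factor-analytic truth.

The generator emulates a soybean variety-trial network: randomized complete
block designs (RCBD, three replicates by default) run across many
location-by-season environments, with genetic effects drawn from a known
factor-analytic covariance ``G = Lambda Lambda' + Psi``, heterogeneous
per-environment residual variances, and optional genotype-by-environment
unbalance.  Environmental covariate tables with a planted mega-environment
structure are generated from the same feature catalogue used for
envirotyping.

Default scales are tuned to the trial network the package targets: grain
yield around 2,500 kg/ha with environment means ranging roughly 1,500-3,500
kg/ha, residual variances giving within-trial CVs near 0.23 and plot-based
heritabilities near 0.77.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_CATALOGUE, FeatureInfo

__all__ = [
    "FATruth",
    "EnvFeatureTable",
    "simulate_fa_truth",
    "simulate_met_phenotypes",
    "simulate_environment_covariates",
    "make_env_codes",
    "default_ranges",
]


def default_ranges() -> dict:
    """Default sampling bounds for :func:`simulate_fa_truth` (kg/ha scale)."""
    return {
        "loading": (300.0, 700.0),       # first-factor loadings, kg/ha per score unit
        "loading_decay": 0.6,            # geometric decay of later-factor magnitude
        "specific_variance": (2.0e4, 8.0e4),
        "residual_variance": (1.5e5, 4.5e5),
        "env_mean": (1500.0, 3500.0),
        "block_sd": 150.0,
    }


def make_env_codes(n_env: int) -> list[str]:
    """Deterministic environment codes in trial-network style.

    Codes look like ``M22s2E062``: country letter (Malawi/Zambia), two-digit
    season start year, season number within year, and a running trial index.
    Roughly 57% of environments are assigned to Malawi, matching a 47:36
    split at 83 environments.
    """
    n_malawi = int(np.ceil(n_env * 47 / 83))
    codes = []
    for i in range(n_env):
        country = "M" if i < n_malawi else "Z"
        year = 18 + (i % 6)
        season = 1 + (i % 2)
        codes.append(f"{country}{year}s{season}E{i + 1:03d}")
    return codes


@dataclass
class FATruth:
    """Ground-truth parameters of a factor-analytic MET generating model.

    ``loadings`` (t x k), ``specific_variances`` (t,), ``scores`` (v x k),
    ``residual_variances`` (t,), ``env_means`` (t,) and ``block_sd`` are the
    quantities a fitted FA model should recover (up to rotation of the
    loadings/scores).
    """

    n_env: int
    n_gen: int
    k: int
    loadings: np.ndarray
    specific_variances: np.ndarray
    scores: np.ndarray
    residual_variances: np.ndarray
    env_means: np.ndarray
    block_sd: float
    env_codes: list[str] = field(default_factory=list)
    genotype_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.specific_variances = np.asarray(self.specific_variances, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.residual_variances = np.asarray(self.residual_variances, dtype=float)
        self.env_means = np.asarray(self.env_means, dtype=float)
        if self.loadings.shape != (self.n_env, self.k):
            raise ValueError("loadings must be n_env x k")
        if self.scores.shape != (self.n_gen, self.k):
            raise ValueError("scores must be n_gen x k")
        if np.any(self.specific_variances <= 0):
            raise ValueError("specific_variances must be positive")
        if np.any(self.residual_variances < 0):
            raise ValueError("residual_variances must be non-negative")
        if not self.env_codes:
            self.env_codes = make_env_codes(self.n_env)
        if not self.genotype_ids:
            self.genotype_ids = [f"V{i + 1:03d}" for i in range(self.n_gen)]

    @property
    def genetic_covariance(self) -> np.ndarray:
        """Implied between-environment genetic covariance Lambda Lambda' + Psi."""
        return self.loadings @ self.loadings.T + np.diag(self.specific_variances)

    @property
    def genetic_effects(self) -> np.ndarray:
        """Factor-driven genetic effects ``scores @ loadings.T`` (v x t), without delta."""
        return self.scores @ self.loadings.T

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("loadings", "specific_variances", "scores",
                    "residual_variances", "env_means"):
            d[key] = np.asarray(d[key]).tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FATruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


def simulate_fa_truth(
    n_env: int,
    n_gen: int,
    k: int,
    seed: int | np.random.Generator = 0,
    ranges: Mapping | None = None,
) -> FATruth:
    """Draw a ground-truth FA(k) generating model.

    First-factor loadings are sampled positive (an overall-performance
    factor, as expected for yield); later factors have random signs and
    geometrically decaying magnitude.  Scores are standard normal per
    factor, matching the unit-variance convention for factor scores.
    """
    if n_env < 2 or n_gen < 2:
        raise ValueError("need n_env >= 2 and n_gen >= 2")
    if not (1 <= k < n_env):
        raise ValueError(f"need 1 <= k < n_env, got k={k}, n_env={n_env}")
    r = dict(default_ranges())
    if ranges:
        r.update(ranges)
    rng = np.random.default_rng(seed)

    lo, hi = r["loading"]
    decay = r["loading_decay"]
    loadings = np.empty((n_env, k))
    loadings[:, 0] = rng.uniform(lo, hi, size=n_env)
    for j in range(1, k):
        mag = rng.uniform(lo, hi, size=n_env) * decay**j
        sign = rng.choice([-1.0, 1.0], size=n_env)
        loadings[:, j] = mag * sign

    psi = rng.uniform(*r["specific_variance"], size=n_env)
    resid = rng.uniform(*r["residual_variance"], size=n_env)
    env_means = rng.uniform(*r["env_mean"], size=n_env)
    scores = rng.standard_normal((n_gen, k))

    return FATruth(
        n_env=n_env, n_gen=n_gen, k=k,
        loadings=loadings, specific_variances=psi, scores=scores,
        residual_variances=resid, env_means=env_means,
        block_sd=float(r["block_sd"]),
    )


def simulate_met_phenotypes(
    truth: FATruth,
    n_blocks: int = 3,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a long-format plot-level trial table from a known truth.

    Each plot yield is ``env_mean + block_effect + g_vt + eps`` where
    ``g_vt = (scores @ loadings')_vt + delta_vt`` with
    ``delta_vt ~ N(0, psi_t)`` and ``eps ~ N(0, sigma2_eps_t)``.  Unbalance
    is introduced by dropping whole genotype-in-environment cells (all
    replicates) independently with probability ``missing_rate``; every
    environment is guaranteed to retain at least two genotypes.

    Returns a DataFrame with columns environment, country, location, season,
    genotype, block, yield.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t, v = truth.n_env, truth.n_gen

    delta = rng.standard_normal((v, t)) * np.sqrt(truth.specific_variances)
    g = truth.genetic_effects + delta                        # v x t
    block_eff = rng.standard_normal((t, n_blocks)) * truth.block_sd

    keep = rng.random((v, t)) >= missing_rate
    for j in range(t):  # keep every environment fittable
        if keep[:, j].sum() < 2:
            keep[:2, j] = True

    env_idx, gen_idx = np.meshgrid(np.arange(t), np.arange(v))
    mask = keep.ravel()
    env_flat = np.repeat(env_idx.ravel()[mask], n_blocks)
    gen_flat = np.repeat(gen_idx.ravel()[mask], n_blocks)
    blk_flat = np.tile(np.arange(n_blocks), mask.sum())

    resid_sd = np.sqrt(truth.residual_variances)
    eps = rng.standard_normal(env_flat.size) * resid_sd[env_flat]
    y = (truth.env_means[env_flat] + block_eff[env_flat, blk_flat]
         + g[gen_flat, env_flat] + eps)

    codes = np.asarray(truth.env_codes)
    gens = np.asarray(truth.genotype_ids)
    env_col = codes[env_flat]
    loc_col = np.char.add("L", np.char.zfill((env_flat % 19 + 1).astype(str), 2))
    return pd.DataFrame({
        "environment": env_col,
        "country": [c[0] for c in env_col],
        "location": loc_col,
        "season": [c[1:5] for c in env_col],
        "genotype": gens[gen_flat],
        "block": blk_flat + 1,
        "yield": y,
    })


@dataclass
class EnvFeatureTable:
    """Environment-by-feature covariate table with optional true labels."""

    features: pd.DataFrame                 # rows = environments
    true_mega: pd.Series | None = None     # planted mega-environment labels

    def to_csv(self, path) -> None:
        out = self.features.copy()
        if self.true_mega is not None:
            out["true_mega"] = self.true_mega
        out.to_csv(path, index_label="environment")


def simulate_environment_covariates(
    n_env: int,
    n_features: int = 37,
    n_mega: int = 3,
    separation: float = 4.0,
    seed: int | np.random.Generator = 0,
    env_codes: Sequence[str] | None = None,
) -> EnvFeatureTable:
    """Simulate an environmental covariate table with planted clusters.

    Mega-environment centres for each feature are drawn around the
    catalogue mean with SD equal to the feature's scale; within-cluster
    noise has SD ``scale / max(separation, 1)``, so ``separation`` is the
    ratio of between-centre spread to within-cluster spread.
    ``separation=0`` collapses all centres onto the feature mean (labels
    carry no information).  Values of named catalogue features are clipped
    to their observed range.
    """
    if n_mega < 1:
        raise ValueError("n_mega must be >= 1")
    if n_mega > n_env:
        raise ValueError("n_mega cannot exceed n_env")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)

    feats: list[FeatureInfo] = list(FEATURE_CATALOGUE[:n_features])
    extra = n_features - len(feats)
    for j in range(extra):  # anonymous standardized features beyond the catalogue
        feats.append(FeatureInfo(f"x{j + 1:02d}", f"synthetic feature {j + 1}",
                                 "synthetic", "-", -3.0, 0.0, 3.0))

    codes = list(env_codes) if env_codes is not None else make_env_codes(n_env)
    labels = rng.integers(0, n_mega, size=n_env)
    # guarantee all clusters non-empty when possible
    labels[:n_mega] = np.arange(n_mega)

    data = np.empty((n_env, n_features))
    for j, f in enumerate(feats):
        if separation > 0:
            centres = rng.normal(f.mean, f.scale, size=n_mega)
            noise_sd = f.scale / max(separation, 1.0)
        else:
            centres = np.full(n_mega, f.mean)
            noise_sd = f.scale
        vals = centres[labels] + rng.normal(0.0, noise_sd, size=n_env)
        data[:, j] = np.clip(vals, f.min, f.max)

    df = pd.DataFrame(data, index=pd.Index(codes, name="environment"),
                      columns=[f.id for f in feats])
    return EnvFeatureTable(features=df,
                           true_mega=pd.Series(labels + 1, index=df.index,
                                               name="true_mega"))
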