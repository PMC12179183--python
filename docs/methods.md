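# fastmet methods

This note documents the statistical models, the numerical choices, and
the places where the design was genuinely open and a convention had to be
fixed. Everything stated here is implemented and exercised by the test
suite; no empirical claim is made beyond what the tests and the
acceptance script compute.

## Plot-level mixed model

The phenotypic model for grain yield (kg/ha) across `t` environments
(location-by-season trials), `v` genotypes and RCBD blocks is

```
y = μ1 + X₁s + X₂b + Z₁g + ε
```

- `s` (environment) and `b` (block within environment) are fixed;
- `g`, the genotype-in-environment effects, are random with
  `var(g) = G ⊗ I_v`; genotypes are independent of each other, and `G`
  (t×t) carries all between-environment genetic covariance;
- residuals are independent with a separate variance per environment
  (`R = diag(σ²ε₁…σ²εₜ)`), accommodating heterogeneous trial precision.

Three structures for `G` are fitted, all by REML:

- **FA(k)** — `G = ΛΛ' + Ψ` with `Λ` a t×k loading matrix and `Ψ`
  diagonal specific variances. For k > 1 the upper triangle of `Λ` is
  constrained to zero and factor scores have identity prior covariance;
  this fixes the rotational indeterminacy during estimation.
- **diagonal** (k = 0) — independent environments, used as the base of
  the model-comparison series.
- **compound symmetry** — `G = σ²g J + σ²ge I` with a single homogeneous
  residual variance. This deliberately simple structure (equal variances,
  equal covariances) is the neutral baseline for decomposing G×E into
  scale heterogeneity versus crossover.

### REML engine

Missing plots are simply dropped; REML handles the unbalance natively.
Environment and genotype levels are taken in sorted order, making every
estimate invariant to input row order.

The marginal covariance is inverted through the Woodbury identity. The
absorbed random-effect coefficient matrix
`M = G⁻¹ ⊗ I_v + Z'R⁻¹Z` is block diagonal with one t×t block per
genotype, so the REML log-likelihood

```
-2ℓ = (n-p)·log 2π + log|R| + v·log|G| + log|M| + log|X'V⁻¹X| + y'Py
```

costs `O(v·t³ + v·t·p²)` per evaluation (`p` = number of fixed-effect
columns). Exact first derivatives are propagated through the same
decomposition: for any parameterization of `G`,
`∂(-2ℓ)/∂α = tr(Q ∂G/∂α)` with `Q` assembled from the per-genotype
blocks of `Z'PZ` and `Z'Py`; the blocks are computed in the
cancellation-free forms `D M⁻¹G⁻¹`, `G⁻¹M⁻¹A` and `G⁻¹ĝ`, which stay
accurate even when residual variances are orders of magnitude below the
genetic variances. Residual-variance derivatives come from per-environment
sums of squared conditional residuals and diagonal traces.

Optimization is bounded L-BFGS-B over free loadings and log-variances.
Numerical choices:

- yields are internally standardized (divided by their SD) so all
  parameters are O(1); estimates and the log-likelihood are transformed
  back exactly;
- specific variances are floored at 1e-8 (standardized scale) to keep `G`
  invertible; residual variances are bounded in log space;
- starting values: loadings from an eigen-decomposition of the
  genotype-mean covariance (adjusted for replicate noise), residual
  variances from within-cell replicate variation;
- convergence: relative likelihood change below 1e-11 with gradient
  tolerance 1e-6, at most 500 iterations per run, L-BFGS memory 60. Up to
  two optimizer restarts from the incumbent solution are performed; a
  restart that fails to improve the objective by more than 1e-6 relative
  is treated as convergence (stiff near-degenerate problems can exhaust
  line-search precision exactly at the optimum). Non-convergence is
  flagged on the returned fit, never raised.

Environments with no genotype overlap with the rest make between-group
correlations inestimable; the fitter proceeds but records the
disconnected groups and warns.

BLUPs of `g` and their prediction error variances (PEV, including
fixed-effect uncertainty) come from the inverse mixed-model coefficient
matrix; factor-score BLUPs are recovered as `f̂ = Λ'G⁻¹ĝ` and the lack of
fit as `δ̂ = ĝ − Λf̂`.

### Single-trial models

Two per-environment RCBD models support the two-stage analyses:

- genotype **fixed** (cell-means coding) with replication random — yields
  genotype eBLUEs, averaged into environment-level adjusted means;
- genotype **random** with block fixed — yields BLUPs, their full v×v PEV
  matrix, and the variance components behind the Cullis heritability and
  the residual CV. Block is treated as fixed here, consistent with the
  plot-level MET model; the adjusted-means stage uses replication as
  random per its own specification. The stage-specific defaults follow
  each analysis's convention and both roles are available.

## Model selection

The FA order is compared on deviance (`−2 log L`), the count of genetic
variance parameters (`t·k − k(k−1)/2 + t`: free loadings plus specific
variances; residual variances are reported separately), the
per-environment explained variance

```
v_kt = 100 · λ²_kt d_k / (Σ_k λ²_kt d_k + ψ_t)
```

computed from the rotated solution, and the average semi-variance ratio
(ASVR): the ratio of the average pairwise semi-variance of the common
factor part `ΛDΛ'` to that of the full `G`, in percent. The *overall*
explained variance aggregates the per-environment totals by an unweighted
mean over environments — the aggregation is not uniquely determined by a
single reported number, and the unweighted mean treats trials
symmetrically. Selection takes the smallest k whose overall variance and
ASVR both reach the 80% thresholds (parsimony breaks ties toward smaller
k); if no order qualifies, the largest fitted order is returned with an
explicit warning.

## FAST statistics

The constrained solution is rotated by SVD, `Λ* = U L^{1/2} V'`, giving
orthonormal loadings `Λ = U`, factor variances `D = L` (decreasing) and
scores `f̃ = f* V L^{1/2}`. The first loading column is sign-flipped (with
its scores) so its mean is non-negative; with yield data the first factor
is then an overall-performance axis. No further sign or positivity
rotation is attempted for later factors, whose signs are arbitrary.

- **OP_v** = (mean of first-factor loadings) × first-factor score: the
  genotype main effect, in trait units.
- **RMSD_v**: the deviations from the first-factor latent regression are
  `ε*_vt = Σ_{k≥2} λ_kt f̃_vk` — the genetic fit from all factors except
  the first. RMSD is the root mean square of these deviations over
  environments, the quantity the name defines; a `method="literal"`
  option reproduces the plain mean of the deviations for audit. The
  lack-of-fit BLUPs `δ̂` are excluded from the deviations by default (they
  are residual genetic signal, not factor-driven G×E); a flag includes
  them.
- **RE_vk** (k ≥ 2) = (mean positive loading − mean negative loading) ×
  score: responsiveness to the environmental contrast that factor k
  represents; an empty sign group contributes zero.
- **R_v** = 1 − PEV_v/σ̄²g, clamped to [0,1], with σ̄²g the mean of
  `diag(G)` and PEV_v the genotype's prediction error variance *averaged
  over environments* (the aggregation is not otherwise pinned down; the
  mean is the documented default).
- **FAST_v** = (2·z(OP_v) − z(RMSD_v))·R_v, with z-scores taken across
  genotypes (sample SD). Reading the index's denominators as standard
  deviations makes the two terms commensurable; performance carries twice
  the weight of stability, and the reliability factor discounts weakly
  estimated genotypes.

All FAST statistics are invariant (tested to 1e-6) to orthogonal
re-parameterizations of the constrained solution and, as rankings, to
affine rescaling of the yields.

## Genetic summaries

- **Cullis H²** = 1 − v̄_Δ/(2σ̂²g), with v̄_Δ the mean PEV of BLUP
  differences over all genotype pairs — valid under unbalance, and equal
  to `rσ²g/(rσ²g+σ²e)` in the balanced limit. Zero genetic variance
  returns 0 by convention with a warning.
- **CV** = σ̂ε/μ̂ per environment, with μ̂ the model-based environment mean.
- **Genetic correlations** `ρ = D G D`, `D = diag(1/√diag G)`, computed
  from the selected MET fit (not from single-trial fits); per-environment
  means and SDs of the off-diagonals screen for trials driving crossover.
- **Crossover share** = 1 − dispersion(scale_t)/σ²ge, clamped to [0,1].
  The dispersion of the per-environment genetic scale is ambiguous between
  the variance of the variances and the variance of the SDs; the default
  is the sample (n−1) variance of `√σ²gt` — the scale on which the
  classical heterogeneity/lack-of-correlation decomposition operates —
  with `heterogeneity="variance"` and a `ddof` switch available. The
  per-environment genetic variances come from `diag(ΛΛ'+Ψ)` of the MET
  fit; σ²ge comes from the CS baseline.

## Envirotyping

Covariates are z-scored (sample SD; constant columns are an error), then
greedily de-correlated: while any pair exceeds `|r| > 0.9` (the
threshold is configurable; the convention follows common practice), the
member of the worst pair with the larger mean absolute correlation is
dropped, deterministically. The enviromic kernel is
`K_E = WW'/(trace(WW')/n)`, implemented exactly as that formula, which
fixes `trace(K_E) = n` (diagonal entries average one; descriptions of
this normalization as "unit trace" refer to the trace *per environment*).
Grain yield is not part of the kernel by default — `W` is defined from
covariates — but an environment-mean-yield column can be appended via an
option, since both conventions appear in practice.

Mega-environment delineation follows a split-first protocol to avoid
circularity: environments are randomly split 70/30; standardization,
collinearity filtering, PCA and clustering use the training split only;
cluster assignments become labels for an XGBoost `multi:softmax`
classifier (depth 6, learning rate 0.3, 100 rounds) on the first three
principal components, scored on the held-out split (test environments
get nearest-centroid labels for scoring). Clustering distance is
Euclidean on the standardized covariate rows (equivalently derivable from
the kernel). Both UPGMA (which also provides the dendrogram) and K-means
are implemented; the pipeline default uses K-means for labels and UPGMA
for the tree, both seed-controlled. The number of clusters is the elbow
of the K-means within-cluster sum of squares — the k with the largest
second difference — guarded by a flatness rule: if the candidate elbow
still leaves more than half of W(1) unexplained, the curve is treated as
elbow-free and k = 1 is returned.

The environment-mean regression is OLS of the adjusted means (mean of
genotype eBLUEs per environment) on standardized features, with the
collinearity filter applied first by default (37 features on ~80
environments is fittable but unstable otherwise); no stepwise selection
and no multiple-testing correction are applied — coefficients are ranked
by |β| and flagged at raw p < 0.05. Table-style feature identifiers
(gdd, tmean, fue, …) follow the canonical covariate dictionary in
`fastmet.features`.

## Synthetic data

The generator emulates a soybean variety-trial network: RCBD with three
replicates, genetic effects from a known FA(k) truth (standard-normal
scores; first-factor loadings positive; later factors with random signs
and geometrically decaying magnitude), per-environment residual
variances, and unbalance created by dropping whole
genotype-in-environment cells independently (each environment keeps at
least two genotypes). Block effects are drawn normal(0, block_sd²) per
environment; the fitters estimate blocks as fixed, which is compatible —
a draw is just one realization of fixed values. Environment codes follow
the trial-network style (country letter, season year, season index,
trial number) with a deterministic ~57/43 country split.

Default scales are chosen once to match the targeted network's published
summary level: environment means uniform on 1,500–3,500 kg/ha (network
mean ≈ 2,500), first-factor loadings 300–700 kg/ha, specific variances
2–8×10⁴, residual variances 1.5–4.5×10⁵ (kg/ha)² and block SD 150 kg/ha —
together giving within-trial CVs near 0.23 and plot heritabilities near
0.77, the level reported for such networks. The covariate generator
draws mega-environment centres around each feature's catalogue mean with
the feature's scale (range/6) as spread and within-cluster noise of
scale/max(separation, 1), clipping named features to their observed
ranges; `separation` is therefore a between/within SD ratio, with 0
producing label-free data.

What the generator does **not** emulate: spatial field trends (row/column
effects), pedigree or genomic relatedness, season-to-season correlation
of environmental drivers, non-normal yield errors, and informative
missingness (real unbalance follows trial logistics, not independent
coin flips). Passing tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to these
real-data features.

## Validation sizes and degenerate cases

The recovery checks run at sizes a single CPU handles in seconds while
leaving sampling error small: FA(1) at t=10, v=150 and FA(2) at t=20,
v=200, three blocks, 10% missing cells; the REML oracle comparison uses
twenty 3×5×2 datasets against a dense multivariate-normal implementation;
heritability calibration uses 200 balanced single-trial replicates. In
the noise-free validation of the degenerate limit, simulated factor
scores are whitened (exact zero mean, unit sample variance) because REML
necessarily recovers the *realized* score covariance — with raw scores
the comparison would be bounded by √(2/v) sampling noise rather than by
the fitter's accuracy.

## Known limitations

- No pedigree or genomic relationship matrices, and no spatial residual
  models; genotypes are assumed independent.
- The CS baseline assumes a homogeneous residual variance; its σ²ge
  therefore absorbs some residual heterogeneity on strongly heteroscedastic
  networks.
- Reliability and heritability inherit the fitted model's assumptions;
  they are not design-based quantities.
- The elbow rule's flatness guard (0.5) is a heuristic; for weakly
  separated environments the cluster count should be examined against
  the dendrogram rather than taken from the rule alone.
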