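"""Heritability, CV, genetic correlations and the crossover decomposition."""

import numpy as np
import pandas as pd
import pytest

import fastmet as fm
from fastmet.fa import CSFit, SingleEnvFit
from fastmet.fast import RotatedFA


def _single_env_fit(sigma2_g, pev, mu=10.0, sigma2_e=1.0):
    v = pev.shape[0]
    return SingleEnvFit(
        environment="E0", genotype_role="random",
        genotypes=[f"G{i}" for i in range(v)],
        effects=pd.Series(np.zeros(v)), mu_hat=mu, sigma2_g=sigma2_g,
        sigma2_block=None, sigma2_e=sigma2_e, pev=pev, se=None,
        loglik=0.0, converged=True)


def _rotated(loadings, psi):
    lam = np.atleast_2d(np.asarray(loadings, dtype=float))
    if lam.shape[0] == 1:
        lam = lam.T
    t, k = lam.shape
    U, s, Vt = np.linalg.svd(lam, full_matrices=False)
    return RotatedFA(U=U, L=s**2, V=Vt.T, rotated_scores=np.zeros((2, k)),
                     psi=np.asarray(psi, dtype=float),
                     env_codes=[f"E{i}" for i in range(t)],
                     genotype_ids=["G0", "G1"], delta=np.zeros((2, t)),
                     fitted_genetic=np.zeros((2, t)),
                     beta_tilde=np.zeros((2, t)))


def _rcbd(v, r, s2g, s2e, seed):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), v)
    rows = []
    for i in range(v):
        for b in range(r):
            rows.append(("E0", f"G{i:03d}", b + 1,
                         10 + 0.2 * b + g[i] + rng.normal(0, np.sqrt(s2e))))
    return pd.DataFrame(rows, columns=["environment", "genotype", "block", "yield"])


class TestCullisH2:
    def test_zero_pairwise_pev_gives_one(self):
        fit = _single_env_fit(1.0, np.zeros((4, 4)))
        assert fm.cullis_h2(fit) == pytest.approx(1.0)

    def test_pev_equal_twice_variance_gives_zero(self):
        fit = _single_env_fit(1.0, np.eye(4) * 1.0)
        # vbar_Delta = 2 sigma2_g exactly when diag PEV = 1 and off-diag = 0
        assert fm.cullis_h2(fit) == pytest.approx(0.0)

    def test_zero_variance_convention(self):
        fit = _single_env_fit(0.0, np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            assert fm.cullis_h2(fit) == 0.0

    def test_fixed_role_rejected(self, small_table):
        env = small_table[small_table.environment == small_table.environment.iloc[0]]
        fit = fm.fit_single_env_lmm(env, genotype_role="fixed")
        with pytest.raises(ValueError):
            fm.cullis_h2(fit)

    def test_balanced_design_matches_plot_formula(self):
        """H2 approx r*sigma2_g/(r*sigma2_g + sigma2_e) on balanced trials."""
        h2s = []
        for rep in range(40):
            fit = fm.fit_single_env_lmm(_rcbd(150, 3, 1.0, 1.0, 500 + rep),
                                        genotype_role="random")
            h2s.append(fm.cullis_h2(fit))
        assert np.mean(h2s) == pytest.approx(0.75, abs=0.03)

    def test_h2_monotone_in_replicates(self):
        """More replicates raise heritability at fixed variance components."""
        means = {}
        for r in (2, 3, 5):
            vals = [fm.cullis_h2(fm.fit_single_env_lmm(
                _rcbd(100, r, 1.0, 1.0, 900 + r * 50 + i), "random"))
                for i in range(15)]
            means[r] = np.mean(vals)
        assert means[2] < means[3] < means[5]


class TestEnvCV:
    def test_hand_value(self):
        fit = _single_env_fit(1.0, np.zeros((2, 2)), mu=2.0, sigma2_e=0.25)
        assert fm.env_cv(fit) == pytest.approx(0.25)

    def test_zero_residual(self):
        fit = _single_env_fit(1.0, np.zeros((2, 2)), mu=2.0, sigma2_e=0.0)
        assert fm.env_cv(fit) == 0.0

    def test_scale_invariance(self):
        a = _single_env_fit(1.0, np.zeros((2, 2)), mu=2.0, sigma2_e=0.25)
        b = _single_env_fit(1.0, np.zeros((2, 2)), mu=4.0, sigma2_e=1.0)
        assert fm.env_cv(a) == pytest.approx(fm.env_cv(b))

    def test_zero_mean_rejected(self):
        fit = _single_env_fit(1.0, np.zeros((2, 2)), mu=0.0)
        with pytest.raises(ValueError):
            fm.env_cv(fit)


class TestGeneticCorrelations:
    def test_rank_one_no_specific_variance_is_unity(self):
        gc = fm.genetic_correlations(_rotated([1.0, 2.0], [0.0, 0.0]))
        assert gc.matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        gc = fm.genetic_correlations(_rotated([1.0, 2.0], [1.0, 0.0]))
        assert gc.matrix.iloc[0, 1] == pytest.approx(2 / np.sqrt(8))

    def test_sign_flip(self):
        gc = fm.genetic_correlations(_rotated([1.0, -1.0], [0.0, 0.0]))
        assert gc.matrix.iloc[0, 1] == pytest.approx(-1.0)

    def test_matrix_is_psd_with_unit_diagonal(self, fa2_fit):
        gc = fm.genetic_correlations(fm.rotate_loadings(fa2_fit))
        rho = gc.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        assert np.linalg.eigvalsh(rho).min() >= -1e-8
        assert np.abs(rho).max() <= 1 + 1e-12

    def test_all_positive_rank_one_fit_gives_unit_correlations(self):
        """A fitted k=1 structure with all-positive loadings and vanishing
        specific variance implies pairwise genetic correlations of one."""
        truth = fm.simulate_fa_truth(4, 150, 1, seed=31, ranges={
            "loading": (0.8, 1.5), "specific_variance": (1e-10, 2e-10),
            "residual_variance": (1e-6, 2e-6), "env_mean": (1, 2),
            "block_sd": 0.0})
        tab = fm.simulate_met_phenotypes(truth, 3, 0.0, seed=32)
        fit = fm.fit_fa_model(tab, 1)
        gc = fm.genetic_correlations(fm.rotate_loadings(fit))
        off = gc.matrix.to_numpy()[np.triu_indices(4, 1)]
        assert off.min() > 1 - 1e-6

    def test_zero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            fm.genetic_correlations(_rotated([1.0, 0.0], [0.5, 0.0]))


class TestCrossoverShare:
    def _cs(self, s2ge):
        return CSFit(genetic_variance=1.0, gxe_variance=s2ge,
                     residual_variance=1.0, loglik=0.0, converged=True)

    def test_equal_variances_give_unity(self):
        dec = fm.crossover_share(np.full(5, 2.3), self._cs(1.0))
        assert dec.crossover_share == pytest.approx(1.0)
        assert dec.heterogeneity == pytest.approx(0.0)

    def test_hand_example(self):
        # genetic SDs (1, 3): sample variance 2; share = 1 - 2/4
        dec = fm.crossover_share(np.array([1.0, 9.0]), self._cs(4.0))
        assert dec.heterogeneity == pytest.approx(2.0)
        assert dec.crossover_share == pytest.approx(0.5)

    def test_variance_convention_switch(self):
        dec = fm.crossover_share(np.array([1.0, 9.0]), self._cs(40.0),
                                 heterogeneity="variance")
        assert dec.heterogeneity == pytest.approx(np.var([1.0, 9.0], ddof=1))

    def test_excess_heterogeneity_clamps_to_zero(self):
        with pytest.warns(UserWarning, match="clamped"):
            dec = fm.crossover_share(np.array([1.0, 100.0]), self._cs(0.5))
        assert dec.crossover_share == 0.0

    def test_zero_gxe_variance_rejected(self):
        with pytest.raises(ValueError):
            fm.crossover_share(np.array([1.0, 2.0]), self._cs(0.0))


class TestEnvironmentSummary:
    def test_columns_and_ranges(self, small_table):
        summary = fm.environment_summary(small_table)
        assert set(summary.columns) == {"mean_yield", "h2", "cv",
                                        "sigma2_g", "sigma2_e"}
        assert summary["h2"].between(0, 1).all()
        assert (summary["cv"] >= 0).all()
        assert len(summary) == small_table["environment"].nunique()
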