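"""FAST selection statistics: rotation, hand examples, invariances."""

import numpy as np
import pandas as pd
import pytest

import fastmet as fm
from fastmet.fa import FAFit


def _make_fit(lam, scores, psi=None, resid=None, pev=None, delta=None):
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    t, k = lam.shape
    v = scores.shape[0]
    psi = np.full(t, 0.5) if psi is None else np.asarray(psi, dtype=float)
    resid = np.full(t, 1.0) if resid is None else np.asarray(resid, dtype=float)
    pev = np.full((v, t), 0.2) if pev is None else np.asarray(pev, dtype=float)
    delta = np.zeros((v, t)) if delta is None else np.asarray(delta, dtype=float)
    return FAFit(
        k=k, env_order=[f"E{i}" for i in range(t)],
        genotype_order=[f"G{i}" for i in range(v)],
        loadings_constrained=lam, specific_variances=psi,
        residual_variances=resid, fixed_effects=pd.Series(dtype=float),
        scores_constrained=scores, lack_of_fit=delta,
        blups=scores @ lam.T + delta, pev=pev,
        pev_blocks=np.zeros((v, t, t)), loglik=0.0, n_params=0,
        converged=True, n_iter=1,
    )


class TestRotation:
    def test_single_column_svd(self):
        fit = _make_fit([[3.0], [4.0]], [[1.0], [0.0], [-1.0]])
        rot = fm.rotate_loadings(fit)
        np.testing.assert_allclose(rot.U.ravel(), [0.6, 0.8])
        np.testing.assert_allclose(rot.L, [25.0])
        np.testing.assert_allclose(rot.rotated_scores.ravel(), [5.0, 0.0, -5.0])

    def test_orthogonal_loadings_keep_direction(self):
        lam = np.array([[3.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        rot = fm.rotate_loadings(_make_fit(lam, np.zeros((3, 2))))
        np.testing.assert_allclose(np.abs(rot.U), np.abs(lam / [3.0, 2.0]),
                                   atol=1e-12)
        np.testing.assert_allclose(np.abs(rot.V), np.eye(2), atol=1e-12)

    def test_covariance_preserved(self, fa2_fit):
        rot = fm.rotate_loadings(fa2_fit)
        lam = fa2_fit.loadings_constrained
        np.testing.assert_allclose((rot.U * rot.L) @ rot.U.T, lam @ lam.T,
                                   atol=1e-8 * np.abs(lam).max() ** 2)
        assert np.allclose(rot.U.T @ rot.U, np.eye(rot.k), atol=1e-8)
        assert rot.L[0] >= rot.L[-1]
        assert rot.U[:, 0].mean() >= 0

    def test_fitted_genetic_preserved(self, fa2_fit):
        rot = fm.rotate_loadings(fa2_fit)
        scale = np.abs(fa2_fit.blups).max()
        np.testing.assert_allclose(rot.fitted_genetic, fa2_fit.blups,
                                   atol=1e-8 * scale)

    def test_rank_deficiency_warns(self):
        lam = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="rank deficient"):
            fm.rotate_loadings(_make_fit(lam, np.zeros((2, 2))))


class TestStatistics:
    def test_overall_performance_hand_examples(self):
        fit = _make_fit([[1.0], [3.0]], [[0.5], [0.0]])
        op = fm.overall_performance(fm.rotate_loadings(fit))
        # rotation preserves lambda' f: mean loading 2 with score 0.5 -> 1.0
        assert op.iloc[0] == pytest.approx(1.0)
        assert op.iloc[1] == pytest.approx(0.0)

    def test_rmsd_hand_example(self):
        rot = fm.rotate_loadings(_make_fit([[1.0], [1.0]], [[1.0]]))
        rot.beta_tilde = np.array([[0.3, -0.4]])
        rmsd = fm.stability_rmsd(rot)
        assert rmsd.iloc[0] == pytest.approx(np.sqrt((0.09 + 0.16) / 2))
        literal = fm.stability_rmsd(rot, method="literal")
        assert literal.iloc[0] == pytest.approx((0.3 - 0.4) / 2)

    def test_rmsd_homogeneity(self):
        rot = fm.rotate_loadings(_make_fit([[1.0], [1.0]], [[1.0]]))
        rot.beta_tilde = np.array([[0.3, -0.4]])
        base = fm.stability_rmsd(rot).iloc[0]
        rot.beta_tilde = rot.beta_tilde * 3.0
        assert fm.stability_rmsd(rot).iloc[0] == pytest.approx(3 * base)

    @pytest.mark.parametrize("loadings,score,expected", [
        ([0.5, -0.5], 1.0, 1.0),     # symmetric split
        ([0.2, 0.4], 1.0, 0.3),      # empty negative group contributes 0
        ([0.5, -0.5], 0.0, 0.0),
    ])
    def test_responsiveness(self, loadings, score, expected):
        from fastmet.fast import RotatedFA

        U = np.c_[[0.7, 0.7], np.asarray(loadings)]
        rot = RotatedFA(U=U, L=np.array([2.0, 1.0]), V=np.eye(2),
                        rotated_scores=np.array([[0.0, score], [0.0, 0.0]]),
                        psi=np.full(2, 0.1), env_codes=["E0", "E1"],
                        genotype_ids=["G0", "G1"], delta=np.zeros((2, 2)),
                        fitted_genetic=np.zeros((2, 2)),
                        beta_tilde=np.zeros((2, 2)))
        re = fm.responsiveness(rot, 2)
        assert re.iloc[0] == pytest.approx(expected)

    def test_responsiveness_first_factor_rejected(self, fa2_fit):
        with pytest.raises(ValueError):
            fm.responsiveness(fm.rotate_loadings(fa2_fit), 1)

    @pytest.mark.parametrize("pev,expected", [(0.0, 1.0), (1.0, 0.0), (0.2, 0.8)])
    def test_reliability(self, pev, expected):
        # mean genetic variance = mean(diag(lam lam' + psi)) = 1
        fit = _make_fit([[np.sqrt(0.5)], [np.sqrt(0.5)]], [[1.0], [0.0]],
                        psi=[0.5, 0.5], pev=np.full((2, 2), pev))
        rel = fm.reliability(fit)
        assert rel.iloc[0] == pytest.approx(expected)

    def test_fast_index_hand_values(self):
        op = pd.Series([1.0, 0.0, -1.0])
        rmsd = pd.Series([0.5, 1.0, 1.5])
        rel = pd.Series([0.9, 0.9, 0.9])
        out = fm.fast_index(op, rmsd, rel)
        assert out.iloc[1] == pytest.approx(0.0)          # at both means
        assert out.iloc[0] == pytest.approx((2 * 1.0 - (-1.0)) * 0.9)

    def test_fast_index_zero_spread_rejected(self):
        op = pd.Series([1.0, 1.0])
        rmsd = pd.Series([0.5, 1.0])
        with pytest.raises(ValueError):
            fm.fast_index(op, rmsd, pd.Series([1.0, 1.0]))


class TestInvariances:
    def test_orthogonal_reparameterization_leaves_fast_unchanged(self):
        """Any rotation of the constrained solution with the same implied
        covariance yields identical FAST statistics."""
        rng = np.random.default_rng(17)
        lam = rng.normal(size=(6, 2)) + [2.0, 0.0]
        scores = rng.normal(size=(30, 2))
        psi = rng.uniform(0.2, 0.5, 6)
        pev = rng.uniform(0.05, 0.3, (30, 6))
        fit1 = _make_fit(lam, scores, psi=psi, pev=pev)
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        fit2 = _make_fit(lam @ Q, scores @ Q, psi=psi, pev=pev)
        s1 = fm.fast_summary(fit1).table
        s2 = fm.fast_summary(fit2).table
        np.testing.assert_allclose(
            s1[["OP", "RMSD", "reliability", "FAST"]],
            s2[["OP", "RMSD", "reliability", "FAST"]], atol=1e-6)

    def test_yield_rescaling_preserves_ranking(self):
        """kg/ha -> t/ha rescaling leaves the FAST ranking unchanged."""
        rng = np.random.default_rng(23)
        lam = rng.uniform(300, 700, (5, 2))
        scores = rng.normal(size=(40, 2))
        psi = rng.uniform(2e4, 8e4, 5)
        pev = rng.uniform(2e4, 2e5, (40, 5))
        fit = _make_fit(lam, scores, psi=psi, pev=pev)
        c = 1e-3
        scaled = _make_fit(lam * c, scores, psi=psi * c**2, pev=pev * c**2)
        f1 = fm.fast_summary(fit).table["FAST"]
        f2 = fm.fast_summary(scaled).table["FAST"]
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-9)

    def test_mean_standardized_op_centers_at_zero(self, fa2_fit):
        table = fm.fast_summary(fa2_fit).table
        z = (table["OP"] - table["OP"].mean()) / table["OP"].std(ddof=1)
        assert abs(z.mean()) < 1e-12
        assert (table["RMSD"] >= 0).all()
        assert table["reliability"].between(0, 1).all()
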