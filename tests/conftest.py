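"""Shared fixtures and the dense-matrix REML oracle used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fastmet as fm
from fastmet.reml import METDesign

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def dense_neg2_reml(y, X, Z, Gfull, Rdiag):
    """Brute-force multivariate-normal REML evaluation on dense matrices.

    Independent of the structured engine: builds the full n x n marginal
    covariance and evaluates
    ``(n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py`` directly.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    V = Z @ Gfull @ Z.T + np.diag(Rdiag)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    yPy = (y - X @ beta) @ Vi @ y
    return ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XVX)[1] + yPy)


def incidence_matrices(design: METDesign):
    """Dense Z (cells ordered genotype-major) matching the engine layout."""
    Z = np.zeros((design.n, design.v * design.t))
    for i, (g, e) in enumerate(zip(design.gen_idx, design.env_idx)):
        Z[i, g * design.t + e] = 1.0
    return Z


def align_to_fit(truth: fm.FATruth, env_order) -> np.ndarray:
    """Permutation taking the truth's environment order to the fit's."""
    return np.asarray([truth.env_codes.index(c) for c in env_order])


@pytest.fixture(scope="session")
def small_truth() -> fm.FATruth:
    return fm.simulate_fa_truth(5, 40, 1, seed=101)


@pytest.fixture(scope="session")
def small_table(small_truth) -> pd.DataFrame:
    return fm.simulate_met_phenotypes(small_truth, n_blocks=3,
                                      missing_rate=0.1, seed=102)


@pytest.fixture(scope="session")
def small_fit(small_table) -> fm.FAFit:
    return fm.fit_fa_model(small_table, k=1)


@pytest.fixture(scope="session")
def fa2_truth() -> fm.FATruth:
    return fm.simulate_fa_truth(8, 60, 2, seed=201)


@pytest.fixture(scope="session")
def fa2_table(fa2_truth) -> pd.DataFrame:
    return fm.simulate_met_phenotypes(fa2_truth, n_blocks=3,
                                      missing_rate=0.05, seed=202)


@pytest.fixture(scope="session")
def fa2_fit(fa2_table) -> fm.FAFit:
    return fm.fit_fa_model(fa2_table, k=2)
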