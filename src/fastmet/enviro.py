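"""Envirotyping: covariate standardization, enviromic kernel, mega-environments.

Environmental covariates (climate, soil, geography) are z-score
standardized, screened for collinearity, and combined into an
environment-by-environment similarity kernel.  Mega-environments —
repeatable groups of trials with homogeneous G x E patterns — are
delineated by clustering (UPGMA for the dendrogram, K-means for labels),
with the number of groups chosen by the elbow rule, and validated by a
gradient-boosted multiclass classifier trained on the leading principal
components of a training split and scored on a held-out test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.model_selection import train_test_split

__all__ = [
    "zscore_standardize", "filter_collinear", "build_kernel", "EnvKernel",
    "upgma_cluster", "UPGMAResult", "elbow_k", "pca_project", "PCAResult",
    "train_megaenv_classifier", "ClassifierResult",
    "delineate_mega_environments", "MegaEnvAssignment",
]


def zscore_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with sample SD; errors on constant columns."""
    if table.isna().any().any():
        raise ValueError("covariate table contains missing values")
    sd = table.std(ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise ValueError(f"constant column(s): {bad}")
    return (table - table.mean()) / sd


def filter_collinear(W: pd.DataFrame, r_threshold: float = 0.9
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Greedy removal of collinear features.

    While any pair exceeds ``|r| > r_threshold``, the member of the worst
    pair with the larger mean absolute correlation to all other retained
    features is dropped (ties drop the later column).  Deterministic.
    """
    cols = list(W.columns)
    dropped: list[str] = []
    while len(cols) > 1:
        corr = W[cols].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        absc = np.abs(corr)
        i, j = np.unravel_index(np.argmax(absc), absc.shape)
        if absc[i, j] <= r_threshold:
            break
        mean_i = absc[i].sum() / (len(cols) - 1)
        mean_j = absc[j].sum() / (len(cols) - 1)
        drop = max(i, j) if np.isclose(mean_i, mean_j) else (i if mean_i > mean_j else j)
        dropped.append(cols.pop(drop))
    return W[cols], dropped


@dataclass
class EnvKernel:
    """Standardized covariates and the enviromic similarity kernel."""

    W: pd.DataFrame                # n x p standardized covariates
    KE: pd.DataFrame               # n x n kernel, trace n
    feature_names: list[str]
    dropped_features: list[str] = field(default_factory=list)


def build_kernel(W: pd.DataFrame, dropped: list[str] | None = None) -> EnvKernel:
    """Enviromic kernel K_E = W W' / (trace(W W') / n).

    The normalization fixes ``trace(K_E) = n`` so diagonal entries average
    one and environments are comparable across analyses.
    """
    Wm = W.to_numpy(dtype=float)
    if not np.all(np.isfinite(Wm)):
        raise ValueError("W must be finite")
    WWt = Wm @ Wm.T
    tr = np.trace(WWt)
    if tr <= 0:
        raise ValueError("W is all zero; kernel undefined")
    KE = WWt / (tr / len(W))
    ke = pd.DataFrame(KE, index=W.index, columns=W.index)
    return EnvKernel(W=W, KE=ke, feature_names=list(W.columns),
                     dropped_features=list(dropped or []))


@dataclass
class UPGMAResult:
    """Average-linkage merge tree with optional flat labels."""

    linkage: np.ndarray            # scipy linkage matrix
    heights: np.ndarray            # merge heights in order
    labels: pd.Series | None       # cluster labels at the requested k
    n_clusters: int | None


def upgma_cluster(distance: pd.DataFrame | np.ndarray,
                  k: int | None = None) -> UPGMAResult:
    """UPGMA (average linkage) hierarchical clustering of a distance matrix.

    ``distance`` must be square, symmetric, non-negative with a zero
    diagonal.  Cutting the tree at ``k`` clusters yields flat labels.
    """
    if isinstance(distance, pd.DataFrame):
        idx = list(distance.index)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        idx = list(range(D.shape[0]))
    if D.shape[0] < 2:
        raise ValueError("need at least 2 environments to cluster")
    if not np.allclose(D, D.T) or np.any(D < 0) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
    Z = linkage(squareform(D, checks=False), method="average")
    labels = None
    if k is not None:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(lab, index=idx, name="cluster")
    return UPGMAResult(linkage=Z, heights=Z[:, 2].copy(), labels=labels,
                       n_clusters=k)


def elbow_k(X: pd.DataFrame | np.ndarray, k_max: int, seed: int = 0,
            flatness_threshold: float = 0.5) -> int:
    """Elbow choice of the cluster count from K-means within-cluster SS.

    Total within-cluster sums of squares W(k) are computed for k = 1..k_max
    and the elbow is the k with the largest curvature (second difference).
    If even at the candidate elbow less than half of W(1) has been
    explained (``W(k*)/W(1) > flatness_threshold``), the curve is treated
    as elbow-free and k = 1 is returned.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_max >= n:
        k_max = n - 1
    if k_max < 1:
        raise ValueError("k_max must be >= 1 and < n")
    wss = []
    for k in range(1, k_max + 1):
        if k == 1:
            wss.append(float(((X - X.mean(axis=0))**2).sum()))
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            wss.append(float(km.inertia_))
    if k_max < 3:
        return 1 if (k_max == 1 or wss[-1] / max(wss[0], 1e-300) > flatness_threshold) else k_max
    w = np.asarray(wss)
    curv = w[:-2] - 2 * w[1:-1] + w[2:]          # second difference at k = 2..k_max-1
    k_star = int(np.argmax(curv)) + 2
    if w[k_star - 1] / max(w[0], 1e-300) > flatness_threshold:
        return 1
    return k_star


@dataclass
class PCAResult:
    """Principal components of the standardized covariate matrix."""

    scores: pd.DataFrame           # n x m component scores
    loadings: pd.DataFrame         # p x m feature loadings
    var_explained: np.ndarray      # shares summing to 1

    def project(self, W: pd.DataFrame) -> pd.DataFrame:
        """Project new standardized rows onto the fitted components."""
        sc = (W.to_numpy(dtype=float) - self._center) @ self.loadings.to_numpy()
        return pd.DataFrame(sc, index=W.index, columns=self.loadings.columns)

    _center: np.ndarray = field(default_factory=lambda: np.zeros(0))


def pca_project(W: pd.DataFrame) -> PCAResult:
    """PCA of the covariate matrix via SVD of the centered data.

    Components are ordered by decreasing variance; each component's sign
    is fixed so its largest-magnitude feature loading is positive.
    """
    Wm = W.to_numpy(dtype=float)
    center = Wm.mean(axis=0)
    Xc = Wm - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = len(s)
    for j in range(m):                       # deterministic sign convention
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    shares = var / var.sum() if var.sum() > 0 else var
    names = [f"PC{j + 1}" for j in range(m)]
    scores = pd.DataFrame(U * s[None, :], index=W.index, columns=names)
    loadings = pd.DataFrame(Vt.T, index=W.columns, columns=names)
    res = PCAResult(scores=scores, loadings=loadings, var_explained=shares)
    res._center = center
    return res


@dataclass
class ClassifierResult:
    """Held-out validation of mega-environment labels."""

    model: object
    test_accuracy: float
    predictions: pd.Series         # predicted labels for all rows
    train_index: list
    test_index: list


def train_megaenv_classifier(pc_scores: pd.DataFrame, labels: pd.Series,
                             split: float = 0.7,
                             hyperparams: dict | None = None,
                             seed: int = 0,
                             train_index: list | None = None) -> ClassifierResult:
    """Gradient-boosted multiclass validation of cluster labels.

    Trains an XGBoost ``multi:softmax`` classifier (tree depth 6, learning
    rate 0.3, 100 boosting rounds by default) on a stratified ``split``
    fraction of the environments (or on ``train_index`` when a split was
    made upstream), using the supplied component scores as features, and
    reports held-out accuracy.
    """
    from xgboost import XGBClassifier

    hp = {"max_depth": 6, "learning_rate": 0.3, "n_estimators": 100}
    hp.update(hyperparams or {})
    labels = labels.loc[pc_scores.index]
    classes, y = np.unique(labels.to_numpy(), return_inverse=True)
    X = pc_scores.to_numpy(dtype=float)

    if len(classes) == 1:
        pred = pd.Series(labels.iloc[0], index=pc_scores.index, name="predicted")
        return ClassifierResult(model=None, test_accuracy=1.0, predictions=pred,
                                train_index=list(pc_scores.index), test_index=[])

    if train_index is not None:
        in_train = pc_scores.index.isin(train_index)
        idx_tr = np.where(in_train)[0]
        idx_te = np.where(~in_train)[0]
    else:
        counts = np.bincount(y)
        strat = y if counts.min() >= 2 else None
        idx_tr, idx_te = train_test_split(np.arange(len(y)), train_size=split,
                                          random_state=seed, stratify=strat)
    missing = set(range(len(classes))) - set(y[idx_tr])
    if missing:
        names = [classes[c] for c in sorted(missing)]
        raise ValueError(
            f"class(es) {names} absent from the training split; "
            "reduce the number of clusters or use a different seed")

    model = XGBClassifier(objective="multi:softmax", num_class=len(classes),
                          random_state=seed, verbosity=0, **hp)
    model.fit(X[idx_tr], y[idx_tr])
    yhat = model.predict(X)
    acc = float(np.mean(yhat[idx_te] == y[idx_te]))
    pred = pd.Series(classes[yhat], index=pc_scores.index, name="predicted")
    return ClassifierResult(model=model, test_accuracy=acc, predictions=pred,
                            train_index=list(pc_scores.index[idx_tr]),
                            test_index=list(pc_scores.index[idx_te]))


@dataclass
class MegaEnvAssignment:
    """Full mega-environment delineation output."""

    labels: pd.Series              # final label per environment
    n_clusters: int
    dendrogram: UPGMAResult        # UPGMA tree on all environments
    pca: PCAResult                 # fitted on the training split
    pca_scores: pd.DataFrame       # first n_pcs scores, all environments
    train_envs: list
    test_envs: list
    classifier: ClassifierResult | None
    kernel: EnvKernel


def delineate_mega_environments(features: pd.DataFrame, k_max: int = 10,
                                r_threshold: float = 0.9, split: float = 0.7,
                                n_pcs: int = 3, seed: int = 0,
                                cluster_method: str = "kmeans",
                                n_clusters: int | None = None,
                                env_mean_yield: pd.Series | None = None
                                ) -> MegaEnvAssignment:
    """Delineate mega-environments from an environment-by-feature table.

    Protocol: environments are split into training and test subsets before
    any unsupervised step (to avoid circularity); standardization,
    collinearity filtering, PCA and clustering (K-means by default, UPGMA
    optional) use the training subset only; cluster assignments become
    labels for a boosted classifier on the leading ``n_pcs`` components,
    scored on the held-out environments.  Test environments receive
    nearest-centroid labels for scoring.  ``env_mean_yield``, when given,
    is appended as an extra standardized feature before kernel
    construction (the covariate-only kernel is the default).
    """
    rng = np.random.default_rng(seed)
    feats = features.copy()
    if env_mean_yield is not None:
        feats["mean_yield"] = env_mean_yield.loc[feats.index]

    n = len(feats)
    idx = rng.permutation(n)
    n_train = max(int(round(split * n)), 2)
    train_envs = feats.index[np.sort(idx[:n_train])]
    test_envs = feats.index[np.sort(idx[n_train:])]

    train_raw = feats.loc[train_envs]
    mu, sd = train_raw.mean(), train_raw.std(ddof=1)
    keepable = sd.index[sd > 0]
    W_train = ((train_raw - mu) / sd)[keepable]
    W_train, dropped = filter_collinear(W_train, r_threshold)
    cols = W_train.columns
    W_all = ((feats - mu) / sd)[cols]
    kernel = build_kernel(W_all, dropped)

    pca = pca_project(W_train)
    m = min(n_pcs, pca.scores.shape[1])
    pcs_train = pca.scores.iloc[:, :m]
    pcs_all = pca.project(W_all).iloc[:, :m]

    k = n_clusters or elbow_k(pcs_train.to_numpy(), min(k_max, len(train_envs) - 1),
                              seed=seed)
    if cluster_method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs_train)
        train_labels = km.labels_ + 1
        centroids = km.cluster_centers_
    elif cluster_method == "upgma":
        D = pd.DataFrame(squareform(pdist(W_train)), index=train_envs,
                         columns=train_envs)
        res = upgma_cluster(D, k=k)
        train_labels = res.labels.to_numpy()
        centroids = np.vstack([
            pcs_train.to_numpy()[train_labels == c].mean(axis=0)
            for c in range(1, k + 1)])
    else:
        raise ValueError("cluster_method must be 'kmeans' or 'upgma'")

    d2 = ((pcs_all.to_numpy()[:, None, :] - centroids[None, :, :])**2).sum(axis=2)
    nearest = d2.argmin(axis=1) + 1
    labels_all = pd.Series(nearest, index=feats.index, name="mega_environment")
    labels_all.loc[train_envs] = train_labels

    classifier = None
    if len(test_envs) > 0 and k > 1:
        try:
            classifier = train_megaenv_classifier(
                pcs_all, labels_all, split=split, seed=seed,
                train_index=list(train_envs))
        except ValueError as err:
            warnings.warn(f"classifier validation skipped: {err}")

    D_all = pd.DataFrame(squareform(pdist(W_all)), index=feats.index,
                         columns=feats.index)
    dendro = upgma_cluster(D_all, k=k)

    return MegaEnvAssignment(
        labels=labels_all, n_clusters=k, dendrogram=dendro, pca=pca,
        pca_scores=pcs_all, train_envs=list(train_envs),
        test_envs=list(test_envs), classifier=classifier, kernel=kernel,
    )
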