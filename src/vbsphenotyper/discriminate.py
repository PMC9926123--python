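"""Unsupervised genotype discrimination on the per-animal feature table.

A random-forest classifier is scored by leave-one-out cross-validation,
repeated over seeded runs; the per-variable Gini importances (mean
decrease in impurity) collected across runs are grouped by a k-means
clustering (k = 4) into importance tiers, and a centered, unit-variance
PCA summarizes the same table with per-variable contributions to each
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class DiscriminationResult:
    accuracies: np.ndarray          # LOO accuracy per run
    importances: pd.DataFrame       # runs x variables Gini importances
    variable_clusters: pd.Series    # variable -> cluster id (0 = most important)
    cluster_mean_importance: pd.Series

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def top_cluster_variables(self) -> list:
        return list(self.variable_clusters.index[self.variable_clusters == 0])


def rf_discriminate(
    table: pd.DataFrame,
    labels: pd.Series,
    n_runs: int = 100,
    n_trees: int = 500,
    n_clusters: int = 4,
    seed: int = 0,
) -> DiscriminationResult:
    """Repeated-run leave-one-out random-forest discrimination.

    Each run r uses RNG seed ``seed + r`` for both the forest and the
    LOO refits; accuracy is the fraction of held-out animals whose
    genotype the forest predicts correctly, and the Gini importances of
    a same-seed fit on the full table are collected per run.
    """
    x = table.to_numpy(float)
    y = pd.Series(labels).to_numpy()
    if table.isna().any().any():
        bad = table.isna().stack()
        cell = bad.index[bad.values][0]
        raise ValueError(f"missing value for animal {cell[0]}, column {cell[1]!r}")
    if len(np.unique(y)) < 2:
        raise ValueError("discrimination needs at least two classes")
    n = len(y)
    accuracies = np.empty(n_runs)
    importances = np.empty((n_runs, x.shape[1]))
    for run in range(n_runs):
        rs = seed + run
        correct = 0
        for i in range(n):
            mask = np.arange(n) != i
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=rs
            )
            clf.fit(x[mask], y[mask])
            correct += int(clf.predict(x[i : i + 1])[0] == y[i])
        accuracies[run] = correct / n
        full = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=rs
        )
        full.fit(x, y)
        importances[run] = full.feature_importances_
    imp = pd.DataFrame(importances, columns=table.columns)
    clusters, means = cluster_importances(imp, n_clusters=n_clusters, seed=seed)
    return DiscriminationResult(accuracies, imp, clusters, means)


def cluster_importances(
    importances: pd.DataFrame, n_clusters: int = 4, seed: int = 0
) -> tuple[pd.Series, pd.Series]:
    """k-means on per-variable importance profiles over runs.

    Clusters are relabeled by decreasing mean importance so cluster 0 is
    the most discriminating tier.
    """
    profiles = importances.to_numpy(float).T      # variables x runs
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    raw = km.fit_predict(profiles)
    order = np.argsort(-np.array([
        profiles[raw == c].mean() if (raw == c).any() else -np.inf
        for c in range(n_clusters)
    ]))
    relabel = {int(c): int(rank) for rank, c in enumerate(order)}
    clusters = pd.Series(
        [relabel[int(c)] for c in raw], index=importances.columns, name="cluster"
    )
    means = pd.Series(
        {relabel[int(c)]: profiles[raw == c].mean()
         for c in range(n_clusters) if (raw == c).any()},
        name="mean_importance",
    ).sort_index()
    return clusters, means


@dataclass(frozen=True)
class PcaResult:
    coordinates: pd.DataFrame        # animals x dimensions
    explained_variance_pct: np.ndarray
    contributions_pct: pd.DataFrame  # variables x dimensions, columns sum to 100
    centroids: pd.DataFrame
    ellipses: pd.DataFrame           # 0.95 confidence ellipse parameters


def pca_profile(table: pd.DataFrame, labels: pd.Series | None = None) -> PcaResult:
    """Centered, unit-variance PCA of the feature table.

    Contributions are squared-loading shares per dimension (percent).
    When genotype labels are given, per-group centroids and 0.95
    confidence ellipses of the first two dimensions are included.
    """
    if table.isna().any().any():
        raise ValueError("PCA cannot handle missing data")
    z = StandardScaler().fit_transform(table.to_numpy(float))
    pca = PCA()
    coords = pca.fit_transform(z)
    dims = [f"dim{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=table.index, columns=dims)
    contrib = pd.DataFrame(
        100.0 * pca.components_**2 / (pca.components_**2).sum(axis=1, keepdims=True),
        index=dims, columns=table.columns,
    ).T
    centroids = pd.DataFrame(columns=dims)
    ellipses = pd.DataFrame(
        columns=["width", "height", "angle_deg"]
    )
    if labels is not None:
        labels = pd.Series(labels, index=table.index)
        centroids = coordinates.groupby(labels).mean()
        rows = {}
        q = chi2.ppf(0.95, df=2)
        for lab, grp in coordinates.groupby(labels):
            cov = np.cov(grp[["dim1", "dim2"]].to_numpy().T)
            vals, vecs = np.linalg.eigh(cov)
            rows[lab] = {
                "width": 2 * np.sqrt(q * vals[1]),
                "height": 2 * np.sqrt(q * vals[0]),
                "angle_deg": float(
                    np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1]))
                ),
            }
        ellipses = pd.DataFrame(rows).T
    return PcaResult(
        coordinates=coordinates,
        explained_variance_pct=100.0 * pca.explained_variance_ratio_,
        contributions_pct=contrib,
        centroids=centroids,
        ellipses=ellipses,
    )
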