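"""Representation analyses: reconstruction error, PCA + K-means clustering,
cluster/category agreement, and the RL-level/information-loss trend.

After training, the DBN's mean-field reconstructions of the 64 retina
vectors are the model's "perceptual representations" of the stimuli.
Categorical perception shows up as clustering of these representations
by the task's categories: the 64 reconstructions are projected onto
their first two principal components and grouped by K-means with K = 4
(one cluster per ideal action). Agreement between the clusters and any
attribute partition is scored by Hungarian-matched accuracy (primary)
and the adjusted Rand index (secondary).

Information loss is the mean squared error between each retina and its
reconstruction; across the λ conditions its relationship with the RL
contribution is summarised by a Pearson correlation of level index
(0 = pure UL ... 4 = pure RL) against error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .perceptual import Dbn, reconstruct_batch

__all__ = [
    "ClusterReport",
    "mse_error",
    "reconstruction_error",
    "representations",
    "pca2",
    "kmeans4",
    "category_agreement",
    "level_error_correlation",
    "analyse_dbn",
    "plot_clusters",
]


@dataclass
class ClusterReport:
    """K-means (K=4) clustering of the 2-D PCA coordinates."""

    coords: np.ndarray          # (n, 2) PCA coordinates
    labels: np.ndarray          # (n,) cluster labels in {0..3}
    centroids: np.ndarray       # (4, 2)
    radii: np.ndarray           # max distance of a member from its centroid
    sizes: np.ndarray           # members per cluster
    empty_clusters: int         # clusters with at most 2 members ("almost empty")
    agreement: float | None = None
    ari: float | None = None
    extras: dict = field(default_factory=dict)


def mse_error(reconstructions: np.ndarray, retinas: np.ndarray) -> float:
    """Mean over stimuli of the per-pixel mean squared reconstruction error."""
    reconstructions = np.asarray(reconstructions, dtype=np.float64)
    retinas = np.asarray(retinas, dtype=np.float64)
    if reconstructions.shape != retinas.shape:
        raise ValueError("reconstructions and retinas must have the same shape")
    return float(np.mean((reconstructions - retinas) ** 2))


def representations(dbn: Dbn, retinas: np.ndarray) -> np.ndarray:
    """Mean-field reconstructed visible vectors, one row per stimulus."""
    return reconstruct_batch(dbn, retinas)


def reconstruction_error(dbn: Dbn, retinas: np.ndarray) -> float:
    """Information loss: mean MSE between retinas and their reconstructions."""
    return mse_error(representations(dbn, retinas), retinas)


def pca2(X: np.ndarray) -> np.ndarray:
    """Project rows onto the first two principal axes (centred, unscaled).

    The sign of each axis is fixed so that its largest-magnitude loading
    is positive, making coordinates reproducible across runs.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for a 2-component PCA")
    if float(X.var(axis=0).max()) < 1e-24:
        raise ValueError("zero-variance input: PCA is undefined")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for k, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, k] *= -1.0
    return coords


def kmeans4(points: np.ndarray, seed: int = 0, restarts: int = 10) -> ClusterReport:
    """K-means with K=4 on 2-D points: best of ``restarts`` k-means++ runs."""
    points = np.asarray(points, dtype=np.float64)
    km = KMeans(n_clusters=4, n_init=restarts, random_state=seed)
    labels = km.fit_predict(points)
    centroids = km.cluster_centers_
    radii = np.zeros(4)
    sizes = np.zeros(4, dtype=int)
    for c in range(4):
        members = points[labels == c]
        sizes[c] = len(members)
        if len(members):
            radii[c] = float(np.linalg.norm(members - centroids[c], axis=1).max())
    return ClusterReport(
        coords=points,
        labels=labels,
        centroids=centroids,
        radii=radii,
        sizes=sizes,
        empty_clusters=int((sizes <= 2).sum()),
    )


def category_agreement(cluster_labels: np.ndarray, task_categories: np.ndarray) -> float:
    """Best-permutation accuracy between cluster labels and categories.

    The 4 clusters are matched to the 4 categories by Hungarian
    assignment on the contingency table; returns the fraction of items
    whose matched cluster equals their category.
    """
    cluster_labels = np.asarray(cluster_labels)
    task_categories = np.asarray(task_categories)
    if cluster_labels.shape != task_categories.shape:
        raise ValueError("label vectors must have equal length")
    n_c = int(cluster_labels.max()) + 1
    n_k = int(task_categories.max()) + 1
    table = np.zeros((n_c, n_k))
    for c, k in zip(cluster_labels, task_categories):
        table[c, k] += 1
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(cluster_labels))


def level_error_correlation(levels: np.ndarray, errors: np.ndarray) -> float:
    """Pearson correlation of λ-level index (0..4) against reconstruction error."""
    levels = np.asarray(levels, dtype=np.float64)
    errors = np.asarray(errors, dtype=np.float64)
    if len(levels) < 3 or len(np.unique(levels)) < 2:
        raise ValueError("need at least 3 rows spanning at least 2 levels")
    if np.allclose(errors.var(), 0.0) or np.allclose(levels.var(), 0.0):
        raise ValueError("zero variance: correlation is undefined")
    return float(pearsonr(levels, errors).statistic)


def analyse_dbn(
    dbn: Dbn,
    retinas: np.ndarray,
    task_categories: np.ndarray,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterReport:
    """Full pipeline: reconstruct → PCA(2) → K-means(4) → agreement scores."""
    reps = representations(dbn, retinas)
    coords = pca2(reps)
    report = kmeans4(coords, seed=seed, restarts=restarts)
    report.agreement = category_agreement(report.labels, task_categories)
    report.ari = float(adjusted_rand_score(task_categories, report.labels))
    report.extras["reconstruction_error"] = mse_error(reps, retinas)
    return report


def plot_clusters(
    report: ClusterReport,
    task_categories: np.ndarray,
    path: str | Path,
    title: str = "",
) -> None:
    """Scatter of PCA coordinates coloured by category, with cluster circles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for cat in np.unique(task_categories):
        m = task_categories == cat
        ax.scatter(
            report.coords[m, 0], report.coords[m, 1],
            s=18, color=cmap(int(cat)), label=f"category {cat}",
        )
    for c in range(4):
        ax.add_patch(
            plt.Circle(report.centroids[c], report.radii[c],
                       fill=False, color="grey", lw=0.8)
        )
        ax.plot(*report.centroids[c], "k.", ms=8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
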