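"""Subpopulation discovery by partitive clustering.

Cells are clustered on their clipped log2 expression profiles with
restarted, k-means++-seeded Lloyd iteration; the best of ``n_restarts``
runs by within-cluster sum of squares (WCSS) is kept and clusters are
renumbered 1..k by decreasing size so reports are stable. The number of
clusters is chosen with the gap statistic of Tibshirani, Walther &
Hastie: log(WCSS) is compared against its mean over uniform-box reference
datasets sampled within the per-gene observed range, and the smallest k
with gap(k) >= gap(k+1) - se(k+1) wins.

Lloyd iteration is implemented here rather than delegated so that the
per-iteration WCSS trace (monotone non-increasing, asserted in tests),
the deterministic restart/seeding scheme, and empty-cluster repair are
part of the contract; scikit-learn's KMeans is used only as an
independent cross-check in the test suite.

Hierarchical ordering for heatmaps delegates to scipy's agglomerative
linkage and returns the dendrogram leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import ExpressionMatrix

__all__ = [
    "ClusterResult",
    "KSelection",
    "CompositionTable",
    "kmeans_partition",
    "select_k",
    "hierarchical_order",
    "composition",
]


@dataclass
class ClusterResult:
    """Partitive clustering of cells; labels are 1..k, ordered by size."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    seed: int
    n_restarts: int
    wcss: float
    wcss_trace: list[float] = field(default_factory=list)

    def mask(self, cluster: int) -> np.ndarray:
        return self.labels == cluster


@dataclass
class KSelection:
    """Gap-statistic trace for cluster-number selection."""

    candidate_ks: list[int]
    gap: np.ndarray
    se: np.ndarray
    log_wcss: np.ndarray
    chosen_k: int
    n_reference: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.candidate_ks,
                "log_wcss": self.log_wcss,
                "gap": self.gap,
                "se": self.se,
                "chosen": [k == self.chosen_k for k in self.candidate_ks],
            }
        )


@dataclass
class CompositionTable:
    """Cluster x group cross-tabulation with both fraction views."""

    counts: pd.DataFrame
    cluster_fractions: pd.DataFrame  # rows (clusters) sum to 1
    group_fractions: pd.DataFrame  # columns (groups) sum to 1


def _as_values(matrix) -> np.ndarray:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: each new center drawn with probability ~ D^2."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with a chosen center
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = (
        (X**2).sum(axis=1)[:, None]
        + (centers**2).sum(axis=1)[None, :]
        - 2.0 * X @ centers.T
    )
    return np.maximum(d2, 0.0)


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One k-means run; returns (labels, centers, wcss, per-iteration wcss)."""
    centers = _kmeanspp_init(X, k, rng)
    labels = np.full(X.shape[0], -1)
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = _sq_dists(X, centers)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: claim the point farthest from its center
        for j in range(k):
            if not (new_labels == j).any():
                farthest = int(d2[np.arange(len(X)), new_labels].argmax())
                centers[j] = X[farthest]
                d2 = _sq_dists(X, centers)
                new_labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(X)), new_labels].sum()))
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    wcss = trace[-1]
    return labels, centers, wcss, trace


def _renumber_by_size(labels: np.ndarray, centers: np.ndarray, k: int):
    """Relabel clusters 1..k by decreasing size, ties by smallest cell index."""
    order = sorted(
        range(k),
        key=lambda j: (-(labels == j).sum(), int(np.flatnonzero(labels == j)[0])),
    )
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels], centers[order]


def kmeans_partition(
    matrix, k: int, seed: int = 0, n_restarts: int = 50
) -> ClusterResult:
    """Euclidean k-means on clipped log2 values, best of ``n_restarts``.

    Deterministic given (seed, n_restarts). Clusters come back renumbered
    1..k by decreasing size (ties broken by the smallest contained cell
    index), so label identity is stable across runs.
    """
    X = _as_values(matrix)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty matrix")
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, centers, wcss, trace = _lloyd(X, k, rng)
        if best is None or wcss < best[2] - 1e-12:
            best = (labels, centers, wcss, trace)
    labels, centers, wcss, trace = best
    labels, centers = _renumber_by_size(labels, centers, k)
    return ClusterResult(
        labels=labels,
        k=k,
        centroids=centers,
        seed=seed,
        n_restarts=n_restarts,
        wcss=wcss,
        wcss_trace=trace,
    )


def select_k(
    matrix,
    k_max: int,
    n_reference: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
) -> KSelection:
    """Choose the number of clusters with the gap statistic.

    For each k in 1..k_max the observed log(WCSS) is compared with its mean
    over ``n_reference`` datasets drawn uniformly within the per-gene
    observed range; gap(k) is the difference and se(k) the reference
    standard deviation inflated by sqrt(1 + 1/n_reference). The chosen k is
    the smallest with gap(k) >= gap(k+1) - se(k+1), falling back to k_max.
    """
    X = _as_values(matrix)
    n, g = X.shape
    if k_max < 1 or k_max > n:
        raise ValueError(f"k_max must be in [1, {n}], got {k_max}")
    ks = list(range(1, k_max + 1))
    seeds = np.random.SeedSequence(seed).generate_state(2 + n_reference) % (2**31)
    log_w = np.array(
        [
            np.log(kmeans_partition(X, k, seed=int(seeds[0]), n_restarts=n_restarts).wcss)
            for k in ks
        ]
    )
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_log_w = np.empty((n_reference, len(ks)))
    for b in range(n_reference):
        rng = np.random.default_rng(int(seeds[2 + b]))
        ref = rng.uniform(lo, hi, size=(n, g))
        for i, k in enumerate(ks):
            ref_log_w[b, i] = np.log(
                kmeans_partition(ref, k, seed=int(seeds[1]), n_restarts=n_restarts).wcss
            )
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)
    chosen = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            chosen = ks[i]
            break
    return KSelection(
        candidate_ks=ks,
        gap=gap,
        se=se,
        log_wcss=log_w,
        chosen_k=chosen,
        n_reference=n_reference,
        seed=seed,
    )


def hierarchical_order(
    matrix,
    axis: str = "cells",
    metric: str = "euclidean",
    linkage: str = "average",
) -> np.ndarray:
    """Dendrogram leaf order of cells or genes for heatmap display.

    Builds an agglomerative tree (scipy) with the stated metric and linkage
    and returns the leaf permutation. Ward linkage requires the euclidean
    metric; a constant axis under the correlation metric has undefined
    distances and raises with advice to use euclidean.
    """
    X = _as_values(matrix)
    if axis == "genes":
        X = X.T
    elif axis != "cells":
        raise ValueError(f"axis must be 'cells' or 'genes', got {axis!r}")
    if X.shape[0] < 2:
        raise ValueError("need at least two items to order")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    if metric == "correlation" and np.any(X.std(axis=1) == 0):
        raise ValueError(
            "correlation distance undefined for constant profiles; "
            "use metric='euclidean'"
        )
    dist = pdist(X, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    return np.asarray(hierarchy.leaves_list(Z))


def composition(clusters: ClusterResult, groups) -> CompositionTable:
    """Cross-tabulate cluster membership against biological group.

    Returns counts plus per-cluster group fractions (each cluster row sums
    to 1) and per-group cluster fractions (each group column sums to 1).
    """
    groups = np.asarray(groups)
    if groups.shape != clusters.labels.shape:
        raise ValueError(
            f"group labels ({groups.shape}) not aligned with "
            f"cluster labels ({clusters.labels.shape})"
        )
    counts = pd.crosstab(
        pd.Series(clusters.labels, name="cluster"),
        pd.Series(groups, name="group"),
    )
    counts = counts.reindex(index=range(1, clusters.k + 1), fill_value=0)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        cluster_fractions = counts.div(row_tot.replace(0, np.nan), axis=0)
        group_fractions = counts.div(col_tot, axis=1)
    return CompositionTable(
        counts=counts,
        cluster_fractions=cluster_fractions,
        group_fractions=group_fractions,
    )
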