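"""k-means clustering of temporal expression profiles.

Genes are clustered by Euclidean distance between their normalised temporal
profiles using Lloyd's algorithm with many random restarts (random centroid
initialisation by sampling k distinct genes; the restart with minimal total
within-cluster squared distance wins).  Because a single "correct" number of
clusters does not exist for this kind of data, :func:`sweep_k` fits a family
of partitions over a range of k and quantifies how much each partition refines
the previous one: when clusters subdivide rather than reshuffle as k grows,
the organisation is roughly hierarchical.

Cluster labels are arbitrary (they depend on initialisation), so downstream
analyses refer to clusters via their chronological rank — the order of the age
at which the cluster's mean profile peaks — or via explicit label maps, never
via any fixed numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from connscreen.normalize import NormalizedTable


@dataclass
class ClusterModel:
    """A k-way partition of genes with its centroids and objective value."""

    k: int
    assignments: np.ndarray  # label in [0, k) per row of the clustered matrix
    centroids: np.ndarray  # k x n_ages
    inertia: float  # total within-cluster squared Euclidean distance
    restarts: int
    seed: int
    n_iter: int = 0
    gene_ids: list[str] | None = None

    def assignments_by_gene(self) -> pd.Series:
        if self.gene_ids is None:
            raise ValueError("model carries no gene ids")
        return pd.Series(self.assignments, index=self.gene_ids, name="cluster")


@dataclass
class ClusterSummary:
    """Per-cluster mean profiles with peak ages and chronological ranks.

    ``profiles`` is cluster × age (means over present values); ``peak_age``
    maps cluster label to the age of the profile maximum (ties broken toward
    the earliest age); ``rank`` is the chronological rank, a permutation of
    0..k-1 non-decreasing in peak age; ``sizes`` counts members.
    """

    profiles: pd.DataFrame
    peak_age: pd.Series
    rank: pd.Series
    sizes: pd.Series


@dataclass
class KSweepResult:
    """Partitions across a k range with adjacent-pair correspondence.

    For each adjacent pair (k, k+1), ``parent_maps[k]`` sends every cluster of
    the k+1 model to the k cluster sharing the most members, and
    ``stability[k]`` is the summed maximal overlap divided by the gene count —
    1.0 exactly when the finer partition is a refinement of the coarser one.
    """

    models: dict[int, ClusterModel]
    parent_maps: dict[int, dict[int, int]] = field(default_factory=dict)
    stability: dict[int, float] = field(default_factory=dict)


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float):
    """One run of Lloyd's algorithm from the given initial centroids.

    Empty clusters are re-seeded at the point farthest from its currently
    assigned centroid, keeping all k clusters non-empty deterministically.
    """
    k = centroids.shape[0]
    centroids = centroids.copy()
    labels = np.zeros(X.shape[0], dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1)
        new_centroids = centroids.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centroids[j] = X[members].mean(axis=0)
            else:
                dist_own = d2[np.arange(X.shape[0]), labels]
                far = int(np.argmax(dist_own))
                new_centroids[j] = X[far]
                labels[far] = j
                d2 = cdist(X, new_centroids, metric="sqeuclidean")
        shift = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        centroids = new_centroids
        if shift < tol:
            break
    d2 = cdist(X, centroids, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centroids, inertia, n_iter


def kmeans(
    m: np.ndarray,
    k: int,
    restarts: int = 1000,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> ClusterModel:
    """Best-of-``restarts`` k-means with Euclidean distance.

    Each restart initialises centroids at k distinct rows sampled uniformly,
    runs Lloyd's algorithm to convergence (centroid shift below ``tol``) or
    ``max_iter``, and the restart with minimal inertia is returned.
    Deterministic given ``seed``.
    """
    X = np.asarray(m, dtype=float)
    if X.ndim != 2:
        raise ValueError("input matrix must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("input matrix contains non-finite values")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    if gene_ids is not None and len(gene_ids) != n:
        raise ValueError("gene_ids length mismatch")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        init = X[rng.choice(n, size=k, replace=False)]
        labels, cents, inertia, n_iter = _lloyd(X, init, max_iter, tol)
        if best is None or inertia < best[2]:
            best = (labels, cents, inertia, n_iter)
    labels, cents, inertia, n_iter = best
    return ClusterModel(
        k=k, assignments=labels, centroids=cents, inertia=inertia,
        restarts=restarts, seed=seed, n_iter=n_iter, gene_ids=gene_ids,
    )


def cluster_correspondence(a: np.ndarray, b: np.ndarray) -> tuple[dict[int, int], float]:
    """Map each cluster of partition ``b`` to its maximal-overlap cluster in ``a``.

    Both arrays label the same genes in the same order.  Returns the parent
    map (ties broken toward the lower ``a`` label) and the stability score:
    the summed maximal overlaps divided by the gene count.  The score is 1
    exactly when ``b`` refines ``a``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions label different gene sets")
    n = a.size
    crosstab = pd.crosstab(pd.Series(b, name="b"), pd.Series(a, name="a"))
    parent: dict[int, int] = {}
    overlap_sum = 0
    for b_label, row in crosstab.iterrows():
        best = row.max()
        parent[int(b_label)] = int(row.index[np.argmax(row.to_numpy())])
        overlap_sum += int(best)
    return parent, overlap_sum / n


def sweep_k(
    m: np.ndarray,
    k_min: int = 6,
    k_max: int = 18,
    restarts: int = 1000,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> KSweepResult:
    """Fit k-means for every k in [k_min, k_max] and score adjacent-pair flux."""
    if k_max < k_min:
        raise ValueError("k_max < k_min")
    models = {}
    for k in range(k_min, k_max + 1):
        # distinct stream per k so adding a k never perturbs the others
        models[k] = kmeans(m, k, restarts=restarts, max_iter=max_iter,
                           tol=tol, seed=seed + k, gene_ids=gene_ids)
    result = KSweepResult(models=models)
    for k in range(k_min, k_max):
        parent, stab = cluster_correspondence(models[k].assignments, models[k + 1].assignments)
        result.parent_maps[k] = parent
        result.stability[k] = stab
    return result


def summarize_clusters(nt: NormalizedTable, cm: ClusterModel) -> ClusterSummary:
    """Average normalised profiles per cluster and rank clusters chronologically.

    The per-cluster profile is the mean over present values at each age.  The
    peak age is the profile argmax (ties toward the earliest age).  Ranks
    order clusters by peak age; ties are broken by the larger peak value
    first, then by label.
    """
    if cm.gene_ids is None:
        raise ValueError("cluster model carries no gene ids")
    df = nt.data.loc[cm.gene_ids]
    labels = pd.Series(cm.assignments, index=df.index)
    profiles = df.groupby(labels).mean()  # nan-aware column means
    if profiles.isna().any().any():
        raise ValueError("a cluster has an age with no present values")
    sizes = labels.value_counts().sort_index()
    if len(sizes) < cm.k:
        missing = sorted(set(range(cm.k)) - set(sizes.index))
        raise ValueError(f"empty cluster(s): {missing}")
    ages = list(df.columns)
    peak_idx = profiles.to_numpy().argmax(axis=1)  # argmax takes first maximum: earliest age
    peak_age = pd.Series([ages[i] for i in peak_idx], index=profiles.index, name="peak_age")
    peak_val = profiles.to_numpy()[np.arange(len(profiles)), peak_idx]
    order = sorted(
        range(len(profiles)),
        key=lambda i: (peak_idx[i], -peak_val[i], profiles.index[i]),
    )
    rank = pd.Series(0, index=profiles.index, name="rank")
    for r, i in enumerate(order):
        rank.iloc[i] = r
    return ClusterSummary(profiles=profiles, peak_age=peak_age, rank=rank, sizes=sizes)
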