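"""Agglomerative clustering, silhouette diagnostics and classical MDS.

The clustering operates on a precomputed dissimilarity matrix (here:
normalized DTW distances).  The agglomeration is Ward.D2: squared
dissimilarities drive the Lance–Williams update

    d(k, i∪j)^2 = [ (n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2
                    - n_k d(i,j)^2 ] / (n_i + n_j + n_k)

and the recorded merge height is the unsquared dissimilarity.  Ward is
reducible, so merging the globally closest pair at each step yields
monotone non-decreasing heights.  DTW dissimilarities are not Euclidean,
so Ward on them is a (standard, documented) heuristic rather than an
exact variance decomposition.

Classical MDS (Torgerson scaling) double-centres the squared-distance
matrix, eigendecomposes it, and scales the top eigenvectors by the
square root of their eigenvalues; the ratio of each positive eigenvalue
to the sum of positive eigenvalues is the variance fraction of that
dimension.  Negative eigenvalues (expected for non-Euclidean input) are
excluded from both the coordinates and the variance denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class ClusterMixin:  # type: ignore[no-redef]
        pass

    class TransformerMixin:  # type: ignore[no-redef]
        pass

from .dtw import DissimilarityMatrix

__all__ = [
    "LinkageTree",
    "MdsEmbedding",
    "ward_linkage",
    "cut_tree",
    "renumber_by_value",
    "avg_silhouette",
    "silhouette_scan",
    "classical_mds",
    "WardClustering",
    "ClassicalMDS",
]


def _as_square(dm) -> np.ndarray:
    values = dm.values if isinstance(dm, DissimilarityMatrix) else np.asarray(dm, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(values < 0):
        raise ValueError("dissimilarities must be nonnegative")
    return np.asarray(values, dtype=float)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration record in scipy linkage convention.

    ``merges`` is an (n_leaves - 1, 4) array; row t merges clusters with
    ids ``merges[t, 0]`` and ``merges[t, 1]`` (leaves are 0..n-1, the
    cluster formed at step t gets id n + t) at height ``merges[t, 2]``
    into a cluster of size ``merges[t, 3]``.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("need exactly n_leaves - 1 merges")
        if np.any(self.merges[:, 2] < 0):
            raise ValueError("heights must be nonnegative")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_scipy(self) -> np.ndarray:
        return self.merges.copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["member_a", "member_b", "height", "new_size"]
        )


def ward_linkage(dm: DissimilarityMatrix | np.ndarray) -> LinkageTree:
    """Ward.D2 agglomeration of a dissimilarity matrix.

    At each step the pair of active clusters with the smallest updated
    (squared) dissimilarity is merged; ties break on the smallest
    (index_a, index_b) pair for determinism.  O(n^3) with vectorised
    row updates — comfortable for cohort-scale matrices.
    """
    D = _as_square(dm)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    S = D.astype(float) ** 2  # work on squared dissimilarities
    np.fill_diagonal(S, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    ids = np.arange(n)
    merges = np.empty((n - 1, 4))
    # mask the lower triangle so argmin scans each unordered pair once,
    # returning the lexicographically smallest (i, j) on ties
    iu = np.tril_indices(n)
    M = S.copy()
    M[iu] = np.inf
    for step in range(n - 1):
        flat = int(np.argmin(M))
        i, j = divmod(flat, n)
        s_ij = M[i, j]
        height = float(np.sqrt(s_ij))
        merges[step] = (ids[i], ids[j], height, sizes[i] + sizes[j])
        # Lance-Williams update into slot i
        k = active.copy()
        k[i] = k[j] = False
        ni, nj, nk = sizes[i], sizes[j], sizes[k]
        new = ((ni + nk) * S[k, i] + (nj + nk) * S[k, j] - nk * s_ij) / (
            ni + nj + nk
        )
        S[k, i] = new
        S[i, k] = new
        active[j] = False
        sizes[i] += sizes[j]
        ids[i] = n + step
        # refresh masked matrix rows/cols touched
        M[:, j] = np.inf
        M[j, :] = np.inf
        M[:i, i] = S[:i, i].copy()
        M[i, i + 1:] = S[i, i + 1:].copy()
        inactive = ~active
        M[inactive, :] = np.inf
        M[:, inactive] = np.inf
        np.fill_diagonal(M, np.inf)
    return LinkageTree(merges=merges, n_leaves=n)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels for k clusters by undoing the last k - 1 merges.

    Returns integer labels 0..k-1, numbered by order of first leaf
    appearance (deterministic; semantic renumbering is a separate step,
    see :func:`renumber_by_value`).  Cuts at different k are nested.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = np.arange(n + max(0, n - k))
    cluster_members: dict[int, int] = {}  # cluster id -> representative leaf

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    reps = {i: i for i in range(n)}  # cluster id -> union-find root
    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        ra, rb = find(reps[int(a)]), find(reps[int(b)])
        parent[rb] = ra
        reps[n + step] = ra
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_index=False, return_inverse=True)
    # renumber by first appearance
    order = {}
    out = np.empty(n, dtype=int)
    for idx, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[idx] = order[lab]
    return out


def renumber_by_value(
    labels: np.ndarray, values: Sequence[float], one_based: bool = True
) -> np.ndarray:
    """Renumber clusters by increasing mean of ``values`` (per element).

    Used to give clusters their semantic order — cluster 1 is the
    lowest-protein pattern.  Ties break by decreasing cluster size.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    stats = []
    for lab in np.unique(labels):
        mask = labels == lab
        stats.append((float(values[mask].mean()), -int(mask.sum()), lab))
    mapping = {lab: rank + (1 if one_based else 0)
               for rank, (_, _, lab) in enumerate(sorted(stats))}
    return np.array([mapping[lab] for lab in labels])


def avg_silhouette(
    dm: DissimilarityMatrix | np.ndarray, labels: Sequence[int]
) -> tuple[float, np.ndarray]:
    """Mean silhouette width and per-point widths.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean
    within-cluster dissimilarity excluding self and b(i) the smallest
    mean dissimilarity to another cluster.  Points in singleton
    clusters score 0.
    """
    D = _as_square(dm)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if uniq.size > len(labels) - 0:
        raise ValueError("more clusters than points")
    n = len(labels)
    widths = np.zeros(n)
    # mean distance from every point to every cluster
    means = np.stack([D[:, labels == c].mean(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    for idx, c in enumerate(uniq):
        mask = labels == c
        size = sizes[idx]
        if size == 1:
            widths[mask] = 0.0
            continue
        a = means[mask, idx] * size / (size - 1)  # exclude self-distance 0
        other = np.delete(means[mask], idx, axis=1)
        b = other.min(axis=1)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            s = np.where(denom > 0, (b - a) / denom, 0.0)
        widths[mask] = s
    return float(widths.mean()), widths


def silhouette_scan(
    dm: DissimilarityMatrix | np.ndarray,
    tree: LinkageTree,
    k_range: Sequence[int],
) -> pd.DataFrame:
    """Mean silhouette width per candidate k; flags the argmax."""
    rows = []
    for k in k_range:
        labels = cut_tree(tree, int(k))
        mean_width, _ = avg_silhouette(dm, labels)
        rows.append({"k": int(k), "mean_width": mean_width})
    table = pd.DataFrame(rows)
    table["is_best"] = table["mean_width"] == table["mean_width"].max()
    return table


@dataclass(frozen=True)
class MdsEmbedding:
    coordinates: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray  # full spectrum, decreasing
    variance_fraction: np.ndarray  # per retained dimension

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, columns=cols,
                            index=list(labels) if labels is not None else None)


def classical_mds(
    dm: DissimilarityMatrix | np.ndarray, dims: int = 2
) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    B = -1/2 J D^2 J with J = I - 11'/n; coordinates are the top
    eigenvectors of B scaled by sqrt(eigenvalue).  Variance fractions
    are eigenvalues over the sum of positive eigenvalues.  If fewer
    than ``dims`` positive eigenvalues exist, the embedding is reduced
    with a warning.
    """
    D = _as_square(dm)
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-12 * abs(eigvals[0]))
    n_pos = int(positive.sum())
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing embedding from "
            f"{dims} to {n_pos} dimensions",
            stacklevel=2,
        )
        dims = n_pos
    coords = eigvecs[:, :dims] * np.sqrt(eigvals[:dims])
    pos_sum = eigvals[positive].sum()
    variance_fraction = eigvals[:dims] / pos_sum if pos_sum > 0 else np.zeros(dims)
    return MdsEmbedding(
        coordinates=coords,
        eigenvalues=eigvals,
        variance_fraction=variance_fraction,
    )


class WardClustering(ClusterMixin, BaseEstimator):
    """Ward.D2 agglomerative clustering over a precomputed dissimilarity.

    Parameters
    ----------
    n_clusters : int, default 3
        Where to cut the tree.

    Attributes
    ----------
    linkage_ : LinkageTree
        Full agglomeration record (scipy linkage convention).
    labels_ : ndarray of int
        Cluster labels, 0-based, numbered by first leaf appearance.
    heights_ : ndarray
        Merge heights, monotone non-decreasing.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "WardClustering":
        X = X.values if isinstance(X, DissimilarityMatrix) else np.asarray(X, float)
        self.linkage_ = ward_linkage(X)
        self.heights_ = self.linkage_.heights
        self.labels_ = cut_tree(self.linkage_, self.n_clusters)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical MDS transformer over a precomputed dissimilarity.

    Attributes
    ----------
    embedding_ : ndarray (n, n_components)
    eigenvalues_ : ndarray, full spectrum in decreasing order
    variance_fraction_ : ndarray, per retained dimension
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "ClassicalMDS":
        result = classical_mds(X, dims=self.n_components)
        self.embedding_ = result.coordinates
        self.eigenvalues_ = result.eigenvalues
        self.variance_fraction_ = result.variance_fraction
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_

    def transform(self, X) -> np.ndarray:
        # classical MDS has no out-of-sample map; transform refits
        return self.fit_transform(X)
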