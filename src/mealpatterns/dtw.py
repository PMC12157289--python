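"""Normalized Dynamic Time Warping over per-EO protein series.

DTW aligns two sequences by a monotone warping path and returns the
minimum cumulative cost.  The step pattern is the classic symmetric one
(diagonal steps weighted 2, horizontal/vertical weighted 1), whose
cumulative cost admits the per-path normalisation constant n + m — the
only standard pattern with a defined normalisation, which is what makes
series of different lengths comparable:

    D(1,1) = d(1,1)
    D(i,j) = min( D(i-1,j-1) + 2 d(i,j),
                  D(i-1,j)   +   d(i,j),
                  D(i,j-1)   +   d(i,j) )      with d(i,j) = |x_i - y_j|

    normalized_distance = D(n,m) / (n + m)

Clock times are deliberately not inputs: the alignment compares the
*shape* of intake across eating occasions, not when they happened.
Series carry raw protein grams, unscaled — z-normalisation would erase
the intake-level differences the clustering is meant to find.

No warping window is applied.  DTW is not a metric (no triangle
inequality); downstream consumers treat the matrix as a dissimilarity,
not a distance in the metric sense.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

try:  # estimator facade; the numerical core has no sklearn dependency
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore[no-redef]
        pass

__all__ = [
    "DtwResult",
    "DissimilarityMatrix",
    "dtw_distance",
    "pairwise_dtw",
    "distance_matrix",
    "DtwDistance",
]


@dataclass(frozen=True)
class DtwResult:
    raw_distance: float
    normalized_distance: float
    path: tuple[tuple[int, int], ...]  # 1-based (i, j) pairs
    path_length_norm: int  # the normalisation constant n + m


def dtw_distance(x: Sequence[float], y: Sequence[float]) -> DtwResult:
    """DTW distance between two series with full path backtracking.

    Ties among predecessor cells break diagonal > up > left; this
    affects only the reported path, never the distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW requires non-empty series")
    n, m = x.size, y.size
    cost = np.abs(x[:, None] - y[None, :])
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            D[i, j] = min(
                D[i - 1, j - 1] + 2.0 * cost[i, j],
                D[i - 1, j] + cost[i, j],
                D[i, j - 1] + cost[i, j],
            )
    # backtrack
    path = [(n, m)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i > 0 and j > 0:
            candidates = (
                (D[i - 1, j - 1] + 2.0 * cost[i, j], (i - 1, j - 1)),
                (D[i - 1, j] + cost[i, j], (i - 1, j)),
                (D[i, j - 1] + cost[i, j], (i, j - 1)),
            )
            best = min(c[0] for c in candidates)
            for value, pred in candidates:  # diagonal > up > left on ties
                if value == best:
                    i, j = pred
                    break
        elif i > 0:
            i -= 1
        else:
            j -= 1
        path.append((i + 1, j + 1))
    raw = float(D[n - 1, m - 1])
    return DtwResult(
        raw_distance=raw,
        normalized_distance=raw / (n + m),
        path=tuple(reversed(path)),
        path_length_norm=n + m,
    )


def _batched_dtw(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Normalized DTW for a batch of equal-length pairs.

    X is (B, n), Y is (B, m); returns (B,) normalized distances.  The
    dynamic programme runs cell-by-cell with the batch vectorised, so
    the Python-level work is n*m steps regardless of batch size.
    """
    B, n = X.shape
    m = Y.shape[1]
    D = np.empty((B, n, m))
    d00 = np.abs(X[:, 0] - Y[:, 0])
    D[:, 0, 0] = d00
    for j in range(1, m):
        D[:, 0, j] = D[:, 0, j - 1] + np.abs(X[:, 0] - Y[:, j])
    for i in range(1, n):
        D[:, i, 0] = D[:, i - 1, 0] + np.abs(X[:, i] - Y[:, 0])
        for j in range(1, m):
            d = np.abs(X[:, i] - Y[:, j])
            D[:, i, j] = d + np.minimum(
                D[:, i - 1, j - 1] + d,
                np.minimum(D[:, i - 1, j], D[:, i, j - 1]),
            )
    return D[:, n - 1, m - 1] / (n + m)


def _dtw_for_pairs(
    xs: list[np.ndarray],
    ys: list[np.ndarray],
    pi: np.ndarray,
    pj: np.ndarray,
) -> np.ndarray:
    """Normalized DTW for explicit (pi[k], pj[k]) index pairs, batched by shape."""
    out = np.empty(pi.size)
    lx = np.array([s.size for s in xs])
    ly = np.array([s.size for s in ys])
    shapes = lx[pi] * 100000 + ly[pj]
    for shape in np.unique(shapes):
        mask = shapes == shape
        X = np.stack([xs[i] for i in pi[mask]])
        Y = np.stack([ys[j] for j in pj[mask]])
        out[mask] = _batched_dtw(X, Y)
    return out


def pairwise_dtw(
    series_x: Sequence[np.ndarray], series_y: Sequence[np.ndarray]
) -> np.ndarray:
    """Cross matrix of normalized DTW distances, (len_x, len_y).

    Pairs are grouped by their (len(x), len(y)) so each group runs as
    one batched dynamic programme.
    """
    xs = [np.asarray(s, dtype=float) for s in series_x]
    ys = [np.asarray(s, dtype=float) for s in series_y]
    if any(s.size == 0 for s in xs) or any(s.size == 0 for s in ys):
        raise ValueError("DTW requires non-empty series")
    pairs_i, pairs_j = np.meshgrid(np.arange(len(xs)), np.arange(len(ys)), indexing="ij")
    pi, pj = pairs_i.ravel(), pairs_j.ravel()
    return _dtw_for_pairs(xs, ys, pi, pj).reshape(len(xs), len(ys))


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative matrix of normalized DTW distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("off-diagonals must be finite and nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def label_checksum(self) -> str:
        return hashlib.sha256("\n".join(self.labels).encode()).hexdigest()[:16]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.index.name = f"checksum_{self.label_checksum()}"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        dm = cls(labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))
        stamp = str(df.index.name or "")
        if stamp.startswith("checksum_") and stamp != f"checksum_{dm.label_checksum()}":
            raise ValueError("label checksum mismatch reading dissimilarity matrix")
        return dm


def distance_matrix(
    series: Sequence, labels: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Full matrix of normalized DTW distances over a list of series.

    Accepts :class:`~mealpatterns.intake.IntakeSeries` objects or plain
    arrays.  All unordered pairs are computed once; the diagonal is
    fixed at zero (self-comparison is excluded by construction).
    """
    values = [
        np.asarray(getattr(s, "values", s), dtype=float) for s in series
    ]
    if len(values) < 2:
        raise ValueError("need at least 2 series for a distance matrix")
    if labels is None:
        labels = [
            getattr(s, "series_id", str(i)) for i, s in enumerate(series)
        ]
    n = len(values)
    pi, pj = np.triu_indices(n, k=1)  # each unordered pair exactly once
    d = _dtw_for_pairs(values, values, pi, pj)
    full = np.zeros((n, n))
    full[pi, pj] = d
    full[pj, pi] = d
    return DissimilarityMatrix(labels=list(labels), values=full)


class DtwDistance(TransformerMixin, BaseEstimator):
    """Pairwise normalized-DTW transformer (scikit-learn style).

    ``fit`` stores the reference series; ``transform`` returns the
    cross matrix of normalized DTW distances between its argument and
    the reference, so ``fit_transform(X)`` yields the square
    dissimilarity matrix used for clustering and embedding.

    Examples
    --------
    >>> import numpy as np
    >>> DtwDistance().fit_transform([np.r_[1.0, 3.0], np.r_[1.0, 2.0, 3.0]]).shape
    (2, 2)
    """

    def fit(self, X: Sequence[np.ndarray], y=None) -> "DtwDistance":
        X = [np.asarray(getattr(s, "values", s), dtype=float) for s in X]
        if len(X) == 0 or any(s.size == 0 for s in X):
            raise ValueError("DTW requires a non-empty list of non-empty series")
        self.series_ = X
        self.n_features_in_ = len(X)
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        if not hasattr(self, "series_"):
            raise ValueError("DtwDistance is not fitted")
        X = [np.asarray(getattr(s, "values", s), dtype=float) for s in X]
        out = pairwise_dtw(X, self.series_)
        return out

    def fit_transform(self, X: Sequence[np.ndarray], y=None) -> np.ndarray:
        self.fit(X)
        return distance_matrix(self.series_).values
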