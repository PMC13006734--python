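"""Pattern-similarity analytics: dynamic time warping and DTW clustering.

DTW aligns two multichannel time series with the classic dynamic program
over (insert, delete, match) steps, boundary-matched, with squared Euclidean
local cost across channels.  On top of it sit a k-medoids clusterer (cluster
centers are the DTW-closest members) and group-wise mean-distance heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "DTWResult",
    "ClusterAssignment",
    "dtw_distance",
    "dtw_kmeans",
    "distance_heatmap",
    "pairwise_dtw",
    "TimeSeriesKMedoids",
]


@dataclass
class DTWResult:
    distance: float
    path: list[tuple[int, int]] | None = None


def _as2d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("sequences must be non-empty 1-D or (T, C) arrays")
    return np.ascontiguousarray(arr)


@njit(cache=True)
def _dtw_matrix(a, b):  # pragma: no cover - compiled
    n, m = a.shape[0], b.shape[0]
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0.0
            for c in range(a.shape[1]):
                d = a[i - 1, c] - b[j - 1, c]
                cost += d * d
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D


def dtw_distance(a, b, return_path: bool = False, band: int | None = None) -> DTWResult:
    """Minimal cumulative squared-difference alignment cost between a and b.

    Symmetric step pattern (up, right, diagonal), boundary-matched.  With
    ``band`` set, a Sakoe-Chiba window of that half-width constrains the
    warping path.
    """
    A, B = _as2d(a), _as2d(b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("channel counts must match")
    if band is None:
        D = _dtw_matrix(A, B)
    else:
        D = _dtw_matrix_banded(A, B, band)
    dist = float(D[A.shape[0], B.shape[0]])
    path = None
    if return_path:
        path = []
        i, j = A.shape[0], B.shape[0]
        while i > 0 and j > 0:
            path.append((i - 1, j - 1))
            moves = [(D[i - 1, j - 1], i - 1, j - 1), (D[i - 1, j], i - 1, j), (D[i, j - 1], i, j - 1)]
            _, i, j = min(moves)
        path.reverse()
    return DTWResult(distance=dist, path=path)


@njit(cache=True)
def _dtw_matrix_banded(a, b, band):  # pragma: no cover - compiled
    n, m = a.shape[0], b.shape[0]
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo = max(1, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            cost = 0.0
            for c in range(a.shape[1]):
                d = a[i - 1, c] - b[j - 1, c]
                cost += d * d
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D


def pairwise_dtw(sequences) -> np.ndarray:
    """Symmetric matrix of DTW distances between all sequence pairs."""
    seqs = [_as2d(s) for s in sequences]
    n = len(seqs)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = dtw_distance(seqs[i], seqs[j]).distance
    return M


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # (n,) in [0, k)
    medoid_indices: np.ndarray  # (k,)
    mean_intra_distance: np.ndarray  # (k,) mean member-to-medoid DTW
    inertia: float  # sum of member-to-medoid distances


def dtw_kmeans(sequences, k: int, max_iter: int = 50, seed: int = 0) -> ClusterAssignment:
    """DTW-based k-means with medoid centers.

    Alternates nearest-medoid assignment and medoid update (the member
    minimizing the summed DTW distance to its cluster) until labels
    stabilize or ``max_iter``; the within-cluster objective is
    non-increasing.  Distances are computed once into a pairwise matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = list(sequences)
    n = len(seqs)
    if k > n:
        raise ValueError("k cannot exceed the number of sequences")
    M = pairwise_dtw(seqs)
    rng = np.random.default_rng(seed)
    # farthest-point initialization: spreads the k seeds across the data
    first = int(rng.integers(n))
    chosen = [first]
    while len(chosen) < k:
        mind = M[:, chosen].min(axis=1)
        mind[chosen] = -1.0
        chosen.append(int(np.argmax(mind)))
    medoids = np.array(chosen)
    labels = np.argmin(M[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = M[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = np.argmin(M[:, new_medoids], axis=1)
        if np.array_equal(new_labels, labels) and np.array_equal(new_medoids, medoids):
            break
        medoids, labels = new_medoids, new_labels
    intra = np.zeros(k)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members):
            intra[c] = M[members, medoids[c]].mean()
    inertia = float(M[np.arange(n), medoids[labels]].sum())
    return ClusterAssignment(labels=labels, medoid_indices=medoids, mean_intra_distance=intra, inertia=inertia)


def distance_heatmap(groups: dict) -> tuple[np.ndarray, list]:
    """Mean pairwise DTW distance between labeled sequence groups.

    Entry (i, j) is the mean DTW over pairs from group i x group j; the
    diagonal is the mean over distinct intra-group pairs (0 for singleton
    groups).  Symmetric for the symmetric step pattern.
    """
    keys = list(groups)
    n = len(keys)
    H = np.zeros((n, n))
    for i in range(n):
        gi = [_as2d(s) for s in groups[keys[i]]]
        if not gi:
            raise ValueError(f"group {keys[i]!r} is empty")
        for j in range(i, n):
            gj = [_as2d(s) for s in groups[keys[j]]]
            if i == j:
                pairs = [(a, b) for ai, a in enumerate(gi) for b in gi[ai + 1 :]]
                val = float(np.mean([dtw_distance(a, b).distance for a, b in pairs])) if pairs else 0.0
            else:
                val = float(np.mean([dtw_distance(a, b).distance for a in gi for b in gj]))
            H[i, j] = H[j, i] = val
    return H, keys


class TimeSeriesKMedoids(BaseEstimator, ClusterMixin):
    """scikit-learn-style wrapper around DTW k-medoids clustering."""

    def __init__(self, n_clusters: int = 3, max_iter: int = 50, random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        seqs = [_as2d(x) for x in X]
        result = dtw_kmeans(seqs, self.n_clusters, max_iter=self.max_iter, seed=self.random_state)
        self.labels_ = result.labels
        self.medoid_indices_ = result.medoid_indices
        self.medoids_ = [seqs[i] for i in result.medoid_indices]
        self.inertia_ = result.inertia
        self.mean_intra_distance_ = result.mean_intra_distance
        return self

    def predict(self, X):
        return np.array(
            [int(np.argmin([dtw_distance(_as2d(x), m).distance for m in self.medoids_])) for x in X]
        )
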