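"""Weighted feature graph and greedy similarity-path orderings.

Every pair of feature columns gets an edge weighted by the Euclidean
distance between the (standardized) columns, giving a complete weighted
graph over features. Walking that graph greedily — always to the nearest
unvisited feature — yields a permutation U_min along which each sample's
feature vector varies smoothly; always to the farthest unvisited feature
yields U_max, the most oscillatory arrangement. These two orderings feed
the multilevel wavelet decomposition downstream.

The diagonal of the distance matrix is +inf when the minimum-similarity
search is intended and -1 when the maximum-similarity search is intended,
so a feature can never be its own nearest or farthest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import FeatureMatrix


@dataclass
class FeatureGraph:
    n_features: int
    dis: np.ndarray               # (N, N) distances with mode-dependent diagonal
    diagonal_mode: str            # "min_search" | "max_search"


@dataclass
class FeatureOrdering:
    permutation: np.ndarray       # bijection on 0..N-1
    mode: str                     # "min" | "max"
    start_vertex: int

    def __post_init__(self):
        p = np.asarray(self.permutation, dtype=int)
        n = len(p)
        if not np.array_equal(np.sort(p), np.arange(n)):
            raise ValueError("permutation is not a bijection on 0..N-1")
        if p[0] != self.start_vertex:
            raise ValueError("permutation must begin at start_vertex")
        self.permutation = p

    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(len(self.permutation))
        return inv


def pairwise_distance(X: FeatureMatrix | np.ndarray,
                      diagonal_mode: str = "min_search") -> FeatureGraph:
    """Complete weighted graph: dis[i, j] = ||column_i - column_j||_2."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need at least 2 features to build a feature graph")
    if diagonal_mode not in ("min_search", "max_search"):
        raise ValueError(f"unknown diagonal_mode {diagonal_mode!r}")
    dis = squareform(pdist(values.T, metric="euclidean"))
    np.fill_diagonal(dis, np.inf if diagonal_mode == "min_search" else -1.0)
    return FeatureGraph(n_features=n, dis=dis, diagonal_mode=diagonal_mode)


def path_length(graph: FeatureGraph, path: np.ndarray) -> float:
    """Total edge weight along consecutive pairs of a feature path."""
    return float(graph.dis[path[:-1], path[1:]].sum())


def _greedy_walk(graph: FeatureGraph, mode: str, start_vertex: int) -> np.ndarray:
    n = graph.n_features
    visited = np.zeros(n, dtype=bool)
    path = np.empty(n, dtype=int)
    current = start_vertex
    path[0] = current
    visited[current] = True
    mask_value = np.inf if mode == "min" else -np.inf
    pick = np.argmin if mode == "min" else np.argmax
    for k in range(1, n):
        row = graph.dis[current].copy()
        row[visited] = mask_value
        current = int(pick(row))          # argmin/argmax take the lowest index on ties
        path[k] = current
        visited[current] = True
    return path


def greedy_similarity_path(graph: FeatureGraph, mode: str,
                           start_vertex: int | None = None) -> FeatureOrdering:
    """Greedy nearest- (mode="min") or farthest- (mode="max") neighbour path.

    From the current feature, append the unvisited feature at minimum
    (maximum) distance, until every feature is visited. Ties break to the
    lowest feature index.

    With ``start_vertex=None`` the walk is run from every possible start
    and the shortest (mode="min") or longest (mode="max") resulting path
    is kept — the multi-start approximation to the shortest/longest route
    through the feature graph. A single fixed start can fold the path
    back on itself when it happens to sit mid-way along the features'
    latent arrangement; scanning all starts costs only O(N^3) and is
    deterministic (ties break to the lowest start index).
    """
    if mode not in ("min", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    expected = "min_search" if mode == "min" else "max_search"
    if graph.diagonal_mode != expected:
        raise ValueError(
            f"graph built for {graph.diagonal_mode}, but mode={mode!r} requested")
    n = graph.n_features
    off_diag = graph.dis[~np.eye(n, dtype=bool)]
    if not np.all(np.isfinite(off_diag)):
        raise ValueError("non-finite off-diagonal distance in feature graph")
    if start_vertex is not None:
        if not 0 <= start_vertex < n:
            raise ValueError(f"start_vertex {start_vertex} out of range for N={n}")
        path = _greedy_walk(graph, mode, start_vertex)
        return FeatureOrdering(permutation=path, mode=mode,
                               start_vertex=start_vertex)
    best_path = None
    best_len = None
    for start in range(n):
        path = _greedy_walk(graph, mode, start)
        length = path_length(graph, path)
        better = (best_len is None
                  or (mode == "min" and length < best_len)
                  or (mode == "max" and length > best_len))
        if better:
            best_path, best_len = path, length
    return FeatureOrdering(permutation=best_path, mode=mode,
                           start_vertex=int(best_path[0]))


def apply_ordering(X: FeatureMatrix, ordering: FeatureOrdering) -> FeatureMatrix:
    """Reorder every row (and the feature names) by the permutation."""
    p = ordering.permutation
    if len(p) != X.values.shape[1]:
        raise ValueError(
            f"ordering length {len(p)} != feature count {X.values.shape[1]}")
    return FeatureMatrix(values=X.values[:, p],
                         feature_names=[X.feature_names[i] for i in p],
                         sample_ids=list(X.sample_ids),
                         standardized=X.standardized)


def min_max_orderings(X: FeatureMatrix,
                      start_vertex: int | None = None,
                      ) -> tuple[FeatureOrdering, FeatureOrdering]:
    """Convenience: both greedy orderings from one matrix."""
    g_min = pairwise_distance(X, "min_search")
    g_max = pairwise_distance(X, "max_search")
    return (greedy_similarity_path(g_min, "min", start_vertex),
            greedy_similarity_path(g_max, "max", start_vertex))


def first_difference_energy(X: FeatureMatrix | np.ndarray,
                            ordering: FeatureOrdering | None = None) -> float:
    """Mean over rows of sum_k (x[k+1] - x[k])^2 — the smoothness proxy."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    if ordering is not None:
        values = values[:, ordering.permutation]
    return float(np.mean(np.sum(np.diff(values, axis=1) ** 2, axis=1)))
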