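"""Batch (Lloyd-sweep) K-means with pluggable initial centroids.

One *sweep* = assign every point to its nearest centroid, then recompute
each centroid as its cluster mean.  The run stops when an entire sweep
leaves the assignment vector unchanged; that confirming sweep is the last
one counted.  ``iterations`` on the returned :class:`Partition` is the
number of completed sweeps (>= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import DegeneracyError, InputError, NumericError

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """A hard clustering: assignments, centroids, objective and run metadata."""

    labels: np.ndarray
    centroids: np.ndarray
    K: int
    sse: float
    iterations: int
    converged: bool
    sse_path: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)


def sse_of(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Total within-cluster sum of squared Euclidean distances to centroids."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if labels.min() < 0 or labels.max() >= centroids.shape[0]:
        raise IndexError(
            f"label out of range [0, {centroids.shape[0]}): "
            f"min={labels.min()}, max={labels.max()}"
        )
    diff = X - centroids[labels]
    return float((diff * diff).sum())


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # argmin breaks ties toward the lowest cluster index
    return cdist(X, centroids, metric="sqeuclidean").argmin(axis=1)


def _update(X: np.ndarray, labels: np.ndarray, old_centroids: np.ndarray, K: int) -> np.ndarray:
    """Cluster means; an empty cluster's centroid is reset to the data point
    farthest from that cluster's previous centroid (keeps K fixed)."""
    centroids = old_centroids.copy()
    counts = np.bincount(labels, minlength=K)
    for k in range(K):
        if counts[k] > 0:
            centroids[k] = X[labels == k].mean(axis=0)
    taken: set[int] = set()
    for k in np.flatnonzero(counts == 0):
        dist = ((X - old_centroids[k]) ** 2).sum(axis=1)
        for i in taken:
            dist[i] = -np.inf
        far = int(dist.argmax())
        taken.add(far)
        centroids[k] = X[far]
        logger.debug("empty cluster %d reseeded at row %d", k, far)
    return centroids


def run_kmeans(X: np.ndarray, init_centroids: np.ndarray,
               max_iter: int = 300, tol: float = 1e-9) -> Partition:
    """Run batch K-means from the given centroids until the assignment is stable.

    Parameters
    ----------
    X : (n, d) array
    init_centroids : (K, d) array with pairwise-distinct rows
    max_iter : hard cap on sweeps
    tol : safeguard — also stop once the largest centroid shift drops below it

    Returns
    -------
    Partition with every cluster non-empty, ``sse`` recomputed from the final
    assignment, and the per-sweep SSE trace in ``sse_path``.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise NumericError("X contains non-finite values")
    centroids = np.atleast_2d(np.asarray(init_centroids, dtype=float)).copy()
    K = centroids.shape[0]
    n = X.shape[0]
    if K > n:
        raise InputError(f"K={K} exceeds n={n}")
    if len(np.unique(centroids, axis=0)) != K:
        raise DegeneracyError("initial centroids must be pairwise distinct")

    labels = _assign(X, centroids)
    iterations = 0
    converged = False
    sse_path: list[float] = []
    for it in range(1, max_iter + 1):
        new_centroids = _update(X, labels, centroids, K)
        new_labels = _assign(X, new_centroids)
        iterations = it
        sse_path.append(sse_of(X, new_labels, new_centroids))
        shift = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        stable = bool((new_labels == labels).all())
        labels, centroids = new_labels, new_centroids
        if stable or shift < tol:
            converged = True
            break

    # final safeguard: repair any empty cluster left at the boundary
    for _ in range(K):
        if np.bincount(labels, minlength=K).min() > 0:
            break
        centroids = _update(X, labels, centroids, K)
        labels = _assign(X, centroids)

    return Partition(
        labels=labels,
        centroids=centroids,
        K=K,
        sse=sse_of(X, labels, centroids),
        iterations=iterations,
        converged=converged,
        sse_path=sse_path,
    )


def random_init(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    """K distinct rows of X drawn uniformly without replacement."""
    X = np.asarray(X, dtype=float)
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < K:
        raise DegeneracyError(
            f"only {distinct.shape[0]} distinct rows, cannot draw K={K}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(distinct.shape[0], size=K, replace=False)
    return distinct[idx]


def best_of_restarts(X: np.ndarray, K: int, restarts: int, seed: int,
                     max_iter: int = 300, tol: float = 1e-9) -> Partition:
    """Minimum-SSE partition over ``restarts`` random-init runs (seeds seed..seed+restarts-1)."""
    if restarts < 1:
        raise InputError("restarts must be >= 1")
    best: Partition | None = None
    for s in range(seed, seed + restarts):
        part = run_kmeans(X, random_init(X, K, s), max_iter=max_iter, tol=tol)
        if best is None or part.sse < best.sse:
            best = part
    assert best is not None
    return best
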