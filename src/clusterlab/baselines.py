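"""Comparison clusterers: agglomerative, DBSCAN and EM Gaussian mixture.

These wrap scikit-learn / scipy behind a uniform result type.  DBSCAN noise
points keep label -1; non-noise labels are always consecutive from 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .exceptions import InputError
from .initializers import tree_cut_labels
from .kmeans import Partition, sse_of

logger = logging.getLogger(__name__)


@dataclass
class BaselineResult:
    """Partition produced by one baseline method plus the parameters used."""

    partition: Partition
    method: str
    params: dict[str, Any]


def _partition_from_labels(X: np.ndarray, labels: np.ndarray,
                           iterations: int = 1, converged: bool = True) -> Partition:
    """Build a Partition from a hard labelling; noise (-1) rows are excluded
    from centroids and SSE."""
    labels = np.asarray(labels, dtype=int)
    core = labels >= 0
    k_eff = int(labels[core].max()) + 1 if core.any() else 0
    if k_eff:
        centroids = np.stack([X[labels == k].mean(axis=0) for k in range(k_eff)])
        sse = sse_of(X[core], labels[core], centroids)
    else:
        centroids = np.empty((0, X.shape[1]))
        sse = 0.0
    return Partition(labels=labels, centroids=centroids, K=k_eff, sse=sse,
                     iterations=iterations, converged=converged)


def agglomerative(X: np.ndarray, K: int, linkage: str = "ward") -> BaselineResult:
    """Cut an agglomerative tree into K clusters (same tree as ``hier_init``)."""
    X = np.asarray(X, dtype=float)
    labels = tree_cut_labels(X, K, linkage)
    return BaselineResult(
        partition=_partition_from_labels(X, labels),
        method="hierarchical",
        params={"K": K, "linkage": linkage},
    )


def auto_eps(X: np.ndarray, min_pts: int) -> float:
    """Knee of the sorted min_pts-NN distance curve: maximum second difference."""
    X = np.asarray(X, dtype=float)
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    kdist = np.sort(dist[:, min_pts])  # distance to the min_pts-th neighbour, self excluded
    if kdist.size < 3:
        return float(kdist[-1])
    d2 = kdist[:-2] - 2.0 * kdist[1:-1] + kdist[2:]
    knee = int(d2.argmax()) + 1
    eps = float(kdist[knee])
    return eps if eps > 0 else float(kdist[kdist > 0][0]) if (kdist > 0).any() else 1e-12


def dbscan(X: np.ndarray, eps: float | str = "auto", min_pts: int = 4) -> BaselineResult:
    """Density-based clustering; ``eps='auto'`` picks the k-distance knee."""
    if min_pts < 2:
        raise InputError("min_pts must be >= 2")
    X = np.asarray(X, dtype=float)
    eps_val = auto_eps(X, min_pts) if eps == "auto" else float(eps)
    raw = DBSCAN(eps=eps_val, min_samples=min_pts).fit_predict(X)
    core = raw >= 0
    labels = raw.copy()
    if core.any():
        _, consec = np.unique(raw[core], return_inverse=True)
        labels[core] = consec
    else:
        warnings.warn("DBSCAN labelled every point as noise", stacklevel=2)
    return BaselineResult(
        partition=_partition_from_labels(X, labels),
        method="dbscan",
        params={"eps": eps_val, "min_pts": min_pts, "eps_mode": eps},
    )


def em_gmm(X: np.ndarray, K: int, restarts: int = 5, seed: int = 0) -> BaselineResult:
    """Full-covariance Gaussian mixture via EM, best log-likelihood over restarts.

    Fitting first runs unregularized; a singular covariance triggers a logged
    retry with a 1e-6 ridge on the diagonals.
    """
    X = np.asarray(X, dtype=float)
    if K > X.shape[0]:
        raise InputError(f"K={K} exceeds n={X.shape[0]}")
    if restarts < 1:
        raise InputError("restarts must be >= 1")
    kwargs = dict(n_components=K, covariance_type="full", n_init=restarts,
                  random_state=seed, max_iter=200)
    reg = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            gm = GaussianMixture(reg_covar=0.0, **kwargs).fit(X)
    except Exception:
        reg = 1e-6
        logger.info("em_gmm: singular covariance, refitting with 1e-6 ridge")
        gm = GaussianMixture(reg_covar=reg, **kwargs).fit(X)
    labels = np.unique(gm.predict(X), return_inverse=True)[1]
    part = _partition_from_labels(X, labels, iterations=int(gm.n_iter_),
                                  converged=bool(gm.converged_))
    return BaselineResult(
        partition=part,
        method="em",
        params={"K": K, "restarts": restarts, "seed": seed, "reg_covar": reg,
                "log_likelihood": float(gm.lower_bound_)},
    )
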