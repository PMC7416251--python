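"""Cluster-validity indices and optimal-k selection.

Internal indices (silhouette, Dunn, stability-weighted RPT) score a single
partition against the geometry; external indices (RI, ARI, AC, F, Hubert's
gamma, MI/VI) compare two labelings.  All pair-counting quantities are
computed exactly from the contingency table with Python integers, so they
agree with a naive O(n^2) double loop to the last bit.

``select_k`` votes among average silhouette, the gap statistic and an
automated elbow over a k range, resolving three-way disagreement by the
median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, log
from typing import Callable, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist

from .exceptions import ConfigError, UndefinedIndexError
from .kmeans import Partition, best_of_restarts, sse_of

logger = logging.getLogger(__name__)

#: Report column order used by every TSV emitted by the pipeline.
REPORT_COLUMNS = ("I", "SSE", "Si", "RPT", "Dunn", "RI", "ARI", "AC", "F", "HI", "VI")


# ---------------------------------------------------------------------------
# internal indices
# ---------------------------------------------------------------------------

def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the point's own cluster (self excluded);
    b_i the smallest mean distance to another cluster.  A singleton point
    contributes s_i = 0; coincident clusters give s_i = 1 via the a_i = 0
    convention (max(a_i, b_i) > 0 there).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedIndexError("silhouette requires >= 2 clusters")
    D = squareform(pdist(X))
    n = X.shape[0]
    sizes = {int(k): int((labels == k).sum()) for k in uniq}
    s = np.zeros(n)
    # mean distance from every point to every cluster
    cluster_means = np.stack([D[:, labels == k].sum(axis=1) for k in uniq], axis=1)
    counts = np.array([sizes[int(k)] for k in uniq], dtype=float)
    for i in range(n):
        ki = int(labels[i])
        pos = int(np.flatnonzero(uniq == ki)[0])
        if sizes[ki] == 1:
            s[i] = 0.0
            continue
        a = cluster_means[i, pos] / (sizes[ki] - 1)
        others = np.delete(cluster_means[i] / counts, pos)
        b = float(others.min())
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster point distance over maximum cluster diameter."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedIndexError("Dunn index requires >= 2 clusters")
    D = squareform(pdist(X))
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, True)
    inter = D[~same]
    intra = D[same & ~np.eye(len(labels), dtype=bool)]
    max_diam = float(intra.max()) if intra.size else 0.0
    min_inter = float(inter.min())
    if max_diam == 0.0:
        logger.warning("dunn_index: all clusters are point masses, returning inf")
        return float("inf")
    return min_inter / max_diam


ReclusterFn = Callable[[np.ndarray, int, int], np.ndarray]


def _default_recluster(Xb: np.ndarray, K: int, seed: int) -> np.ndarray:
    return best_of_restarts(Xb, K, restarts=5, seed=seed).labels


def rpt(X: np.ndarray, labels: np.ndarray, B: int = 50, seed: int = 0,
        recluster: Optional[ReclusterFn] = None) -> float:
    """Stability-weighted silhouette: ``Si * (1 + S_bar)``.

    S_bar in [0, 1] is the mean Rand index between the input labelling and a
    re-clustering of each of B bootstrap resamples (same method, same K),
    both restricted to the resampled points.
    """
    if B < 10:
        raise ConfigError("rpt requires B >= 10 bootstrap resamples")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = labels >= 0  # noise points (DBSCAN) are excluded
    Xc, lc = X[keep], labels[keep]
    si = silhouette_mean(Xc, lc)
    K = int(np.unique(lc).size)
    fn = recluster or _default_recluster
    rng = np.random.default_rng(seed)
    n = Xc.shape[0]
    agreements = []
    for b in range(B):
        idx = rng.choice(n, size=n, replace=True)
        idx = np.unique(idx)  # distinct resampled points; pair counting needs >= 2
        if idx.size < max(K + 1, 3):
            continue
        new = fn(Xc[idx], K, int(rng.integers(2**31)))
        ri, _ = rand_and_ari(lc[idx], new)
        agreements.append(ri)
    sbar = float(np.mean(agreements)) if agreements else 0.0
    return si * (1.0 + sbar)


# ---------------------------------------------------------------------------
# external (pair-counting / set-matching / information-theoretic) indices
# ---------------------------------------------------------------------------

def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.shape != v.shape:
        raise ValueError("label vectors must have equal length")
    if u.size < 2:
        raise ValueError("need at least 2 points")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    N = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(N, (ui, vi), 1)
    return N


def pair_counts(u: np.ndarray, v: np.ndarray) -> tuple[int, int, int, int]:
    """(a, b, c, d): pairs together in both / only u / only v / neither."""
    N = _contingency(u, v)
    n = int(N.sum())
    total = comb(n, 2)
    a = int(sum(comb(int(x), 2) for x in N.ravel()))
    p1 = int(sum(comb(int(x), 2) for x in N.sum(axis=1)))
    p2 = int(sum(comb(int(x), 2) for x in N.sum(axis=0)))
    b, c = p1 - a, p2 - a
    return a, b, c, total - a - b - c


def rand_and_ari(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Rand index and the Hubert-Arabie adjusted Rand index."""
    a, b, c, d = pair_counts(u, v)
    total = a + b + c + d
    ri = (a + d) / total
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        identical = b == 0 and c == 0
        logger.info("ARI denominator zero (trivial partitions); defining ARI=%d",
                    1 if identical else 0)
        return ri, 1.0 if identical else 0.0
    ari = 2.0 * (a * d - b * c) / denom
    return ri, ari


def accuracy_matched(u: np.ndarray, v: np.ndarray) -> float:
    """Fraction correct under the best one-to-one cluster-to-class assignment."""
    N = _contingency(u, v)
    r, s = linear_sum_assignment(N, maximize=True)
    return float(N[r, s].sum() / N.sum())


def f_measure(u: np.ndarray, v: np.ndarray) -> float:
    """Class-size-weighted best F1 of any cluster against each class of u."""
    N = _contingency(u, v).astype(float)
    n = N.sum()
    class_sizes = N.sum(axis=1)
    cluster_sizes = N.sum(axis=0)
    total = 0.0
    for i in range(N.shape[0]):
        best = 0.0
        for j in range(N.shape[1]):
            if N[i, j] == 0:
                continue
            prec = N[i, j] / cluster_sizes[j]
            rec = N[i, j] / class_sizes[i]
            best = max(best, 2 * prec * rec / (prec + rec))
        total += (class_sizes[i] / n) * best
    return float(total)


def hubert_gamma(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of the pairwise co-membership indicators."""
    a, b, c, d = pair_counts(u, v)
    total = a + b + c + d
    p1, p2 = a + b, a + c
    var = p1 * (total - p1) * p2 * (total - p2)
    if var == 0:
        raise UndefinedIndexError("Hubert's gamma undefined for a trivial partition")
    return float((total * a - p1 * p2) / np.sqrt(float(var)))


def mi_and_vi(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Mutual information and variation of information, in nats."""
    N = _contingency(u, v).astype(float)
    n = N.sum()
    p = N / n
    pu = p.sum(axis=1)
    pv = p.sum(axis=0)
    hu = -sum(x * log(x) for x in pu if x > 0)
    hv = -sum(x * log(x) for x in pv if x > 0)
    huv = -sum(x * log(x) for x in p.ravel() if x > 0)
    mi = hu + hv - huv
    vi = hu + hv - 2.0 * mi
    return float(mi), float(max(vi, 0.0))


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class ValidityReport:
    """All indices for one method on one dataset (one report row)."""

    iterations: int
    sse: float
    silhouette: float
    rpt: float
    dunn: float
    rand: Optional[float] = None
    ari: Optional[float] = None
    accuracy: Optional[float] = None
    f_measure: Optional[float] = None
    hubert: Optional[float] = None
    vi: Optional[float] = None

    def as_row(self) -> dict[str, Optional[float]]:
        return {
            "I": self.iterations, "SSE": self.sse, "Si": self.silhouette,
            "RPT": self.rpt, "Dunn": self.dunn, "RI": self.rand,
            "ARI": self.ari, "AC": self.accuracy, "F": self.f_measure,
            "HI": self.hubert, "VI": self.vi,
        }


def evaluate_partition(X: np.ndarray, part: Partition,
                       truth: Optional[np.ndarray] = None,
                       rpt_B: int = 50, seed: int = 0,
                       recluster: Optional[ReclusterFn] = None) -> ValidityReport:
    """Assemble the full index row for one partition (external block only
    when ground-truth labels are supplied)."""
    X = np.asarray(X, dtype=float)
    labels = part.labels
    keep = labels >= 0
    rep = ValidityReport(
        iterations=part.iterations,
        sse=part.sse,
        silhouette=silhouette_mean(X[keep], labels[keep]),
        rpt=rpt(X, labels, B=rpt_B, seed=seed, recluster=recluster),
        dunn=dunn_index(X[keep], labels[keep]),
    )
    if truth is not None:
        t, l = np.asarray(truth)[keep], labels[keep]
        rep.rand, rep.ari = rand_and_ari(t, l)
        rep.accuracy = accuracy_matched(t, l)
        rep.f_measure = f_measure(t, l)
        rep.hubert = hubert_gamma(t, l)
        _, rep.vi = mi_and_vi(t, l)
    return rep


# ---------------------------------------------------------------------------
# optimal-k selection
# ---------------------------------------------------------------------------

ClusterFn = Callable[[np.ndarray, int, int], np.ndarray]


@dataclass
class KSelection:
    """Votes of the three k-selection heuristics and the majority decision."""

    k_elbow: int
    k_gap: int
    k_silhouette: int
    k_final: int
    search_range: tuple[int, int] = (2, 15)
    tie: bool = False
    sse_curve: dict[int, float] = field(default_factory=dict)
    gap_curve: dict[int, float] = field(default_factory=dict)
    silhouette_curve: dict[int, float] = field(default_factory=dict)


def majority_vote(k_elbow: int, k_gap: int, k_sil: int) -> tuple[int, bool]:
    """Mode of the three votes; a three-way split falls back to the median."""
    votes = [k_elbow, k_gap, k_sil]
    if len(set(votes)) == 3:
        return int(np.median(votes)), True
    return max(set(votes), key=votes.count), False


def _default_cluster(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    return best_of_restarts(X, k, restarts=10, seed=seed).labels


def _sse_for(X: np.ndarray, labels: np.ndarray) -> float:
    cents = np.stack([X[labels == k].mean(axis=0) for k in np.unique(labels)])
    _, consec = np.unique(labels, return_inverse=True)
    return sse_of(X, consec, cents)


def select_k(X: np.ndarray, method: Optional[ClusterFn] = None,
             k_range: tuple[int, int] = (2, 15), gap_B: int = 50,
             seed: int = 0) -> KSelection:
    """Vote among average silhouette, gap statistic and elbow over a k range.

    k_silhouette maximizes mean silhouette; k_gap is the smallest k with
    ``Gap(k) >= Gap(k+1) - se(k+1)`` (one-SE rule; uniform bounding-box
    references); k_elbow maximizes the second difference of the SSE curve.
    Majority wins; a three-way split falls back to the median (flagged).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    kmin, kmax = k_range
    if kmax > n - 1:
        logger.warning("select_k: clipping k range to n-1 = %d", n - 1)
        kmax = n - 1
    if kmin < 2:
        kmin = 2
    fn = method or _default_cluster
    ks = list(range(kmin, kmax + 1))

    sse_curve: dict[int, float] = {1: _sse_for(X, np.zeros(n, dtype=int))}
    sil_curve: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in ks:
        lab = fn(X, k, seed)
        labelings[k] = lab
        sse_curve[k] = _sse_for(X, lab)
        sil_curve[k] = silhouette_mean(X, lab)

    k_sil = max(ks, key=lambda k: (sil_curve[k], -k))

    # elbow: maximum second difference of SSE over k (uses k=1 anchor)
    d2 = {k: sse_curve[k - 1] - 2 * sse_curve[k] + sse_curve[k + 1]
          for k in ks if (k - 1 in sse_curve and k + 1 in sse_curve)}
    k_elbow = max(d2, key=lambda k: (d2[k], -k)) if d2 else kmin

    # gap statistic with uniform references over the bounding box; anchored
    # at k=1 so the one-SE rule can signal "no structure" (clipped to kmin)
    rng = np.random.default_rng(seed + 104729)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks_gap = [1] + ks
    log_wref = {k: [] for k in ks_gap}
    for b in range(gap_B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31))
        log_wref[1].append(log(_sse_for(ref, np.zeros(n, dtype=int))))
        for k in ks:
            log_wref[k].append(log(_sse_for(ref, fn(ref, k, ref_seed))))
    gap, se = {}, {}
    for k in ks_gap:
        lw = np.asarray(log_wref[k])
        gap[k] = float(lw.mean() - log(sse_curve[k]))
        se[k] = float(lw.std(ddof=0) * np.sqrt(1.0 + 1.0 / gap_B))
    k_gap = max(ks, key=lambda k: (gap[k], -k))
    for k in ks_gap[:-1]:
        if gap[k] >= gap[k + 1] - se[k + 1]:
            k_gap = max(k, kmin)
            break
    gap.pop(1, None)

    k_final, tie = majority_vote(k_elbow, k_gap, k_sil)
    if tie:
        logger.info("select_k: three-way split %s, taking median %d",
                    (k_elbow, k_gap, k_sil), k_final)

    return KSelection(k_elbow=k_elbow, k_gap=k_gap, k_silhouette=k_sil,
                      k_final=k_final, search_range=(kmin, kmax), tie=tie,
                      sse_curve=sse_curve, gap_curve=gap,
                      silhouette_curve=sil_curve)
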