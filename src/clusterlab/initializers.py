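"""Three hybrid centroid-selection strategies for K-means.

* :func:`mst_init` — minimum-spanning-tree skeleton: build the Euclidean MST
  (Prim), rank high-degree "skeleton" vertices, then spread K of them apart
  with a degree-weighted maxi-min rule.
* :func:`ga_init` — genetic search over chromosomes of K distinct data rows,
  fitness ``1 / (1 + SSE)`` of a single nearest-centroid assignment.
* :func:`hier_init` — cut an agglomerative tree (default Ward) into K groups
  and use the group means.

Each returns a ``(K, d)`` matrix of pairwise-distinct rows ready for
:func:`clusterlab.kmeans.run_kmeans`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist

from .exceptions import ConfigError, DegeneracyError, InputError

logger = logging.getLogger(__name__)

LINKAGES = ("ward", "complete", "average", "single")


# ---------------------------------------------------------------------------
# minimum spanning tree
# ---------------------------------------------------------------------------

@dataclass
class SpanningTree:
    """MST of the complete Euclidean graph on the data rows."""

    edges: list[tuple[int, int, float]]  # (u, v, weight) with u < v
    degrees: np.ndarray                  # per-vertex edge counts
    total_weight: float


def prim_mst(X: np.ndarray) -> SpanningTree:
    """Euclidean MST by Prim's algorithm, deterministic under distance ties.

    The next vertex attached is always the one with the smallest candidate
    distance, ties broken by the smaller vertex index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise InputError("need at least 2 points for a spanning tree")
    if not np.isfinite(X).all():
        raise InputError("X contains non-finite values")

    in_tree = np.zeros(n, dtype=bool)
    best_dist = np.full(n, np.inf)
    parent = np.full(n, -1, dtype=int)
    in_tree[0] = True
    best_dist[0] = 0.0
    d0 = np.sqrt(((X - X[0]) ** 2).sum(axis=1))
    mask = ~in_tree
    best_dist[mask] = d0[mask]
    parent[mask] = 0

    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        cand = np.where(in_tree, np.inf, best_dist)
        v = int(cand.argmin())  # argmin takes the lowest index on ties
        u = int(parent[v])
        w = float(best_dist[v])
        edges.append((min(u, v), max(u, v), w))
        in_tree[v] = True
        dv = np.sqrt(((X - X[v]) ** 2).sum(axis=1))
        improve = (~in_tree) & (dv < best_dist)
        best_dist[improve] = dv[improve]
        parent[improve] = v

    degrees = np.zeros(n, dtype=int)
    for u, v, _ in edges:
        degrees[u] += 1
        degrees[v] += 1
    edges.sort(key=lambda e: (e[0], e[1]))
    return SpanningTree(edges=edges, degrees=degrees,
                        total_weight=float(sum(w for _, _, w in edges)))


@dataclass
class SkeletonSet:
    """Centroid candidates: MST vertices ranked by how many edges pass through them."""

    members: list[int]


def skeleton_points(t: SpanningTree, K: int) -> SkeletonSet:
    """Vertices of degree >= 2 ranked by (degree desc, incident weight asc, index).

    If fewer than K qualify, leaves are appended under the same ranking so the
    set always offers at least K candidates.
    """
    if K < 2:
        raise InputError("K must be >= 2")
    n = t.degrees.shape[0]
    wsum = np.zeros(n)
    for u, v, w in t.edges:
        wsum[u] += w
        wsum[v] += w

    def rank(idx: int) -> tuple:
        return (-t.degrees[idx], wsum[idx], idx)

    internal = sorted((i for i in range(n) if t.degrees[i] >= 2), key=rank)
    members = list(internal)
    if len(members) < K:
        leaves = sorted((i for i in range(n) if t.degrees[i] < 2), key=rank)
        members.extend(leaves[: K - len(members)])
    return SkeletonSet(members=members)


def mst_init(X: np.ndarray, K: int) -> np.ndarray:
    """Skeleton-based initial centroids.

    Pairwise scores between skeleton points are ``h(s_i, s_j) =
    (deg_i + deg_j) * d(s_i, s_j)``.  The top-ranked skeleton point seeds the
    set; each further centroid is the candidate whose smallest h-score to the
    chosen set is largest (maxi-min), ties toward the better-ranked candidate.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K > n:
        raise InputError(f"K={K} exceeds n={n}")
    tree = prim_mst(X)
    members = skeleton_points(tree, K).members

    S = np.asarray(members, dtype=int)
    deg = tree.degrees[S].astype(float)
    dist = cdist(X[S], X[S])
    h = (deg[:, None] + deg[None, :]) * dist

    chosen = [0]  # positions within S; S[0] is the top-ranked skeleton point
    available = [i for i in range(len(S)) if i != 0]
    while len(chosen) < K and available:
        scores = [h[i, chosen].min() for i in available]
        pick = available[int(np.argmax(scores))]
        # skip exact-duplicate coordinates while alternatives remain
        if any(np.array_equal(X[S[pick]], X[S[c]]) for c in chosen):
            nondup = [i for i in available
                      if not any(np.array_equal(X[S[i]], X[S[c]]) for c in chosen)]
            if nondup:
                pick = nondup[int(np.argmax([h[i, chosen].min() for i in nondup]))]
        chosen.append(pick)
        available.remove(pick)
    if len(chosen) < K:
        raise DegeneracyError("not enough distinct skeleton candidates")
    return X[S[np.asarray(chosen)]].copy()


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Operator rates and sizes for the genetic centroid search."""

    pop_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ConfigError("operator rates must lie in [0, 1]")
        if not (0 <= self.elitism < self.pop_size):
            raise ConfigError("elitism must be < pop_size")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")


@dataclass
class Chromosome:
    """One candidate centroid set and its fitness."""

    centroids: np.ndarray
    fitness: float


def _fitness(X: np.ndarray, rows: np.ndarray, idx: np.ndarray) -> float:
    cents = rows[idx]
    d = cdist(X, cents, metric="sqeuclidean")
    return 1.0 / (1.0 + float(d.min(axis=1).sum()))


def _resample_duplicates(idx: np.ndarray, n_rows: int, rng: np.random.Generator) -> np.ndarray:
    """Replace repeated gene values so each chromosome keeps K distinct rows."""
    seen: set[int] = set()
    out = idx.copy()
    for pos, g in enumerate(out):
        if int(g) in seen:
            choices = np.setdiff1d(np.arange(n_rows), out)
            out[pos] = int(rng.choice(choices))
        seen.add(int(out[pos]))
    return out


def ga_init(X: np.ndarray, K: int, cfg: GAConfig | None = None) -> np.ndarray:
    """Best-ever chromosome of a seeded genetic search over data-row centroid sets.

    Chromosomes encode K distinct (deduplicated) data rows.  Each generation:
    elites copied, parents drawn by roulette wheel on fitness, single-point
    crossover at centroid boundaries with probability ``crossover_rate``, and
    with probability ``mutation_rate`` one centroid replaced by a uniformly
    drawn data row.  Offspring that would repeat a centroid are repaired by
    resampling the offending gene.
    """
    cfg = cfg or GAConfig()
    X = np.asarray(X, dtype=float)
    rows = np.unique(X, axis=0)
    n_rows = rows.shape[0]
    if n_rows < K:
        raise DegeneracyError(f"only {n_rows} distinct rows, cannot pick K={K}")
    rng = np.random.default_rng(cfg.seed)
    M = cfg.pop_size

    pop = np.stack([rng.choice(n_rows, size=K, replace=False) for _ in range(M)])
    fit = np.array([_fitness(X, rows, ind) for ind in pop])
    best_idx = pop[int(fit.argmax())].copy()
    best_fit = float(fit.max())

    for _ in range(cfg.generations):
        order = np.argsort(-fit, kind="stable")
        elites = pop[order[: cfg.elitism]]
        probs = fit / fit.sum()
        children: list[np.ndarray] = []
        while len(children) < M - cfg.elitism:
            pa = rng.choice(M, size=2, p=probs)
            p1 = pop[int(pa[0])].copy()
            p2 = pop[int(pa[1])].copy()
            if K >= 2 and rng.random() < cfg.crossover_rate:
                cut = int(rng.integers(1, K))
                p1, p2 = (np.concatenate([p1[:cut], p2[cut:]]),
                          np.concatenate([p2[:cut], p1[cut:]]))
            for child in (p1, p2):
                if len(children) >= M - cfg.elitism:
                    break
                if rng.random() < cfg.mutation_rate:
                    child[int(rng.integers(K))] = int(rng.integers(n_rows))
                children.append(_resample_duplicates(child, n_rows, rng))
        pop = np.vstack([elites, np.stack(children)]) if cfg.elitism else np.stack(children)
        fit = np.array([_fitness(X, rows, ind) for ind in pop])
        if float(fit.max()) > best_fit:
            best_fit = float(fit.max())
            best_idx = pop[int(fit.argmax())].copy()

    return rows[best_idx].copy()


# ---------------------------------------------------------------------------
# hierarchical tree cut
# ---------------------------------------------------------------------------

def tree_cut_labels(X: np.ndarray, K: int, linkage: str = "ward") -> np.ndarray:
    """Agglomerative grouping: cut the linkage tree into K clusters (labels from 0)."""
    if linkage not in LINKAGES:
        raise ConfigError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    X = np.asarray(X, dtype=float)
    if K > X.shape[0]:
        raise InputError(f"K={K} exceeds n={X.shape[0]}")
    if K == X.shape[0]:
        return np.arange(K)
    Z = scipy_linkage(X, method=linkage)
    raw = fcluster(Z, t=K, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    return labels


def hier_init(X: np.ndarray, K: int, linkage: str = "ward") -> np.ndarray:
    """Group means of the K-cluster cut of an agglomerative (default Ward) tree."""
    X = np.asarray(X, dtype=float)
    labels = tree_cut_labels(X, K, linkage)
    k_eff = labels.max() + 1
    cents = np.stack([X[labels == k].mean(axis=0) for k in range(k_eff)])
    if np.unique(cents, axis=0).shape[0] != cents.shape[0]:
        raise DegeneracyError("tree cut produced coincident group means")
    return cents
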