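"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (double loops, exhaustive search,
union-find Kruskal) and shares no code with the implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- pair counting -----------------------------------------------------------

def naive_pair_counts(u, v):
    u, v = list(u), list(v)
    a = b = c = d = 0
    n = len(u)
    for i in range(n):
        for j in range(i + 1, n):
            su = u[i] == u[j]
            sv = v[i] == v[j]
            if su and sv:
                a += 1
            elif su:
                b += 1
            elif sv:
                c += 1
            else:
                d += 1
    return a, b, c, d


def naive_rand(u, v):
    a, b, c, d = naive_pair_counts(u, v)
    return (a + d) / (a + b + c + d)


def naive_ari(u, v):
    a, b, c, d = naive_pair_counts(u, v)
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * d - b * c) / denom


def naive_hubert(u, v):
    """Pearson correlation of the two co-membership indicator vectors."""
    xs, ys = [], []
    n = len(u)
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(1.0 if u[i] == u[j] else 0.0)
            ys.append(1.0 if v[i] == v[j] else 0.0)
    xs, ys = np.asarray(xs), np.asarray(ys)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return None
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


# --- set matching ------------------------------------------------------------

def naive_accuracy(u, v):
    """Exhaustive search over one-to-one cluster<->class mappings."""
    cu, cv = sorted(set(u)), sorted(set(v))
    small, big, swap = (cu, cv, False) if len(cu) <= len(cv) else (cv, cu, True)
    n = len(u)
    best = 0
    for perm in itertools.permutations(big, len(small)):
        correct = 0
        mapping = dict(zip(small, perm))
        for ui, vi in zip(u, v):
            x, y = (ui, vi) if not swap else (vi, ui)
            if mapping.get(x) == y:
                correct += 1
        best = max(best, correct)
    return best / n


def naive_f_measure(u, v):
    n = len(u)
    total = 0.0
    for cls in set(u):
        members = {i for i in range(n) if u[i] == cls}
        best = 0.0
        for clu in set(v):
            got = {i for i in range(n) if v[i] == clu}
            inter = len(members & got)
            if inter == 0:
                continue
            prec = inter / len(got)
            rec = inter / len(members)
            best = max(best, 2 * prec * rec / (prec + rec))
        total += (len(members) / n) * best
    return total


# --- information theory ------------------------------------------------------

def naive_mi_vi(u, v):
    n = len(u)
    joint: dict[tuple, int] = {}
    pu: dict = {}
    pv: dict = {}
    for x, y in zip(u, v):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        pu[x] = pu.get(x, 0) + 1
        pv[y] = pv.get(y, 0) + 1
    mi = 0.0
    for (x, y), cnt in joint.items():
        pxy = cnt / n
        mi += pxy * math.log(pxy / ((pu[x] / n) * (pv[y] / n)))
    hu = -sum((k / n) * math.log(k / n) for k in pu.values())
    hv = -sum((k / n) * math.log(k / n) for k in pv.values())
    return mi, hu + hv - 2 * mi


# --- geometry ----------------------------------------------------------------

def kruskal_mst_weight(X):
    """Total MST weight by Kruskal with union-find."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((float(np.linalg.norm(X[i] - X[j])), i, j))
    edges.sort()
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == n - 1:
                break
    return total


def naive_dunn(X, labels):
    X = np.asarray(X, float)
    labels = list(labels)
    n = len(labels)
    min_inter, max_diam = math.inf, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(X[i] - X[j]))
            if labels[i] == labels[j]:
                max_diam = max(max_diam, d)
            else:
                min_inter = min(min_inter, d)
    return math.inf if max_diam == 0 else min_inter / max_diam


def naive_silhouette(X, labels):
    X = np.asarray(X, float)
    labels = list(labels)
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            vals.append(0.0)
            continue
        a = sum(np.linalg.norm(X[i] - X[j]) for j in own) / len(own)
        b = math.inf
        for cls in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == cls]
            b = min(b, sum(np.linalg.norm(X[i] - X[j]) for j in other) / len(other))
        m = max(a, b)
        vals.append(0.0 if m == 0 else (b - a) / m)
    return sum(vals) / n


# --- exhaustive K-means optima ----------------------------------------------

def best_two_cluster_sse(X):
    """Global optimum SSE over all bipartitions with two non-empty clusters."""
    X = np.asarray(X, float)
    n = X.shape[0]
    best = math.inf
    for mask in range(1, 2 ** n - 1):
        g1 = [i for i in range(n) if mask & (1 << i)]
        g2 = [i for i in range(n) if not mask & (1 << i)]
        sse = 0.0
        for grp in (g1, g2):
            mu = X[grp].mean(axis=0)
            sse += float(((X[grp] - mu) ** 2).sum())
        best = min(best, sse)
    return best


def best_centroid_pair_sse(X):
    """Min one-assignment SSE over all C(n,2) data-row centroid pairs."""
    X = np.asarray(X, float)
    n = X.shape[0]
    best = math.inf
    for i, j in itertools.combinations(range(n), 2):
        cents = X[[i, j]]
        d2 = ((X[:, None, :] - cents[None]) ** 2).sum(axis=2)
        best = min(best, float(d2.min(axis=1).sum()))
    return best
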