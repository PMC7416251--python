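"""Labelled Gaussian-mixture generators emulating the benchmark dataset shapes.

Components are isotropic with unit within-component SD, so ``separation`` is
directly the nearest-mean distance in within-SD units.  Every draw is fully
determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import PROFILES, Dataset
from .exceptions import SpecError


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of one synthetic Gaussian-mixture dataset."""

    n: int
    d: int
    K: int
    separation: float = 3.0
    weights: Optional[tuple[float, ...]] = None
    outlier_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 * self.K:
            raise SpecError(f"need n >= 2*K, got n={self.n}, K={self.K}")
        if self.d < 1 or self.K < 1:
            raise SpecError("d and K must be positive")
        if self.separation < 0:
            raise SpecError("separation must be >= 0")
        if not (0.0 <= self.outlier_frac <= 0.2):
            raise SpecError("outlier_frac must lie in [0, 0.2]")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.K,):
                raise SpecError(f"weights length {w.size} != K={self.K}")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
                raise SpecError("weights must be a simplex vector (sum 1)")

    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.K, 1.0 / self.K)
        return np.asarray(self.weights, dtype=float)


def _component_means(K: int, d: int, separation: float) -> np.ndarray:
    """Place K means with nearest-mean distance exactly ``separation``.

    For K <= d the means sit on scaled coordinate axes (a regular simplex:
    every pair at distance ``separation``); otherwise they occupy the K
    lattice points of ``separation * Z^d`` closest to the origin, whose
    nearest-neighbour spacing is one lattice step.
    """
    if K == 1:
        return np.zeros((1, d))
    if K <= d:
        return np.eye(K, d) * (separation / np.sqrt(2.0))
    # lattice fallback: enumerate integer points by norm, deterministically
    reach = int(np.ceil(K ** (1.0 / d))) + 1
    axes = np.arange(-reach, reach + 1)
    grid = np.stack(np.meshgrid(*([axes] * d), indexing="ij"), axis=-1).reshape(-1, d)
    order = np.lexsort(tuple(grid[:, j] for j in range(d - 1, -1, -1)))
    grid = grid[order]
    norms = (grid ** 2).sum(axis=1)
    grid = grid[np.argsort(norms, kind="stable")][:K]
    return grid.astype(float) * separation


def make_mixture(spec: MixtureSpec) -> Dataset:
    """Draw one labelled mixture dataset; bit-identical for equal specs."""
    rng = np.random.default_rng(spec.seed)
    means = _component_means(spec.K, spec.d, spec.separation)
    weights = spec.resolved_weights()

    counts = rng.multinomial(spec.n, weights)
    # every component keeps at least one point so labels cover all K classes
    while (counts == 0).any():
        k_empty = int(np.flatnonzero(counts == 0)[0])
        counts[int(np.argmax(counts))] -= 1
        counts[k_empty] += 1

    labels = np.repeat(np.arange(spec.K), counts)
    X = means[labels] + rng.standard_normal((spec.n, spec.d))

    n_out = int(np.floor(spec.outlier_frac * spec.n))
    if n_out:
        lo, hi = X.min(axis=0), X.max(axis=0)
        centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        lo15, hi15 = centre - 1.5 * half, centre + 1.5 * half
        idx = rng.choice(spec.n, size=n_out, replace=False)
        X[idx] = rng.uniform(lo15, hi15, size=(n_out, spec.d))
        d2 = ((X[idx, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        labels = labels.copy()
        labels[idx] = d2.argmin(axis=1)

    return Dataset(
        name=f"mixture(n={spec.n},d={spec.d},K={spec.K},seed={spec.seed})",
        X=X,
        labels=labels,
    )


def emulate_profile(name: str, separation: float = 3.0, seed: int = 0,
                    outlier_frac: float = 0.0) -> Dataset:
    """Synthetic stand-in with the exact n, d and class count of a named profile."""
    if name not in PROFILES:
        known = ", ".join(sorted(PROFILES))
        raise SpecError(f"unknown profile {name!r}; known profiles: {known}")
    p = PROFILES[name]
    ds = make_mixture(MixtureSpec(n=p.n, d=p.d, K=p.n_classes,
                                  separation=separation, seed=seed,
                                  outlier_frac=outlier_frac))
    ds.name = f"{name}_synth"
    return ds
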