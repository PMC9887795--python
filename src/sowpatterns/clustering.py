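"""Partitioning Around Medoids (PAM) with silhouette-based selection of k.

This is a from-scratch k-medoids implementation on Euclidean distances:

* build phase — k distinct rows drawn uniformly at random (seeded);
* swap phase — every (medoid, non-medoid) exchange is evaluated and the
  single best strictly-cost-decreasing swap is applied, repeating until no
  swap lowers the total cost (best-improvement; a greedy first-improvement
  variant is available);
* restarts — the whole procedure is repeated ``n_restarts`` times and the
  lowest-cost solution returned.

The objective is the sum over points of the Euclidean distance to their
cluster's medoid.  Ties (nearest medoid, equal-cost swaps, equal silhouette)
break toward the lowest index, so results are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .features import NormalizedMatrix

__all__ = [
    "PamResult",
    "SilhouetteProfile",
    "euclidean_distance",
    "pam",
    "silhouette_mean",
    "select_k",
    "adjusted_rand_index",
]


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


@dataclass(frozen=True)
class PamResult:
    """A fitted k-medoids partition."""

    k: int
    medoid_indices: np.ndarray  # row indices of the k medoids, sorted ascending
    assignments: np.ndarray  # n labels in 0..k-1, label = position in medoid_indices
    total_cost: float
    n_swaps: int
    seed: int

    def medoid_of(self, i: int) -> int:
        """Row index of the medoid serving point ``i``."""
        return int(self.medoid_indices[self.assignments[i]])


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, NormalizedMatrix):
        return X.values
    x = np.asarray(X, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    return x


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    # argmin returns the first (lowest-index) minimizer, our tie rule
    sub = D[:, medoids]
    labels = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(D.shape[0]), labels].sum())
    return labels, cost


def _pam_single(
    D: np.ndarray, k: int, rng: np.random.Generator, method: str
) -> tuple[np.ndarray, float, int]:
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    in_set = np.zeros(n, dtype=bool)
    in_set[medoids] = True
    n_swaps = 0

    sub = D[:, medoids]
    order = np.argsort(sub, axis=1)
    d1 = sub[np.arange(n), order[:, 0]]
    nearest = order[:, 0]
    d2 = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
    cost = float(d1.sum())

    while True:
        best_delta = -1e-12  # strict decrease required
        best = None
        candidates = np.flatnonzero(~in_set)
        if candidates.size == 0:
            break
        for mi in range(k):
            # removing medoid mi: points served by it fall back to their second choice
            base = np.where(nearest == mi, d2, d1)
            # new cost for each candidate replacement p: sum_i min(base_i, D[i, p])
            new_costs = np.minimum(base[:, None], D[:, candidates]).sum(axis=0)
            j = int(np.argmin(new_costs))
            delta = float(new_costs[j]) - cost
            if delta < best_delta:
                best_delta = delta
                best = (mi, candidates[j], float(new_costs[j]))
                if method == "first":
                    break
        if best is None:
            break
        mi, p, new_cost = best
        in_set[medoids[mi]] = False
        in_set[p] = True
        medoids[mi] = p
        medoids = np.sort(medoids)
        in_set = np.zeros(n, dtype=bool)
        in_set[medoids] = True
        n_swaps += 1
        sub = D[:, medoids]
        order = np.argsort(sub, axis=1)
        d1 = sub[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d2 = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = float(d1.sum())

    return medoids, cost, n_swaps


def pam(
    X,
    k: int,
    *,
    seed: int = 0,
    n_restarts: int = 10,
    method: Literal["best", "first"] = "best",
) -> PamResult:
    """Fit k medoids to the rows of ``X`` (ndarray or :class:`NormalizedMatrix`).

    The best (lowest total cost) of ``n_restarts`` seeded random starts is
    returned; with an equal cost the earlier restart wins.  Identical
    ``(X, k, seed, n_restarts, method)`` give identical results.
    """
    x = _as_matrix(X)
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n ({k=}, {n=})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    D = cdist(x, x)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, int] | None = None
    for _ in range(n_restarts):
        medoids, cost, n_swaps = _pam_single(D, k, rng, method)
        if best is None or cost < best[1] - 1e-12:
            best = (medoids, cost, n_swaps)
    medoids, cost, n_swaps = best
    labels, cost = _assign(D, medoids)
    return PamResult(
        k=k,
        medoid_indices=medoids,
        assignments=labels,
        total_cost=cost,
        n_swaps=n_swaps,
        seed=seed,
    )


def silhouette_mean(X, assignments, *, precomputed: bool = False) -> float:
    """Mean silhouette width of a partition, in [-1, 1].

    For point i with mean intra-cluster distance a(i) (excluding itself) and
    b(i) the smallest mean distance to another cluster,
    s(i) = (b(i) - a(i)) / max(a(i), b(i)); singleton clusters and exact
    a = b = 0 ties contribute s(i) = 0.  ``X`` may be a data matrix or, with
    ``precomputed=True``, a full distance matrix.
    """
    labels = np.asarray(assignments)
    D = np.asarray(X, dtype=float) if precomputed else cdist(_as_matrix(X), _as_matrix(X))
    n = D.shape[0]
    if labels.shape != (n,):
        raise ValueError("assignments length must match number of rows")
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    # n x k matrix of summed distances to each cluster
    sums = np.zeros((n, uniq.size))
    for c in range(uniq.size):
        sums[:, c] = D[:, inv == c].sum(axis=1)
    own = counts[inv]
    s = np.zeros(n)
    nontrivial = own > 1
    a = np.where(nontrivial, sums[np.arange(n), inv] / np.maximum(own - 1, 1), 0.0)
    other = sums / counts
    other[np.arange(n), inv] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    ok = nontrivial & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return float(s.mean())


@dataclass(frozen=True)
class SilhouetteProfile:
    """Mean silhouette width per candidate k, and the argmax."""

    per_k: Mapping[int, float]
    best_k: int
    results: Mapping[int, PamResult]


def select_k(
    X,
    *,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
    method: Literal["best", "first"] = "best",
) -> SilhouetteProfile:
    """Run PAM for each k in [k_min, k_max] and pick k by mean silhouette.

    Ties break toward the smaller k.  ``k_max`` must be at most n - 1 (the
    silhouette is undefined when every point is its own cluster).
    """
    x = _as_matrix(X)
    n = x.shape[0]
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1 ({k_min=}, {k_max=}, {n=})")
    D = cdist(x, x)
    per_k: dict[int, float] = {}
    results: dict[int, PamResult] = {}
    for k in range(k_min, k_max + 1):
        res = pam(x, k, seed=seed, n_restarts=n_restarts, method=method)
        per_k[k] = silhouette_mean(D, res.assignments, precomputed=True)
        results[k] = res
    best_k = max(sorted(per_k), key=lambda k: (per_k[k], -k))
    return SilhouetteProfile(per_k=per_k, best_k=best_k, results=results)


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two partitions of the same items.

    1 for identical partitions (up to label names), ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
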