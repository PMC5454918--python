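"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package: plain double loops and O(n^2) scans.
"""

from __future__ import annotations

import numpy as np


def brute_moments(qi: np.ndarray, origin: tuple[int, int]):
    """Literal double-loop evaluation of Q, mu, sigma^2 per axis (pixel units)."""
    r0, c0 = origin
    Q = 0.0
    for row in qi:
        for v in row:
            Q += v
    mu_x = mu_y = 0.0
    for i in range(qi.shape[0]):
        for j in range(qi.shape[1]):
            mu_x += qi[i, j] * (c0 + j + 0.5)
            mu_y += qi[i, j] * (r0 + i + 0.5)
    mu_x /= Q
    mu_y /= Q
    var_x = var_y = 0.0
    for i in range(qi.shape[0]):
        for j in range(qi.shape[1]):
            var_x += qi[i, j] * ((c0 + j + 0.5) - mu_x) ** 2
            var_y += qi[i, j] * ((r0 + i + 0.5) - mu_y) ** 2
    return Q, mu_x, mu_y, var_x / Q, var_y / Q


def brute_precision(qi: np.ndarray, origin: tuple[int, int], nb: float,
                    mu_x: float, mu_y: float):
    """Double-loop evaluation of the precision sums, per axis (pixel units)."""
    r0, c0 = origin
    Q = float(qi.sum())
    sx = sy = 0.0
    for i in range(qi.shape[0]):
        for j in range(qi.shape[1]):
            sx += (((c0 + j + 0.5) - mu_x) / Q) ** 2 * (qi[i, j] + nb)
            sy += (((r0 + i + 0.5) - mu_y) / Q) ** 2 * (qi[i, j] + nb)
    return (np.sqrt(1.0 / (12 * Q) + sx), np.sqrt(1.0 / (12 * Q) + sy))


def brute_neighbor_counts(xy: np.ndarray, radius: float) -> np.ndarray:
    """O(n^2) pairwise count of other points within the radius."""
    n = len(xy)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.hypot(*(xy[i] - xy[j])) <= radius:
                counts[i] += 1
    return counts


def dbscan_reference(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) density-reachability closure.

    Core = point with >= min_pts points (itself included) within eps.
    Clusters are grown from unlabeled cores in index order; border points
    keep the label of the first cluster that reaches them.
    """
    n = len(xy)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    cid = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != -1:
            continue
        labels[seed] = cid
        stack = [seed]
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two labelings agree up to a bijective renaming of cluster ids."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if np.any((a == -1) != (b == -1)):
        return False
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True


def naive_scan(seq: str, probe: str) -> list[int]:
    """Sliding-window exact match over an uppercase sequence."""
    k = len(probe)
    return [i for i in range(len(seq) - k + 1) if seq[i:i + k] == probe]


def random_point_mixture(rng: np.random.Generator, max_n: int = 1000):
    """Random mixed cluster/noise instance for DBSCAN comparisons."""
    n_clusters = int(rng.integers(0, 6))
    parts = []
    for _ in range(n_clusters):
        c = rng.uniform(0, 5000, 2)
        m = int(rng.integers(5, 60))
        parts.append(c + rng.normal(0, rng.uniform(20, 120), (m, 2)))
    n_noise = int(rng.integers(10, 200))
    parts.append(rng.uniform(0, 5000, (n_noise, 2)))
    xy = np.concatenate(parts)
    if len(xy) > max_n:
        xy = xy[:max_n]
    rng.shuffle(xy)
    return xy
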