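"""Naive reference implementations of the graph metrics, for validation.

Every function here recomputes a metric by direct enumeration or a textbook
algorithm (neighbor-pair counting, Floyd–Warshall, power iteration,
edge-fraction sums, the assortativity formula term by term), with no code
shared with the fast implementations in :mod:`scnet.graphmetrics` and
:mod:`scnet.community`. They are quadratic-to-cubic and meant for small
graphs only (validation suites use <= 12 nodes).
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "clustering_brute",
    "path_length_brute",
    "eigenvector_brute",
    "modularity_brute",
    "assortativity_brute",
]


def clustering_brute(adjacency: np.ndarray) -> np.ndarray:
    """Local clustering by enumerating each node's neighbor pairs."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    coeffs = np.zeros(n)
    for i in range(n):
        neighbors = [j for j in range(n) if a[i, j]]
        if len(neighbors) < 2:
            continue
        links = sum(
            1 for u, v in itertools.combinations(neighbors, 2) if a[u, v]
        )
        coeffs[i] = links / (len(neighbors) * (len(neighbors) - 1) / 2)
    return coeffs


def path_length_brute(adjacency: np.ndarray) -> float:
    """Mean shortest-path length over reachable pairs via Floyd–Warshall."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    dist = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        raise ValueError("no reachable pairs")
    return float(dist[finite].mean())


def eigenvector_brute(adjacency: np.ndarray, n_iter: int = 10_000, tol: float = 1e-14) -> np.ndarray:
    """Principal eigenvector by plain power iteration, unit 2-norm."""
    a = np.asarray(adjacency, float)
    n = a.shape[0]
    v = np.ones(n) / np.sqrt(n)
    # shift guarantees the dominant eigenvalue of (A + cI) is the largest in
    # magnitude and positive, so power iteration converges to the Perron vector
    shift = a.sum(axis=1).max() + 1.0
    m = a + shift * np.eye(n)
    for _ in range(n_iter):
        w = m @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    if v.sum() < 0:
        v = -v
    return np.clip(v, 0.0, None) / np.linalg.norm(np.clip(v, 0.0, None))


def modularity_brute(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman Q by summing edge fractions module by module, edge by edge."""
    a = np.asarray(adjacency, float)
    labels = np.asarray(labels)
    two_m = a.sum()
    q = 0.0
    for module in np.unique(labels):
        inside = 0.0
        attached = 0.0
        for i in range(a.shape[0]):
            for j in range(a.shape[0]):
                if labels[i] == module:
                    attached += a[i, j]
                    if labels[j] == module:
                        inside += a[i, j]
        q += inside / two_m - (attached / two_m) ** 2
    return q


def assortativity_brute(adjacency: np.ndarray, strength: np.ndarray) -> float:
    """Strength assortativity evaluated term by term over the edge list."""
    a = np.asarray(adjacency)
    strength = np.asarray(strength, float)
    edges = [
        (i, j)
        for i in range(a.shape[0])
        for j in range(i + 1, a.shape[0])
        if a[i, j]
    ]
    m = len(edges)
    sum_prod = sum(strength[i] * strength[j] for i, j in edges)
    sum_avg = sum(0.5 * (strength[i] + strength[j]) for i, j in edges)
    sum_sq = sum(0.5 * (strength[i] ** 2 + strength[j] ** 2) for i, j in edges)
    numerator = sum_prod / m - (sum_avg / m) ** 2
    denominator = sum_sq / m - (sum_avg / m) ** 2
    return numerator / denominator
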