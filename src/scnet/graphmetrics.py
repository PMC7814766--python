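"""Global topology, eigenvector-centrality hubs, and strength assortativity.

All metrics operate on binarized covariance graphs. They are implemented on
the dense adjacency matrix (triangle counts by matrix powers, BFS shortest
paths via ``scipy.sparse.csgraph``, the principal eigenvector from a dense
symmetric eigensolver) because permutation testing rebuilds and re-measures
thousands of graphs; independent brute-force implementations back them in
the test suite.

Conventions:

* clustering of a node with degree < 2 is 0;
* the characteristic path length of a disconnected graph is the mean over
  reachable pairs, with a ``disconnected`` flag raised;
* global efficiency defaults to ``1/L`` (the literal inverse of the
  characteristic path length); the Latora–Marchiori mean of inverse pairwise
  distances is available as a variant — the two differ on any non-complete
  graph;
* eigenvector centrality is the nonnegative Perron vector with unit
  Euclidean norm; on disconnected graphs it is supported on the component
  with the largest leading eigenvalue;
* small-worldness is the Humphries–Gurney sigma against degree-preserving
  Maslov–Sneppen rewired references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .covariance import BinaryGraph, CovarianceMatrix, grid_points, threshold_density

__all__ = [
    "MetricCurve",
    "HubProfile",
    "SmallWorldResult",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "random_reference",
    "small_worldness",
    "eigenvector_centrality",
    "hub_profile",
    "assortativity",
]

HUB_Z_THRESHOLD = 1.5
HUB_GRID = (0.05, 0.35, 0.05)  # d_min, d_max, step for the hub density grid


@dataclass
class MetricCurve:
    """One global metric evaluated over a density grid for one group."""

    metric: str
    densities: np.ndarray
    values: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.densities = np.asarray(self.densities, float)
        self.values = np.asarray(self.values, float)
        if len(self.densities) != len(self.values):
            raise ValueError("densities and values must have equal length")
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")


@dataclass
class HubProfile:
    """Density-averaged eigenvector centrality per region, z-scored."""

    regions: list
    mean_centrality: np.ndarray
    z_scores: np.ndarray
    group: str = ""
    z_threshold: float = HUB_Z_THRESHOLD

    @property
    def hubs(self) -> np.ndarray:
        return self.z_scores > self.z_threshold

    @property
    def hub_regions(self) -> list:
        return [r for r, h in zip(self.regions, self.hubs) if h]


@dataclass
class SmallWorldResult:
    sigma: float
    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    sigma_sd: float
    connected: bool = True


def clustering_coefficient(graph: BinaryGraph):
    """Watts–Strogatz local clustering per node and its unweighted mean.

    The per-node coefficient is the number of edges among the node's
    neighbors over all neighbor pairs; nodes with degree < 2 score 0.
    """
    a = graph.adjacency.astype(float)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    k = graph.degrees.astype(float)
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_node = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return per_node, float(per_node.mean())


def _distance_matrix(graph: BinaryGraph) -> np.ndarray:
    return shortest_path(csr_matrix(graph.adjacency), method="D", unweighted=True)


def characteristic_path_length(graph: BinaryGraph):
    """Mean shortest-path length over reachable ordered pairs.

    Returns ``(L, disconnected)``. For disconnected graphs the mean is
    restricted to reachable pairs and the flag is set. An edgeless graph has
    no reachable pair and raises.
    """
    if graph.n_nodes < 2:
        raise ValueError("path length needs >= 2 nodes")
    if graph.n_edges == 0:
        raise ValueError("path length undefined for an edgeless graph")
    dist = _distance_matrix(graph)
    off = ~np.eye(graph.n_nodes, dtype=bool)
    finite = np.isfinite(dist) & off
    disconnected = bool((~np.isfinite(dist) & off).any())
    return float(dist[finite].mean()), disconnected


def global_efficiency(graph: BinaryGraph, variant: str = "inverse_path_length") -> float:
    """Global efficiency: ``1/L`` by default, or the mean inverse distance.

    ``variant="latora_marchiori"`` computes the mean of 1/d over all ordered
    node pairs (unreachable pairs contribute 0); the default is the literal
    inverse of the characteristic path length.
    """
    if variant == "inverse_path_length":
        length, _ = characteristic_path_length(graph)
        return 1.0 / length
    if variant == "latora_marchiori":
        if graph.n_nodes < 2:
            raise ValueError("efficiency needs >= 2 nodes")
        dist = _distance_matrix(graph)
        off = ~np.eye(graph.n_nodes, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
        return float(inv[off].mean())
    raise ValueError(f"unknown efficiency variant {variant!r}")


def random_reference(graph: BinaryGraph, seed=None, swap_factor: int = 10) -> BinaryGraph:
    """Degree-preserving Maslov–Sneppen rewiring (double-edge swaps).

    Attempts ``swap_factor * |E|`` swaps: each attempt picks two edges
    (u, v) and (x, y) and rewires them to (u, x) and (v, y) unless that
    would create a self-loop or a duplicate edge. Degrees are preserved
    exactly. Graphs admitting no swap (e.g. complete graphs) are returned
    unchanged with a warning.
    """
    if graph.n_edges < 2:
        raise ValueError("rewiring needs >= 2 edges")
    rng = np.random.default_rng(seed)
    adj = graph.adjacency.astype(bool).copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.column_stack([iu, ju])
    m = len(edges)
    n_attempts = swap_factor * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    successes = 0
    for t in range(n_attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flips[t]:
            x, y = y, x
        # rewire (u,v),(x,y) -> (u,x),(v,y)
        if len({u, v, x, y}) < 4 or adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = adj[v, u] = adj[x, y] = adj[y, x] = False
        adj[u, x] = adj[x, u] = adj[v, y] = adj[y, v] = True
        edges[e1] = (u, x)
        edges[e2] = (v, y)
        successes += 1
    if successes == 0:
        warnings.warn("no swappable edge pair; returning graph unchanged", stacklevel=2)
    return BinaryGraph(
        adj.astype(np.int8), density=graph.density, group=graph.group, regions=graph.regions
    )


def small_worldness(graph: BinaryGraph, n_rand: int = 100, seed=None) -> SmallWorldResult:
    """Humphries–Gurney sigma = (C/C_rand) / (L/L_rand).

    ``C_rand`` and ``L_rand`` are means over ``n_rand`` rewired references.
    The Monte-Carlo SD of sigma across references is reported; a
    ``connected=False`` flag marks graphs whose L was restricted to
    reachable pairs.
    """
    rng = np.random.default_rng(seed)
    _, c_obs = clustering_coefficient(graph)
    l_obs, disconnected = characteristic_path_length(graph)
    c_rand = np.empty(n_rand)
    l_rand = np.empty(n_rand)
    for i in range(n_rand):
        ref = random_reference(graph, seed=int(rng.integers(2**31)))
        _, c_rand[i] = clustering_coefficient(ref)
        l_rand[i], _ = characteristic_path_length(ref)
    if c_rand.mean() == 0:
        raise ValueError("mean reference clustering is 0; sigma undefined")
    sigma = (c_obs / c_rand.mean()) / (l_obs / l_rand.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_ref = (c_obs / c_rand) / (l_obs / l_rand)
    return SmallWorldResult(
        sigma=float(sigma),
        clustering=c_obs,
        path_length=l_obs,
        clustering_rand=float(c_rand.mean()),
        path_length_rand=float(l_rand.mean()),
        sigma_sd=float(np.std(per_ref[np.isfinite(per_ref)])),
        connected=not disconnected,
    )


def eigenvector_centrality(graph: BinaryGraph) -> np.ndarray:
    """Nonnegative principal eigenvector of the adjacency, unit 2-norm.

    On disconnected graphs the vector is supported on the component with the
    largest leading eigenvalue (a warning is emitted).
    """
    if graph.n_edges == 0:
        raise ValueError("eigenvector centrality undefined for an edgeless graph")
    n_comp, _ = connected_components(csr_matrix(graph.adjacency), directed=False)
    if n_comp > 1:
        warnings.warn(
            "graph is disconnected; centrality is supported on the dominant component",
            stacklevel=2,
        )
    vals, vecs = np.linalg.eigh(graph.adjacency.astype(float))
    v = vecs[:, -1]
    # Perron convention: flip sign so the vector is nonnegative
    if v.sum() < 0:
        v = -v
    if v.min() < -1e-8:
        raise ValueError("principal eigenvector is not one-signed; cannot normalize")
    v = np.clip(v, 0.0, None)
    return v / np.linalg.norm(v)


def hub_profile(
    matrix: CovarianceMatrix,
    grid: tuple = HUB_GRID,
    z_threshold: float = HUB_Z_THRESHOLD,
) -> HubProfile:
    """Density-averaged eigenvector centrality, z-scored across regions.

    Centrality is averaged over the hub density grid (default the strongest
    5–35% of links in 5% increments, 7 densities); regions with z-score
    above ``z_threshold`` are flagged as hubs.
    """
    densities = grid_points(*grid)
    cent = np.zeros(matrix.n_regions)
    for d in densities:
        cent += eigenvector_centrality(threshold_density(matrix, d))
    cent /= len(densities)
    sd = cent.std()
    if sd <= 1e-12:
        raise ValueError("centrality is constant across regions; z-scores undefined")
    z = (cent - cent.mean()) / sd
    return HubProfile(
        regions=list(matrix.regions),
        mean_centrality=cent,
        z_scores=z,
        group=matrix.group,
        z_threshold=z_threshold,
    )


def assortativity(graph: BinaryGraph, strength: np.ndarray) -> float:
    """Strength assortativity over edges.

    With j_i, k_i the strengths (here density-averaged eigenvector
    centralities) of the endpoints of edge i and M the edge count::

        r = [M^-1 sum(j k) - (M^-1 sum((j+k)/2))^2]
            / [M^-1 sum((j^2+k^2)/2) - (M^-1 sum((j+k)/2))^2]

    Positive r: similar-strength nodes attach to each other; negative r:
    hubs attach to non-hubs.
    """
    strength = np.asarray(strength, float)
    if strength.shape != (graph.n_nodes,):
        raise ValueError("strength vector length must equal node count")
    iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
    m = len(iu)
    if m < 2:
        raise ValueError("assortativity needs >= 2 edges")
    j, k = strength[iu], strength[ju]
    mean_prod = (j * k).mean()
    mean_avg = ((j + k) / 2.0).mean()
    mean_sq = ((j**2 + k**2) / 2.0).mean()
    denom = mean_sq - mean_avg**2
    if denom == 0:
        raise ValueError("assortativity undefined: all edge-endpoint strengths equal")
    return float((mean_prod - mean_avg**2) / denom)
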