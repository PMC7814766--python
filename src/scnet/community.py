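"""Consensus Louvain modules, modularity, and the modular segregation index.

Community detection runs on the weighted covariance network after removing
negative connections, avoiding any dependence on a binarization density.
Because Louvain is stochastic, the partition is stabilized by consensus
clustering: many randomized runs are summarized in a co-assignment
(agreement) matrix, weak agreements are pruned, and Louvain is re-run on the
agreement matrix until a single partition is reproduced by every run.

The segregation index of a module contrasts its mean within-module
Fisher-z connectivity against its mean connectivity to the rest of the
network::

    SI = (Zw - Zb) / Zw

SI near 1 marks a module nearly uncoupled from the remaining regions; 0
marks no segregation. Group contrasts transfer one group's partition onto
the other group's covariance so the same region sets are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .covariance import CovarianceMatrix

__all__ = [
    "Partition",
    "louvain_once",
    "coassignment_matrix",
    "consensus_partition",
    "modularity_q",
    "segregation_index",
    "transfer_si_contrast",
]


@dataclass
class Partition:
    """Module assignment per region: labels contiguous from 1."""

    labels: np.ndarray
    group: str = ""
    stage: str = "single-run"  # single-run | consensus | planted

    def __post_init__(self):
        self.labels = canonical_labels(np.asarray(self.labels, dtype=int))

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K in order of first appearance (canonical form)."""
    mapping = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _positive_weight_matrix(weights) -> np.ndarray:
    if isinstance(weights, CovarianceMatrix):
        return weights.positive_weights()
    w = np.asarray(weights, float).copy()
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    return w


def louvain_once(weights, seed=None, resolution: float = 1.0) -> Partition:
    """One Louvain run on the positive weighted graph (randomized by seed)."""
    w = _positive_weight_matrix(weights)
    if w.shape[0] == 0:
        raise ValueError("empty graph")
    g = nx.from_numpy_array(w)
    g.add_nodes_from(range(w.shape[0]))  # keep isolated nodes
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(w.shape[0], dtype=int)
    for lab, nodes in enumerate(communities, start=1):
        labels[list(nodes)] = lab
    group = weights.group if isinstance(weights, CovarianceMatrix) else ""
    return Partition(labels, group=group, stage="single-run")


def coassignment_matrix(partitions: list) -> np.ndarray:
    """Fraction of partitions assigning each region pair to the same module.

    Symmetric with unit diagonal; from identical partitions it is exactly
    0/1-valued.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].n_regions
    agree = np.zeros((n, n))
    for p in partitions:
        agree += p.labels[:, None] == p.labels[None, :]
    agree /= len(partitions)
    np.fill_diagonal(agree, 1.0)
    return agree


def consensus_partition(
    weights,
    n_runs: int = 150,
    tau: float = 0.5,
    n_consensus_runs: int = 100,
    seed=None,
    max_iter: int = 20,
    resolution: float = 1.0,
) -> Partition:
    """Consensus Louvain partition of the positive weighted network.

    ``n_runs`` randomized Louvain partitions are reduced to a co-assignment
    matrix; agreements below ``tau`` are zeroed; ``n_consensus_runs`` Louvain
    runs on the pruned agreement matrix either all coincide (convergence) or
    are themselves reduced to a new agreement matrix, up to ``max_iter``
    rounds. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    runs = [louvain_once(weights, seed=int(rng.integers(2**31))) for _ in range(n_runs)]
    group = weights.group if isinstance(weights, CovarianceMatrix) else ""
    for _ in range(max_iter):
        agree = coassignment_matrix(runs)
        agree[agree < tau] = 0.0
        if not np.any(np.triu(agree, k=1)):
            raise ValueError("consensus matrix fully zeroed; no stable agreement")
        runs = [
            louvain_once(agree, seed=int(rng.integers(2**31)), resolution=resolution)
            for _ in range(n_consensus_runs)
        ]
        first = runs[0].labels
        if all(np.array_equal(first, p.labels) for p in runs[1:]):
            return Partition(first, group=group, stage="consensus")
    raise RuntimeError(f"consensus did not converge within {max_iter} iterations")


def modularity_q(graph_or_weights, partition: Partition) -> float:
    """Newman modularity Q = sum_m (e_mm - a_m^2) on a binary or weighted graph.

    ``e_mm`` is the fraction of edge weight inside module m and ``a_m`` the
    fraction of edge-endpoint weight attached to m.
    """
    if hasattr(graph_or_weights, "adjacency"):
        w = graph_or_weights.adjacency.astype(float)
    else:
        w = _positive_weight_matrix(graph_or_weights)
    if w.shape[0] != partition.n_regions:
        raise ValueError("partition size does not match graph node count")
    total = w.sum()  # 2m
    if total == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    q = 0.0
    for m in range(1, partition.n_modules + 1):
        idx = partition.members(m)
        e_mm = w[np.ix_(idx, idx)].sum() / total
        a_m = w[idx, :].sum() / total
        q += e_mm - a_m**2
    return float(q)


ARCTANH_CLIP = 1.0 - 1e-7


def _fisher_z(values: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(values, -ARCTANH_CLIP, ARCTANH_CLIP))


def segregation_index(weights, partition: Partition, module: int) -> float:
    """SI = (Zw - Zb) / Zw for one module of a correlation network.

    ``Zw``: mean Fisher-z correlation over within-module region pairs;
    ``Zb``: mean over pairs joining the module to all other regions
    (unweighted by the other modules' sizes). Correlations at +-1 are
    clipped before the arctanh.
    """
    w = weights.values if isinstance(weights, CovarianceMatrix) else np.asarray(weights, float)
    if w.shape[0] != partition.n_regions:
        raise ValueError("partition size does not match matrix size")
    inside = partition.labels == module
    if inside.sum() < 2:
        raise ValueError(f"module {module} has fewer than 2 regions")
    if inside.sum() == partition.n_regions:
        raise ValueError("module spans all regions; no between-module pairs")
    z = _fisher_z(w)
    idx = np.flatnonzero(inside)
    iu, ju = np.triu_indices(len(idx), k=1)
    z_within = z[idx[iu], idx[ju]].mean()
    z_between = z[np.ix_(idx, np.flatnonzero(~inside))].mean()
    if z_within == 0:
        raise ValueError("mean within-module Fisher z is 0; SI undefined")
    return float((z_within - z_between) / z_within)


def transfer_si_contrast(weights_a, weights_b, partition_from_a: Partition, module: int):
    """SI of one module in both groups under group A's partition.

    Returns ``(si_a, si_b, si_a - si_b)``; the difference is the statistic
    handed to the permutation engine, with the partition held fixed.
    """
    si_a = segregation_index(weights_a, partition_from_a, module)
    si_b = segregation_index(weights_b, partition_from_a, module)
    return si_a, si_b, si_a - si_b
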