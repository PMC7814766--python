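"""Group-level structural covariance matrices and density thresholding.

The structural covariance network of a group is the matrix of Pearson
correlations, across the group's subjects, between the residualized
morphometric measures of every pair of regions. With R regions the matrix
holds R(R-1)/2 unique inter-regional connections (10,878 for the 148-region
Destrieux parcellation).

Binarization retains a fixed fraction (link density) of the strongest
positive correlations: self-connections and negative correlations are
excluded, the remaining edges ranked by correlation, and the top
``round(density * R(R-1)/2)`` kept. Because the ranking does not depend on
the density, graphs over a density grid are nested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import region_columns

__all__ = [
    "CovarianceMatrix",
    "BinaryGraph",
    "build_covariance",
    "threshold_density",
    "density_grid",
]


@dataclass
class CovarianceMatrix:
    """Symmetric region x region Pearson correlation matrix for one group."""

    values: np.ndarray
    regions: list
    group: str = ""
    n_subjects: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("covariance matrix must be square")
        if v.shape[0] != len(self.regions):
            raise ValueError("matrix size does not match region count")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("covariance matrix must be symmetric (tol 1e-12)")
        self.values = v

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_connections(self) -> int:
        """Number of unique off-diagonal region pairs, R(R-1)/2."""
        r = self.n_regions
        return r * (r - 1) // 2

    def positive_weights(self) -> np.ndarray:
        """Copy with the diagonal and all non-positive entries zeroed."""
        w = self.values.copy()
        np.fill_diagonal(w, 0.0)
        w[w < 0] = 0.0
        return w


@dataclass
class BinaryGraph:
    """Unweighted thresholded graph with provenance."""

    adjacency: np.ndarray
    density: float
    group: str = ""
    regions: list = field(default_factory=list)
    achieved_density: float | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = a.astype(np.int8)
        if self.achieved_density is None:
            self.achieved_density = self.n_edges / max(self.n_pairs, 1)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def build_covariance(residuals: pd.DataFrame, group: str) -> CovarianceMatrix:
    """Pearson correlations across one group's subjects for every region pair.

    ``residuals`` is a residual table (one stratum); rows with
    ``residuals["group"] == group`` are used.
    """
    rows = residuals[residuals["group"] == group]
    regions = region_columns(residuals)
    if len(rows) < 3:
        raise ValueError(f"group {group!r} has {len(rows)} subjects; need >= 3")
    values = rows[regions].to_numpy(float)
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = regions[int(np.argmax(sd == 0))]
        raise ValueError(f"region {bad!r} is constant within group {group!r}")
    corr = np.corrcoef(values, rowvar=False)
    # corrcoef can drift past 1e-12 asymmetry on large inputs; re-symmetrize
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CovarianceMatrix(corr, list(regions), group=group, n_subjects=len(rows))


def _ranked_positive_edges(matrix: CovarianceMatrix):
    """Upper-triangle positive edges sorted by descending correlation.

    Ties are broken by lexicographic (i, j) region-index order so the
    ranking — and hence every thresholded graph — is deterministic.
    """
    iu, ju = np.triu_indices(matrix.n_regions, k=1)
    vals = matrix.values[iu, ju]
    keep = vals > 0
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def threshold_density(matrix: CovarianceMatrix, density: float) -> BinaryGraph:
    """Binarize by retaining the strongest positive correlations.

    Keeps the top ``k = round(density * R(R-1)/2)`` positive edges, the total
    pair count including negative pairs (a "% of connections" out of all
    R(R-1)/2). If fewer positive edges exist, all are kept and the achieved
    density recorded with a warning.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    iu, ju, _ = _ranked_positive_edges(matrix)
    k = int(round(density * matrix.n_connections))
    if len(iu) < k:
        warnings.warn(
            f"only {len(iu)} positive edges available for requested "
            f"k={k} at density {density:.3f}; keeping all",
            stacklevel=2,
        )
        k = len(iu)
    adj = np.zeros((matrix.n_regions, matrix.n_regions), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adj, density=density, group=matrix.group, regions=matrix.regions)


def density_grid(
    matrix: CovarianceMatrix, d_min: float = 0.08, d_max: float = 0.35, step: float = 0.01
) -> list:
    """One BinaryGraph per density over an inclusive grid; graphs are nested."""
    if d_min > d_max or step <= 0:
        raise ValueError("need d_min <= d_max and step > 0")
    densities = grid_points(d_min, d_max, step)
    return [threshold_density(matrix, d) for d in densities]


def grid_points(d_min: float, d_max: float, step: float) -> np.ndarray:
    """Inclusive arange robust to float endpoints (0.08..0.35 by 0.01 -> 28 points)."""
    n = int(np.floor((d_max - d_min) / step + 1e-9)) + 1
    return np.round(d_min + step * np.arange(n), 10)
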