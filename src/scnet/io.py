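"""Plain-text serialization of every pipeline artifact.

All tabular artifacts are CSV; structured results are JSON. Each writer has
a matching reader satisfying ``read(write(x)) == x`` (numeric round-trips at
full float precision). Formats carry a ``format`` tag in their JSON sidecars
so schema mismatches fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import BinaryGraph, CovarianceMatrix
from .community import Partition
from .inference import TestResult

__all__ = [
    "write_cohort", "read_cohort",
    "write_matrix", "read_matrix",
    "write_graph", "read_graph",
    "write_partition", "read_partition",
    "write_test_result", "read_test_result",
]

FLOAT_FORMAT = "%.17g"


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(matrix: CovarianceMatrix, path) -> None:
    """Square CSV with region-label header plus a JSON provenance sidecar."""
    frame = pd.DataFrame(matrix.values, index=matrix.regions, columns=matrix.regions)
    frame.to_csv(path, float_format=FLOAT_FORMAT)
    _write_sidecar(path, {
        "format": "scnet.covariance_matrix/1",
        "group": matrix.group,
        "n_subjects": matrix.n_subjects,
    })


def read_matrix(path) -> CovarianceMatrix:
    meta = _read_sidecar(path, "scnet.covariance_matrix/1")
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy(float)
    values = (values + values.T) / 2.0  # text round-trip can break symmetry in the last ulp
    return CovarianceMatrix(
        values,
        regions=list(frame.columns),
        group=meta["group"],
        n_subjects=meta["n_subjects"],
    )


def write_graph(graph: BinaryGraph, path) -> None:
    """Edge-list CSV (region_i, region_j, 1) plus a JSON sidecar."""
    iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
    regions = graph.regions or [str(i) for i in range(graph.n_nodes)]
    pd.DataFrame({
        "region_i": [regions[i] for i in iu],
        "region_j": [regions[j] for j in ju],
        "weight": 1,
    }).to_csv(path, index=False)
    _write_sidecar(path, {
        "format": "scnet.binary_graph/1",
        "density": graph.density,
        "achieved_density": graph.achieved_density,
        "group": graph.group,
        "regions": list(regions),
    })


def read_graph(path) -> BinaryGraph:
    meta = _read_sidecar(path, "scnet.binary_graph/1")
    regions = meta["regions"]
    index = {r: i for i, r in enumerate(regions)}
    edges = pd.read_csv(path)
    adj = np.zeros((len(regions), len(regions)), dtype=np.int8)
    for _, row in edges.iterrows():
        i, j = index[row["region_i"]], index[row["region_j"]]
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(
        adj,
        density=meta["density"],
        group=meta["group"],
        regions=regions,
        achieved_density=meta["achieved_density"],
    )


def write_partition(partition: Partition, path) -> None:
    """Two-column CSV (region index, module) plus a JSON sidecar."""
    pd.DataFrame({
        "region": np.arange(partition.n_regions),
        "module": partition.labels,
    }).to_csv(path, index=False)
    _write_sidecar(path, {
        "format": "scnet.partition/1",
        "group": partition.group,
        "stage": partition.stage,
    })


def read_partition(path) -> Partition:
    meta = _read_sidecar(path, "scnet.partition/1")
    frame = pd.read_csv(path)
    return Partition(
        frame["module"].to_numpy(int), group=meta["group"], stage=meta["stage"]
    )


def write_test_result(result: TestResult, path, include_null: bool = True) -> None:
    payload = {
        "format": "scnet.test_result/1",
        "statistic": result.statistic,
        "observed": result.observed.tolist(),
        "p": result.p.tolist(),
        "ci_low": result.ci_low.tolist(),
        "ci_high": result.ci_high.tolist(),
        "family": list(result.family),
        "q": None if result.q is None else result.q.tolist(),
        "n_failed": result.n_failed,
        "null": result.null.tolist() if include_null else None,
    }
    Path(path).write_text(json.dumps(payload))


def read_test_result(path) -> TestResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "scnet.test_result/1":
        raise ValueError(f"not a scnet test-result file: {path}")
    return TestResult(
        statistic=payload["statistic"],
        observed=np.asarray(payload["observed"]),
        null=np.asarray(payload["null"]) if payload["null"] is not None else np.empty((0, 0)),
        p=np.asarray(payload["p"]),
        ci_low=np.asarray(payload["ci_low"]),
        ci_high=np.asarray(payload["ci_high"]),
        family=payload["family"],
        q=None if payload["q"] is None else np.asarray(payload["q"]),
        n_failed=payload["n_failed"],
    )


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload))


def _read_sidecar(path, expected_format: str) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing sidecar {sidecar}; not a scnet artifact")
    payload = json.loads(sidecar.read_text())
    if payload.get("format") != expected_format:
        raise ValueError(
            f"format mismatch for {path}: expected {expected_format!r}, "
            f"got {payload.get('format')!r}"
        )
    return payload
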