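"""Validation experiments: oracle suites, calibration and power studies.

These are the package's own quality-control studies, shared by the test
suite and the acceptance script: closed-form spot checks of the graph
metrics, brute-force oracle comparisons, consensus-module recovery on
planted covariance blocks, type-I-error calibration of the center-paired
permutation under site confounds, power of the segregation-index contrast,
small-worldness sanity on canonical graph families, and an end-to-end
determinism check.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import reference
from .community import (
    Partition,
    consensus_partition,
    modularity_q,
    segregation_index,
)
from .covariance import BinaryGraph, CovarianceMatrix, build_covariance, threshold_density
from .graphmetrics import (
    assortativity,
    characteristic_path_length,
    clustering_coefficient,
    eigenvector_centrality,
    global_efficiency,
    small_worldness,
)
from .inference import permutation_test
from .pipeline import PipelineConfig, run_pipeline
from .preprocess import mad_rescale, regress_covariates
from .synthetic import SyntheticConfig, generate_cohort, planted_truth

__all__ = [
    "closed_form_checks",
    "metric_oracle_suite",
    "consensus_recovery",
    "permutation_calibration",
    "si_contrast_power",
    "smallworld_sanity",
    "determinism_check",
    "random_binary_graph",
]


def _graph(adjacency) -> BinaryGraph:
    a = np.asarray(adjacency, dtype=np.int8)
    return BinaryGraph(a, density=a.sum() / (a.shape[0] * (a.shape[0] - 1)))


def random_binary_graph(rng, max_nodes: int = 12, p: float | None = None) -> BinaryGraph:
    """Random Erdős–Rényi graph with >= 2 edges, for oracle suites."""
    while True:
        n = int(rng.integers(4, max_nodes + 1))
        prob = float(rng.uniform(0.25, 0.8)) if p is None else p
        a = (rng.random((n, n)) < prob).astype(np.int8)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() >= 4:
            return _graph(a)


def closed_form_checks() -> dict:
    """Spot checks with hand-computable answers on tiny graphs.

    Returns the computed values; the analytic targets are K4 clustering 1,
    P3 path length 4/3 and efficiency 3/4, two-equal-clique modularity 1/2,
    star centrality ratio sqrt(3), P3 strength assortativity -1, and the
    worked segregation-index example 0.6310.
    """
    k4 = _graph(1 - np.eye(4))
    p3 = _graph([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    star = _graph([[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]])
    two_cliques = np.zeros((6, 6), dtype=int)
    two_cliques[:3, :3] = 1 - np.eye(3)
    two_cliques[3:, 3:] = 1 - np.eye(3)

    _, k4_clust = clustering_coefficient(k4)
    p3_length, _ = characteristic_path_length(p3)
    star_vec = eigenvector_centrality(star)
    p3_vec = eigenvector_centrality(p3)

    # worked SI example: within-module correlations all 0.5, between all 0.2
    si4 = np.eye(4)
    pairs = {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5, (0, 3): 0.2, (1, 3): 0.2, (2, 3): 0.2}
    for (i, j), v in pairs.items():
        si4[i, j] = si4[j, i] = v
    si_value = segregation_index(si4, Partition([1, 1, 1, 2]), 1)

    return {
        "k4_clustering": k4_clust,
        "p3_path_length": p3_length,
        "p3_efficiency": global_efficiency(p3),
        "p3_efficiency_latora_marchiori": global_efficiency(p3, "latora_marchiori"),
        "two_clique_modularity": modularity_q(_graph(two_cliques), Partition([1, 1, 1, 2, 2, 2])),
        "star_centrality_ratio": float(star_vec[0] / star_vec[1]),
        "p3_strength_assortativity": assortativity(p3, p3_vec),
        "si_worked_example": si_value,
    }


def metric_oracle_suite(n_graphs: int = 100, max_nodes: int = 12, seed: int = 0) -> float:
    """Max absolute deviation of fast metrics from brute-force references.

    Compares clustering, characteristic path length, eigenvector centrality,
    modularity Q under random partitions, and the strength assortativity
    against independent naive implementations on random graphs.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        graph = random_binary_graph(rng, max_nodes=max_nodes)
        a = graph.adjacency
        per_node, _ = clustering_coefficient(graph)
        worst = max(worst, float(np.max(np.abs(per_node - reference.clustering_brute(a)))))
        length, _ = characteristic_path_length(graph)
        worst = max(worst, abs(length - reference.path_length_brute(a)))
        # eigenvector comparison only where the Perron vector is unique (connected)
        if nx.is_connected(nx.from_numpy_array(a)):
            vec = eigenvector_centrality(graph)
            ref_vec = reference.eigenvector_brute(a)
            worst = max(worst, float(np.max(np.abs(vec - ref_vec))))
        labels = rng.integers(1, 4, size=graph.n_nodes)
        labels[0] = 1  # at least one nonempty module label
        part = Partition(labels)
        worst = max(worst, abs(modularity_q(graph, part) - reference.modularity_brute(a, part.labels)))
        strength = rng.random(graph.n_nodes)
        try:
            fast = assortativity(graph, strength)
        except ValueError:
            continue
        worst = max(worst, abs(fast - reference.assortativity_brute(a, strength)))
    return worst


def recovery_config(seed: int = 0, split: bool = False) -> SyntheticConfig:
    """Planted 4-block covariance study conditions: 60 regions, rho 0.6/0.1."""
    return SyntheticConfig(
        n_regions=60,
        module_labels=np.repeat([1, 2, 3, 4], 15),
        per_site_counts={"site01": 75, "site02": 75},
        rho_within=0.6,
        rho_between=0.1,
        site_scales={"site01": 1.0, "site02": 1.6},
        split_module=1 if split else None,
        split_strength=0.4,
        seed=seed,
    )


def _preprocessed_residuals(config: SyntheticConfig):
    cohort = generate_cohort(config)
    return regress_covariates(mad_rescale(cohort))


def consensus_recovery(n_seeds: int = 20, seed: int = 0, n_runs: int = 150,
                       n_consensus_runs: int = 100) -> np.ndarray:
    """ARI of the consensus partition against the planted 4-block partition.

    One cohort per seed at the planted-block study conditions; the consensus
    partition of group A's covariance network is scored against the planted
    module labels by adjusted Rand index.
    """
    rng = np.random.default_rng(seed)
    scores = np.empty(n_seeds)
    for i in range(n_seeds):
        config = recovery_config(seed=int(rng.integers(2**31)))
        residuals = _preprocessed_residuals(config)
        cov = build_covariance(residuals, "A")
        part = consensus_partition(cov, n_runs=n_runs, n_consensus_runs=n_consensus_runs,
                                   seed=int(rng.integers(2**31)))
        truth, _ = planted_truth(config)
        scores[i] = adjusted_rand_score(truth["A"], part.labels)
    return scores


def confounded_null_config(seed: int) -> SyntheticConfig:
    """Group-null cohort with a strong site confound and unbalanced sites.

    Sites differ in overall scale and in per-(site, region) scale jitter,
    and the two groups sample the sites unequally, so a site effect that
    survives preprocessing masquerades as a group effect unless the
    permutation null preserves site composition.
    """
    return SyntheticConfig(
        n_regions=40,
        module_labels=np.repeat([1, 2, 3, 4], 10),
        per_site_counts={"site01": (40, 10), "site02": (10, 40)},
        rho_within=0.4,
        rho_between=0.1,
        site_scales={"site01": 1.0, "site02": 2.5},
        site_scale_jitter=0.4,
        matched=False,
        seed=seed,
    )


def mean_clustering_difference(values_a, values_b, density: float = 0.15) -> float:
    """Difference in mean clustering of the two groups' thresholded networks."""
    out = []
    for values in (values_a, values_b):
        corr = np.corrcoef(values, rowvar=False)
        corr = (corr + corr.T) / 2.0
        matrix = CovarianceMatrix(corr, [f"r{i}" for i in range(corr.shape[0])])
        _, mean_c = clustering_coefficient(threshold_density(matrix, density))
        out.append(mean_c)
    return out[0] - out[1]


def permutation_calibration(n_cohorts: int = 200, n_perm: int = 1000,
                            alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of stratified vs unstratified permutation under site confounds.

    Each simulated cohort has no group effect but a strong site confound
    left in the data (no MAD rescaling). The mean-clustering-difference
    statistic is tested both ways; returns the two rejection rates.
    """
    rng = np.random.default_rng(seed)
    rejections = {"stratified": 0, "unstratified": 0}
    for _ in range(n_cohorts):
        config = confounded_null_config(seed=int(rng.integers(2**31)))
        cohort = generate_cohort(config)
        residuals = regress_covariates(cohort)  # deliberately no MAD rescale
        for mode, stratified in (("stratified", True), ("unstratified", False)):
            result = permutation_test(
                residuals, mean_clustering_difference, n_perm=n_perm,
                seed=int(rng.integers(2**31)), stratified=stratified,
            )
            rejections[mode] += int(result.p[0] < alpha)
    return {
        "type1_stratified": rejections["stratified"] / n_cohorts,
        "type1_unstratified": rejections["unstratified"] / n_cohorts,
        "n_cohorts": n_cohorts,
        "n_perm": n_perm,
    }


def si_contrast_power(n_seeds: int = 20, n_perm: int = 1000, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Power of the transfer-SI permutation test on a planted module split.

    Group B's split of planted module 1 into two sub-blocks raises the
    segregation of each sub-block relative to group A. Per seed, the
    consensus partition of group B identifies the sub-module; its SI
    difference (B minus A, partition held fixed) is tested under the
    center-paired null.
    """
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_seeds)
    observed = np.empty(n_seeds)
    for i in range(n_seeds):
        config = recovery_config(seed=int(rng.integers(2**31)), split=True)
        residuals = _preprocessed_residuals(config)
        cov_b = build_covariance(residuals, "B")
        part_b = consensus_partition(cov_b, seed=int(rng.integers(2**31)))
        truth, _ = planted_truth(config)
        # sub-module of the split: the consensus module best matching planted sub-block 1
        sub_block = truth["B"] == truth["B"][0]
        overlaps = [
            (np.sum((part_b.labels == m) & sub_block) / max(np.sum((part_b.labels == m) | sub_block), 1), m)
            for m in range(1, part_b.n_modules + 1)
        ]
        module = max(overlaps)[1]

        def si_difference(values_a, values_b):
            out = []
            for values in (values_a, values_b):
                corr = np.corrcoef(values, rowvar=False)
                corr = (corr + corr.T) / 2.0
                out.append(segregation_index(corr, part_b, module))
            return out[1] - out[0]  # B minus A

        result = permutation_test(residuals, si_difference, n_perm=n_perm,
                                  seed=int(rng.integers(2**31)))
        p_values[i] = result.p[0]
        observed[i] = result.observed[0]
    return {
        "power": float(np.mean(p_values < alpha)),
        "positive_fraction": float(np.mean(observed > 0)),
        "p_values": p_values,
        "n_seeds": n_seeds,
    }


def smallworld_sanity(n_rand: int = 50, seed: int = 0) -> dict:
    """Sigma of an Erdős–Rényi graph (≈1) and a Watts–Strogatz ring (>1.5)."""
    er = nx.erdos_renyi_graph(100, 0.15, seed=seed)
    ws = nx.watts_strogatz_graph(100, 6, 0.1, seed=seed)
    out = {}
    for name, g in (("erdos_renyi", er), ("watts_strogatz", ws)):
        adj = nx.to_numpy_array(g, dtype=np.int8)
        graph = _graph(adj)
        sw = small_worldness(graph, n_rand=n_rand, seed=seed + 1)
        out[f"sigma_{name}"] = sw.sigma
    return out


def small_pipeline_config(outdir, seed: int = 0) -> PipelineConfig:
    """Reduced problem-size pipeline configuration for end-to-end runs."""
    synth = SyntheticConfig(
        n_regions=40,
        module_labels=np.repeat([1, 2, 3, 4], 10),
        per_site_counts={"site01": 40, "site02": 40},
        rho_within=0.5,
        rho_between=0.1,
        site_scales={"site01": 1.0, "site02": 1.5},
        age_range=(7.0, 29.0),
        seed=seed,
    )
    return PipelineConfig(
        synthetic=synth,
        age_bands={"all": (7, 29)},
        density_grid=(0.10, 0.30, 0.05),
        n_perm=200,
        n_rand=20,
        n_rand_perm=2,
        consensus_runs=(50, 30),
        seed=seed,
        outdir=str(outdir),
    )


def determinism_check(tmpdir, seed: int = 0) -> bool:
    """Run the reduced pipeline twice with one seed; compare artifacts bytewise."""
    tmpdir = Path(tmpdir)
    dirs = []
    for name in ("run1", "run2"):
        config = small_pipeline_config(tmpdir / name, seed=seed)
        run_pipeline(config)
        dirs.append(tmpdir / name)
    return _trees_identical(dirs[0], dirs[1])


def _trees_identical(a: Path, b: Path) -> bool:
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    if files_a != files_b:
        return False
    return all(filecmp.cmp(a / f, b / f, shallow=False) for f in files_a)
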