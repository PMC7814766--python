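"""End-to-end orchestration: cohort table in, analysis artifacts out.

For each age band the pipeline runs: MAD rescaling (once, per site, on the
full cohort) -> covariate regression to residuals -> per-group covariance
matrices -> density-grid binarization -> global metric curves with
center-paired permutation tests -> hub profiles and the assortativity
contrast -> consensus modules per group -> segregation-index contrasts with
partition transfer -> regionwise group tests -> structure-centrality
correlations. All artifacts are written as CSV/JSON plus a run manifest
(seed, package versions, config) so any run is auditable; with a fixed seed
the tables are byte-identical across reruns.

Every stage draws its randomness from a child of one top-level
``numpy.random.SeedSequence(config.seed)``; children are spawned in a fixed
documented order (see ``stage_seeds``), so adding permutations to one stage
never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scio
from .community import consensus_partition, modularity_q, segregation_index
from .covariance import CovarianceMatrix, build_covariance, grid_points, threshold_density
from .graphmetrics import (
    HUB_GRID,
    assortativity,
    clustering_coefficient,
    characteristic_path_length,
    global_efficiency,
    hub_profile,
    small_worldness,
)
from .inference import (
    correlate_structure_centrality,
    fdr_correct,
    permutation_test,
    regionwise_group_test,
)
from .preprocess import mad_rescale, region_columns, regress_covariates, site_bias_check
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

logger = logging.getLogger(__name__)

DEFAULT_AGE_BANDS = {"child": (7, 11), "adolescent": (12, 17), "adult": (18, 29)}

#: fixed spawn order of per-stage seed-sequence children
STAGE_NAMES = ("synthetic", "metric_perm", "assortativity_perm", "consensus", "si_perm", "regionwise")


@dataclass
class PipelineConfig:
    """All tunable parameters of a full analysis run."""

    input_path: str | None = None  # cohort CSV; exclusive with `synthetic`
    synthetic: SyntheticConfig | None = None
    measure: str = "SA"
    age_bands: dict = field(default_factory=lambda: dict(DEFAULT_AGE_BANDS))
    density_grid: tuple = (0.08, 0.35, 0.01)
    hub_grid: tuple = HUB_GRID
    hub_z_threshold: float = 1.5
    n_perm: int = 5000
    n_rand: int = 100  # references for the observed sigma
    n_rand_perm: int = 5  # references per permutation draw (sigma null)
    tau: float = 0.5
    consensus_runs: tuple = (150, 100)
    efficiency_variant: str = "inverse_path_length"
    apply_mad_rescale: bool = True
    asd_role: str = "B"  # group whose consensus partition seeds the SI transfer
    q_level: float = 0.05
    seed: int = 0
    outdir: str = "scnet_output"

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")
        lo, hi, step = self.density_grid
        if not (0 < lo <= hi <= 1 and step > 0):
            raise ValueError("invalid density grid")
        bands = sorted(self.age_bands.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(bands, bands[1:]):
            if b_lo <= a_hi:
                raise ValueError("age bands must not overlap")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def stage_seeds(seed: int) -> dict:
    """Per-stage integer seeds spawned from one top-level SeedSequence.

    Children are spawned in the fixed order of ``STAGE_NAMES``; each stage
    seed is the first 31-bit state drawn from its child sequence.
    """
    children = np.random.SeedSequence(seed).spawn(len(STAGE_NAMES))
    return {
        name: int(child.generate_state(1, np.uint64)[0] % (2**31))
        for name, child in zip(STAGE_NAMES, children)
    }


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return scio.read_cohort(config.input_path)
    synth = dataclasses.replace(config.synthetic, seed=stage_seeds(config.seed)["synthetic"])
    return generate_cohort(synth)


def _metric_vector(values, densities, n_rand_perm, efficiency_variant, rng, partitions):
    """All global metrics over the density grid for one pseudo-group.

    Returns a dict metric -> vector over densities. ``partitions`` maps the
    group role to the fixed consensus partition used for the Q curve.
    """
    corr = np.corrcoef(values, rowvar=False)
    corr = (corr + corr.T) / 2.0
    matrix = CovarianceMatrix(corr, [f"r{i}" for i in range(corr.shape[0])])
    out = {m: np.empty(len(densities)) for m in ("clustering", "path_length", "efficiency", "sigma", "modularity")}
    for i, d in enumerate(densities):
        graph = threshold_density(matrix, d)
        _, out["clustering"][i] = clustering_coefficient(graph)
        out["path_length"][i], _ = characteristic_path_length(graph)
        out["efficiency"][i] = global_efficiency(graph, efficiency_variant)
        sw = small_worldness(graph, n_rand=n_rand_perm, seed=int(rng.integers(2**31)))
        out["sigma"][i] = sw.sigma
        out["modularity"][i] = modularity_q(graph, partitions)
    return out


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True) -> dict:
    """Execute the full analysis; returns (and optionally writes) all artifacts."""
    config.validate()
    seeds = stage_seeds(config.seed)
    outdir = Path(config.outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)

    cohort = _load_cohort(config)
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"cohort must contain exactly 2 groups, got {groups}")
    asd_role = config.asd_role
    tdc_role = [g for g in groups if g != asd_role][0]

    rescaled = mad_rescale(cohort) if config.apply_mad_rescale else cohort.copy()
    densities = grid_points(*config.density_grid)
    results: dict = {"bands": {}, "seeds": seeds}
    correlation_family = []  # (band, group, r, p) across bands for joint FDR

    for band, (lo, hi) in config.age_bands.items():
        rows = rescaled[(rescaled["age"] >= lo) & (rescaled["age"] <= hi)]
        if rows.empty:
            logger.warning("age band %s [%s, %s] is empty; skipped", band, lo, hi)
            continue
        band_out = _run_band(
            rows, band, config, densities, seeds, groups, asd_role, tdc_role,
            correlation_family,
        )
        results["bands"][band] = band_out

    # FDR over the structure-centrality correlation family (group x band)
    if correlation_family:
        qs, _ = fdr_correct([rec["p"] for rec in correlation_family], config.q_level)
        for rec, q in zip(correlation_family, qs):
            rec["q"] = float(q)
            results["bands"][rec["band"]]["structure_centrality"][rec["group"]]["q"] = float(q)

    if write_artifacts:
        _write_outputs(results, cohort, rescaled, config, outdir)
    return results


def _run_band(rows, band, config, densities, seeds, groups, asd_role, tdc_role, correlation_family):
    residuals = regress_covariates(rows, stratum=band)
    bias = site_bias_check(rows) if rows["site"].nunique() > 1 else None

    covs = {g: build_covariance(residuals, g) for g in groups}
    rng_cons = np.random.default_rng(seeds["consensus"])
    n_runs, n_cons = config.consensus_runs
    partitions = {
        g: consensus_partition(
            covs[g], n_runs=n_runs, tau=config.tau, n_consensus_runs=n_cons,
            seed=int(rng_cons.integers(2**31)),
        )
        for g in groups
    }

    # ---- global metric curves + permutation tests -----------------------
    metric_names = ("clustering", "path_length", "efficiency", "sigma", "modularity")
    rng_obs = np.random.default_rng(seeds["metric_perm"])
    observed_curves = {
        g: _metric_vector(
            residuals[residuals["group"] == g][region_columns(residuals)].to_numpy(float),
            densities, config.n_rand, config.efficiency_variant, rng_obs, partitions[g],
        )
        for g in groups
    }

    def metric_stack(values_a, values_b):
        rng = np.random.default_rng(seeds["metric_perm"] + 1)
        out = []
        for values, g in ((values_a, groups[0]), (values_b, groups[1])):
            m = _metric_vector(values, densities, config.n_rand_perm,
                               config.efficiency_variant, rng, partitions[g])
            out.append(np.concatenate([m[k] for k in metric_names]))
        return out[0] - out[1]

    metric_test = permutation_test(
        residuals, metric_stack, n_perm=config.n_perm, seed=seeds["metric_perm"],
        statistic_name="global_metric_difference",
    )
    metric_tests = _split_metric_test(metric_test, metric_names, densities, config.q_level)

    # ---- hubs + assortativity ------------------------------------------
    profiles = {
        g: hub_profile(covs[g], grid=config.hub_grid, z_threshold=config.hub_z_threshold)
        for g in groups
    }

    def assort_curve(values):
        corr = np.corrcoef(values, rowvar=False)
        corr = (corr + corr.T) / 2.0
        matrix = CovarianceMatrix(corr, [f"r{i}" for i in range(corr.shape[0])])
        prof = hub_profile(matrix, grid=config.hub_grid, z_threshold=config.hub_z_threshold)
        return np.array([
            assortativity(threshold_density(matrix, d), prof.mean_centrality)
            for d in densities
        ])

    def assort_difference(values_a, values_b):
        return assort_curve(values_a) - assort_curve(values_b)

    assort_test = permutation_test(
        residuals, assort_difference, n_perm=config.n_perm,
        seed=seeds["assortativity_perm"], statistic_name="assortativity_difference",
    )
    assort_test.family = [f"{d:g}" for d in densities]
    assort_test.q, _ = fdr_correct(assort_test.p, config.q_level)

    # ---- SI contrasts under the ASD-role partition ----------------------
    si_partition = partitions[asd_role]
    si_tests = {}
    for module in range(1, si_partition.n_modules + 1):
        if len(si_partition.members(module)) < 2 or len(si_partition.members(module)) == si_partition.n_regions:
            continue

        def si_difference(values_a, values_b, module=module):
            out = []
            for values in (values_a, values_b):
                corr = np.corrcoef(values, rowvar=False)
                corr = (corr + corr.T) / 2.0
                out.append(segregation_index(corr, si_partition, module))
            # ASD-role minus TDC-role, matching the reported direction
            diff = out[0] - out[1]
            return diff if groups[0] == asd_role else -diff

        si_tests[module] = permutation_test(
            residuals, si_difference, n_perm=config.n_perm,
            seed=seeds["si_perm"] + module, statistic_name=f"si_module_{module}",
        )
    if si_tests:
        qs, _ = fdr_correct([t.p[0] for t in si_tests.values()], config.q_level)
        for t, q in zip(si_tests.values(), qs):
            t.q = np.array([q])

    # ---- regionwise tests + structure-centrality correlations -----------
    region_test = regionwise_group_test(
        residuals, n_perm=config.n_perm, seed=seeds["regionwise"], q_level=config.q_level
    )
    structure_centrality = {}
    for g in groups:
        r, p = correlate_structure_centrality(residuals, profiles[g], group=g)
        rec = {"band": band, "group": g, "r": r, "p": p}
        structure_centrality[g] = {"r": r, "p": p}
        correlation_family.append(rec)

    return {
        "residuals": residuals,
        "site_bias": bias,
        "covariances": covs,
        "partitions": partitions,
        "curves": observed_curves,
        "metric_tests": metric_tests,
        "hub_profiles": profiles,
        "assortativity_test": assort_test,
        "si_tests": si_tests,
        "regionwise_test": region_test,
        "structure_centrality": structure_centrality,
    }


def _split_metric_test(test, metric_names, densities, q_level):
    """Slice the stacked metric permutation test back into per-metric results."""
    from .inference import TestResult

    k = len(densities)
    out = {}
    for i, name in enumerate(metric_names):
        sl = slice(i * k, (i + 1) * k)
        sub = TestResult(
            statistic=name,
            observed=test.observed[sl],
            null=test.null[:, sl],
            p=test.p[sl],
            ci_low=test.ci_low[sl],
            ci_high=test.ci_high[sl],
            family=[f"{d:g}" for d in densities],
            n_failed=test.n_failed,
        )
        sub.q, _ = fdr_correct(sub.p, q_level)
        out[name] = sub
    return out


def _write_outputs(results, cohort, rescaled, config, outdir: Path) -> None:
    import scnet

    scio.write_cohort(cohort, outdir / "cohort.csv")
    scio.write_cohort(rescaled, outdir / "cohort_rescaled.csv")
    manifest = {
        "package": "scnet",
        "version": scnet.__version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": results["seeds"],
        "config": _config_payload(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    summary_rows = []
    for band, band_out in results["bands"].items():
        bdir = outdir / band
        bdir.mkdir(exist_ok=True)
        scio.write_cohort(band_out["residuals"], bdir / "residuals.csv")
        if band_out["site_bias"] is not None:
            band_out["site_bias"].to_csv(bdir / "site_bias.csv", index=False, float_format="%.17g")
        for g, cov in band_out["covariances"].items():
            scio.write_matrix(cov, bdir / f"covariance_{g}.csv")
            scio.write_partition(band_out["partitions"][g], bdir / f"partition_{g}.csv")
            prof = band_out["hub_profiles"][g]
            pd.DataFrame({
                "region": prof.regions,
                "mean_centrality": prof.mean_centrality,
                "z": prof.z_scores,
                "hub": prof.hubs,
            }).to_csv(bdir / f"hub_profile_{g}.csv", index=False, float_format="%.17g")
        curve_frames = []
        for g, curves in band_out["curves"].items():
            for metric, vals in curves.items():
                curve_frames.append(pd.DataFrame({
                    "group": g, "metric": metric,
                    "density": grid_points(*config.density_grid), "value": vals,
                }))
        pd.concat(curve_frames, ignore_index=True).to_csv(
            bdir / "metric_curves.csv", index=False, float_format="%.17g")
        for name, test in band_out["metric_tests"].items():
            scio.write_test_result(test, bdir / f"test_{name}.json", include_null=False)
        scio.write_test_result(band_out["assortativity_test"], bdir / "test_assortativity.json",
                               include_null=False)
        for module, test in band_out["si_tests"].items():
            scio.write_test_result(test, bdir / f"test_si_module_{module}.json", include_null=False)
            summary_rows.append({
                "band": band, "statistic": f"si_module_{module}",
                "observed": test.observed[0], "p": test.p[0],
                "q": float(test.q[0]) if test.q is not None else np.nan,
            })
        scio.write_test_result(band_out["regionwise_test"], bdir / "test_regionwise.json",
                               include_null=False)
        pd.DataFrame([
            {"band": band, "group": g, **vals}
            for g, vals in band_out["structure_centrality"].items()
        ]).to_csv(bdir / "structure_centrality.csv", index=False, float_format="%.17g")
    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(outdir / "summary_si.csv", index=False,
                                          float_format="%.17g")


def _config_payload(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)  # manifest describes the analysis, not its location
    synth = payload.get("synthetic")
    if synth is not None:
        synth["module_labels"] = list(map(int, synth["module_labels"]))
    return payload
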