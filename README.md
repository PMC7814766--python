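# scnet — structural covariance network analysis for multi-site morphometry

`scnet` compares the group-level *structural covariance networks* of two
diagnostic cohorts measured at several MRI acquisition sites. It is aimed at
neuroimaging researchers with per-subject regional morphometry tables
(cortical surface area or thickness over a parcellation such as the
148-region Destrieux atlas) who want the full chain from raw regional
measures to statistically tested network differences:

1. **harmonization** — per-site, per-region median-absolute-deviation (MAD)
   rescaling, with a one-sample-t QC check of residual site bias;
2. **covariate adjustment** — OLS residuals of each region on age, sex and
   the subject's whole-cortex mean, per age band, groups pooled;
3. **network construction** — per group, the R × R matrix of inter-regional
   Pearson correlations across subjects (R(R−1)/2 unique connections;
   10,878 at R = 148), binarized by keeping the strongest positive
   correlations over a density grid (default 8–35% in 1% steps);
4. **graph topology** — clustering coefficient C, characteristic path
   length L, global efficiency 1/L, small-worldness
   σ = (C/C_rand)/(L/L_rand) against degree-preserving rewired references,
   Newman modularity Q, eigenvector-centrality hub profiles (hubs: z > 1.5
   on the density-averaged centrality), and strength assortativity;
5. **modules** — consensus Louvain partitions of the positive weighted
   network (150 runs → co-assignment matrix, τ = 0.5 pruning, re-clustered
   until stable) and the modular segregation index
   SI = (Z̄w − Z̄b)/Z̄w on Fisher-z correlations, with cross-group partition
   transfer;
6. **inference** — a center-paired permutation null (group labels shuffled
   only *within* each site, preserving per-site counts, default 5,000
   draws), two-tailed empirical p-values with add-one correction, and
   Benjamini–Hochberg FDR per family.

A fully parameterized synthetic cohort generator (latent-factor
block-correlation model with site scales, covariate effects, matched groups
and an optional group-specific module split) makes every stage testable
without access to restricted imaging data. See `docs/methods.md` for the
model details and design decisions.

## Worked example

```python
import numpy as np
from scnet import (
    SyntheticConfig, generate_cohort, planted_truth, mad_rescale,
    regress_covariates, build_covariance, threshold_density, small_worldness,
    hub_profile, consensus_partition, segregation_index, permutation_test,
)

# two-site cohort, 60 regions in four planted modules; group B's first
# module is split into two weakly-coupled sub-blocks
config = SyntheticConfig(
    n_regions=60, module_labels=np.repeat([1, 2, 3, 4], 15),
    per_site_counts={"site01": 75, "site02": 75},
    rho_within=0.6, rho_between=0.1,
    site_scales={"site01": 1.0, "site02": 1.6},
    split_module=1, split_strength=0.4, seed=2,
)
cohort = generate_cohort(config)
residuals = regress_covariates(mad_rescale(cohort))

cov_a = build_covariance(residuals, "A")
cov_b = build_covariance(residuals, "B")
print("unique connections:", cov_a.n_connections)

sw = small_worldness(threshold_density(cov_a, 0.16), n_rand=50, seed=2)
print(f"sigma at 16% density: {sw.sigma:.2f} "
      f"(C={sw.clustering:.2f} vs C_rand={sw.clustering_rand:.2f}, "
      f"L={sw.path_length:.2f} vs L_rand={sw.path_length_rand:.2f})")

profile = hub_profile(cov_a)
print("hub regions in group A:", profile.hubs.sum())

partition_b = consensus_partition(cov_b, seed=3)
print("consensus modules in group B:", partition_b.n_modules)

# module of group B's partition that best covers the planted split module
truth, _ = planted_truth(config)
split_regions = truth["A"] == config.split_module
module = int(np.argmax([
    np.sum((partition_b.labels == m) & split_regions)
    for m in range(1, partition_b.n_modules + 1)
])) + 1

def si_difference(values_a, values_b):
    out = []
    for values in (values_a, values_b):
        corr = np.corrcoef(values, rowvar=False)
        out.append(segregation_index((corr + corr.T) / 2, partition_b, module))
    return out[1] - out[0]  # clinical group minus controls

result = permutation_test(residuals, si_difference, n_perm=1000, seed=4)
print(f"SI difference for module {module}: {result.observed[0]:+.3f}, "
      f"p = {result.p[0]:.4f} "
      f"(null 95% CI {result.ci_low[0]:+.3f} to {result.ci_high[0]:+.3f})")
```

Output:

```
unique connections: 1770
sigma at 16% density: 2.67 (C=0.75 vs C_rand=0.15, L=3.89 vs L_rand=2.02)
hub regions in group A: 9
consensus modules in group B: 4
SI difference for module 1: +0.033, p = 0.0330 (null 95% CI -0.030 to +0.032)
```

Reading it: 60 regions give 60·59/2 = 1,770 possible connections. The
group-A network at 16% density is strongly small-world (σ = 2.67 ≫ 1: five
times the clustering of degree-matched random graphs at comparable path
length), as block-structured covariance should be. Nine regions qualify as
hubs. Consensus Louvain finds the four planted modules in group B, and the
module covering the planted split shows a higher segregation index in
group B than under the same partition in group A (+0.033); the observed
difference falls outside the permutation null's 95% band (p = 0.033,
uncorrected), detecting the planted modular reorganization.

## Command line

The same pipeline is scriptable via `scnet` with subcommands `simulate`,
`preprocess`, `covnet`, `metrics`, `hubs`, `modules`, `permtest`,
`run-all` (YAML config; writes all artifacts plus a run manifest) and
`report` (plots). All outputs are CSV/JSON; reruns with the same seed are
byte-identical.

```bash
scnet simulate --n-regions 60 --subjects-per-site 50 --seed 1 --out cohort.csv
scnet preprocess cohort.csv --out residuals.csv --qc-report site_bias.csv
scnet covnet residuals.csv --group A --out cov_A.csv
scnet modules cov_A.csv --out partition_A.csv --seed 2
```

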