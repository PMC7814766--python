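# Methods

## The analysis in one paragraph

`scnet` compares the *structural covariance networks* of two diagnostic
groups measured at several acquisition sites. Each subject contributes one
row of regional morphometry (surface area in mm² or mean cortical thickness
in mm over a cortical parcellation, 148 Destrieux regions by default).
Regional values are harmonized across sites by median-absolute-deviation
(MAD) rescaling, adjusted for age, sex and the subject's whole-cortex mean
by linear regression, and the residuals correlated across subjects region
pair by region pair — one Pearson correlation matrix per group. Graph
topology (clustering, characteristic path length, global efficiency,
small-worldness, modularity) is measured on binarized versions of that
matrix over a grid of link densities; eigenvector-centrality hub profiles,
strength assortativity, consensus Louvain modules and the modular
segregation index are computed on top. Group differences are tested against
a center-paired permutation null: group labels are shuffled only within each
site, preserving per-site group counts, and networks are rebuilt per draw.

## Preprocessing

**MAD rescaling.** For each site and region, MAD = median(|x − median(x)|)
across that site's subjects (both groups pooled), and every value is divided
by it — a "ratio of MAD". The raw MAD is used without the 1.4826 Gaussian
consistency constant: the constant is a global factor that cancels in
Pearson correlations. A superset reference table (e.g. all
quality-controlled subjects before matched selection) can supply the MADs.
A zero MAD (constant data) is an error naming the site and region.

**Covariate regression.** Per age stratum and per region, OLS on intercept
+ age + sex (female = 0, male = 1) + subject whole-cortex mean, fitted with
the two diagnostic groups *pooled*. Pooling is what makes residuals
exchangeable under the within-site permutation null; a per-group fit would
build the group difference into the residuals and break the null. Constant
regressors (e.g. sex in a single-sex stratum) are dropped with a warning.
Regression is idempotent on its own residuals.

**Site-bias QC.** For each group and stratum, each site's subject-level
whole-cortex means are compared to the grand mean by a one-sample t-test,
BH-FDR corrected across sites. The check is meaningful on *corrected* data
(rescaled and regressed): on ratio-of-MAD values that have not been
regressed, the location term μ/MAD carries the finite-sample error of the
MAD estimate, which dominates the within-site standard error whenever the
location/spread ratio is large, and every site gets flagged for a reason
that has nothing to do with the confound of interest. On residuals, site
means sit near zero and the test flags exactly the sites whose effects
survived harmonization.

## Network construction

Edges are Pearson correlations of residuals across a group's subjects; R
regions give R(R−1)/2 unique connections (10,878 at R = 148). Binarization
at density d removes the diagonal and all non-positive correlations, ranks
the remaining edges by value, and keeps the top k = round(d · R(R−1)/2) —
the denominator counts *all* pairs, so "density" means percent of possible
connections. Ties at the cutoff break by lexicographic region-index order,
making every graph deterministic. Graphs over a density grid are nested
because the ranking is density-independent. The default analysis grid is
8–35% in 1% steps (28 graphs); the hub grid is 5–35% in 5% steps (7
graphs). Connectedness is tracked: below ~8% density these networks are
often fragmented, and metrics on disconnected graphs are flagged.

## Graph metrics

- **Clustering**: Watts–Strogatz local coefficient (edges among neighbors
  over neighbor pairs); degree-<2 nodes score 0; the network value is the
  unweighted node mean.
- **Characteristic path length L**: mean shortest-path length over
  reachable ordered pairs; disconnected graphs restrict to reachable pairs
  and raise a flag rather than returning infinity.
- **Global efficiency**: 1/L by default (the literal inverse of the
  characteristic path length). The Latora–Marchiori mean of inverse
  distances is available as a config variant; the two differ on any
  non-complete graph (P3: 0.75 vs 5/6).
- **Small-worldness**: Humphries–Gurney σ = (C/C_rand)/(L/L_rand) against
  degree-preserving Maslov–Sneppen references (10·|E| attempted double-edge
  swaps each; 100 references for observed curves). The Monte-Carlo SD of σ
  across references is reported.
- **Eigenvector centrality**: nonnegative Perron eigenvector of the
  adjacency matrix, unit Euclidean norm, from a dense symmetric
  eigensolver. On disconnected graphs the vector is supported on the
  component with the largest leading eigenvalue (warned). Hub profiles
  average centrality over the hub grid and z-score across regions; regions
  with z > 1.5 are hubs. z-scoring makes hub calls invariant to the norm
  convention.
- **Assortativity**: the edge-wise strength-mixing coefficient
  r = [M⁻¹Σjk − (M⁻¹Σ(j+k)/2)²] / [M⁻¹Σ(j²+k²)/2 − (M⁻¹Σ(j+k)/2)²]
  with endpoint strengths j, k taken from the density-averaged eigenvector
  centralities and M the edge count.

All metrics run on dense numpy adjacency (triangle counts via matrix
products, BFS distances via `scipy.sparse.csgraph`, `numpy.linalg.eigh`)
because permutation tests rebuild thousands of networks; brute-force
implementations (neighbor-pair enumeration, Floyd–Warshall, power
iteration, term-by-term formula evaluation) validate them to 1e-9 in the
test suite.

## Modules and segregation

Louvain community detection (resolution 1.0, seeded node order) runs on the
weighted network after removing negative correlations, avoiding any
dependence on a binarization density. Stability comes from consensus
clustering: 150 randomized runs are summarized in a co-assignment matrix D
(D_ij = fraction of runs placing i and j together), entries below τ = 0.5
are zeroed, 100 Louvain runs on the pruned D either all agree
(convergence) or are reduced to a new D, up to 20 rounds (error beyond
that; the procedure almost always converges in one or two).

Newman modularity Q = Σ_m (e_mm − a_m²) is evaluated on the binary graphs
of the density grid (using the group's consensus partition held fixed) and
on weights for diagnostics.

The segregation index of a module is SI = (Z̄w − Z̄b)/Z̄w, where Z̄w and Z̄b
are mean Fisher-z-transformed correlations over within-module pairs and
module-to-rest pairs respectively (all such pairs, unweighted by the other
modules' sizes). Correlations at ±1 are clipped to ±(1 − 1e-7) before the
arctanh. Group contrasts *transfer* the partition: the module definition
comes from one group's consensus partition (the clinical group by default)
and SI is evaluated in both groups on that fixed region set, so the
difference measures connectivity, not partition disagreement.

## Inference

The center-paired permutation shuffles group labels within each site,
preserving per-site counts; concatenated over sites this yields one
randomized labeling, and site composition is identical between
pseudo-groups in every draw. An unrestricted shuffle can concentrate a site
in one group; with sites of different measurement scale and unequal group
composition, that inflates the false-positive rate — the package's
calibration study reproduces this contrast. Permutations act on
post-regression residuals (valid because the regression pools groups), so
only networks are rebuilt per draw; 5,000 draws are the default at
full scale.

Two-tailed p-values use the empirical null with add-one correction,
p = (1 + #{|d₀| ≥ |d_obs|})/(n_perm + 1), so p is never zero; the 95%
percentile interval of the null is retained for plotting. BH-FDR at
q = 0.05 is applied per family: the density grid within each metric within
each age band; the module set for SI contrasts; regions for the regionwise
tests; group × band for the structure–centrality correlations.

For the SI contrast the clinical group's observed partition is held fixed
across permutations: the null says the module (as defined in that group) is
equally segregated in both groups, not that both groups share a partition.

## Synthetic cohorts

The generator emulates exactly the data structure the pipeline assumes:
multiple sites with different measurement scales (optionally with
per-(site, region) lognormal scale jitter, emulating site × region
interactions that pure per-site rescaling must handle), two groups matched
on covariates (group B clones group A's age/sex/FIQ draws per site),
additive age and sex effects, and block-structured correlation from latent
module factors. A designated module can split into two sub-blocks in group
B only, planting a group-specific modular reorganization.

With V = noise_sd²/(1 − ρ_w), loadings a = √(ρ_b V) on a global factor and
b = √((ρ_w − ρ_b) V) on per-module factors give expected correlations
exactly ρ_w within and ρ_b between modules; the implied covariance is
positive semidefinite by construction. The split divides the module loading
into a shared part b₁ = √((ρ_w − s − ρ_b) V) and sub-block parts
b₂ = √(s V), dropping the cross-boundary correlation to ρ_w − s while
leaving within-sub-block correlation at ρ_w (attainable for
s ≤ ρ_w − ρ_b). `planted_truth` returns these expected matrices and the
ground-truth partitions as recovery oracles. The expected matrices describe
the covariate-conditional structure; age/sex effects add a small shared
component on top that covariate regression removes.

What the generator does **not** emulate: spatial autocorrelation on the
cortical sheet, heavy-tailed or skewed morphometry distributions,
site-specific covariate distributions, missing data, motion or QC
artifacts, and any effect of IQ on structure. Passing recovery and
calibration tests therefore demonstrates the machinery is correct under the
model's assumptions, not that real cortical data satisfy them.

One consequence of the global-mean adjustment is worth knowing: regressing
the subject whole-cortex mean (global signal) shifts the correlation scale
— planted within/between correlations of 0.6/0.1 become roughly 0.41/−0.15
in residual space. Block structure and module recovery survive (consensus
ARI ≥ 0.9), but absolute correlation values in residual networks are not
the generator's targets.

## Validation studies and problem sizes

The package validates itself at reduced but statistically meaningful sizes,
chosen as the smallest scales at which each property is identifiable:

- metric oracles: 100 random graphs of ≤ 12 nodes, agreement to 1e-9;
- consensus recovery: 60 regions, 4 planted blocks (ρ_w = 0.6, ρ_b = 0.1),
  150 subjects/group over 2 sites, 20 cohorts — mean ARI ≥ 0.9;
- permutation calibration: 200 null cohorts (40 regions, two sites of scale
  1.0 vs 2.5 with jitter 0.4, group compositions 40/10 vs 10/40) × 1,000
  permutations of the mean-clustering difference at 15% density, no MAD
  rescaling so the confound survives — stratified type-I error in
  [0.02, 0.09] and below the unstratified rate;
- SI power: split strength 0.4 (a calibration choice; no empirical effect
  size exists for it), 20 cohorts × 1,000 permutations — rejection in
  ≥ 80% of cohorts. The planted split expresses itself in the SI contrast
  through two routes, depending on what the clinical group's consensus
  partition resolves. When it keeps the split module whole (the usual
  outcome at this split strength), the dropped cross-boundary correlations
  lower the module's mean within-module Fisher z, which *raises* SI because
  the module-to-rest Fisher z is negative in residual space — a strong,
  reliably detected effect. When it isolates a sub-block exactly, that
  sub-block's own within-z is unchanged and only the handful of
  cross-boundary pairs inside its much larger module-to-rest average carry
  the signal, so the contrast is small and the test usually fails for that
  cohort. Power is therefore bounded by module-resolution behavior, not by
  the permutation machinery;
- small-worldness: Erdős–Rényi (n = 100, p = 0.15) σ within 1 ± 0.15;
  Watts–Strogatz (n = 100, k = 6, 10% rewiring) σ > 1.5; 50 references;
- determinism: the full pipeline twice at one seed (40 regions, 200
  permutations, reduced consensus and reference counts) — byte-identical
  artifacts.

## Randomness and determinism

One top-level seed feeds a `numpy.random.SeedSequence`; per-stage children
(synthetic, metric permutations, assortativity permutations, consensus,
SI permutations, regionwise) are spawned in a fixed order, so enlarging one
stage never perturbs another. All stochastic components (generator,
shuffles, Louvain, rewiring) are seeded from these streams; tables are
written with explicit float formatting, and reruns are byte-identical.

## Known limitations

- Group-level networks only: no subject-level covariance estimates, partial
  correlations, or covariance regularization.
- The literal-inverse efficiency (1/L) and the Latora–Marchiori variant
  disagree on disconnected or sparse graphs; the config records which was
  used.
- The consensus procedure can fail to converge on adversarial weight
  matrices (capped at 20 rounds); real covariance matrices converge in 1–2.
- Permutation tests reuse residuals from the pooled covariate fit rather
  than refitting per draw; if covariate effects truly differ by group, the
  null is approximate.
- The bias QC t-test assumes roughly normal subject means within sites;
  at very small sites (< 3 subjects) it is skipped, not replaced.
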