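"""Synthetic multi-site, two-group morphometry cohorts with planted covariance.

Emulates the statistical structure of a multi-center cortical morphometry
study: several acquisition sites with different measurement scales, two
diagnostic groups matched on covariates, additive age/sex effects, and
block-structured inter-regional correlation generated by latent module
factors. One module can optionally be split into two sub-blocks in group B
only, planting a group-specific modular reorganization for power studies.

Latent-factor construction
--------------------------
Each region r in module m of subject s is generated as::

    raw(s, r)   = baseline + beta_age * age_s + beta_sex * male_s
                  + a * h_s + b * f_{m,s} + eps_{s,r}
    value(s, r) = site_scale(site_s) * raw(s, r)

with h_s a global factor shared by all regions, f_{m,s} independent
per-module factors, and eps iid Normal(0, noise_sd^2), all standard normal
factors. Writing V for the common region variance, the loadings

    V = noise_sd^2 / (1 - rho_within)
    a = sqrt(rho_between * V)
    b = sqrt((rho_within - rho_between) * V)

give exact expected correlations rho_within inside a module and rho_between
across modules (requires 0 <= rho_between <= rho_within < 1, so the loadings
are real and nonnegative and the implied covariance is positive
semidefinite by construction).

For group B inside the split module, the module loading is divided between a
still-shared part and two sub-block factors g::

    b1 = sqrt((rho_within - split_strength - rho_against_between) * V)   # shared
    b2 = sqrt(split_strength * V)                                        # sub-block

where rho_against_between = rho_between, so within-sub-block correlation
stays rho_within while the correlation across the sub-block boundary drops
to rho_within - split_strength (requires split_strength <= rho_within -
rho_between).

Groups are covariate-matched by cloning the age/sex/FIQ draws of each group-A
subject for its group-B counterpart (the matched-pairs design); latent
factors and noise are drawn independently per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate_cohort", "planted_truth"]

METADATA_COLUMNS = ["subject_id", "site", "group", "age", "sex", "fiq"]


def _contiguous_labels(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal module blocks labelled 1..n_modules."""
    labels = np.empty(n_regions, dtype=int)
    for m, idx in enumerate(np.array_split(np.arange(n_regions), n_modules), start=1):
        labels[idx] = m
    return labels


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``per_site_counts`` maps site name -> subjects per group (matched design),
    or site name -> (n_group_A, n_group_B) when ``matched=False``.
    """

    n_regions: int = 148
    module_labels: np.ndarray | None = None  # module id per region, 1-based
    per_site_counts: dict = field(default_factory=lambda: {"site01": 30, "site02": 30})
    rho_within: float = 0.5
    rho_between: float = 0.1
    site_scales: dict | None = None  # site -> positive multiplier; default all 1
    site_scale_jitter: float = 0.0  # lognormal sigma of per-(site,region) scale
    beta_age: float = 0.05
    beta_sex: float = 0.5
    baseline: float = 10.0
    noise_sd: float = 1.0
    age_range: tuple = (7.0, 29.0)
    p_male: float = 0.8
    fiq_mean: float = 105.0
    fiq_sd: float = 12.0
    split_module: int | None = None  # module id split into two halves in group B
    split_strength: float = 0.3  # correlation drop across the sub-block boundary
    matched: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.module_labels is None:
            self.module_labels = _contiguous_labels(self.n_regions, 4)
        self.module_labels = np.asarray(self.module_labels, dtype=int)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if len(self.module_labels) != self.n_regions:
            raise ValueError("module_labels length must equal n_regions")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError(
                "need 0 <= rho_between <= rho_within < 1 "
                f"(got rho_within={self.rho_within}, rho_between={self.rho_between})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for site, cnt in self.per_site_counts.items():
            n_a, n_b = self._counts(site)
            if n_a <= 0 or n_b <= 0:
                raise ValueError(f"non-positive subject count for site {site!r}")
            if self.matched and n_a != n_b:
                raise ValueError(
                    f"matched design requires equal per-site counts (site {site!r})"
                )
        scales = self.resolved_site_scales()
        if any(s <= 0 for s in scales.values()):
            raise ValueError("site_scales must all be positive")
        if self.split_module is not None:
            if self.split_module not in set(self.module_labels.tolist()):
                raise ValueError(f"split_module {self.split_module} not a module label")
            if np.sum(self.module_labels == self.split_module) < 2:
                raise ValueError("split_module must contain >= 2 regions")
            if not (0 <= self.split_strength <= self.rho_within - self.rho_between):
                raise ValueError(
                    "split_strength must lie in [0, rho_within - rho_between]; "
                    "larger drops are unattainable with nonnegative loadings"
                )

    def _counts(self, site) -> tuple:
        cnt = self.per_site_counts[site]
        if np.isscalar(cnt):
            return int(cnt), int(cnt)
        n_a, n_b = cnt
        return int(n_a), int(n_b)

    def resolved_site_scales(self) -> dict:
        if self.site_scales is None:
            return {site: 1.0 for site in self.per_site_counts}
        return dict(self.site_scales)

    # -- derived loadings -------------------------------------------------
    def loadings(self) -> dict:
        """Factor loadings implied by the correlation targets (see module docs)."""
        v = self.noise_sd**2 / (1.0 - self.rho_within)
        a = np.sqrt(self.rho_between * v)
        b = np.sqrt((self.rho_within - self.rho_between) * v)
        out = {"variance": v, "global": a, "module": b}
        if self.split_module is not None:
            out["split_shared"] = np.sqrt(
                max(self.rho_within - self.split_strength - self.rho_between, 0.0) * v
            )
            out["split_sub"] = np.sqrt(self.split_strength * v)
        return out

    def region_names(self) -> list:
        width = max(3, len(str(self.n_regions)))
        return [f"region_{i + 1:0{width}d}" for i in range(self.n_regions)]

    def sub_block_labels(self) -> np.ndarray | None:
        """0 outside the split module; 1/2 for its two halves (first/second)."""
        if self.split_module is None:
            return None
        sub = np.zeros(self.n_regions, dtype=int)
        idx = np.flatnonzero(self.module_labels == self.split_module)
        half = len(idx) // 2
        sub[idx[:half]] = 1
        sub[idx[half:]] = 2
        return sub


def _simulate_group(cfg, rng, group, covariates, site, scale_row):
    """Region-value matrix for one group at one site (subjects x regions)."""
    load = cfg.loadings()
    n = len(covariates["age"])
    modules = np.unique(cfg.module_labels)
    f = rng.normal(size=(n, len(modules)))  # per-module factors
    h = rng.normal(size=n)  # global factor
    eps = rng.normal(scale=cfg.noise_sd, size=(n, cfg.n_regions))

    raw = np.full((n, cfg.n_regions), cfg.baseline)
    raw += np.outer(covariates["age"], np.full(cfg.n_regions, cfg.beta_age))
    raw += np.outer(covariates["male"], np.full(cfg.n_regions, cfg.beta_sex))
    raw += load["global"] * h[:, None]

    sub = cfg.sub_block_labels()
    use_split = group == "B" and cfg.split_module is not None
    g = rng.normal(size=(n, 2)) if use_split else None
    for j, m in enumerate(modules):
        cols = cfg.module_labels == m
        if use_split and m == cfg.split_module:
            raw[:, cols] += load["split_shared"] * f[:, j][:, None]
            for blk in (1, 2):
                blk_cols = cols & (sub == blk)
                raw[:, blk_cols] += load["split_sub"] * g[:, blk - 1][:, None]
        else:
            raw[:, cols] += load["module"] * f[:, j][:, None]
    raw += eps
    return raw * scale_row[None, :]


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a cohort table: metadata columns, then one column per region.

    Output is bit-reproducible for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scales = config.resolved_site_scales()
    rows = []
    subject_counter = 1
    for site in config.per_site_counts:
        n_a, n_b = config._counts(site)
        scale_row = np.full(config.n_regions, scales.get(site, 1.0))
        if config.site_scale_jitter > 0:
            scale_row = scale_row * rng.lognormal(
                mean=0.0, sigma=config.site_scale_jitter, size=config.n_regions
            )

        def draw_covariates(n):
            return {
                "age": rng.uniform(*config.age_range, size=n),
                "male": (rng.random(n) < config.p_male).astype(int),
                "fiq": rng.normal(config.fiq_mean, config.fiq_sd, size=n),
            }

        cov_a = draw_covariates(n_a)
        # matched design: group B reuses group A's covariate draws
        cov_b = cov_a if (config.matched and n_a == n_b) else draw_covariates(n_b)
        for group, cov in (("A", cov_a), ("B", cov_b)):
            values = _simulate_group(config, rng, group, cov, site, scale_row)
            n = len(cov["age"])
            frame = pd.DataFrame(values, columns=config.region_names())
            frame.insert(0, "fiq", cov["fiq"])
            frame.insert(0, "sex", np.where(cov["male"] == 1, "male", "female"))
            frame.insert(0, "age", cov["age"])
            frame.insert(0, "group", group)
            frame.insert(0, "site", site)
            frame.insert(
                0,
                "subject_id",
                [f"sub-{subject_counter + i:04d}" for i in range(n)],
            )
            subject_counter += n
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def planted_truth(config: SyntheticConfig):
    """Ground-truth partitions and analytic expected correlation matrices.

    Returns ``(partitions, expected)`` where each is a dict keyed by group
    ("A", "B"). Group B's partition counts the split sub-blocks as separate
    modules; expected matrices follow from the factor loadings.
    """
    config.validate()
    labels_a = config.module_labels.copy()
    labels_b = labels_a.copy()
    if config.split_module is not None:
        sub = config.sub_block_labels()
        new_label = labels_a.max() + 1
        labels_b = labels_a.copy()
        labels_b[sub == 2] = new_label

    def expected_matrix(split: bool) -> np.ndarray:
        same_module = labels_a[:, None] == labels_a[None, :]
        mat = np.where(same_module, config.rho_within, config.rho_between)
        if split and config.split_module is not None:
            sub = config.sub_block_labels()
            in_split = labels_a == config.split_module
            cross = (
                in_split[:, None]
                & in_split[None, :]
                & (sub[:, None] != sub[None, :])
            )
            mat = np.where(cross, config.rho_within - config.split_strength, mat)
        np.fill_diagonal(mat, 1.0)
        return mat

    partitions = {"A": labels_a, "B": labels_b}
    expected = {"A": expected_matrix(False), "B": expected_matrix(True)}
    return partitions, expected
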