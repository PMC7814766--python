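"""Center-paired permutation inference for group network contrasts.

Group labels are permuted *within each acquisition site*, preserving every
site's per-group counts; the per-site shuffles are concatenated into one
randomized labeling. This keeps site composition identical between the
pseudo-groups in every draw, so a site whose measurement scale differs
cannot masquerade as a group effect — the failure mode of an unrestricted
shuffle, which can reassign most of one site to one group.

For each permutation the statistic (a scalar, or a vector over densities or
regions) is recomputed from the residual tables of the two pseudo-groups;
two-tailed p-values come from the empirical null with add-one correction::

    p = (1 + #{|d_null| >= |d_obs|}) / (n_perm + 1)

and the 95% percentile interval of the null is retained for plotting.
Families of p-values are controlled by Benjamini–Hochberg FDR.

Permutations operate on post-regression residuals: the covariate fit is
pooled across diagnostic groups, so residuals are exchangeable under the
null and only the networks — not the regressions — are rebuilt per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import region_columns

__all__ = [
    "TestResult",
    "center_paired_shuffle",
    "unstratified_shuffle",
    "permutation_test",
    "fdr_correct",
    "regionwise_group_test",
    "correlate_structure_centrality",
]


@dataclass
class TestResult:
    """Observed group difference with its permutation null."""

    statistic: str
    observed: np.ndarray  # shape (k,) — k densities, regions or modules
    null: np.ndarray  # shape (n_perm, k)
    p: np.ndarray  # shape (k,)
    ci_low: np.ndarray  # 2.5th percentile of the null, per element
    ci_high: np.ndarray  # 97.5th percentile of the null, per element
    family: list = field(default_factory=list)  # element labels
    q: np.ndarray | None = None
    n_failed: int = 0

    @property
    def n_perm(self) -> int:
        return self.null.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {
            "element": self.family if self.family else list(range(len(self.observed))),
            "observed": self.observed,
            "null_ci_low": self.ci_low,
            "null_ci_high": self.ci_high,
            "p": self.p,
        }
        if self.q is not None:
            data["q"] = self.q
        frame = pd.DataFrame(data)
        frame.insert(0, "statistic", self.statistic)
        return frame


def center_paired_shuffle(group_labels, site_labels, seed=None) -> np.ndarray:
    """Permute group labels within each site, preserving per-site counts.

    Raises if any site holds subjects of only one group (nothing to pair).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = np.asarray(group_labels)
    sites = np.asarray(site_labels)
    out = groups.copy()
    for site in np.unique(sites):
        idx = np.flatnonzero(sites == site)
        if len(np.unique(groups[idx])) < 2:
            raise ValueError(
                f"site {site!r} has all subjects in one group; cannot pair"
            )
        out[idx] = groups[idx][rng.permutation(len(idx))]
    return out


def unstratified_shuffle(group_labels, site_labels=None, seed=None) -> np.ndarray:
    """Plain shuffle of group labels ignoring sites (comparison baseline)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = np.asarray(group_labels)
    return groups[rng.permutation(len(groups))]


def permutation_test(
    residuals: pd.DataFrame,
    statistic,
    n_perm: int = 5000,
    seed=None,
    stratified: bool = True,
    statistic_name: str = "",
    max_failure_rate: float = 0.01,
) -> TestResult:
    """Permutation test of a group-difference statistic on residual tables.

    ``statistic(values_a, values_b)`` maps the two groups' residual value
    matrices (subjects x regions) to a real number or a vector (e.g. one
    value per density). Group roles follow sorted group labels (first label
    -> first argument). Draws on which the statistic fails are recorded;
    more than ``max_failure_rate`` failures aborts with diagnostics.
    """
    rng = np.random.default_rng(seed)
    regions = region_columns(residuals)
    values = residuals[regions].to_numpy(float)
    groups = residuals["group"].to_numpy()
    sites = residuals["site"].to_numpy()
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(names)}")

    def evaluate(labels):
        return np.atleast_1d(
            np.asarray(statistic(values[labels == names[0]], values[labels == names[1]]), float)
        )

    observed = evaluate(groups)
    shuffle = center_paired_shuffle if stratified else unstratified_shuffle
    null = np.full((n_perm, len(observed)), np.nan)
    failures = []
    for i in range(n_perm):
        permuted = shuffle(groups, sites, seed=rng)
        try:
            null[i] = evaluate(permuted)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append((i, str(exc)))
    if len(failures) > max_failure_rate * n_perm:
        raise RuntimeError(
            f"statistic failed on {len(failures)}/{n_perm} permutations; "
            f"first failure: {failures[0][1]}"
        )
    ok = ~np.isnan(null).any(axis=1)
    null_ok = null[ok]
    exceed = (np.abs(null_ok) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (null_ok.shape[0] + 1.0)
    return TestResult(
        statistic=statistic_name or getattr(statistic, "__name__", "statistic"),
        observed=observed,
        null=null_ok,
        p=p,
        ci_low=np.percentile(null_ok, 2.5, axis=0),
        ci_high=np.percentile(null_ok, 97.5, axis=0),
        n_failed=len(failures),
    )


def fdr_correct(p_values, q_level: float = 0.05):
    """Benjamini–Hochberg q-values and rejection flags for one family."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def regionwise_group_test(
    table: pd.DataFrame,
    n_perm: int = 5000,
    seed=None,
    q_level: float = 0.05,
) -> TestResult:
    """Per-region group difference in means under the center-paired null.

    Tests every region's mean difference between the two groups with the
    same within-site permutation scheme as the network contrasts, then
    applies BH-FDR across regions.
    """
    counts = table.groupby("group").size()
    if len(counts) != 2 or counts.min() < 3:
        raise ValueError("both groups need >= 3 subjects")

    def mean_difference(values_a, values_b):
        return values_a.mean(axis=0) - values_b.mean(axis=0)

    result = permutation_test(
        table, mean_difference, n_perm=n_perm, seed=seed,
        statistic_name="regionwise_mean_difference",
    )
    result.family = region_columns(table)
    result.q, _ = fdr_correct(result.p, q_level)
    return result


def correlate_structure_centrality(residuals: pd.DataFrame, profile, group: str | None = None):
    """Pearson r between group-mean regional residuals and centrality z-scores.

    Each region's residuals are averaged across the group's subjects and
    correlated, across regions, with the z-scored density-averaged
    eigenvector centrality. Returns ``(r, p)`` from the standard correlation
    test; FDR across the group x age-band family is the caller's concern.
    """
    group = group if group is not None else profile.group
    rows = residuals[residuals["group"] == group] if group else residuals
    regions = region_columns(residuals)
    if len(regions) != len(profile.z_scores):
        raise ValueError("region counts of residuals and hub profile differ")
    mean_structure = rows[regions].to_numpy(float).mean(axis=0)
    if np.std(mean_structure) == 0 or np.std(profile.z_scores) == 0:
        raise ValueError("zero-variance vector; correlation undefined")
    r, p = stats.pearsonr(mean_structure, profile.z_scores)
    return float(r), float(p)
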