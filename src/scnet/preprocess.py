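"""Site harmonization and covariate regression for multi-site morphometry.

Two preprocessing steps precede network construction:

1. **MAD rescaling** — each region's values are divided by that region's
   median absolute deviation computed across all subjects of the same
   acquisition site, turning raw measures into dimensionless "ratios of MAD"
   and equalizing measurement scales across sites. The raw MAD
   (``median(|x - median(x)|)``, no Gaussian consistency constant) is used:
   the output is a ratio, and a constant factor would cancel in the
   correlations downstream anyway.

2. **Covariate regression** — per region, ordinary least squares of the
   rescaled measure on intercept + age + sex + the subject's whole-cortex
   mean of the same measure, fitted on all subjects of the given stratum
   pooled across diagnostic groups (so residuals are exchangeable under the
   within-site permutation null). The residuals are the basis of all
   downstream correlations.

A per-site bias check (one-sample t-test of each site's subject-level
whole-cortex means against the grand mean, BH-FDR across sites) quantifies
how well harmonization removed site effects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import METADATA_COLUMNS

__all__ = [
    "region_columns",
    "mad_rescale",
    "regress_covariates",
    "site_bias_check",
]

logger = logging.getLogger(__name__)

#: numeric code for sex in the regression design (reference level: female=0)
SEX_CODES = {"female": 0.0, "male": 1.0}


def region_columns(table: pd.DataFrame) -> list:
    """Names of the region-value columns (everything except metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def _mad(values: np.ndarray, axis=0) -> np.ndarray:
    return np.median(np.abs(values - np.median(values, axis=axis, keepdims=True)), axis=axis)


def mad_rescale(table: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Divide each region by its per-site MAD across that site's subjects.

    The MAD is computed per (site, region) over all of the site's subjects,
    both diagnostic groups jointly. If ``reference`` is given (a superset
    cohort table, e.g. all quality-controlled subjects before matched
    selection), MADs are computed on it instead and applied to ``table``.

    Raises ``ValueError`` naming the site and region if any per-(site,
    region) MAD is zero (degenerate constant data), and if any site has
    fewer than two subjects.
    """
    regions = region_columns(table)
    source = table if reference is None else reference
    out = table.copy()
    for site, site_rows in table.groupby("site", sort=False):
        src = source[source["site"] == site]
        if len(src) < 2:
            raise ValueError(f"site {site!r} has fewer than 2 subjects; cannot compute MAD")
        mads = _mad(src[regions].to_numpy(float))
        if np.any(mads == 0):
            bad = regions[int(np.argmax(mads == 0))]
            raise ValueError(
                f"MAD is zero for site {site!r}, region {bad!r} (constant values)"
            )
        out.loc[site_rows.index, regions] = site_rows[regions].to_numpy(float) / mads
    return out


def _design_matrix(table: pd.DataFrame, global_mean: np.ndarray):
    """Intercept + age + sex + subject global mean; drops constant regressors."""
    sex = table["sex"].map(SEX_CODES)
    if sex.isna().any():
        raise ValueError("sex column must contain only 'male'/'female'")
    columns = {
        "intercept": np.ones(len(table)),
        "age": table["age"].to_numpy(float),
        "sex": sex.to_numpy(float),
        "global_mean": global_mean,
    }
    kept, names = [], []
    for name, col in columns.items():
        if name != "intercept" and np.ptp(col) == 0:
            logger.warning("dropping constant regressor %r (collinear with intercept)", name)
            continue
        kept.append(col)
        names.append(name)
    return np.column_stack(kept), names


def regress_covariates(table: pd.DataFrame, stratum: str | None = None) -> pd.DataFrame:
    """OLS residuals of each region on intercept + age + sex + global mean.

    The regression is fitted on all subjects of ``table`` (one age stratum),
    pooled across diagnostic groups; ``stratum`` is a label recorded in log
    output only. Returns a table with identical metadata and region values
    replaced by residuals.
    """
    regions = region_columns(table)
    y = table[regions].to_numpy(float)
    global_mean = y.mean(axis=1)
    x, names = _design_matrix(table, global_mean)
    if len(table) < x.shape[1] + 2:
        raise ValueError(
            f"stratum {stratum or '<unnamed>'!r} has {len(table)} subjects; "
            f"need at least {x.shape[1] + 2} for {x.shape[1]} regressors"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    residuals = y - x @ beta
    logger.info(
        "regressed %d regions on %s in stratum %s (n=%d)",
        len(regions), names, stratum or "<unnamed>", len(table),
    )
    out = table.copy()
    out[regions] = residuals
    return out


def site_bias_check(table: pd.DataFrame, min_subjects: int = 3) -> pd.DataFrame:
    """Per-site one-sample t-test of whole-cortex means against the grand mean.

    For each diagnostic group in ``table`` (one stratum), each site's
    subject-level whole-cortex mean values are tested against the grand mean
    over all sites; BH-FDR is applied per group across its family of sites.
    Sites with fewer than ``min_subjects`` subjects are flagged and skipped.

    Returns a tidy frame: group, site, n, t, p, q, flagged.
    """
    if table["site"].nunique() < 2:
        raise ValueError("site bias check needs at least 2 sites")
    regions = region_columns(table)
    records = []
    for group, group_rows in table.groupby("group", sort=False):
        subject_means = group_rows[regions].to_numpy(float).mean(axis=1)
        grand_mean = subject_means.mean()
        sites = group_rows["site"].to_numpy()
        family = []
        for site in dict.fromkeys(sites):  # preserve order
            vals = subject_means[sites == site]
            rec = {"group": group, "site": site, "n": len(vals)}
            if len(vals) < min_subjects:
                rec.update(t=np.nan, p=np.nan, skipped=True)
            else:
                t, p = stats.ttest_1samp(vals, grand_mean)
                rec.update(t=t, p=p, skipped=False)
            family.append(rec)
        tested = [r for r in family if not r["skipped"]]
        if tested:
            qs = multipletests([r["p"] for r in tested], method="fdr_bh")[1]
            for rec, q in zip(tested, qs):
                rec["q"] = q
        for rec in family:
            rec.setdefault("q", np.nan)
        records.extend(family)
    frame = pd.DataFrame.from_records(records)
    frame["flagged"] = frame["q"] < 0.05
    return frame
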