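"""Per-site metric tables and rank correlations along development gradients.

Each surveyed site gets one :func:`metrics_report` under a shared
configuration; systemic statistics are joined to the site's development
index and natural-log population density, and Spearman rank correlations
describe how each statistic moves along the two gradients.  Missing
covariates (population density is unavailable for small-island sites) are
carried as NaN and handled by pairwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .categories import DEFAULT_CATEGORIES, CategorySet
from .metrics import DEFAULT_PRUNE_THRESHOLD, metrics_report
from .survey_io import CommunityMetadata, HouseholdRecord

SYSTEMIC_METRICS = (
    "density_binary",
    "density_weighted",
    "centralization_binary",
    "centralization_weighted",
    "mean_occupations",
)
COVARIATES = ("development_index", "ln_population_density")


@dataclass
class GradientTable:
    """Per-site systemic metrics + covariates (wide) and per-node degrees (long)."""

    systemic: pd.DataFrame
    per_node: pd.DataFrame


def site_metrics_table(
    records: Sequence[HouseholdRecord],
    metadata: Sequence[CommunityMetadata],
    categories: CategorySet = DEFAULT_CATEGORIES,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
    denominator_mode: str = "origin_total",
    node_set: str = "fixed",
) -> GradientTable:
    """Run the metrics pipeline per site and join covariates.

    Every site appearing in ``records`` must appear in ``metadata``; the
    log transform of population density is applied here, exactly once.
    """
    meta_by_site = {m.site_id: m for m in metadata}
    site_order: list[str] = []
    for rec in records:
        if rec.site_id not in site_order:
            site_order.append(rec.site_id)
    missing = [s for s in site_order if s not in meta_by_site]
    if missing:
        raise ValueError(f"sites in survey but not in covariates: {missing}")

    wide_rows = []
    long_rows = []
    for site in site_order:
        site_records = [r for r in records if r.site_id == site]
        report = metrics_report(
            site_records,
            categories,
            prune_threshold=prune_threshold,
            denominator_mode=denominator_mode,
            node_set=node_set,
            provenance=f"site {site}",
        )
        meta = meta_by_site[site]
        pop = meta.population_density
        row = {"site_id": site, **report.systemic()}
        row["development_index"] = meta.development_index
        row["ln_population_density"] = (
            math.log(pop) if pop is not None and pop > 0 else math.nan
        )
        row["n_hh"] = report.n_hh
        wide_rows.append(row)
        for cat in categories:
            for stat, value in (
                ("weighted_in", report.weighted_in[cat]),
                ("weighted_out", report.weighted_out[cat]),
                ("binary_in", report.binary_in[cat]),
                ("binary_out", report.binary_out[cat]),
            ):
                long_rows.append(
                    {
                        "site_id": site,
                        "category": cat,
                        "statistic": stat,
                        "value": value,
                    }
                )
    return GradientTable(
        systemic=pd.DataFrame(wide_rows),
        per_node=pd.DataFrame(long_rows),
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "approx",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Ties get average ranks.  ``method='approx'`` uses the large-sample t
    approximation for the p-value; ``method='permutation'`` estimates it by
    seeded random permutation (useful below ~10 complete pairs, where the t
    approximation is rough).  Requires at least 3 complete pairs.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return math.nan, math.nan
    if method == "approx":
        res = stats.spearmanr(xa, ya)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        rho = float(stats.spearmanr(xa, ya).statistic)
        perm = stats.permutation_test(
            (xa, ya),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=n_resamples,
            rng=np.random.default_rng(seed),
        )
        return rho, float(perm.pvalue)
    raise ValueError(f"unknown method {method!r}")


def correlate_metrics(
    table: GradientTable | pd.DataFrame,
    metrics: Sequence[str] = SYSTEMIC_METRICS,
    covariates: Sequence[str] = COVARIATES,
    method: str = "approx",
) -> pd.DataFrame:
    """Correlate every systemic metric with every covariate.

    Returns one row per (metric, covariate) with ``rho``, ``p``, ``n_used``
    and two significance flags, ``sig_05`` (p < 0.05) and ``sig_10``
    (p < 0.10), kept separate so exploratory borderline relationships stay
    distinguishable.  A constant covariate (or metric) yields NaN.
    """
    df = table.systemic if isinstance(table, GradientTable) else table
    if df.empty:
        raise ValueError("empty gradient table")
    rows = []
    for metric in metrics:
        for cov in covariates:
            x = df[metric].to_numpy(dtype=float)
            y = df[cov].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            n_used = int(keep.sum())
            if n_used < 3:
                rho, p = math.nan, math.nan
            else:
                rho, p = spearman(x, y, method=method)
            rows.append(
                {
                    "metric": metric,
                    "covariate": cov,
                    "rho": rho,
                    "p": p,
                    "n_used": n_used,
                    "sig_05": bool(p < 0.05) if not math.isnan(p) else False,
                    "sig_10": bool(p < 0.10) if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)
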