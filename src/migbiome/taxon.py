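"""Genus-group ratios, named-cluster abundances, and the association report.

The Bacteroides/Prevotella (B/P) log-ratio is a westernization index:
log10 of the summed Bacteroides + Phocaeicola counts (Phocaeicola was
formerly classified as Bacteroides) over the summed Prevotella counts, with
a pseudocount on both sums to keep the ratio finite at zero.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import bh_adjust, mann_whitney_u, spearman_rho

__all__ = [
    "bp_ratio",
    "cluster_abundance",
    "association_report",
    "significance_tier",
    "BACTEROIDES_GROUP",
    "PREVOTELLA_GROUP",
]

BACTEROIDES_GROUP = ("Bacteroides", "Phocaeicola")
PREVOTELLA_GROUP = ("Prevotella",)


def bp_ratio(table: pd.DataFrame, taxonomy: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-sample log10 Bacteroides(+Phocaeicola) / Prevotella ratio."""
    genus = taxonomy.loc[table.columns, "genus"]
    b_cols = table.columns[genus.isin(BACTEROIDES_GROUP)]
    p_cols = table.columns[genus.isin(PREVOTELLA_GROUP)]
    if len(b_cols) == 0 and len(p_cols) == 0:
        raise ValueError("taxonomy contains no Bacteroides/Phocaeicola or Prevotella ASVs")
    b = table[b_cols].sum(axis=1).astype(float)
    p = table[p_cols].sum(axis=1).astype(float)
    return pd.DataFrame({
        "bacteroides_sum": b,
        "prevotella_sum": p,
        "log10_bp_ratio": np.log10((b + pseudocount) / (p + pseudocount)),
    })


def cluster_abundance(table: pd.DataFrame, core_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-sample percentage of total counts falling in each named core set."""
    totals = table.sum(axis=1).astype(float)
    out = {}
    for name, asvs in core_sets.items():
        cols = [a for a in asvs if a in table.columns]
        if not cols:
            raise ValueError(f"core set {name!r} is empty or absent from the table")
        out[name] = 100.0 * table[cols].sum(axis=1) / totals
    return pd.DataFrame(out, index=table.index)


def significance_tier(p: float) -> str:
    """Report stars: (.) <= 0.1, * <= 0.05, ** <= 0.01, *** <= 0.001."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "(.)"
    return ""


def association_report(
    cluster_ab: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = ("bmi", "triglycerides"),
) -> pd.DataFrame:
    """Per (ethnicity, cluster): generation means + covariate/diversity correlations.

    Mirrors the layout of cohort summary tables: mean abundance per
    generation with a Mann-Whitney contrast (BH-adjusted per cluster family)
    and Spearman rho against each covariate and the Shannon index, annotated
    with significance tiers. Missing or constant covariates yield missing
    cells, never failure.
    """
    meta = meta.loc[cluster_ab.index]
    rows = []
    for cluster in cluster_ab.columns:
        fam = []
        for eth, sub in meta.groupby("ethnicity", sort=True):
            vals = cluster_ab.loc[sub.index, cluster]
            g1 = vals[sub["generation"] == 1]
            g2 = vals[sub["generation"] == 2]
            rec = {"ethnicity": eth, "cluster": cluster,
                   "mean_gen1": float(g1.mean()), "mean_gen2": float(g2.mean())}
            if len(g1) and len(g2):
                rec["p_generation"] = mann_whitney_u(g1, g2).p_value
            else:
                rec["p_generation"] = np.nan
            targets = {c: sub[c] if c in sub.columns else None for c in covariates}
            if alpha is not None:
                targets["shannon"] = alpha.loc[sub.index, "shannon"]
            for cname, cvals in targets.items():
                if cvals is None:
                    rec[f"rho_{cname}"], rec[f"p_{cname}"] = np.nan, np.nan
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = spearman_rho(vals.to_numpy(), cvals.to_numpy(dtype=float))
                rec[f"rho_{cname}"], rec[f"p_{cname}"] = rho, p
                rec[f"tier_{cname}"] = significance_tier(p)
            fam.append(rec)
        ps = np.array([r["p_generation"] for r in fam])
        ok = ~np.isnan(ps)
        if ok.any():
            adj = bh_adjust(ps[ok])
            it = iter(adj)
            for r, good in zip(fam, ok):
                r["p_generation_adj"] = float(next(it)) if good else np.nan
                r["tier_generation"] = significance_tier(r["p_generation_adj"])
        rows.extend(fam)
    return pd.DataFrame(rows)
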