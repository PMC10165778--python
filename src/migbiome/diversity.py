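"""Rarefaction and alpha-diversity.

Shannon entropy is computed in natural log (nats); the "Shannon effective
number" is exp(H). Faith's phylogenetic diversity is the total branch length
of the subtree spanning the observed tips, including the path to the root by
default (the convention of the common R tooling); pass ``include_root=False``
for the unrooted variant.

Rarefaction subsamples each sample's counts without replacement (multivariate
hypergeometric) to a fixed depth. Each sample gets its own deterministic
random substream derived from the global seed and the sample id, so dropping
or reordering samples never changes another sample's draw.
"""
from __future__ import annotations

import logging
import warnings
import zlib

import numpy as np
import pandas as pd

from .stats import bh_adjust, mann_whitney_u
from .exceptions import ReconciliationError

__all__ = [
    "rarefy",
    "shannon",
    "richness",
    "faith_pd",
    "alpha_diversity_table",
    "alpha_contrast",
    "RAREFACTION_DEPTH",
]

logger = logging.getLogger(__name__)

#: default even-sampling depth (reads per sample)
RAREFACTION_DEPTH = 15221


def rarefy(table: pd.DataFrame, depth: int = RAREFACTION_DEPTH, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.index[~keep])
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:10])
    if not keep.any():
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    out = np.empty((int(keep.sum()), table.shape[1]), dtype=np.int64)
    kept_ids = table.index[keep]
    values = table.loc[kept_ids].to_numpy()
    for i, sid in enumerate(kept_ids):
        counts = values[i]
        if counts.sum() == depth:
            out[i] = counts
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(str(sid).encode())])
        )
        out[i] = rng.multivariate_hypergeometric(counts, depth)
    return pd.DataFrame(out, index=kept_ids, columns=table.columns)


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over nonzero proportions (nats)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no Shannon entropy")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Number of features with a nonzero count."""
    c = np.asarray(counts)
    if c.sum() <= 0:
        raise ValueError("all-zero sample has no richness")
    return int((c > 0).sum())


def faith_pd(counts, asv_ids, tree, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of the observed ASV set.

    Sum of branch lengths on the union of root-to-tip paths over observed
    tips. With ``include_root=False`` branches above the observed tips' most
    recent common ancestor are excluded.
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("all-zero sample has no phylogenetic diversity")
    observed = {a for a, x in zip(asv_ids, c) if x > 0}
    tip_names = {t.name for t in tree.tips()}
    missing = observed - tip_names
    if missing:
        raise ReconciliationError(f"ASVs absent from tree: {sorted(missing)[:5]}")
    if include_root:
        total = 0.0
        for node in tree.postorder(include_self=False):
            node._pd_obs = (
                (node.name in observed)
                if node.is_tip()
                else any(ch._pd_obs for ch in node.children)
            )
            if node._pd_obs and node.length:
                total += node.length
        for node in tree.postorder(include_self=False):
            del node._pd_obs
        return float(total)
    sub = tree.shear(sorted(observed)) if len(observed) > 1 else None
    if sub is None:
        return 0.0
    return float(sum(n.length or 0.0 for n in sub.postorder(include_self=False)))


def alpha_diversity_table(table: pd.DataFrame, tree=None) -> pd.DataFrame:
    """Per-sample Shannon, effective Shannon, richness, and Faith's PD."""
    recs = {}
    for sid, row in table.iterrows():
        h = shannon(row.to_numpy())
        rec = {
            "shannon": h,
            "shannon_effective": float(np.exp(h)),
            "richness": richness(row.to_numpy()),
        }
        if tree is not None:
            rec["faith_pd"] = faith_pd(row.to_numpy(), table.columns, tree)
        recs[sid] = rec
    out = pd.DataFrame.from_dict(recs, orient="index")
    out.index.name = "sample_id"
    return out


def alpha_contrast(alpha: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Generation 1 vs 2 contrast of each alpha metric within each ethnicity.

    Mann-Whitney U per (ethnicity, metric); BH adjustment within each metric
    family across ethnicities; medians per generation reported.
    """
    meta = meta.loc[alpha.index]
    rows = []
    for metric in alpha.columns:
        fam = []
        for eth, sub in meta.groupby("ethnicity", sort=True):
            gens = set(sub["generation"])
            if not {1, 2} <= gens:
                warnings.warn(f"{eth}: only one generation present, skipped", stacklevel=2)
                continue
            g1 = alpha.loc[sub.index[sub["generation"] == 1], metric]
            g2 = alpha.loc[sub.index[sub["generation"] == 2], metric]
            res = mann_whitney_u(g1, g2)
            fam.append({
                "ethnicity": eth,
                "metric": metric,
                "median_gen1": float(g1.median()),
                "median_gen2": float(g2.median()),
                "n1": res.n1,
                "n2": res.n2,
                "p": res.p_value,
            })
        if fam:
            adj = bh_adjust([r["p"] for r in fam])
            for r, q in zip(fam, adj):
                r["p_adj"] = float(q)
            rows.extend(fam)
    return pd.DataFrame(rows)
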