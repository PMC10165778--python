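"""Phylogenetic agglomeration of ASVs into genus-like clusters.

An internal node is "agglomerable" when its maximum distance to any
descendant tip is at most the height threshold (default 0.10, chosen to sit
at a genus-like resolution). Clusters are the tip sets below the *maximal*
agglomerable nodes, so the result is a partition. Node height rather than
cophenetic (tip-to-tip) distance is used — it is well defined on
non-ultrametric trees; note this admits cophenetic distances up to twice the
threshold. Pass ``height`` explicitly to use another convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ReconciliationError, SchemaError

__all__ = ["AgglomerationMap", "agglomerate", "aggregate_by_genus"]

AGGLOMERATION_HEIGHT = 0.10


@dataclass
class AgglomerationMap:
    asv_to_cluster: dict[str, str]
    members: dict[str, list[str]]
    representative: dict[str, str]   # cluster -> most abundant member


def agglomerate(
    table: pd.DataFrame, tree, height: float = AGGLOMERATION_HEIGHT
) -> tuple[pd.DataFrame, AgglomerationMap]:
    """Collapse ASV columns into phylogenetic clusters at a tree height.

    Cluster counts are sums over member columns, so per-sample totals are
    conserved exactly. Cluster ids are the representative (most abundant)
    member's id so downstream tables stay interpretable.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    if len(tree.children) == 0:
        raise ValueError("tree has no structure (single node)")
    tips = {t.name for t in tree.tips()}
    missing = set(map(str, table.columns)) - tips
    if missing:
        raise ReconciliationError(f"table ASVs absent from tree: {sorted(missing)[:5]}")

    # max distance from each node down to any descendant tip
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._tipdist = 0.0
        else:
            node._tipdist = max(ch._tipdist + (ch.length or 0.0) for ch in node.children)

    clusters: list[list[str]] = []

    def collect(node):
        if node._tipdist <= height:
            clusters.append([t.name for t in node.tips()] if not node.is_tip() else [node.name])
            return
        for ch in node.children:
            collect(ch)

    collect(tree)
    for node in tree.postorder(include_self=True):
        del node._tipdist

    mean_ab = table.mean(axis=0)
    asv_to_cluster, members, representative = {}, {}, {}
    cluster_cols = {}
    for tip_set in clusters:
        tip_set = [t for t in tip_set if t in table.columns]
        if not tip_set:
            continue
        rep = max(tip_set, key=lambda a: (mean_ab[a], a))
        cid = rep
        members[cid] = sorted(tip_set)
        representative[cid] = rep
        for a in tip_set:
            asv_to_cluster[a] = cid
        cluster_cols[cid] = table[tip_set].sum(axis=1)
    out = pd.DataFrame(cluster_cols, index=table.index)
    return out, AgglomerationMap(asv_to_cluster, members, representative)


def aggregate_by_genus(table: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Sum ASV counts per genus label; column totals are conserved."""
    missing = set(map(str, table.columns)) - set(map(str, taxonomy.index))
    if missing:
        raise SchemaError(f"taxonomy rows missing for ASVs: {sorted(missing)[:5]}")
    genus = taxonomy.loc[table.columns, "genus"].replace("", "unclassified")
    return table.T.groupby(genus.values).sum().T
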