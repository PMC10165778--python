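"""Consensus trophic-network (correlation-block) detection across strata.

Per stratum (ethnicity x generation), the Spearman correlation matrix of the
top-N most abundant ASVs is hierarchically clustered (Euclidean distance
between correlation rows); the blocks of mutually positively correlated ASVs
are the candidate trophic networks. Blocks are labeled across strata by
anchor genera (e.g. Bacteroides/Blautia/Bifidobacterium for BBB,
Christensenellaceae/Methanobrevibacter/Oscillibacter for CMO, and the two
Prevotella networks split by species), and an ASV is a *core* member of a
named cluster when it falls in that cluster's block in at least
``min_support`` of the strata (default 6 of 10).

The number of blocks per heatmap is chosen by maximal mean silhouette width
over a k-range — an objective surrogate for reading blocks off a heatmap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

__all__ = [
    "CorrelationMatrix",
    "BlockPartition",
    "ConsensusClusterSet",
    "stratum_correlation",
    "extract_blocks",
    "match_blocks",
    "consensus_core",
    "run_trophic_consensus",
    "CLUSTER_NAMES",
]

CLUSTER_NAMES = ("BBB", "P_copri", "P_stercorea", "CMO")
MIN_SUPPORT = 6


@dataclass
class CorrelationMatrix:
    stratum: str
    matrix: pd.DataFrame      # symmetric Spearman rho, unit diagonal

    @property
    def asv_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class BlockPartition:
    stratum: str
    assignment: dict[str, int]          # ASV -> block id
    k: int
    merge_heights: np.ndarray           # linkage merge distances, ascending
    mean_within_rho: dict[int, float]
    correlation: pd.DataFrame           # kept for anchor tie-breaking
    labels: dict[str, int] = field(default_factory=dict)  # cluster name -> block id

    def members(self, block: int) -> list[str]:
        return sorted(a for a, b in self.assignment.items() if b == block)


@dataclass
class ConsensusClusterSet:
    core: dict[str, list[str]]               # cluster name -> core ASV ids
    support: dict[str, dict[str, int]]       # cluster name -> ASV -> stratum count
    matched_block: dict[str, dict[str, int | None]]  # name -> stratum -> block id
    min_support: int
    n_strata: int


def stratum_key(ethnicity: str, generation: int) -> str:
    return f"{ethnicity}|g{generation}"


def stratum_correlation(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    ethnicity: str,
    generation: int,
    top_n: int = 200,
) -> CorrelationMatrix:
    """Spearman correlation matrix of the stratum's top-N abundant ASVs.

    ASVs are ranked by mean relative abundance within the stratum; the
    ranking (and hence the matrix) is deterministic, ties broken by ASV id.
    """
    sel = meta.index[(meta["ethnicity"] == ethnicity) & (meta["generation"] == generation)]
    sel = [s for s in sel if s in table.index]
    if len(sel) < 3:
        raise ValueError(f"stratum {ethnicity}/gen{generation} has fewer than 3 samples")
    sub = table.loc[sel]
    rel = sub.div(sub.sum(axis=1), axis=0)
    mean_ab = rel.mean(axis=0)
    top = mean_ab.sort_values(ascending=False, kind="mergesort").index[: min(top_n, table.shape[1])]
    top = sorted(top, key=lambda a: (-mean_ab[a], a))
    x = rel[top].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(x).statistic
    rho = np.atleast_2d(rho)
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    m = pd.DataFrame(rho, index=top, columns=top)
    return CorrelationMatrix(stratum_key(ethnicity, generation), m)


def extract_blocks(
    corr: CorrelationMatrix,
    linkage: str = "complete",
    k_range: tuple[int, int] = (3, 15),
) -> BlockPartition:
    """Cut the correlation-row dendrogram into blocks.

    Agglomerative clustering (Euclidean distance between rho rows, linkage
    configurable among complete/average/ward); k chosen in ``k_range`` by
    maximal mean silhouette width on the same distances.
    """
    m = corr.matrix
    ids = list(m.index)
    n = len(ids)
    dvec = pdist(m.to_numpy(), metric="euclidean")
    if np.allclose(dvec, 0):
        warnings.warn("all correlation rows identical: single block", stacklevel=2)
        return BlockPartition(corr.stratum, {a: 1 for a in ids}, 1,
                              np.zeros(n - 1), {1: 1.0}, m)
    z = scipy_linkage(dvec, method=linkage)
    dsq = squareform(dvec)
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in range(max(2, k_range[0]), min(k_range[1], n - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(dsq, labels, metric="precomputed")
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    assignment = {a: int(b) for a, b in zip(ids, best_labels)}
    rho_np = m.to_numpy()
    mean_within = {}
    for b in np.unique(best_labels):
        idx = np.where(best_labels == b)[0]
        if len(idx) < 2:
            mean_within[int(b)] = 1.0
        else:
            blockm = rho_np[np.ix_(idx, idx)]
            mean_within[int(b)] = float(
                blockm[np.triu_indices_from(blockm, k=1)].mean()
            )
    return BlockPartition(corr.stratum, assignment, int(best_k), z[:, 2].copy(),
                          mean_within, m)


def match_blocks(partition: BlockPartition, taxonomy: pd.DataFrame) -> BlockPartition:
    """Assign named clusters to blocks via anchor-tagged ASVs.

    A named cluster takes the block containing most of its anchors present
    in this heatmap; ties go to the block whose anchors have the higher mean
    within-block correlation. A name whose anchors are absent from the
    top-N stays unmatched in this stratum.
    """
    labels: dict[str, int] = {}
    present = [a for a in partition.assignment if a in taxonomy.index]
    anchors_of = {
        name: [a for a in present if taxonomy.loc[a, "anchor"] == name]
        for name in CLUSTER_NAMES
    }
    rho = partition.correlation
    for name in CLUSTER_NAMES:
        anchors = anchors_of[name]
        if not anchors:
            continue
        counts: dict[int, list[str]] = {}
        for a in anchors:
            counts.setdefault(partition.assignment[a], []).append(a)
        best, best_key = None, (-1, -np.inf)
        for b, members in sorted(counts.items()):
            anchor_rho = (
                float(rho.loc[members, members].to_numpy()[
                    np.triu_indices(len(members), k=1)].mean())
                if len(members) > 1 else 1.0
            )
            key = (len(members), anchor_rho)
            if key > best_key:
                best, best_key = b, key
        labels[name] = best
    partition.labels = labels
    return partition


def consensus_core(
    partitions: dict[str, BlockPartition],
    min_support: int = MIN_SUPPORT,
) -> ConsensusClusterSet:
    """Core ASVs per named cluster: membership in >= min_support strata.

    ``partitions`` maps stratum key -> labeled partition (one per stratum,
    normally the 10 ethnicity x generation heatmaps). The support denominator
    is the full stratum count: an ASV absent from a stratum's top-N simply
    cannot gain support there.
    """
    if not partitions:
        raise ValueError("no stratum partitions given")
    for key, p in partitions.items():
        if p.labels is None:
            raise ValueError(f"partition {key!r} is unlabeled; run match_blocks first")
    n_strata = len(partitions)
    if min_support > n_strata:
        raise ValueError("min_support exceeds the number of strata")
    support: dict[str, dict[str, int]] = {name: {} for name in CLUSTER_NAMES}
    matched: dict[str, dict[str, int | None]] = {name: {} for name in CLUSTER_NAMES}
    for key in sorted(partitions):
        p = partitions[key]
        for name in CLUSTER_NAMES:
            b = p.labels.get(name)
            matched[name][key] = b
            if b is None:
                continue
            for a in p.members(b):
                support[name][a] = support[name].get(a, 0) + 1
    core = {
        name: sorted(a for a, s in support[name].items() if s >= min_support)
        for name in CLUSTER_NAMES
    }
    return ConsensusClusterSet(core, support, matched, min_support, n_strata)


def run_trophic_consensus(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    taxonomy: pd.DataFrame,
    top_n: int = 200,
    min_support: int = MIN_SUPPORT,
    linkage: str = "complete",
    k_range: tuple[int, int] = (3, 15),
) -> tuple[ConsensusClusterSet, dict[str, BlockPartition]]:
    """Full pipeline: per-stratum heatmap blocks -> labels -> consensus core."""
    partitions: dict[str, BlockPartition] = {}
    for eth in sorted(meta["ethnicity"].unique()):
        for gen in (1, 2):
            if not ((meta["ethnicity"] == eth) & (meta["generation"] == gen)).any():
                continue
            corr = stratum_correlation(table, meta, eth, gen, top_n=top_n)
            part = extract_blocks(corr, linkage=linkage, k_range=k_range)
            partitions[corr.stratum] = match_blocks(part, taxonomy)
    return consensus_core(partitions, min_support=min_support), partitions
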