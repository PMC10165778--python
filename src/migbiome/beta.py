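"""Beta-diversity distances, ordination, and PERMANOVA.

Distances are returned as :class:`skbio.DistanceMatrix` (symmetric, zero
diagonal, ids attached). PERMANOVA follows the sequential (Type-I)
sums-of-squares decomposition of the Gower-centered distance matrix, the
behaviour of vegan's ``adonis2(..., by = "terms")``: terms are added in the
order given, each term's pseudo-F uses the residual of the full model, and
p-values come from freely permuting sample labels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .exceptions import ReconciliationError
from .stats import bh_adjust, mann_whitney_u

__all__ = [
    "bray_curtis",
    "generalized_unifrac",
    "pcoa",
    "PCoAResult",
    "permanova",
    "PermanovaResult",
    "dissimilarity_to_reference",
]


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(a,b) = sum|a-b| / sum(a+b)."""
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (x < 0).any():
        raise ValueError("negative abundances")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample(s) present")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in table.index])


def _branch_matrix(table: pd.DataFrame, tree):
    """(branch lengths, clade-proportion matrix samples x branches)."""
    tips = {t.name for t in tree.tips()}
    missing = set(map(str, table.columns)) - tips
    if missing:
        raise ReconciliationError(f"table ASVs absent from tree: {sorted(missing)[:5]}")
    prop = table.div(table.sum(axis=1), axis=0)
    col = {a: i for i, a in enumerate(table.columns)}
    n = table.shape[0]
    lengths, clades = [], []
    # postorder accumulation of per-sample clade proportions below each branch
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            vec = (
                prop.iloc[:, col[node.name]].to_numpy(dtype=float)
                if node.name in col
                else np.zeros(n)
            )
        else:
            vec = np.sum([ch._clade for ch in node.children], axis=0)
        node._clade = vec
        if node.length:
            lengths.append(node.length)
            clades.append(vec)
    for node in tree.postorder(include_self=False):
        del node._clade
    return np.asarray(lengths), np.asarray(clades).T  # samples x branches


def generalized_unifrac(table: pd.DataFrame, tree, alpha: float = 0.5) -> DistanceMatrix:
    """Generalized UniFrac distance with abundance-weight exponent alpha.

    d(A,B) = sum_b l_b (pA+pB)^alpha |pA-pB|/(pA+pB) / sum_b l_b (pA+pB)^alpha
    over branches b, with p the clade proportion below b. alpha=1 is weighted
    (normalized) UniFrac; alpha=0.5 is the recommended compromise default.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    lengths, P = _branch_matrix(table, tree)
    n = P.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = P[i] + P[j]
            nz = s > 0
            w = lengths[nz] * s[nz] ** alpha
            num = float((w * np.abs(P[i, nz] - P[j, nz]) / s[nz]).sum())
            den = float(w.sum())
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(d, ids=[str(i) for i in table.index])


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame    # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray      # all eigenvalues incl. negative ones
    proportion_explained: np.ndarray


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0)
    return a - row[None, :] - row[:, None] + a.mean()


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are reported, never
    silently dropped; coordinates use the top-k positive eigenvalues.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_center(d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0, None)
    k = min(k, int((evals > 1e-12).sum()))
    coords = evecs[:, :k] * np.sqrt(pos[:k])[None, :]
    prop = pos / pos.sum() if pos.sum() > 0 else pos
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    table: pd.DataFrame          # per-term df, SumOfSqs, R2, F, p + residual/total rows
    n_permutations: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    col = meta[term]
    if col.nunique() < 2:
        raise ValueError(f"term {term!r} is constant")
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col, drop_first=True, dtype=float)
        return dummies.to_numpy()
    return col.to_numpy(dtype=float)[:, None]


def permanova(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    Pseudo-F per term against the full-model residual; permutation p-values
    count F_perm >= F_obs (ties conservative), p = (hits + 1)/(n_perm + 1).
    """
    ids = list(dm.ids)
    missing = set(ids) - set(map(str, meta.index))
    if missing:
        raise ReconciliationError(f"samples missing from metadata: {sorted(missing)[:5]}")
    meta = meta.loc[[type(meta.index[0])(i) if meta.index.dtype != object else i for i in ids]]
    n = len(ids)
    if n < 5:
        raise ValueError("PERMANOVA needs n >= 5")
    g = _gower_center(dm.data)
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, then each added term
    blocks = [np.ones((n, 1))]
    dfs = []
    for t in terms:
        cols = _design_columns(meta, t)
        blocks.append(cols)
        dfs.append(cols.shape[1])
    hats = []
    for j in range(1, len(blocks) + 1):
        x = np.hstack(blocks[:j])
        q, r = np.linalg.qr(x)
        rank = int((np.abs(np.diag(r)) > 1e-10).sum())
        hats.append(q[:, :rank] @ q[:, :rank].T)
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_ss(gm: np.ndarray) -> tuple[np.ndarray, float]:
        # tr(H G H) = tr(H G) for idempotent symmetric H
        tr = np.array([float(np.sum(h * gm)) for h in hats])
        ss = np.diff(tr)                      # per-term sequential SS
        ss_res = float(np.trace(gm)) - tr[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = term_ss(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_ss(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        hits += f_p >= f_obs
    pvals = (hits + 1) / (n_perm + 1)

    rows = []
    for t, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, pvals):
        rows.append({"term": t, "df": df, "SumOfSqs": ss, "R2": ss / ss_total,
                     "F": f, "p": p})
    rows.append({"term": "Residual", "df": df_res, "SumOfSqs": ss_res_obs,
                 "R2": ss_res_obs / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)


def dissimilarity_to_reference(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    reference_stratum: str,
    age_cutoff: float = 42.0,
) -> pd.DataFrame:
    """Mean dissimilarity of each migrant generation to the reference group.

    Each 1st-generation sample is compared against the older (age >=
    cutoff) reference samples and each 2nd-generation sample against the
    younger reference samples, correcting for the age confound. Per
    ethnicity, the two per-sample mean-distance sets are contrasted with
    Mann-Whitney U, BH-adjusted across ethnicities.
    """
    ids = list(dm.ids)
    meta = meta.loc[ids]
    ref = meta["ethnicity"] == reference_stratum
    if not ref.any():
        raise ValueError(f"reference stratum {reference_stratum!r} absent")
    old_ref = np.where(ref & (meta["age"] >= age_cutoff))[0]
    young_ref = np.where(ref & (meta["age"] < age_cutoff))[0]
    if len(old_ref) == 0 or len(young_ref) == 0:
        raise ValueError("reference stratum lacks one of the age classes")
    d = dm.data
    rows = []
    for eth, sub in meta.groupby("ethnicity", sort=True):
        if eth == reference_stratum:
            continue
        idx = {sid: i for i, sid in enumerate(ids)}
        g1 = [idx[s] for s in sub.index[sub["generation"] == 1]]
        g2 = [idx[s] for s in sub.index[sub["generation"] == 2]]
        if not g1 or not g2:
            continue
        m1 = d[np.ix_(g1, old_ref)].mean(axis=1)
        m2 = d[np.ix_(g2, young_ref)].mean(axis=1)
        res = mann_whitney_u(m1, m2)
        rows.append({
            "ethnicity": eth,
            "mean_dist_gen1": float(m1.mean()),
            "mean_dist_gen2": float(m2.mean()),
            "n1": len(g1), "n2": len(g2),
            "p": res.p_value,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
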