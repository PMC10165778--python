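"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the defining formula or by exhaustive
enumeration, never by calling the code under test.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def bh_bruteforce(p):
    """Benjamini-Hochberg step-up straight from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * n / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def mwu_exact_p_twosided(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_values = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )
        u_values.append(u)
    u_values = np.array(u_values)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    lo = np.mean(u_values <= u_obs)
    hi = np.mean(u_values >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def bray_curtis_pair(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.abs(a - b).sum() / (a + b).sum()


def faith_pd_bruteforce(tree, observed):
    """Union of root-to-tip edge paths via per-tip ancestor walks."""
    edges = {}
    for tip in tree.tips():
        if tip.name not in observed:
            continue
        node = tip
        while node.parent is not None:
            edges[id(node)] = node.length or 0.0
            node = node.parent
    return sum(edges.values())


def auc_bruteforce(y_true, scores):
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, float)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def complete_linkage_bruteforce(x):
    """Naive O(n^3) agglomerative complete linkage on Euclidean distances.

    Returns (merge distances in order, partitions after each merge as sets of
    frozensets of original indices).
    """
    n = x.shape[0]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(n)]
    merges, partitions = [], []
    while len(clusters) > 1:
        best = (math.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        merges.append(dist)
        partitions.append(frozenset(clusters))
    return merges, partitions


def dmm_loglik_bruteforce(counts, pi, alpha):
    """Mixture Dirichlet-multinomial log-likelihood by direct summation."""
    from math import lgamma, log, exp

    counts = np.asarray(counts, float)
    alpha = np.asarray(alpha, float)
    total = 0.0
    for row in counts:
        n = row.sum()
        coef = lgamma(n + 1) - sum(lgamma(v + 1) for v in row)
        comp_logs = []
        for k in range(len(pi)):
            a = alpha[k]
            asum = a.sum()
            ll = coef + lgamma(asum) - lgamma(n + asum)
            ll += sum(lgamma(v + aj) - lgamma(aj) for v, aj in zip(row, a))
            comp_logs.append(log(pi[k]) + ll)
        m = max(comp_logs)
        total += m + log(sum(exp(c - m) for c in comp_logs))
    return total


def weighted_unifrac_pair(tree, table, i, j):
    """alpha=1 generalized UniFrac by independent per-branch summation."""
    prop = table.div(table.sum(axis=1), axis=0)
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        tips = [t for t in tips if t in table.columns]
        pa = float(prop.iloc[i][tips].sum()) if tips else 0.0
        pb = float(prop.iloc[j][tips].sum()) if tips else 0.0
        length = node.length or 0.0
        if pa + pb > 0:
            num += length * abs(pa - pb)
            den += length * (pa + pb)
    return num / den if den else 0.0
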