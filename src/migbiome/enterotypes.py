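"""Community typing: classical JSD+PAM enterotypes and Dirichlet-multinomial
mixtures (DMM).

The classical scheme clusters samples on the square root of the
Jensen-Shannon divergence (a metric) between relative genus abundances,
with partitioning around medoids at k=3. The DMM scheme fits a K=4 mixture
whose components are Dirichlet priors over multinomial compositions, by EM
with a Minka fixed-point M-step for the Dirichlet parameters; the fit is
multi-start and its log-likelihood trace is non-decreasing.

Counts fed to the DMM are phylogeny-agglomerated clusters filtered at a
0.1% detection limit in at least 50% of samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "filter_features",
    "jsd_matrix",
    "pam",
    "pam_enterotypes",
    "DirichletMultinomialMixture",
    "DMMResults",
]

DETECTION_LIMIT = 0.001
PREVALENCE = 0.5


def filter_features(
    table: pd.DataFrame,
    detection: float = DETECTION_LIMIT,
    prevalence: float = PREVALENCE,
) -> pd.DataFrame:
    """Keep features whose relative abundance exceeds ``detection`` (strict)
    in at least a ``prevalence`` fraction of samples (non-strict)."""
    rel = table.div(table.sum(axis=1), axis=0)
    keep = (rel > detection).mean(axis=0) >= prevalence
    if not keep.any():
        raise ValueError("no feature survives the detection/prevalence filter")
    return table.loc[:, keep]


def jsd_matrix(table: pd.DataFrame, pseudocount: float = 1e-9) -> np.ndarray:
    """Square root of Jensen-Shannon divergence (base e) between samples.

    A pseudocount keeps zero abundances off the log; sqrt-JSD is a metric.
    """
    rel = table.div(table.sum(axis=1), axis=0).to_numpy(dtype=float) + pseudocount
    rel /= rel.sum(axis=1, keepdims=True)
    return squareform(pdist(rel, metric="jensenshannon"))


def pam(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    Deterministic: BUILD greedily minimizes total distance; SWAP applies the
    best-improving (medoid, candidate) swap until no swap improves, ties
    broken by lowest index. Returns (labels 0..k-1, medoid indices).
    """
    n = d.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(cur - d[:, c], 0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(ms):
        return d[:, ms].min(axis=1).sum()

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for c in range(n):
                if c in medoids:
                    continue
                trial = sorted(medoids[:mi] + [c] + medoids[mi + 1:])
                tc = cost(trial)
                if tc < best - 1e-12:
                    best, medoids, improved = tc, trial, True
        # best-improvement restart until stable
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, np.array(medoids)


def pam_enterotypes(
    genus_table: pd.DataFrame, k: int = 3, seed: int = 0, pseudocount: float = 1e-9
) -> tuple[pd.Series, np.ndarray]:
    """Classical enterotypes: sqrt-JSD on relative genus abundance + PAM.

    The procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages.
    """
    if k > genus_table.shape[0]:
        raise ValueError("k exceeds the number of samples")
    d = jsd_matrix(genus_table, pseudocount)
    labels, medoids = pam(d, k)
    return (
        pd.Series(labels + 1, index=genus_table.index, name="enterotype"),
        medoids,
    )


def _dm_loglik_matrix(x: np.ndarray, log_coef: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """log DirMult(x_i | alpha_k) for all samples x components."""
    n_tot = x.sum(axis=1)
    a_tot = alpha.sum(axis=1)
    ll = (
        gammaln(a_tot)[None, :]
        - gammaln(n_tot[:, None] + a_tot[None, :])
        + log_coef[:, None]
    )
    for kk in range(alpha.shape[0]):
        ll[:, kk] += (gammaln(x + alpha[kk][None, :]) - gammaln(alpha[kk])[None, :]).sum(axis=1)
    return ll


@dataclass
class DMMResults:
    """Fitted Dirichlet-multinomial mixture."""

    pi_: np.ndarray                  # mixture weights, simplex
    alpha_: pd.DataFrame             # K x features Dirichlet parameters
    responsibilities_: pd.DataFrame  # samples x K posterior weights
    loglik_: float
    loglik_trace_: np.ndarray
    n_iter_: int
    converged_: bool

    @property
    def labels_(self) -> pd.Series:
        lab = self.responsibilities_.to_numpy().argmax(axis=1) + 1
        return pd.Series(lab, index=self.responsibilities_.index, name="enterotype")

    def summary(self) -> str:
        lines = [
            f"Dirichlet-multinomial mixture, K={len(self.pi_)}",
            f"log-likelihood {self.loglik_:.4f} after {self.n_iter_} EM iterations"
            f" ({'converged' if self.converged_ else 'max_iter reached'})",
            "weights: " + ", ".join(f"{w:.3f}" for w in self.pi_),
        ]
        top = self.alpha_.apply(lambda r: r.nlargest(3).index.tolist(), axis=1)
        for kk, feats in enumerate(top):
            lines.append(f"  component {kk + 1}: top features {feats}")
        return "\n".join(lines)


class DirichletMultinomialMixture:
    """DMM community-typing model over integer count compositions.

    Parameters
    ----------
    counts : samples x features integer DataFrame.
    n_components : number K of Dirichlet components (the 4-enterotype scheme
        uses K=4).
    """

    def __init__(self, counts: pd.DataFrame, n_components: int = 4):
        x = counts.to_numpy()
        if not np.issubdtype(x.dtype, np.integer):
            if not np.allclose(x, np.round(x)):
                raise ValueError("DMM requires integer counts")
            x = np.round(x).astype(np.int64)
        if n_components < 1:
            raise ValueError("K must be >= 1")
        if n_components > counts.shape[0]:
            raise ValueError("K exceeds the number of samples")
        self.counts = counts
        self.x = x.astype(float)
        self.K = n_components
        # multinomial coefficient, constant over components
        self._log_coef = (
            gammaln(self.x.sum(axis=1) + 1) - gammaln(self.x + 1).sum(axis=1)
        )

    def _init_alpha(self, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        prop = self.x / self.x.sum(axis=1, keepdims=True)
        if self.K == 1:
            centers = prop.mean(axis=0, keepdims=True)
        else:
            # fit on canonically sorted rows so the init (hence the whole fit)
            # is invariant to sample order
            order = np.lexsort(prop.T[::-1])
            km = KMeans(self.K, n_init=1, random_state=int(rng.integers(2**31)))
            km.fit(prop[order])
            centers = np.clip(km.cluster_centers_, 1e-8, None)
        centers = centers * rng.uniform(0.9, 1.1, size=centers.shape)
        centers /= centers.sum(axis=1, keepdims=True)
        return np.clip(centers * 50.0, 1e-6, None)

    def _fixed_point_alpha(self, alpha_k, resp_k, inner_iter=15):
        """Minka fixed-point update of one component's Dirichlet parameters."""
        x = self.x
        n_tot = x.sum(axis=1)
        w = resp_k
        for _ in range(inner_iter):
            a_tot = alpha_k.sum()
            num = (w[:, None] * (digamma(x + alpha_k[None, :]) - digamma(alpha_k)[None, :])).sum(axis=0)
            den = (w * (digamma(n_tot + a_tot) - digamma(a_tot))).sum()
            if den <= 0:
                break
            new = np.clip(alpha_k * num / den, 1e-10, None)
            if np.max(np.abs(new - alpha_k) / np.maximum(alpha_k, 1e-10)) < 1e-8:
                alpha_k = new
                break
            alpha_k = new
        return alpha_k

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 1000,
        n_init: int = 5,
    ) -> DMMResults:
        """EM fit; best of ``n_init`` starts (k-means centers + jitter)."""
        ss = np.random.SeedSequence(seed)
        best: DMMResults | None = None
        for child in ss.spawn(n_init):
            res = self._fit_once(int(child.generate_state(1)[0] % 2**31), tol, max_iter)
            if best is None or res.loglik_ > best.loglik_:
                best = res
        return best

    def _fit_once(self, seed: int, tol: float, max_iter: int) -> DMMResults:
        alpha = self._init_alpha(seed)
        pi = np.full(self.K, 1.0 / self.K)
        trace = []
        converged = False
        resp = np.ones((self.x.shape[0], self.K)) / self.K
        for it in range(max_iter):
            ll_mat = _dm_loglik_matrix(self.x, self._log_coef, alpha)
            joint = np.log(np.clip(pi, 1e-300, None))[None, :] + ll_mat
            ll = float(logsumexp(joint, axis=1).sum())
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
                converged = True
                break
            resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
            pi = resp.mean(axis=0)
            for kk in range(self.K):
                alpha[kk] = self._fixed_point_alpha(alpha[kk], resp[:, kk])
        if not converged:
            # evaluate at the parameters actually returned
            ll_mat = _dm_loglik_matrix(self.x, self._log_coef, alpha)
            joint = np.log(np.clip(pi, 1e-300, None))[None, :] + ll_mat
            trace.append(float(logsumexp(joint, axis=1).sum()))
            resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        return DMMResults(
            pi_=pi,
            alpha_=pd.DataFrame(alpha, columns=self.counts.columns,
                                index=[f"component_{i + 1}" for i in range(self.K)]),
            responsibilities_=pd.DataFrame(
                resp, index=self.counts.index,
                columns=[f"component_{i + 1}" for i in range(self.K)],
            ),
            loglik_=trace[-1],
            loglik_trace_=np.array(trace),
            n_iter_=len(trace),
            converged_=converged,
        )

    def loglik(self, pi: np.ndarray, alpha: np.ndarray) -> float:
        """Mixture log-likelihood at given parameters (for external checks)."""
        ll_mat = _dm_loglik_matrix(self.x, self._log_coef, np.asarray(alpha, dtype=float))
        joint = np.log(np.clip(pi, 1e-300, None))[None, :] + ll_mat
        return float(logsumexp(joint, axis=1).sum())
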