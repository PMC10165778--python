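"""Stability-selection generation classifier.

A gradient-boosted tree classifier is fitted repeatedly on random balanced
subsets of one ethnic stratum to distinguish 1st- from 2nd-generation
samples, and its impurity-based feature importances are aggregated across all
fitted models. Per subset: the majority class is randomly undersampled to the
minority size, a class-stratified fraction (default 0.5) of the balanced set
is drawn, and leave-one-out cross-validation runs over it — each training
fold tunes hyperparameters by randomized search (3-fold CV on 90% of the
fold, winner checked on the held-back 10%), refits on the whole fold and
scores the left-out sample. Per-subset AUC pools the LOO probabilities.

The classifier is pluggable: any estimator factory returning an object with
``fit``, ``predict_proba`` and ``feature_importances_`` and deterministic
given its seed satisfies the contract; the default is sklearn's
GradientBoostingClassifier. The hyperparameter grid is a configurable
substitute for the original study's unpublished grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold

from .stats import bh_adjust, mann_whitney_u

__all__ = [
    "MLDataset",
    "StabilitySelectionResult",
    "prefilter_features",
    "run_stability",
    "importance_report",
    "auc_score",
    "DEFAULT_GRID",
    "default_classifier_factory",
]

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 3, 4, 6],
    "learning_rate": [0.01, 0.05, 0.1, 0.3],
    "n_estimators": [50, 100, 200],
    "subsample": [0.6, 0.8, 1.0],
    "max_features": [0.6, 0.8, 1.0],
}


def default_classifier_factory(params: dict, seed: int):
    return GradientBoostingClassifier(random_state=seed, **params)


@dataclass
class MLDataset:
    """Feature matrix + binary labels for one stratum's generation model."""

    X: pd.DataFrame                 # samples x selected features (rel. abundance)
    y: pd.Series                    # binary labels aligned to X
    stratum: str
    feature_f: pd.Series            # ANOVA F of each selected feature

    def __post_init__(self):
        classes = pd.unique(self.y)
        if len(classes) != 2:
            raise ValueError("MLDataset requires exactly two label classes")


@dataclass
class StabilitySelectionResult:
    subset_aucs: list[float]
    importances: pd.Series          # normalized to [0, 100], max = 100
    raw_importances: pd.Series
    direction: pd.Series            # per feature: which class has higher median
    n_models: int
    skipped_subsets: int = 0
    validation_scores: list[float] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.subset_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.subset_aucs, ddof=1)) if len(self.subset_aucs) > 1 else 0.0

    def summary(self) -> str:
        top = self.importances.sort_values(ascending=False).head(10)
        lines = [
            f"stability selection: {len(self.subset_aucs)} subsets, "
            f"{self.n_models} fitted models",
            f"AUC {self.mean_auc:.3f} +/- {self.sd_auc:.3f}",
            "top features (importance %, direction):",
        ]
        for feat, imp in top.items():
            lines.append(f"  {feat}: {imp:.1f}%  ({self.direction[feat]})")
        return "\n".join(lines)


def auc_score(y_true, scores) -> float:
    """AUC by the rank (Mann-Whitney) formula, tie-aware.

    Equals the probability that a random positive outranks a random negative,
    counting ties as one half.
    """
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    r = rankdata(s)
    u = r[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def prefilter_features(
    table: pd.DataFrame,
    labels: pd.Series,
    stratum: str = "",
    top_abundance: int = 1000,
    top_f: int = 100,
) -> MLDataset:
    """Dimensionality prefilter: top-N abundant, then top-F by ANOVA F.

    Features are relative abundances; zero-variance features get F = 0 and so
    never displace a varying feature.
    """
    labels = labels.loc[table.index]
    if labels.value_counts().min() < 2:
        raise ValueError("need >= 2 samples per class")
    rel = table.div(table.sum(axis=1), axis=0)
    mean_ab = rel.mean(axis=0)
    top_cols = mean_ab.sort_values(ascending=False, kind="mergesort").index[
        : min(top_abundance, rel.shape[1])
    ]
    x = rel[top_cols]
    y = pd.factorize(labels, sort=True)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_vals, _ = f_classif(x.to_numpy(), y)
    f_vals = np.nan_to_num(f_vals, nan=0.0)
    fs = pd.Series(f_vals, index=top_cols)
    chosen = fs.sort_values(ascending=False, kind="mergesort").index[: min(top_f, len(fs))]
    return MLDataset(X=x[chosen], y=labels, stratum=stratum, feature_f=fs[chosen])


def _sample_grid(rng: np.random.Generator, grid: dict, n: int) -> list[dict]:
    out = []
    keys = sorted(grid)
    for _ in range(n):
        out.append({k: grid[k][rng.integers(len(grid[k]))] for k in keys})
    return out


def _stratified_indices(y: np.ndarray, frac: float, rng) -> np.ndarray:
    """Class-stratified sample of ceil(frac * n_c) indices per class."""
    keep = []
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        n = max(1, int(round(frac * len(idx))))
        keep.append(rng.choice(idx, size=n, replace=False))
    return np.sort(np.concatenate(keep))


def run_stability(
    data: MLDataset,
    n_subsets: int = 20,
    fraction: float = 0.5,
    n_param: int = 10,
    seed: int = 0,
    grid: dict | None = None,
    classifier_factory=default_classifier_factory,
    min_class: int = 4,
) -> StabilitySelectionResult:
    """Repeated balanced-subset LOO evaluation with per-fold tuning.

    Deterministic given ``seed``: subset composition, undersampling, the
    90/10 splits, and hyperparameter draws all derive from one seed sequence.
    """
    grid = grid or DEFAULT_GRID
    x_all = data.X.to_numpy(dtype=float)
    y_codes, classes = pd.factorize(data.y, sort=True)
    counts = np.bincount(y_codes)
    if counts.min() < min_class:
        raise ValueError("too few samples per class for stability selection")
    pos = 1  # class coded 1 = second listed class (e.g. generation 2)

    master = np.random.SeedSequence(seed)
    subset_seeds = master.spawn(n_subsets)
    aucs: list[float] = []
    val_scores: list[float] = []
    imp_sum = np.zeros(x_all.shape[1])
    n_models = 0
    skipped = 0

    for s_idx in range(n_subsets):
        rng = np.random.default_rng(subset_seeds[s_idx])
        # undersample the majority class to the minority size
        n_min = counts.min()
        bal = []
        for cls in (0, 1):
            idx = np.where(y_codes == cls)[0]
            bal.append(rng.choice(idx, size=n_min, replace=False) if len(idx) > n_min else idx)
        bal = np.sort(np.concatenate(bal))
        # class-stratified fractional subset
        sub = bal[_stratified_indices(y_codes[bal], fraction, rng)]
        ys = y_codes[sub]
        if min(np.bincount(ys, minlength=2)) < min_class:
            warnings.warn(f"subset {s_idx}: class too small after subsetting, skipped",
                          stacklevel=2)
            skipped += 1
            continue
        xs = x_all[sub]
        probs = np.empty(len(sub))
        for i in range(len(sub)):
            tr = np.delete(np.arange(len(sub)), i)
            x_tr, y_tr = xs[tr], ys[tr]
            params = _tune(x_tr, y_tr, grid, n_param, rng, classifier_factory, val_scores)
            model = classifier_factory(params, int(rng.integers(2**31)))
            model.fit(x_tr, y_tr)
            probs[i] = model.predict_proba(xs[i : i + 1])[0, pos]
            imp = np.asarray(model.feature_importances_, dtype=float)
            imp_sum += imp
            n_models += 1
        aucs.append(auc_score(ys == pos, probs))

    if not aucs:
        raise ValueError("every subset was skipped; stratum too small")
    raw = pd.Series(imp_sum / n_models, index=data.X.columns)
    norm = raw * (100.0 / raw.max()) if raw.max() > 0 else raw * 0.0
    direction = _directions(data.X, data.y, classes)
    return StabilitySelectionResult(
        subset_aucs=aucs,
        importances=norm,
        raw_importances=raw,
        direction=direction,
        n_models=n_models,
        skipped_subsets=skipped,
        validation_scores=val_scores,
    )


def _tune(x_tr, y_tr, grid, n_param, rng, factory, val_scores) -> dict:
    """Randomized search: 3-fold CV AUC on a 90% split, winner checked on 10%."""
    n = len(y_tr)
    order = rng.permutation(n)
    n_val = max(1, int(round(0.1 * n)))
    val_idx, search_idx = order[:n_val], order[n_val:]
    candidates = _sample_grid(rng, grid, n_param)
    xs, ys = x_tr[search_idx], y_tr[search_idx]
    n_splits = min(3, np.bincount(ys, minlength=2).min())
    best_params, best_score = candidates[0], -np.inf
    for params in candidates:
        if n_splits < 2:
            score = 0.0
        else:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            scores = []
            for tr_i, te_i in skf.split(xs, ys):
                m = factory(params, int(rng.integers(2**31)))
                m.fit(xs[tr_i], ys[tr_i])
                p = m.predict_proba(xs[te_i])[:, 1]
                if len(np.unique(ys[te_i])) == 2:
                    scores.append(auc_score(ys[te_i] == 1, p))
            score = float(np.mean(scores)) if scores else 0.0
        if score > best_score:
            best_params, best_score = params, score
    # confirm the winner on the 10% validation split (recorded, not used to re-pick)
    if len(np.unique(y_tr[val_idx])) == 2:
        m = factory(best_params, int(rng.integers(2**31)))
        m.fit(x_tr[search_idx], y_tr[search_idx])
        val_scores.append(
            auc_score(y_tr[val_idx] == 1, m.predict_proba(x_tr[val_idx])[:, 1])
        )
    return best_params


def _directions(X: pd.DataFrame, y: pd.Series, classes) -> pd.Series:
    med = X.groupby(y.values).median()
    lo, hi = classes[0], classes[1]
    diff = med.loc[hi] - med.loc[lo]
    out = pd.Series(
        np.where(diff > 0, str(hi), np.where(diff < 0, str(lo), "tie")),
        index=X.columns,
    )
    return out


def importance_report(
    result: StabilitySelectionResult,
    table: pd.DataFrame,
    labels: pd.Series,
    top_k: int = 20,
) -> pd.DataFrame:
    """Top-k features by normalized importance, with direction and MWU p.

    Ordering follows importance, ties broken lexicographically by feature id;
    the per-feature Mann-Whitney p-values (full stratum, both classes) are
    BH-adjusted within the report.
    """
    imp = result.importances
    ranked = sorted(imp.index, key=lambda f: (-imp[f], f))[:top_k]
    labels = labels.loc[table.index]
    classes = sorted(pd.unique(labels))
    rel = table.div(table.sum(axis=1), axis=0)
    rows = []
    for f in ranked:
        g1 = rel.loc[labels == classes[0], f]
        g2 = rel.loc[labels == classes[1], f]
        p = mann_whitney_u(g1, g2).p_value
        rows.append({
            "feature": f,
            "importance": float(imp[f]),
            "direction": result.direction[f],
            "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
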