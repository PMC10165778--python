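"""Stability-selection classifier harness."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from migbiome.ml import (
    MLDataset,
    auc_score,
    importance_report,
    prefilter_features,
    run_stability,
)

from oracles import auc_bruteforce


class StumpClassifier:
    """Depth-1 threshold model satisfying the pluggable-classifier contract."""

    def __init__(self, params=None, seed=0):
        self.seed = seed

    def fit(self, X, y):
        X, y = np.asarray(X, float), np.asarray(y)
        best = (-1.0, 0, 0.0)
        for j in range(X.shape[1]):
            thr = np.median(X[:, j])
            score = abs(np.mean(y[X[:, j] > thr]) - np.mean(y[X[:, j] <= thr])
                        ) if 0 < (X[:, j] > thr).sum() < len(y) else 0.0
            if score > best[0]:
                best = (score, j, thr)
        self.j_, self.thr_ = best[1], best[2]
        self.p_hi_ = float(np.mean(y[X[:, self.j_] > self.thr_])) if (
            X[:, self.j_] > self.thr_).any() else 0.5
        self.p_lo_ = float(np.mean(y[X[:, self.j_] <= self.thr_])) if (
            X[:, self.j_] <= self.thr_).any() else 0.5
        self.n_features_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, float)
        p1 = np.where(X[:, self.j_] > self.thr_, self.p_hi_, self.p_lo_)
        return np.column_stack([1 - p1, p1])

    @property
    def feature_importances_(self):
        imp = np.zeros(self.n_features_)
        imp[self.j_] = 1.0
        return imp


def stump_factory(params, seed):
    return StumpClassifier(params, seed)


def _dataset(rng, n_per_class=30, n_features=25, n_signal=5, shift=2.0):
    labels = np.array(["gen1"] * n_per_class + ["gen2"] * n_per_class)
    x = rng.normal(size=(2 * n_per_class, n_features))
    x[n_per_class:, :n_signal] += shift
    x = np.abs(x) + 0.01
    x = x / x.sum(axis=1, keepdims=True)
    idx = [f"s{i}" for i in range(2 * n_per_class)]
    cols = [f"a{i}" for i in range(n_features)]
    X = pd.DataFrame(x, index=idx, columns=cols)
    y = pd.Series(labels, index=idx)
    return MLDataset(X, y, "T", pd.Series(1.0, index=cols))


class TestAUC:
    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 50)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.integers(0, 6, n).astype(float)  # deliberate ties
            assert auc_score(y, s) == pytest.approx(auc_bruteforce(y, s))

    def test_perfect_and_reverse(self):
        assert auc_score([0, 0, 1, 1], [1, 2, 3, 4]) == 1.0
        assert auc_score([0, 0, 1, 1], [4, 3, 2, 1]) == 0.0


class TestPrefilter:
    def test_all_kept_when_top_f_exceeds_features(self, small_cohort):
        _d, (table, meta, *_rest) = small_cohort
        y = meta["generation"].map({1: "g1", 2: "g2"})
        data = prefilter_features(table, y, top_abundance=50, top_f=500)
        assert data.X.shape[1] == 50

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = np.array([0] * 30 + [1] * 30)
        t_stat = sps.ttest_ind(x[y == 0], x[y == 1]).statistic
        from sklearn.feature_selection import f_classif
        f_val = f_classif(x[:, None], y)[0][0]
        assert f_val == pytest.approx(t_stat**2)

    def test_planted_discriminative_asvs_selected(self):
        rng = np.random.default_rng(2)
        n = 150
        counts = rng.integers(1, 50, size=(2 * n, 300))
        # plant a strong generation shift in 10 ASVs
        counts[n:, :10] += 80
        idx = [f"s{i}" for i in range(2 * n)]
        table = pd.DataFrame(counts, index=idx,
                             columns=[f"a{i}" for i in range(300)])
        y = pd.Series(["g1"] * n + ["g2"] * n, index=idx)
        data = prefilter_features(table, y, top_abundance=300, top_f=100)
        assert all(f"a{i}" in data.X.columns for i in range(10))

    def test_zero_variance_features_never_displace_varying(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.full(40, 7.0), rng.normal(size=(40, 3))])
        table = pd.DataFrame(np.abs(x) + 1, index=[f"s{i}" for i in range(40)],
                             columns=["flat", "v1", "v2", "v3"]).round(3) * 1000
        table = table.astype(int)
        y = pd.Series(["a"] * 20 + ["b"] * 20, index=table.index)
        data = prefilter_features(table, y, top_abundance=4, top_f=3)
        assert "flat" not in data.X.columns


class TestRunStability:
    def test_fold_arithmetic_30_vs_10(self):
        # 30 gen1 / 10 gen2, fraction 0.5 -> balanced 10+10, subset 5+5,
        # LOO over 10 samples -> 10 fitted models per subset
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(40)]
        X = pd.DataFrame(rng.uniform(size=(40, 6)), index=idx,
                         columns=[f"a{i}" for i in range(6)])
        y = pd.Series(["gen1"] * 30 + ["gen2"] * 10, index=idx)
        data = MLDataset(X, y, "T", pd.Series(1.0, index=X.columns))
        res = run_stability(data, n_subsets=3, fraction=0.5, n_param=2, seed=0,
                            classifier_factory=stump_factory)
        assert res.n_models == 3 * 10
        assert len(res.subset_aucs) == 3

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        data = _dataset(rng)
        r1 = run_stability(data, n_subsets=3, n_param=2, seed=7,
                           classifier_factory=stump_factory)
        r2 = run_stability(data, n_subsets=3, n_param=2, seed=7,
                           classifier_factory=stump_factory)
        assert r1.subset_aucs == r2.subset_aucs
        pd.testing.assert_series_equal(r1.importances, r2.importances)

    def test_strong_signal_found_with_stump(self):
        rng = np.random.default_rng(6)
        data = _dataset(rng, n_per_class=24, n_signal=3, shift=4.0)
        res = run_stability(data, n_subsets=4, n_param=2, seed=1,
                            classifier_factory=stump_factory)
        assert res.mean_auc >= 0.7  # a depth-1 stump caps well below a GBM
        top3 = res.importances.sort_values(ascending=False).index[:3]
        assert len(set(top3) & {"a0", "a1", "a2"}) >= 2

    def test_importance_normalized_to_hundred(self):
        rng = np.random.default_rng(7)
        data = _dataset(rng)
        res = run_stability(data, n_subsets=2, n_param=2, seed=2,
                            classifier_factory=stump_factory)
        assert res.importances.max() == pytest.approx(100.0)

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(8)]
        X = pd.DataFrame(rng.uniform(size=(8, 3)), index=idx)
        y = pd.Series(["a"] * 6 + ["b"] * 2, index=idx)
        data = MLDataset(X, y, "T", pd.Series(1.0, index=X.columns))
        with pytest.raises(ValueError):
            run_stability(data, n_subsets=2, seed=0,
                          classifier_factory=stump_factory)


class TestImportanceReport:
    def test_direction_and_ordering(self):
        rng = np.random.default_rng(9)
        data = _dataset(rng, n_per_class=25, n_signal=2, shift=3.0)
        res = run_stability(data, n_subsets=2, n_param=2, seed=3,
                            classifier_factory=stump_factory)
        rel_table = data.X  # already relative
        report = importance_report(res, rel_table, data.y, top_k=5)
        assert list(report["importance"]) == sorted(report["importance"],
                                                    reverse=True)
        # planted features are higher in gen2
        planted = report[report["feature"].isin(["a0", "a1"])]
        assert (planted["direction"] == "gen2").all()

    def test_exactly_equal_medians_tie(self):
        idx = [f"s{i}" for i in range(6)]
        X = pd.DataFrame({"a": [1, 2, 3, 1, 2, 3], "b": [1, 1, 2, 2, 3, 3]},
                         index=idx, dtype=float)
        y = pd.Series(["g1"] * 3 + ["g2"] * 3, index=idx)
        from migbiome.ml import _directions
        d = _directions(X, y, ["g1", "g2"])
        assert d["a"] == "tie"
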