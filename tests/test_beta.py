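"""Beta-diversity distances, PCoA and PERMANOVA against oracles."""
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from migbiome import beta
from migbiome.syndata import generate_tree

from oracles import bray_curtis_pair, weighted_unifrac_pair


def _table(rows):
    rows = np.asarray(rows)
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])],
                        columns=[f"a{i}" for i in range(rows.shape[1])])


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        dm = beta.bray_curtis(_table([[1, 0], [1, 0], [0, 1]]))
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == 1.0

    def test_hand_arithmetic(self):
        dm = beta.bray_curtis(_table([[6, 2], [2, 2]]))
        assert dm["s0", "s1"] == pytest.approx(1 / 3)

    def test_matches_formula_on_random_tables(self, small_cohort):
        _d, (table, *_rest) = small_cohort
        sub = table.iloc[:6]
        dm = beta.bray_curtis(sub)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = bray_curtis_pair(sub.iloc[i], sub.iloc[j])
                assert dm[sub.index[i], sub.index[j]] == pytest.approx(expect)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            beta.bray_curtis(_table([[0, 0], [1, 2]]))


class TestGeneralizedUniFrac:
    def test_identical_samples_zero(self, six_tip_tree):
        t = pd.DataFrame([[3, 1, 4, 1, 5, 9]] * 2, index=["x", "y"],
                         columns=list("ABCDEF"))
        dm = beta.generalized_unifrac(t, six_tip_tree, alpha=0.5)
        assert dm["x", "y"] == pytest.approx(0.0)

    def test_alpha_one_matches_bruteforce(self, six_tip_tree, six_tip_table):
        dm = beta.generalized_unifrac(six_tip_table, six_tip_tree, alpha=1.0)
        n = six_tip_table.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                expect = weighted_unifrac_pair(six_tip_tree, six_tip_table, i, j)
                assert dm.data[i, j] == pytest.approx(expect, abs=1e-12)

    def test_alpha_one_matches_skbio_weighted_normalized(self, six_tip_table):
        import skbio
        tree = generate_tree(6, seed=4, asv_ids=list("ABCDEF"))
        dm = beta.generalized_unifrac(six_tip_table, tree, alpha=1.0)
        sk = skbio.diversity.beta_diversity(
            "weighted_unifrac", six_tip_table.to_numpy(),
            ids=list(six_tip_table.index), tree=tree,
            taxa=list(six_tip_table.columns), normalized=True,
        )
        np.testing.assert_allclose(dm.data, sk.data, atol=1e-10)

    def test_disjoint_clades_distance_one(self, six_tip_tree):
        # A,B live in one root clade; C..F in the other
        t = pd.DataFrame([[2, 5, 0, 0, 0, 0], [0, 0, 1, 2, 3, 4]],
                         index=["x", "y"], columns=list("ABCDEF"))
        dm = beta.generalized_unifrac(t, six_tip_tree, alpha=0.5)
        assert dm["x", "y"] == pytest.approx(1.0)

    def test_bad_alpha_rejected(self, six_tip_tree, six_tip_table):
        with pytest.raises(ValueError):
            beta.generalized_unifrac(six_tip_table, six_tip_tree, alpha=2.0)


class TestPCoA:
    def test_recovers_known_plane_geometry(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = beta.pcoa(DistanceMatrix(d, ids=[str(i) for i in range(12)]), k=2)
        x = res.coordinates.to_numpy()
        # compare via inter-point distances (rotation/reflection invariant)
        d2 = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_three_equidistant_points(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = beta.pcoa(DistanceMatrix(d, ids=list("abc")), k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.eigenvalues[0] > 0

    def test_eigenvalue_sum_equals_gower_trace(self, small_cohort):
        _d, (table, *_rest) = small_cohort
        dm = beta.bray_curtis(table.iloc[:15])
        res = beta.pcoa(dm, k=3)
        g = beta._gower_center(dm.data)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g))


class TestPermanova:
    @staticmethod
    def _random_case(seed=0, n=30):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 8))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({
            "generation": rng.integers(1, 3, size=n),
            "age": rng.normal(45, 10, size=n),
        }, index=ids)
        return DistanceMatrix(d, ids=ids), meta

    def test_r2_decomposition_sums_to_one(self):
        dm, meta = self._random_case()
        res = beta.permanova(dm, meta, ["generation", "age"], n_perm=49, seed=1)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_hit_permutation_floor(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(8, 1, (20, 5))])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(40)]
        meta = pd.DataFrame({"generation": [1] * 20 + [2] * 20}, index=ids)
        res = beta.permanova(DistanceMatrix(d, ids=ids), meta, ["generation"],
                             n_perm=999, seed=0)
        assert res.p_value("generation") == pytest.approx(1 / 1000)

    def test_relabeling_invariance(self):
        dm, meta = self._random_case(seed=3)
        perm = np.random.default_rng(9).permutation(len(dm.ids))
        ids2 = [dm.ids[i] for i in perm]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids2)
        res1 = beta.permanova(dm, meta, ["generation"], n_perm=9, seed=5)
        res2 = beta.permanova(dm2, meta, ["generation"], n_perm=9, seed=5)
        assert res1.table.loc["generation", "F"] == pytest.approx(
            res2.table.loc["generation", "F"])

    def test_one_way_f_matches_skbio(self):
        dm, meta = self._random_case(seed=7)
        res = beta.permanova(dm, meta, ["generation"], n_perm=9, seed=0)
        sk = skbio_permanova(dm, meta["generation"].astype(str), permutations=9)
        assert res.table.loc["generation", "F"] == pytest.approx(sk["test statistic"])

    def test_constant_term_rejected(self):
        dm, meta = self._random_case()
        meta["flat"] = 1.0
        with pytest.raises(ValueError):
            beta.permanova(dm, meta, ["flat"], n_perm=9)


class TestDissimilarityToReference:
    def test_all_identical_samples_give_zero_means(self):
        n = 12
        ids = [f"s{i}" for i in range(n)]
        d = DistanceMatrix(np.zeros((n, n)), ids=ids)
        meta = pd.DataFrame({
            "ethnicity": ["Ref"] * 6 + ["Mig"] * 6,
            "generation": [1, 1, 1, 2, 2, 2] * 2,
            "age": [50, 55, 60, 30, 35, 20, 50, 60, 55, 30, 20, 35],
        }, index=ids)
        out = beta.dissimilarity_to_reference(d, meta, "Ref")
        assert (out["mean_dist_gen1"] == 0).all()
        assert (out["mean_dist_gen2"] == 0).all()

    def test_means_are_averages_of_matrix_entries(self):
        rng = np.random.default_rng(1)
        n = 10
        x = rng.normal(size=(n, 3))
        dmat = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({
            "ethnicity": ["Ref"] * 5 + ["Mig"] * 5,
            "generation": [1, 1, 2, 2, 1] + [1, 1, 2, 2, 2],
            "age": [50, 60, 30, 35, 55] + [40, 41, 30, 31, 32],
        }, index=ids)
        out = beta.dissimilarity_to_reference(DistanceMatrix(dmat, ids=ids),
                                              meta, "Ref")
        old_ref = [0, 1, 4]  # Ref samples with age >= 42
        gen1_mig = [5, 6]
        expect = np.mean([dmat[i, old_ref].mean() for i in gen1_mig])
        assert out.iloc[0]["mean_dist_gen1"] == pytest.approx(expect)

    def test_planted_convergence_detected(self):
        # migrant gen2 sits on the reference composition, gen1 far away
        rng = np.random.default_rng(8)
        ref_young = rng.normal(0, 1, (25, 4))
        ref_old = rng.normal(0, 1, (25, 4))
        mig_g1 = rng.normal(5, 1, (25, 4))
        mig_g2 = rng.normal(0, 1, (25, 4))
        x = np.vstack([ref_old, ref_young, mig_g1, mig_g2])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(100)]
        meta = pd.DataFrame({
            "ethnicity": ["Ref"] * 50 + ["Mig"] * 50,
            "generation": [1] * 25 + [2] * 25 + [1] * 25 + [2] * 25,
            "age": [55] * 25 + [30] * 25 + [50] * 25 + [30] * 25,
        }, index=ids)
        out = beta.dissimilarity_to_reference(DistanceMatrix(d, ids=ids), meta, "Ref")
        row = out.iloc[0]
        assert row["mean_dist_gen2"] < row["mean_dist_gen1"]
        assert row["p_adj"] <= 0.05
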