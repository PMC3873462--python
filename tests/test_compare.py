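"""Community comparison statistics and the NJ helper."""

import itertools

import numpy as np
import pytest
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from sporeseg.compare import (
    amova,
    bonferroni_alpha,
    build_nj_tree,
    difference_distance_matrix,
    homova,
    jclass,
    ks_two_sample,
    thetayc,
    unifrac,
    unifrac_statistic,
)


class TestJclass:
    def test_identical_support(self):
        assert jclass([1, 2, 3], [9, 9, 9]) == pytest.approx(0.0)

    def test_disjoint_support(self):
        assert jclass([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_half_overlap(self):
        # supports {a,b,c} vs {b,c,d}: 1 - 2/4 = 0.5
        assert jclass([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            jclass([0, 0], [0, 0])


class TestThetaYC:
    def test_identical_structures(self):
        assert thetayc([2, 2, 4], [1, 1, 2]) == pytest.approx(0.0)

    def test_disjoint(self):
        assert thetayc([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # A=(.5,.5,0), B=(0,.5,.5): theta = .25/(.5+.5-.25) = 1/3
        assert thetayc([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_symmetry_and_range(self, rng):
        for _ in range(30):
            a = rng.integers(0, 9, size=8)
            b = rng.integers(0, 9, size=8)
            if a.sum() == 0 or b.sum() == 0:
                continue
            d1, d2 = thetayc(a, b), thetayc(b, a)
            assert d1 == pytest.approx(d2)
            assert -1e-12 <= d1 <= 1 + 1e-12


class TestUniFrac:
    def tree4(self):
        #  ((t1:1,t2:1):1,(t3:1,t4:1):1);  balanced, unit branches
        return TreeNode.read(["((t1:1,t2:1):1,(t3:1,t4:1):1);"])

    def test_identical_placement_zero(self):
        t = self.tree4()
        c = {"t1": 3, "t2": 1, "t3": 2, "t4": 2}
        assert unifrac_statistic(t, c, dict(c), weighted=True) == pytest.approx(0.0)

    def test_two_tip_exclusive_unweighted_one(self):
        t = TreeNode.read(["(t1:1,t2:1);"])
        a, b = {"t1": 5}, {"t2": 7}
        assert unifrac_statistic(t, a, b, weighted=False) == pytest.approx(1.0)

    def test_balanced_tree_hand_computation(self):
        # A entirely on the left clade, B on the right; every branch carries
        # |a-b| = its full mass.  weighted = sum(l*|a-b|)/sum(l*(a+b)) = 1
        t = self.tree4()
        a = {"t1": 2, "t2": 2}
        b = {"t3": 1, "t4": 3}
        assert unifrac_statistic(t, a, b, weighted=True) == pytest.approx(1.0)
        # hand case with shared mass: A=(t1:1,t3:1), B=(t2:1,t4:1)
        # tip branches all exclusive (l=1, |a-b|=.5) -> num = 4*.5 = 2
        # internal branches: each clade holds .5 of A and .5 of B -> |a-b|=0
        # den = tips 4*(.5+0) + internals 2*(.5+.5) = 4  -> 2/4 = 0.5
        a = {"t1": 1, "t3": 1}
        b = {"t2": 1, "t4": 1}
        assert unifrac_statistic(t, a, b, weighted=True) == pytest.approx(0.5)

    def test_matches_skbio_unweighted(self):
        from skbio.diversity.beta import unweighted_unifrac
        t = self.tree4()
        a = {"t1": 2, "t2": 0, "t3": 1, "t4": 0}
        b = {"t1": 0, "t2": 3, "t3": 1, "t4": 2}
        ours = unifrac_statistic(t, a, b, weighted=False)
        tips = ["t1", "t2", "t3", "t4"]
        theirs = unweighted_unifrac([a[x] for x in tips], [b[x] for x in tips],
                                    taxa=tips, tree=t)
        assert ours == pytest.approx(theirs)

    def test_permutation_p_floor_and_determinism(self):
        t = self.tree4()
        a = {"t1": 30, "t2": 30}
        b = {"t3": 30, "t4": 30}
        r1 = unifrac(t, a, b, weighted=True, n_perms=99, seed=5)
        r2 = unifrac(t, a, b, weighted=True, n_perms=99, seed=5)
        assert r1.p_value == r2.p_value == pytest.approx(1 / 100)

    def test_unmapped_allele_raises(self):
        t = self.tree4()
        with pytest.raises(KeyError):
            unifrac_statistic(t, {"zz": 1}, {"t1": 1})


def clustered_dm(rng, centers, n_per, spread):
    pts = np.concatenate([c + rng.normal(0, spread, size=(n_per, 2))
                          for c in centers])
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    labels = [f"g{i}" for i in range(len(centers)) for _ in range(n_per)]
    ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(d, ids), labels


class TestAmova:
    def test_separated_clusters_minimal_p(self, rng):
        dm, labels = clustered_dm(rng, [np.zeros(2), np.full(2, 50.0)], 6, 0.5)
        res = amova(dm, labels, n_perms=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_null_large_p(self, rng):
        dm, _ = clustered_dm(rng, [np.zeros(2)], 12, 1.0)
        labels = ["a"] * 6 + ["b"] * 6
        res = amova(dm, labels, n_perms=199, seed=1)
        assert res.p_value > 0.05

    def test_singleton_group_raises(self, rng):
        dm, _ = clustered_dm(rng, [np.zeros(2)], 5, 1.0)
        with pytest.raises(ValueError):
            amova(dm, ["a", "a", "a", "a", "b"], n_perms=9, seed=0)


class TestHomova:
    def test_heterogeneous_spread_small_p(self, rng):
        dm, _ = clustered_dm(rng, [np.zeros(2)], 16, 1.0)
        # replace second half with a much more dispersed cloud
        pts = np.concatenate([rng.normal(0, 0.1, size=(8, 2)),
                              rng.normal(0, 5.0, size=(8, 2))])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(16)])
        res = homova(dm, ["a"] * 8 + ["b"] * 8, n_perms=199, seed=2)
        assert res.p_value < 0.05

    def test_equal_spread_large_p(self, rng):
        dm, _ = clustered_dm(rng, [np.zeros(2)], 16, 1.0)
        res = homova(dm, ["a"] * 8 + ["b"] * 8, n_perms=199, seed=3)
        assert res.p_value > 0.05

    def test_statistic_invariant_under_relabeling(self, rng):
        dm, _ = clustered_dm(rng, [np.zeros(2)], 12, 1.0)
        labels = ["a"] * 6 + ["b"] * 6
        flipped = ["b"] * 6 + ["a"] * 6
        s1 = homova(dm, labels, n_perms=9, seed=0).statistic
        s2 = homova(dm, flipped, n_perms=9, seed=0).statistic
        assert s1 == pytest.approx(s2)


class TestKS:
    def test_identical_distributions(self):
        res = ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_non_overlapping_ranges(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == pytest.approx(1.0)

    def test_exact_small_sample_enumeration(self):
        # n=3+3 distinct values: p must match exhaustive enumeration of all
        # C(6,3) equally likely splits of the pooled sample
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        obs = stats.ks_2samp(a, b, method="exact").statistic
        pooled = sorted(a + b)
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            x = [pooled[i] for i in combo]
            y = [pooled[i] for i in range(6) if i not in combo]
            d = stats.ks_2samp(x, y, method="exact").statistic
            total += 1
            if d >= obs - 1e-12:
                hits += 1
        exact_p = hits / total
        got = ks_two_sample(a, b).p_value
        assert got == pytest.approx(exact_p)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestNJ:
    def test_three_taxon_closed_form(self):
        # d(a,b)=3, d(a,c)=5, d(b,c)=6: star branches
        # la=(3+5-6)/2=1, lb=(3+6-5)/2=2, lc=(5+6-3)/2=4
        dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float),
                            ["a", "b", "c"])
        tree = build_nj_tree(dm)
        lengths = {t.name: t.distance(tree.root()) for t in tree.tips()}
        # pairwise path lengths must reproduce the input distances
        tips = {t.name: t for t in tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(3)
        assert tips["a"].distance(tips["c"]) == pytest.approx(5)
        assert tips["b"].distance(tips["c"]) == pytest.approx(6)

    def test_additive_four_taxon_topology(self):
        # additive matrix generated from ((a:1,b:2):1,(c:3,d:1));
        d = {("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 3,
             ("b", "c"): 6, ("b", "d"): 4, ("c", "d"): 4}
        ids = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = v
        tree = build_nj_tree(DistanceMatrix(m, ids))
        tips = {t.name: t for t in tree.tips()}
        for (x, y), v in d.items():
            assert tips[x].distance(tips[y]) == pytest.approx(v)

    def test_non_negative_branch_lengths(self, rng):
        for _ in range(10):
            pts = rng.random((6, 3))
            m = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            np.fill_diagonal(m, 0)
            tree = build_nj_tree(DistanceMatrix(m, [f"t{i}" for i in range(6)]))
            for node in tree.postorder(include_self=False):
                assert node.length is None or node.length >= 0

    def test_too_few_taxa_raises(self):
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"]))


def test_difference_distance_matrix_symmetric():
    dm = difference_distance_matrix(["AAAA", "AAAT", "TTTT"])
    assert dm.data[0, 1] == 1
    assert dm.data[0, 2] == 4
    np.testing.assert_array_equal(dm.data, dm.data.T)


def test_bonferroni_matches_reporting_convention():
    # 28 pairwise comparisons at family alpha ~0.05 -> per-test 0.002
    assert bonferroni_alpha(0.056, 28) == pytest.approx(0.002)
    assert round(bonferroni_alpha(0.05, 28), 3) == pytest.approx(0.002)
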