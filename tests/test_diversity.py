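"""Richness estimators, bottleneck arithmetic, saturation and pi."""

import numpy as np
import pytest

from sporeseg.alleles import RULE_CONSERVATIVE, RULE_CONVENTIONAL
from sporeseg.diversity import (
    DiversityEstimate,
    bottleneck,
    chao1,
    nucleotide_diversity_pi,
    rarefaction,
    saturation_mc,
    shared_chao1,
)


class TestChao1:
    def test_no_singletons_equals_observed(self):
        est = chao1([5, 3, 2])
        assert est.chao1 == est.s_obs == 3

    def test_bias_corrected_hand_arithmetic(self):
        # S=4, n1=2, n2=1: chao1 = 4 + 2*1/(2*2) = 4.5
        est = chao1([1, 1, 2, 5])
        assert est.s_obs == 4 and est.n1 == 2 and est.n2 == 1
        assert est.chao1 == pytest.approx(4.5)

    def test_matches_independent_implementation(self):
        # cross-check the point estimate against scikit-bio's chao1
        from skbio.diversity.alpha import chao1 as skbio_chao1
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = rng.integers(0, 20, size=rng.integers(3, 40))
            if counts.sum() == 0:
                continue
            ours = chao1(counts).chao1
            theirs = skbio_chao1(counts, bias_corrected=True)
            assert ours == pytest.approx(theirs)

    def test_ci_brackets_estimate_random_sweep(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            counts = rng.integers(0, 15, size=rng.integers(2, 60))
            if (counts > 0).sum() == 0:
                continue
            est = chao1(counts)
            assert est.chao1 >= est.s_obs
            assert est.lci <= est.chao1 <= est.hci
            assert est.lci >= est.s_obs

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            chao1([0, 0])


class TestRarefaction:
    def test_full_depth_is_observed_richness(self):
        counts = [4, 2, 1, 8]
        assert rarefaction(counts, [15])[0] == pytest.approx(4.0)

    def test_depth_one(self):
        assert rarefaction([3, 3, 9], [1])[0] == pytest.approx(1.0)

    def test_matches_monte_carlo_oracle(self):
        counts = np.array([4, 2, 1])
        n = 3
        exact = rarefaction(counts, [n])[0]
        rng = np.random.default_rng(0)
        pop = np.repeat(np.arange(3), counts)
        reps = 50_000
        keys = rng.random((reps, pop.size)).argsort(axis=1)[:, :n]
        distinct = np.array([np.unique(pop[k]).size for k in keys])
        mc, se = distinct.mean(), distinct.std() / np.sqrt(reps)
        assert abs(exact - mc) < 3 * se + 1e-9

    def test_concave_non_decreasing(self):
        counts = [10, 5, 3, 1, 1]
        vals = rarefaction(counts, list(range(1, 21)))
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-12)
        assert np.all(np.diff(diffs) <= 1e-9)

    def test_depth_beyond_total_raises(self):
        with pytest.raises(ValueError):
            rarefaction([2, 2], [5])


class TestBottleneck:
    def est(self, s, c, lo, hi):
        return DiversityEstimate(s_obs=s, n1=0, n2=0, chao1=c, lci=lo, hci=hi)

    def test_pooled_row_arithmetic(self):
        bn = bottleneck(356, self.est(356, 813, 664, 1036))
        assert bn.rounded() == (56, 46, 66)

    def test_high_diversity_spore_row(self):
        bn = bottleneck(152, self.est(152, 314, 240, 452))
        assert bn.rounded() == (52, 37, 66)

    def test_no_unseen_richness(self):
        bn = bottleneck(10, self.est(10, 10.0, 10.0, 10.0))
        assert bn.point_pct == pytest.approx(0.0)

    def test_scale_free_pure_arithmetic(self):
        a = bottleneck(50, self.est(50, 100.0, 80.0, 150.0))
        b = bottleneck(500, self.est(500, 1000.0, 800.0, 1500.0))
        assert a.point_pct == pytest.approx(b.point_pct)
        assert a.lower_pct == pytest.approx(b.lower_pct)

    def test_inconsistent_lci_raises(self):
        with pytest.raises(ValueError):
            bottleneck(100, self.est(100, 150.0, 90.0, 200.0))


class TestSharedChao1:
    def test_disjoint_supports(self):
        assert shared_chao1([3, 3, 0, 0], [0, 0, 2, 2]) == 0.0

    def test_identical_abundant_communities(self):
        # all shared abundances >= 3: no correction terms, estimate = S_obs
        assert shared_chao1([3, 4, 5], [5, 4, 3]) == pytest.approx(3.0)

    def test_hand_computed_correction(self):
        # shared species: indices 0..3. f1+ = 1 (index 3 singleton in A),
        # f+1 = 1 (index 2 singleton in B), f2+ = 1, f+2 = 1, f11 = 0
        a = [5, 4, 2, 1, 3, 0]
        b = [5, 4, 1, 3, 0, 2]
        expected = 4 + 1 / 2 + 1 / 2 + 0.0
        assert shared_chao1(a, b) == pytest.approx(expected)

    def test_symmetric(self, rng):
        for _ in range(25):
            a = rng.integers(0, 6, size=12)
            b = rng.integers(0, 6, size=12)
            if not ((a > 0) & (b > 0)).any():
                continue
            assert shared_chao1(a, b) == pytest.approx(shared_chao1(b, a))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            shared_chao1([1, 2], [1, 2, 3])


class TestSaturationMC:
    seqs = ["AAA"] * 6 + ["AAT"] * 3 + ["CCC"] * 2 + ["GGG"]

    def test_full_depth_deterministic(self):
        for rule in (RULE_CONVENTIONAL, RULE_CONSERVATIVE):
            curve = saturation_mc(self.seqs, [len(self.seqs)], n_reps=50,
                                  rule=rule, seed=1)
            full = curve.mean_distinct[0]
            assert curve.ci_half_width[0] == 0.0
            from sporeseg.alleles import call_variants
            assert full == call_variants(self.seqs, rule=rule).distinct_sequences

    def test_depth_one(self):
        curve = saturation_mc(self.seqs, [1], n_reps=20, seed=0)
        assert curve.mean_distinct[0] == pytest.approx(1.0)

    def test_means_non_decreasing_over_seeds(self):
        for seed in range(10):
            curve = saturation_mc(self.seqs, [1, 3, 6, 9, 12], n_reps=60,
                                  seed=seed)
            assert np.all(np.diff(curve.mean_distinct) >= -1e-12)

    def test_too_few_reps_raises(self):
        with pytest.raises(ValueError):
            saturation_mc(self.seqs, [2], n_reps=1)


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        starts, pi = nucleotide_diversity_pi(["ACGT" * 5] * 4, [1] * 4, window=5)
        assert np.allclose(pi, 0.0)

    def test_two_haplotype_closed_form(self):
        # two equifrequent sequences differing at 1 of 10 sites:
        # pi = 2 * 0.5 * 0.5 * (1/10) = 0.05 over one full-length window
        a = "AAAAAAAAAA"
        b = "AAAAAAAAAT"
        _, pi = nucleotide_diversity_pi([a, b], [1, 1], window=10)
        assert pi[0] == pytest.approx(0.05)

    def test_intron_concentrated_diversity(self):
        from sporeseg.simdata import generate_parent_pool
        pool = generate_parent_pool(40, amplicon_length=120,
                                    intron_mutation_bias=0.95, seed=9)
        counts = np.ones(pool.n_alleles)
        starts, pi = nucleotide_diversity_pi(pool.sequences, counts,
                                             window=10, step=10)
        intron = set(pool.region.intron_columns)
        in_intron = [v for s, v in zip(starts, pi)
                     if all(c in intron for c in range(s, s + 10))]
        in_exon = [v for s, v in zip(starts, pi)
                   if all(c not in intron for c in range(s, s + 10))]
        assert np.mean(in_intron) > np.mean(in_exon)

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError):
            nucleotide_diversity_pi(["ACGT"], [1], window=10)
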