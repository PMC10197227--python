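import itertools
import math

import numpy as np
import pytest

from pstfst.popgen import (
    allelic_richness,
    expected_heterozygosity,
    inbreeding_coefficient,
    ld_ne,
    multilocus_theta,
    observed_heterozygosity,
    wc_fst,
)
from pstfst.simulate import GenoSimConfig, simulate_genotypes

from conftest import make_geno, make_map, two_region_map
from wc_oracle import multilocus_theta_bruteforce


class TestHeterozygosity:
    def test_all_heterozygotes_give_ho_one(self):
        g = make_geno(np.ones((4, 3)))
        pmap = two_region_map(2)
        _, ho = observed_heterozygosity(g, pmap, "regA")
        assert ho == 1.0

    def test_monomorphic_locus_ho_zero(self):
        g = make_geno([[0, 1], [0, 1], [0, 1], [0, 1]])
        pmap = two_region_map(2)
        per_locus, _ = observed_heterozygosity(g, pmap, "regA",
                                               polymorphic_only=False)
        assert per_locus[0] == 0.0

    def test_toy_matrix_hand_count(self, toy_geno, toy_map):
        # regA = i1, i2: dosages [[0,1,2],[1,1,0]] -> het fractions 1/2, 1, 0
        per_locus, mean = observed_heterozygosity(toy_geno, toy_map, "regA")
        np.testing.assert_allclose(per_locus, [0.5, 1.0, 0.0])
        assert mean == pytest.approx((0.5 + 1.0 + 0.0) / 3)

    def test_he_half_at_balanced_frequency(self):
        g = make_geno([[0, 2], [2, 0], [1, 1], [1, 1]])
        pmap = two_region_map(2)
        per_locus, _ = expected_heterozygosity(g, pmap, "regA")
        np.testing.assert_allclose(per_locus, [0.5, 0.5])

    def test_he_zero_when_monomorphic(self):
        g = make_geno([[0, 1], [0, 1], [0, 1], [0, 1]])
        pmap = two_region_map(2)
        per_locus, _ = expected_heterozygosity(g, pmap, "regA",
                                               polymorphic_only=False)
        assert per_locus[0] == 0.0

    def test_missing_individual_changes_nothing(self, toy_geno, toy_map):
        import pandas as pd
        from pstfst.containers import GenotypeMatrix, PopulationMap
        g2 = GenotypeMatrix(
            np.vstack([toy_geno.dosage, np.full((1, 3), -1, dtype=np.int8)]),
            toy_geno.locus_meta, toy_geno.sample_ids + ["ghost"])
        rows = toy_map.table.rename_axis("individual").reset_index()
        rows.loc[len(rows)] = ["ghost", "popA", "regA", "native"]
        m2 = PopulationMap(rows.set_index("individual"))
        _, ho1 = observed_heterozygosity(toy_geno, toy_map, "regA")
        _, ho2 = observed_heterozygosity(g2, m2, "regA")
        assert ho1 == ho2
        assert (inbreeding_coefficient(toy_geno, toy_map, "regA")
                == inbreeding_coefficient(g2, m2, "regA"))


class TestAllelicRichness:
    def test_full_sample_equals_distinct_allele_count(self):
        g = make_geno([[0, 0], [1, 0], [2, 0], [1, 0]])
        pmap = two_region_map(2)
        per_locus, _ = allelic_richness(g, pmap, "regA", g_rarefaction=4)
        assert per_locus[0] == pytest.approx(2.0)   # both alleles present
        assert per_locus[1] == pytest.approx(1.0)   # monomorphic

    def test_monomorphic_ar_is_one_for_any_g(self):
        g = make_geno(np.zeros((6, 1)))
        pmap = two_region_map(3)
        for gr in (2, 4, 6):
            per_locus, _ = allelic_richness(g, pmap, "regA", g_rarefaction=gr)
            assert per_locus[0] == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        # one locus, N = 4 diploids, allele counts (6, 2), rarefy to g = 4
        g = make_geno([[1, 0], [1, 0], [0, 0], [0, 0]],
                      sample_ids=["a", "b", "c", "d"])
        pmap = make_map([(s, "p1", "r1", "native") for s in "abcd"])
        per_locus, _ = allelic_richness(g, pmap, "r1", g_rarefaction=4)
        alleles = [1, 1, 0, 0, 0, 0, 0, 0]   # 2 alt copies, 6 ref copies
        counts = [len(set(sub)) for sub in itertools.combinations(alleles, 4)]
        exact = sum(counts) / len(counts)
        assert per_locus[0] == pytest.approx(exact, abs=1e-12)

    def test_non_decreasing_in_rarefaction_size(self):
        g, pmap, _ = simulate_genotypes(GenoSimConfig(
            n_units=2, inds_per_pop=12, n_loci=100, seed=6))
        means = [allelic_richness(g, pmap, "region1", g_rarefaction=gr)[1]
                 for gr in (2, 6, 12, 24)]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_too_small_g_rejected(self, toy_geno, toy_map):
        with pytest.raises(ValueError):
            allelic_richness(toy_geno, toy_map, "regA", g_rarefaction=1)


class TestInbreedingCoefficient:
    def test_zero_when_ho_equals_he(self):
        # p = 0.5 with genotype counts at exact HWE: (1, 2, 1)
        g = make_geno([[0], [1], [1], [2]],
                      sample_ids=["a", "b", "c", "d"])
        pmap = make_map([(s, "p1", "r1", "native") for s in "abcd"])
        assert inbreeding_coefficient(g, pmap, "r1") == pytest.approx(0.0)

    def test_all_heterozygotes_give_minus_one(self):
        g = make_geno(np.ones((4, 2)))
        pmap = two_region_map(2)
        assert inbreeding_coefficient(g, pmap, "regA") == pytest.approx(-1.0)

    def test_monomorphic_unit_warns_and_returns_nan(self):
        g = make_geno(np.zeros((4, 2)))
        pmap = two_region_map(2)
        with pytest.warns(UserWarning, match="no polymorphic loci"):
            assert math.isnan(inbreeding_coefficient(g, pmap, "regA"))

    def test_ratio_of_sums_matches_brute_force(self, toy_geno, toy_map):
        n, p, h = [], [], []
        d = toy_geno.dosage[:2, :]  # regA
        ho_sum = he_sum = 0.0
        for l in range(3):
            col = d[:, l]
            freq = col.sum() / (2 * len(col))
            if 0 < freq < 1:
                ho_sum += (col == 1).mean()
                he_sum += 2 * freq * (1 - freq)
        expected = 1 - ho_sum / he_sum
        assert inbreeding_coefficient(toy_geno, toy_map, "regA") == pytest.approx(expected)


def geno_to_oracle_input(g, pmap, units, level="region"):
    by_locus = []
    for l in range(g.n_loci):
        locus = []
        for u in units:
            ids = set(pmap.individuals_in(level, u))
            rows = [i for i, s in enumerate(g.sample_ids) if s in ids]
            locus.append([int(d) if d != -1 else None
                          for d in g.dosage[rows, l]])
        by_locus.append(locus)
    return by_locus


class TestWcFst:
    def test_fixation_gives_theta_one(self):
        g = make_geno([[2, 2], [2, 2], [0, 0], [0, 0]])
        pmap = two_region_map(2)
        res = wc_fst(g, pmap, "regA", "regB", bootstrap_reps=0)
        assert res.theta == pytest.approx(1.0)

    def test_panmictic_pool_theta_near_zero(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), size=(48, 2000))
        g = make_geno(dosage)
        pmap = two_region_map(24)
        res = wc_fst(g, pmap, "regA", "regB", bootstrap_reps=0)
        assert abs(res.theta) < 0.01

    def test_symmetric_in_unit_order(self, rng):
        g, pmap, _ = simulate_genotypes(GenoSimConfig(
            n_units=2, inds_per_pop=10, n_loci=100, missing_rate=0.05, seed=4))
        r1 = wc_fst(g, pmap, "region1", "region2", bootstrap_reps=0)
        r2 = wc_fst(g, pmap, "region2", "region1", bootstrap_reps=0)
        assert r1.theta == pytest.approx(r2.theta, abs=1e-12)

    def test_locus_order_invariance(self):
        g, pmap, _ = simulate_genotypes(GenoSimConfig(
            n_units=2, inds_per_pop=10, n_loci=100, seed=4))
        perm = np.random.default_rng(1).permutation(g.n_loci)
        r1 = wc_fst(g, pmap, "region1", "region2", bootstrap_reps=0)
        r2 = wc_fst(g.subset_loci(perm), pmap, "region1", "region2",
                    bootstrap_reps=0)
        assert r1.theta == pytest.approx(r2.theta, abs=1e-12)

    def test_matches_bruteforce_oracle_with_missingness(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            dosage = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
            dosage[rng.random(dosage.shape) < 0.15] = -1
            g = make_geno(dosage)
            pmap = two_region_map(5)
            mine = wc_fst(g, pmap, "regA", "regB", bootstrap_reps=0).theta
            oracle = multilocus_theta_bruteforce(
                geno_to_oracle_input(g, pmap, ["regA", "regB"]))
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_bootstrap_ci_narrows_with_more_loci(self):
        widths = []
        for n_loci in (200, 2000):
            g, pmap, _ = simulate_genotypes(GenoSimConfig(
                n_units=2, inds_per_pop=24, n_loci=n_loci, F_neutral=0.05,
                seed=12))
            res = wc_fst(g, pmap, "region1", "region2", bootstrap_reps=400,
                         rng=np.random.default_rng(0))
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0]

    def test_too_few_usable_loci_rejected(self):
        g = make_geno([[0], [0], [0], [0]])
        pmap = two_region_map(2)
        with pytest.raises(ValueError, match="fewer than 2 usable loci"):
            wc_fst(g, pmap, "regA", "regB")


class TestLdNe:
    def test_single_polymorphic_locus_rejected(self):
        g = make_geno([[0, 1], [0, 1], [0, 0], [0, 1],
                       [0, 1], [0, 0], [0, 1], [0, 1],
                       [0, 0], [0, 1]])
        with pytest.raises(ValueError, match=">= 2 loci"):
            ld_ne(g)

    def test_no_drift_pool_estimates_huge_ne(self):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(100, 300))
        est = ld_ne(make_geno(dosage))
        assert math.isinf(est.ne) or est.ne > 1000

    def test_missing_data_handled_pairwise(self):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, rng.uniform(0.3, 0.7, 50), size=(30, 50)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.1] = -1
        est = ld_ne(make_geno(dosage))
        assert est.n_pairs > 0 and est.s_mean < 30

    def test_jackknife_ci_brackets_point_estimate(self):
        from pstfst.simulate import wright_fisher_sample
        rng = np.random.default_rng(8)
        dosage = wright_fisher_sample(50, 24, 150, 25, rng)
        est = ld_ne(make_geno(dosage), jackknife_ci=True)
        if math.isfinite(est.ne):
            assert est.ci_low <= est.ne <= est.ci_high
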