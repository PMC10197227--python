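import numpy as np
import pandas as pd
import pytest

from pstfst.io import apply_filters
from pstfst.outliers import (
    build_report,
    consensus_and_neutral_set,
    import_external_scan,
    pc_regression_scan,
    per_locus_fst_uncorrected,
    trimmed_chi2_scan,
)
from pstfst.popgen import multilocus_theta
from pstfst.simulate import GenoSimConfig, simulate_genotypes

from conftest import make_geno, two_region_map


class TestPerLocusFst:
    def test_fixation_near_one(self):
        g = make_geno([[2, 2], [2, 2], [0, 0], [0, 0]])
        pmap = two_region_map(2)
        stats = per_locus_fst_uncorrected(g, pmap)
        assert (stats["fst_uncorrected"] > 0.9).all()

    def test_panmictic_centered_near_zero(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 1000), size=(48, 1000))
        stats = per_locus_fst_uncorrected(make_geno(dosage), two_region_map(24))
        med = np.nanmedian(stats["fst_uncorrected"])
        assert abs(med) < 0.05

    def test_matches_direct_formula_on_toy(self):
        # 2 pops x 3 inds, balanced, no missing: hand-evaluate the
        # uncorrected components a = (nbar/nc) s2, b, c for one locus
        g = make_geno([[2], [2], [1], [0], [0], [1]],
                      sample_ids=[f"i{j}" for j in range(6)])
        pmap = two_region_map(3, ids=[f"i{j}" for j in range(6)])
        n = [3.0, 3.0]
        p = [5 / 6, 1 / 6]
        h = [1 / 3, 1 / 3]
        r, nbar = 2, 3.0
        nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * s2
        b = pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        c = hbar / 2
        expected = a / (a + b + c)
        got = per_locus_fst_uncorrected(g, pmap)["fst_uncorrected"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_locus_is_nan(self):
        g = make_geno([[0, 1], [0, 1], [0, 1], [0, 1]])
        stats = per_locus_fst_uncorrected(g, two_region_map(2))
        assert np.isnan(stats["fst_uncorrected"].iloc[0])

    def test_single_unit_rejected(self):
        g = make_geno([[0, 1], [1, 1]], sample_ids=["a", "b"])
        from conftest import make_map
        pmap = make_map([("a", "p", "r", "native"), ("b", "p", "r", "native")])
        with pytest.raises(ValueError, match=">= 2 units"):
            per_locus_fst_uncorrected(g, pmap)


class TestTrimmedChi2Scan:
    def test_constant_statistic_rejected(self):
        per_locus = pd.DataFrame({
            "fst_uncorrected": np.full(100, 0.05), "he": np.full(100, 0.3)})
        with pytest.raises(ValueError, match="degenerate"):
            trimmed_chi2_scan(per_locus)

    def test_low_he_loci_excluded_from_calls(self):
        rng = np.random.default_rng(0)
        per_locus = pd.DataFrame({
            "fst_uncorrected": rng.chisquare(5, 500) / 5 * 0.05,
            "he": np.r_[np.full(100, 0.05), np.full(400, 0.4)]})
        res = trimmed_chi2_scan(per_locus)
        assert res["q_value"][:100].isna().all()
        assert res["q_value"][100:].notna().all()

    def test_null_replicates_control_false_discoveries(self):
        flagged = total = 0
        for rep in range(10):
            g, pmap, _ = simulate_genotypes(GenoSimConfig(
                n_units=6, inds_per_pop=24, n_loci=500, F_neutral=0.05,
                seed=3000 + rep))
            res = trimmed_chi2_scan(per_locus_fst_uncorrected(g, pmap))
            q = res["q_value"].to_numpy()
            flagged += np.nansum(q < 0.05)
            total += np.isfinite(q).sum()
        assert flagged / total <= 0.01


class TestPcRegressionScan:
    def test_invalid_k_rejected(self):
        g, _, _ = simulate_genotypes(GenoSimConfig(
            n_units=2, inds_per_pop=5, n_loci=50, seed=1))
        with pytest.raises(ValueError):
            pc_regression_scan(g, K=0)
        with pytest.raises(ValueError):
            pc_regression_scan(g, K=10)

    def test_constant_locus_excluded(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.5, size=(40, 60)).astype(np.int8)
        dosage[:, 0] = 1
        res = pc_regression_scan(make_geno(dosage), K=2)
        assert np.isnan(res["q_value"].iloc[0])

    def test_null_replicates_control_false_discoveries(self):
        flagged = total = 0
        for rep in range(10):
            g, pmap, _ = simulate_genotypes(GenoSimConfig(
                n_units=6, inds_per_pop=24, n_loci=500, F_neutral=0.05,
                seed=4000 + rep))
            q = pc_regression_scan(g, K=5)["q_value"].to_numpy()
            flagged += np.nansum(q < 0.05)
            total += np.isfinite(q).sum()
        assert flagged / total <= 0.01


class TestExternalImport:
    def test_flags_merged(self, tmp_path):
        ids = [f"snp{l}" for l in range(2000)]
        path = tmp_path / "ext.tsv"
        path.write_text("id\tflag\n" + "".join(
            f"snp{l}\t1\n" for l in (3, 99, 500, 1500)))
        flags = import_external_scan(path, ids, "bayesian")
        assert flags.sum() == 4
        assert flags["snp99"]

    def test_unknown_ids_rejected(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("id\tflag\nnope\t1\n")
        with pytest.raises(ValueError, match="not in the dataset"):
            import_external_scan(path, ["snp1"], "x")

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("id\tflag\n")
        with pytest.warns(UserWarning, match="flags no loci"):
            flags = import_external_scan(path, ["snp1"], "x")
        assert flags.sum() == 0


class TestConsensus:
    def make_flags(self, n, flag_sets):
        idx = pd.Index([f"snp{l}" for l in range(n)])
        return pd.DataFrame(
            {m: idx.isin([f"snp{l}" for l in s]) for m, s in flag_sets.items()},
            index=idx)

    def test_neutral_set_arithmetic(self):
        # 2138 loci, 163 flagged by at least one method -> 1975 neutral
        flags = self.make_flags(2138, {
            "m1": range(0, 100), "m2": range(50, 150), "m3": range(140, 163)})
        table, outliers, neutral = consensus_and_neutral_set(flags, "any")
        assert len(outliers) == 163
        assert len(neutral) == 1975
        assert len(outliers) + len(neutral) == 2138

    def test_partition_property(self):
        flags = self.make_flags(50, {"m1": [1, 5], "m2": [5, 9]})
        table, outliers, neutral = consensus_and_neutral_set(flags, "any")
        assert set(outliers) | set(neutral) == set(table.index)
        assert not set(outliers) & set(neutral)

    def test_tiers(self):
        flags = self.make_flags(10, {"m1": [0, 1], "m2": [0, 2], "m3": [0]})
        table, _, _ = consensus_and_neutral_set(flags, "any")
        assert table.loc["snp0", "consensus_tier"] == "all-methods"
        assert table.loc["snp1", "consensus_tier"] == "one-method"
        assert table.loc["snp3", "consensus_tier"] == "none"

    def test_no_flags_means_all_neutral(self):
        flags = self.make_flags(20, {"m1": []})
        _, outliers, neutral = consensus_and_neutral_set(flags, "any")
        assert outliers == [] and len(neutral) == 20

    def test_rules(self):
        flags = self.make_flags(10, {"m1": [0, 1], "m2": [0]})
        _, any_out, _ = consensus_and_neutral_set(flags, "any")
        _, two_out, _ = consensus_and_neutral_set(flags, "at-least-2")
        assert set(any_out) == {"snp0", "snp1"}
        assert set(two_out) == {"snp0"}

    def test_unknown_rule_rejected(self):
        flags = self.make_flags(5, {"m1": [0]})
        with pytest.raises(ValueError):
            consensus_and_neutral_set(flags, "majority")


class TestEndToEndScan:
    def test_excluding_outliers_does_not_raise_theta(self):
        g, pmap, truth = simulate_genotypes(GenoSimConfig(
            n_units=6, inds_per_pop=24, n_loci=1000, F_neutral=0.05,
            selected_fraction=0.05, F_selected=0.5, seed=21))
        g_f, _ = apply_filters(g, pmap)
        report = build_report(g_f, pmap)
        theta_all = multilocus_theta(g_f, pmap)
        g_neutral = g_f.subset_loci(report.neutral_indices(g_f.locus_meta["id"]))
        theta_neutral = multilocus_theta(g_neutral, pmap)
        assert theta_neutral <= theta_all + 1e-9

    def test_report_columns_and_partition(self):
        g, pmap, _ = simulate_genotypes(GenoSimConfig(
            n_units=4, inds_per_pop=12, n_loci=300, F_neutral=0.05, seed=2))
        report = build_report(g, pmap)
        t = report.table
        for col in ("fst_uncorrected", "he", "chi2_q_value", "pca_q_value",
                    "consensus_tier", "consensus_outlier"):
            assert col in t.columns
        assert len(report.neutral_ids) + len(report.outlier_ids) == g.n_loci
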