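"""Expression-screen QC statistics, FDR adjustment and DEG filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from effluxkit import expression
from effluxkit.expression import (
    bh_adjust,
    deg_filter,
    log_cpm,
    outlier_stats,
    two_group_test,
)
from effluxkit.simulate import SyntheticTruth, gen_counts, gen_study


class TestLogCPM:
    def test_proportional_samples_have_matching_columns(self):
        # scale invariance up to the (small) pseudocount contribution
        counts = pd.DataFrame({"s1": [1000, 2000, 7000],
                               "s2": [3000, 6000, 21000]})
        le = log_cpm(counts)
        np.testing.assert_allclose(le["s1"], le["s2"], atol=1e-3)
        exact = log_cpm(counts, pseudocount=1e-12)
        np.testing.assert_allclose(exact["s1"], exact["s2"], atol=1e-9)

    def test_known_value(self):
        counts = pd.DataFrame({"s": [100, 10 ** 6 - 100]})
        le = log_cpm(counts, pseudocount=0.5)
        expected = np.log2(1e6 * 100.5 / (1e6 + 1.0))
        assert le["s"].iloc[0] == pytest.approx(expected)

    def test_zero_library_raises(self):
        with pytest.raises(ValueError):
            log_cpm(pd.DataFrame({"s1": [0, 0]}))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_monotone_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestTwoGroupTest:
    def _toy(self):
        le = pd.DataFrame({"p1": [5.0], "p2": [6.0], "p3": [5.5],
                           "r1": [8.0], "r2": [9.0], "r3": [8.5]},
                          index=["gene1"])
        groups = pd.Series(["parental"] * 3 + ["resistant"] * 3,
                           index=le.columns)
        return le, groups

    def test_welch_matches_hand_computation(self):
        le, groups = self._toy()
        res = two_group_test(le, groups, method="welch")
        # m2-m1 = 3, pooled se = sqrt(1/6), df = 4 (hand-derived)
        assert res["t_stat"].iloc[0] == pytest.approx(7.3484692283, rel=1e-9)
        assert res["p_value"].iloc[0] == pytest.approx(0.001826260668, rel=1e-8)
        assert res["fold_change"].iloc[0] == pytest.approx(8.0)

    def test_identical_groups_fold_one_p_near_one(self, rng):
        vals = rng.normal(8, 1, size=50)
        le = pd.DataFrame({f"s{i}": vals for i in range(6)})
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=le.columns)
        res = two_group_test(le, groups, method="welch")
        assert np.allclose(res["fold_change"], 1.0)

    def test_moderated_power_for_8fold_shift(self):
        detected = 0
        n_seeds = 50
        for s in range(n_seeds):
            counts, samples = gen_counts(SyntheticTruth(seed=2000 + s),
                                         de_genes={"TARGET": 8.0})
            groups = samples.set_index("sample")["group"]
            table = deg_filter(two_group_test(log_cpm(counts), groups))
            detected += bool(table.loc["TARGET", "is_deg"])
        assert detected >= 0.95 * n_seeds

    def test_requires_two_groups_with_replicates(self):
        le, groups = self._toy()
        with pytest.raises(ValueError):
            two_group_test(le, groups.replace("resistant", "parental"))


class TestDEGFilter:
    def test_conjunction_of_fold_and_fdr(self):
        table = pd.DataFrame(
            {
                "log2_fold_change": [np.log2(3287), np.log2(1.9), 2.0, -3.0],
                "p_value": [1e-12, 1e-4, 0.05, 1e-6],
            },
            index=["ABCB1_like", "small_fold", "weak_p", "down_gene"],
        )
        out = deg_filter(table)
        assert bool(out.loc["ABCB1_like", "is_deg"])
        assert not bool(out.loc["small_fold", "is_deg"])    # fold below 2
        assert not bool(out.loc["weak_p", "is_deg"])        # q above 0.05
        assert bool(out.loc["down_gene", "is_deg"])         # symmetric down
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()

    def test_missing_columns_raise_schema_error(self):
        with pytest.raises(KeyError):
            deg_filter(pd.DataFrame({"log2_fold_change": [1.0]}))

    def test_abcb1_like_gene_is_top_fold_deg(self):
        for s in range(5):
            counts, samples = gen_counts(SyntheticTruth(seed=s))
            groups = samples.set_index("sample")["group"]
            table = deg_filter(two_group_test(log_cpm(counts), groups))
            degs = table[table["is_deg"]]
            assert len(degs) > 0
            assert degs["fold_change"].idxmax() == "ABCB1"

    def test_null_data_deg_rate_below_5pct(self):
        for s in range(5):
            counts, samples = gen_counts(SyntheticTruth(seed=900 + s),
                                         de_genes={})
            groups = samples.set_index("sample")["group"]
            table = deg_filter(two_group_test(log_cpm(counts), groups))
            assert table["is_deg"].mean() <= 0.05


class TestOutlierStats:
    def test_identical_samples_have_degenerate_stats_and_no_flags(self):
        col = np.arange(50, dtype=float)
        le = pd.DataFrame({f"s{i}": col for i in range(4)})
        report = outlier_stats(le)
        t = report.table
        assert np.allclose(t["sum_euclidean"], 0.0)
        assert np.allclose(t["mean_pearson"], 1.0)
        assert np.allclose(t["ks_stat"], 0.0)
        assert report.flagged_samples == []

    def test_clean_triplicate_design_produces_zero_flags(self):
        for s in range(3):
            study = gen_study(SyntheticTruth(seed=s))
            report = outlier_stats(log_cpm(study["counts"]))
            assert report.flagged_samples == []

    def test_permuted_sample_is_flagged_by_correlation_statistics(self, rng):
        study = gen_study(SyntheticTruth(seed=4))
        le = log_cpm(study["counts"])
        victim = le.columns[5]
        le[victim] = rng.permutation(le[victim].to_numpy())
        report = outlier_stats(le)
        assert victim in report.flagged_samples
        reasons = report.table.loc[victim, "reasons"]
        assert "mean_pearson" in reasons or "hoeffding_d" in reasons

    def test_flags_invariant_to_gene_and_sample_order(self, rng):
        study = gen_study(SyntheticTruth(seed=5))
        le = log_cpm(study["counts"])
        le.iloc[:, 3] = rng.permutation(le.iloc[:, 3].to_numpy())
        r1 = outlier_stats(le)
        shuffled = le.sample(frac=1.0, random_state=1)
        shuffled = shuffled[list(rng.permutation(le.columns))]
        r2 = outlier_stats(shuffled)
        assert set(r1.flagged_samples) == set(r2.flagged_samples)

    def test_fewer_than_three_samples_raise(self):
        le = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            outlier_stats(le)
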