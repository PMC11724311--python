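"""Benchmark summaries, cross-method standardization and failure rules."""

import numpy as np
import pandas as pd
import pytest

import qclus
from qclus.evaluation import FailureThresholds, flag_failures, standardize_across_methods, summarize


def summary_row(method, sample, n, mean_u=0.5, median_u=0.5):
    return {
        "method": method,
        "sample": sample,
        "n_retained": n,
        "mean_fraction_unspliced": mean_u,
        "median_fraction_unspliced": median_u,
        "mean_pct_mito": 5.0,
        "median_pct_mito": 4.0,
        "mean_total_counts": 4000.0,
        "median_total_counts": 3500.0,
        "mean_n_genes": 2000.0,
        "median_n_genes": 1800.0,
    }


class TestSummarize:
    def test_single_droplet_summary_equals_its_metrics(self, small_feature_table):
        mask = np.zeros(len(small_feature_table), dtype=bool)
        mask[10] = True
        row = summarize(mask, small_feature_table, "m", "s")
        droplet = small_feature_table.iloc[10]
        assert row["n_retained"] == 1
        assert row["mean_pct_mito"] == droplet["pct_mito"]
        assert row["median_fraction_unspliced"] == droplet["fraction_unspliced"]

    def test_empty_mask(self, small_feature_table):
        row = summarize(np.zeros(len(small_feature_table), dtype=bool), small_feature_table, "m", "s")
        assert row["n_retained"] == 0
        assert np.isnan(row["median_pct_mito"])

    def test_medians_match_sort_based_oracle(self, small_feature_table):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=len(small_feature_table)) < 0.4
        row = summarize(mask, small_feature_table, "m", "s")
        vals = np.sort(small_feature_table.loc[mask, "pct_mito"].to_numpy())
        n = len(vals)
        oracle = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
        assert row["median_pct_mito"] == pytest.approx(oracle)


class TestStandardize:
    def test_two_methods_z_scores(self):
        df = pd.DataFrame(
            [summary_row("A", "s1", 1000, mean_u=0.1), summary_row("B", "s1", 3000, mean_u=0.3)]
        )
        z = standardize_across_methods(df)
        np.testing.assert_allclose(z["mean_fraction_unspliced"].to_numpy(), [-1.0, 1.0])
        np.testing.assert_allclose(z["n_retained"].to_numpy(), [-1.0, 1.0])

    def test_constant_metric_maps_to_zero(self):
        df = pd.DataFrame([summary_row("A", "s1", 5), summary_row("B", "s1", 5)])
        z = standardize_across_methods(df)
        assert (z["n_retained"] == 0).all()

    def test_per_sample_mean_zero(self):
        rows = [
            summary_row("A", "s1", 1000, mean_u=0.2),
            summary_row("B", "s1", 2500, mean_u=0.6),
            summary_row("A", "s2", 9000, mean_u=0.7),
            summary_row("B", "s2", 100, mean_u=0.1),
        ]
        z = standardize_across_methods(pd.DataFrame(rows))
        for _, block in z.groupby("sample"):
            assert abs(block["mean_fraction_unspliced"].mean()) < 1e-12


class TestFailureRules:
    def test_low_nuclei_count_with_witness(self):
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 2000, mean_u=0.50),
                summary_row("B", "s1", 9000, mean_u=0.45),
            ]
        )
        flags = flag_failures(df)
        assert flags.to_dict("records") == [
            {"method": "A", "sample": "s1", "flag": "low_nuclei_count", "comparator": "B"}
        ]

    def test_low_count_requires_similar_quality_comparator(self):
        # comparator retains >4x but at a very different unspliced fraction
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 2000, mean_u=0.50),
                summary_row("B", "s1", 9000, mean_u=0.25),
            ]
        )
        assert flag_failures(df).empty

    def test_four_times_ratio_is_strict(self):
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 2000, mean_u=0.5),
                summary_row("B", "s1", 8000, mean_u=0.5),  # exactly 4x, not over
            ]
        )
        assert flag_failures(df).empty

    @pytest.mark.parametrize("n,flagged", [(30000, False), (30001, True)])
    def test_high_nuclei_count_boundary(self, n, flagged):
        df = pd.DataFrame([summary_row("A", "s1", n)])
        flags = flag_failures(df)
        assert ("high_nuclei_count" in flags["flag"].to_numpy()) == flagged

    def test_low_quality_with_witness(self):
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 5000, median_u=0.25),
                summary_row("B", "s1", 6000, median_u=0.50),
            ]
        )
        flags = flag_failures(df)
        assert flags.to_dict("records") == [
            {"method": "A", "sample": "s1", "flag": "low_quality", "comparator": "B"}
        ]

    def test_low_quality_needs_larger_comparator(self):
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 5000, median_u=0.25),
                summary_row("B", "s1", 4000, median_u=0.50),  # better but smaller
            ]
        )
        assert flag_failures(df).empty

    def test_multiple_flags_allowed(self):
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 31000, median_u=0.2),
                summary_row("B", "s1", 32000, median_u=0.5),
            ]
        )
        flags = flag_failures(df)
        a_flags = set(flags.loc[flags["method"] == "A", "flag"])
        assert a_flags == {"high_nuclei_count", "low_quality"}

    def test_relative_margin_mode(self):
        df = pd.DataFrame(
            [
                summary_row("A", "s1", 2000, mean_u=0.50),
                summary_row("B", "s1", 9000, mean_u=0.46),
            ]
        )
        th = FailureThresholds(margin_mode="relative")  # 10% of 0.46 = 0.046 < 0.04 diff
        flags = flag_failures(df, th)
        assert list(flags["flag"]) == ["low_nuclei_count"]

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        rows = [
            summary_row(f"M{i}", f"s{j}", int(rng.integers(100, 40000)),
                        mean_u=rng.uniform(0.1, 0.8), median_u=rng.uniform(0.1, 0.8))
            for i in range(4) for j in range(3)
        ]
        df = pd.DataFrame(rows)
        assert flag_failures(df).equals(flag_failures(df))
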