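import numpy as np
import pandas as pd
import pytest

from tlv.scaling import mva_scale
from tlv.trendline import (
    SCALE_FREE_STATS,
    build_trendline,
    compute_trendline_record,
    percentile_inclusive,
    quartile_segment_sizes,
    quartile_segment_slopes,
    stats_table,
)

import _oracles as oracle


class TestBuildTrendline:
    def test_sorts_ascending_with_provenance(self):
        t = build_trendline(pd.Series([5.0, 2.0, 9.0], index=["s1", "s2", "s3"]))
        assert t.sorted_values.tolist() == [2.0, 5.0, 9.0]
        assert t.sample_at_rank == ["s2", "s1", "s3"]

    def test_sorted_input_gives_identity_permutation(self):
        t = build_trendline(pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]))
        assert t.sample_at_rank == ["a", "b", "c"]

    def test_ties_broken_by_sample_id(self):
        t = build_trendline(pd.Series([3.0, 3.0], index=["s2", "s1"]))
        assert t.sample_at_rank == ["s1", "s2"]

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            build_trendline(pd.Series([1.0], index=["s1"]))


class TestPercentile:
    def test_inclusive_interpolation(self):
        # h = 0.75*(4-1)+1 = 3.25 -> between 3rd and 4th order statistics
        assert percentile_inclusive(np.array([1.0, 2.0, 3.0, 4.0]), 0.75) == 3.25

    @pytest.mark.parametrize("p,expected", [(0.0, 1.0), (1.0, 9.0), (0.5, 5.0)])
    def test_endpoints_and_midpoint(self, p, expected):
        assert percentile_inclusive(np.array([1.0, 5.0, 9.0]), p) == expected

    def test_two_point_midpoint(self):
        assert percentile_inclusive(np.array([1.0, 3.0]), 0.5) == 2.0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            percentile_inclusive(np.array([1.0]), 1.5)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            xs = rng.uniform(0, 100, size=rng.integers(2, 40))
            p = float(rng.uniform(0, 1))
            assert percentile_inclusive(np.sort(xs), p) == pytest.approx(
                oracle.percentile_inclusive(xs, p), rel=1e-12)


class TestTrendlineRecord:
    @pytest.mark.parametrize("mean,sd,cv_printed,decimals", [
        (10.52, 1.88, 17.9, 1),      # linear reference gene
        (26.88, 46.03, 171.24, 2),   # bimodal sex-linked gene
    ])
    def test_cv_matches_published_worked_examples(self, mean, sd, cv_printed,
                                                  decimals):
        """CV computed from vectors constructed to the printed mean/SD
        agrees with the printed percentages at their printed precision."""
        base = np.arange(35, dtype=float)
        base = (base - base.mean()) / base.std(ddof=1)
        values = pd.Series(mean + sd * base,
                           index=[f"s{i:02d}" for i in range(35)])
        rec = compute_trendline_record(build_trendline(values, "g"))
        assert rec["cv"] == pytest.approx(100 * sd / mean, rel=1e-12)
        assert round(rec["cv"], decimals) == pytest.approx(
            cv_printed, abs=0.5 * 10 ** -decimals + 1e-9)

    def test_exact_arithmetic_progression(self):
        values = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        rec = compute_trendline_record(build_trendline(values, "g"))
        assert rec["slope"] == pytest.approx(1.0)
        assert rec["r_squared"] == pytest.approx(1.0)
        assert rec["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_all_statistics_match_oracle_on_8_values(self, rng):
        xs = rng.uniform(1, 50, size=8)
        values = pd.Series(xs, index=[f"s{i}" for i in range(8)])
        rec = compute_trendline_record(build_trendline(values, "g"))
        s = np.sort(xs)
        expected = {
            "mean": oracle.mean(xs), "median": oracle.median(xs),
            "sd": oracle.sample_sd(xs), "cv": oracle.cv_percent(xs),
            "min": s[0], "max": s[-1], "range": s[-1] - s[0],
            "max_min_ratio": s[-1] / s[0],
            "q1_value": oracle.percentile_inclusive(xs, 0.25),
            "q3_value": oracle.percentile_inclusive(xs, 0.75),
            "range_over_median": (s[-1] - s[0]) / oracle.median(xs),
            "range_over_q3": (s[-1] - s[0]) / oracle.percentile_inclusive(xs, 0.75),
            "skewness": oracle.skewness(xs),
            "excess_kurtosis": oracle.excess_kurtosis(xs),
            "slope": oracle.least_squares_slope(list(s)),
            "r_squared": oracle.r_squared_vs_rank(list(s)),
        }
        for key, val in expected.items():
            assert rec[key] == pytest.approx(val, rel=1e-12), key

    def test_constant_gene_flagged_with_zeroed_stats(self):
        values = pd.Series([4.0] * 6, index=[f"s{i}" for i in range(6)])
        rec = compute_trendline_record(build_trendline(values, "g"))
        assert rec["sd"] == 0 and rec["cv"] == 0
        assert rec["slope"] == 0 and rec["r_squared"] == 0
        assert "constant" in rec["flags"]

    def test_zero_median_makes_range_over_median_infinite(self):
        values = pd.Series([0.0, 0.0, 0.0, 0.0, 2.0, 8.0],
                           index=[f"s{i}" for i in range(6)])
        rec = compute_trendline_record(build_trendline(values, "g"))
        assert np.isinf(rec["range_over_median"])
        assert np.isinf(rec["max_min_ratio"])
        assert "inf_range_over_median" in rec["flags"]


class TestQuartileSegments:
    def test_default_split_for_35_samples_is_9_17_9(self):
        assert quartile_segment_sizes(35) == (9, 17, 9)
        assert quartile_segment_sizes(16) == (4, 8, 4)

    def test_linear_trendline_has_unit_ratios(self):
        res = quartile_segment_slopes(np.arange(1.0, 21.0))
        assert res["ratio_q1"] == pytest.approx(1.0)
        assert res["ratio_q4"] == pytest.approx(1.0)

    def test_flat_middle_gives_infinite_ratio(self):
        y = np.concatenate([np.full(15, 5.0), [6.0, 7.0, 9.0, 12.0, 20.0]])
        res = quartile_segment_slopes(y)
        assert np.isinf(res["ratio_q4"])

    def test_tailed_20_point_vector_matches_oracle(self):
        """Values = rank, except the top five ranks are 10x steeper."""
        y = np.concatenate([np.arange(1.0, 16.0), np.arange(16.0, 21.0) * 10])
        res = quartile_segment_slopes(y)
        s1, s23, s4 = oracle.segment_slopes(list(y), 5)
        assert res["slope_q1"] == pytest.approx(s1, rel=1e-12)
        assert res["slope_q23"] == pytest.approx(s23, rel=1e-12)
        assert res["slope_q4"] == pytest.approx(s4, rel=1e-12)
        assert res["ratio_q4"] > 6

    def test_too_small_segment_is_error(self):
        # n=6 splits 2/2/2 and is the smallest legal input
        quartile_segment_slopes(np.arange(1.0, 7.0))
        with pytest.raises(ValueError):
            quartile_segment_slopes(np.arange(1.0, 6.0))


class TestStatsTable:
    def test_one_record_per_gene(self, toy_matrix):
        table = stats_table(toy_matrix)
        assert table.shape[0] == 3
        assert "constant" in table.loc["GB", "flags"]
        assert table.loc["GB", "cv"] == 0

    def test_scale_free_statistics_identical_raw_vs_mva(self, rng):
        values = rng.uniform(2, 200, size=(40, 20))
        m = pd.DataFrame(values, index=[f"g{i}" for i in range(40)],
                         columns=[f"s{j}" for j in range(20)])
        raw_stats = stats_table(m)
        mva_stats = stats_table(mva_scale(m))
        for stat in SCALE_FREE_STATS:
            np.testing.assert_allclose(
                raw_stats[stat], mva_stats[stat], rtol=1e-9,
                err_msg=f"{stat} not scale-invariant")

    def test_raw_mean_column_appended(self, toy_matrix):
        table = stats_table(mva_scale(toy_matrix), raw=toy_matrix)
        assert table.loc["GA", "raw_mean"] == pytest.approx(5.0)
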