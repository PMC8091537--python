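import numpy as np
import pandas as pd
import pytest

from tlv.correlation import (
    calibrate_thresholds,
    extract_cluster,
    pairwise_correlation,
    top_n_by_stat,
)

import _oracles as oracle


def _stats_frame(values: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"stat": pd.Series(values)})


class TestTopN:
    def test_largest_two_of_three(self):
        top = top_n_by_stat(_stats_frame({"A": 5, "B": 3, "C": 9}), "stat", n=2)
        assert top.gene_ids == ["C", "A"]
        assert top.threshold_value == 5

    def test_boundary_ties_included(self):
        top = top_n_by_stat(_stats_frame({"A": 5, "B": 5, "C": 9}), "stat", n=2)
        assert top.gene_ids == ["C", "A", "B"]
        assert top.threshold_value == 5

    def test_n_equal_to_gene_count(self):
        top = top_n_by_stat(_stats_frame({"A": 1, "B": 2, "C": 3}), "stat", n=3)
        assert set(top.gene_ids) == {"A", "B", "C"}

    def test_infinite_values_rank_first_nan_excluded(self):
        top = top_n_by_stat(
            _stats_frame({"A": 2.0, "B": np.inf, "C": np.nan, "D": 5.0}),
            "stat", n=2)
        assert top.gene_ids == ["B", "D"]

    def test_permutation_invariance(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 30))}
        frame = _stats_frame(values)
        shuffled = frame.sample(frac=1, random_state=7)
        assert (top_n_by_stat(frame, "stat", n=10).gene_ids
                == top_n_by_stat(shuffled, "stat", n=10).gene_ids)

    def test_smallest_direction(self):
        top = top_n_by_stat(_stats_frame({"A": 5, "B": 3, "C": 9}), "stat",
                            n=1, direction="smallest")
        assert top.gene_ids == ["B"]


class TestPairwiseCorrelation:
    def test_duplicated_gene_has_r_one(self):
        m = pd.DataFrame([[1.0, 2.0, 5.0], [1.0, 2.0, 5.0]],
                         index=["a", "b"], columns=["s1", "s2", "s3"])
        pairs = pairwise_correlation(m)
        assert pairs.loc[0, "r"] == pytest.approx(1.0)

    def test_negation_about_mean_has_r_minus_one(self):
        x = np.array([1.0, 4.0, 7.0, 2.0])
        m = pd.DataFrame([x, 2 * x.mean() - x], index=["a", "b"],
                         columns=[f"s{i}" for i in range(4)])
        pairs = pairwise_correlation(m)
        assert pairs.loc[0, "r"] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, size=(5, 12)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"s{j}" for j in range(12)])
        pairs = pairwise_correlation(m)
        assert len(pairs) == 10
        for _, row in pairs.iterrows():
            expected = oracle.pearson_r(
                list(m.loc[row.gene_a]), list(m.loc[row.gene_b]))
            assert row.r == pytest.approx(expected, rel=1e-12)

    def test_blockwise_equals_single_block(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, size=(30, 8)),
                         index=[f"g{i:02d}" for i in range(30)],
                         columns=[f"s{j}" for j in range(8)])
        small = pairwise_correlation(m, block_size=7)
        big = pairwise_correlation(m, block_size=1000)
        merged = small.merge(big, on=["gene_a", "gene_b"])
        assert np.allclose(merged["r_x"], merged["r_y"])

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            pairwise_correlation(m)


class TestCalibration:
    @staticmethod
    def _toy(rng):
        """10 genes: two perfectly correlated pairs among unstructured noise."""
        base = rng.uniform(0, 10, size=(10, 15))
        base[1] = 2.0 * base[0] + 1.0
        base[3] = 0.5 * base[2] + 3.0
        return pd.DataFrame(base, index=[f"g{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(15)])

    def test_target_four_selects_exactly_the_paired_genes(self, rng):
        subset = calibrate_thresholds(self._toy(rng), target_size=4)
        assert set(subset.selected_genes) == {"g0", "g1", "g2", "g3"}
        assert subset.hi <= 1.0

    def test_target_all_genes_uses_least_extreme_thresholds(self, rng):
        m = self._toy(rng)
        subset = calibrate_thresholds(m, target_size=10)
        assert len(subset.selected_genes) == 10

    def test_target_zero_gives_empty_set(self, rng):
        subset = calibrate_thresholds(self._toy(rng), target_size=0)
        assert subset.selected_genes == []
        assert subset.hi > 1.0

    def test_selection_size_monotone_in_target(self, rng):
        m = self._toy(rng)
        sizes = [len(calibrate_thresholds(m, target_size=t).selected_genes)
                 for t in range(0, 11, 2)]
        assert sizes == sorted(sizes)

    def test_matches_enumeration_oracle(self, rng):
        """The calibrated set is the smallest achievable >= target over the
        matched and one-tailed quantile-step grids, checked exhaustively."""
        m = self._toy(rng)
        corr = np.corrcoef(m.to_numpy())
        np.fill_diagonal(corr, np.nan)
        max_pos = np.nanmax(corr, axis=1)
        min_neg = np.nanmin(corr, axis=1)
        pos_sorted = np.sort(max_pos)[::-1]
        neg_sorted = np.sort(min_neg)
        for target in (2, 4, 6, 9):
            candidate_sizes = []
            for use_pos, use_neg in ((True, True), (True, False), (False, True)):
                for k in range(1, 11):
                    sel = np.zeros(10, dtype=bool)
                    if use_pos:
                        sel |= max_pos >= pos_sorted[k - 1]
                    if use_neg:
                        sel |= min_neg <= neg_sorted[k - 1]
                    if sel.sum() >= target:
                        candidate_sizes.append(int(sel.sum()))
                        break
            expected = min(candidate_sizes)
            subset = calibrate_thresholds(m, target_size=target)
            assert len(subset.selected_genes) == expected, target


class TestExtractCluster:
    def test_seed_and_duplicate_recovered(self, rng):
        base = rng.uniform(0, 10, size=(3, 10))
        base[1] = base[0]
        m = pd.DataFrame(base, index=["seed", "dup", "other"],
                         columns=[f"s{j}" for j in range(10)])
        assert extract_cluster(m, "seed", 0.99) == ["seed", "dup"]

    def test_unattainable_threshold_returns_seed_only(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, size=(4, 8)),
                         index=["seed", "a", "b", "c"],
                         columns=[f"s{j}" for j in range(8)])
        assert extract_cluster(m, "seed", 1.01) == ["seed"]

    def test_coexpression_module_recovered_from_noise(self, rng):
        """A 6-gene module sharing a latent profile (r ~ 0.98) among 30
        unstructured genes is recovered exactly from its seed."""
        latent = rng.uniform(1, 10, size=25)
        module = latent * rng.uniform(0.5, 2.0, size=(6, 1)) \
            + rng.normal(0, 0.15, size=(6, 25))
        noise = rng.uniform(1, 10, size=(30, 25))
        m = pd.DataFrame(
            np.vstack([module, noise]),
            index=[f"mod{i}" for i in range(6)] + [f"n{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(25)])
        cluster = extract_cluster(m, "mod0", 0.9)
        assert set(cluster) == {f"mod{i}" for i in range(6)}

    def test_constant_seed_is_error(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["seed", "a"], columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="constant"):
            extract_cluster(m, "seed", 0.5)
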