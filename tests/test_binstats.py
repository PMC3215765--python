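"""Adaptive binning, permutation tests, Bonferroni, chi-square homogeneity."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from domarch.binstats import (
    BinningConfig,
    adaptive_bins,
    bin_counts,
    binned_comparison,
    bonferroni_flags,
    chi2_homogeneity,
    permutation_test,
)


class TestAdaptiveBins:
    def test_symmetric_input_recovers_deciles(self):
        values = np.arange(1.0, 101.0)
        t = adaptive_bins(values, values, BinningConfig(n_bins=10))
        assert len(t) == 9
        assert np.allclose(t, [10.5, 20.5, 30.5, 40.5, 50.5, 60.5, 70.5, 80.5, 90.5])
        counts = bin_counts(values, t)
        assert (counts == 10).all()

    def test_initial_thresholds_average_the_category_quantiles(self):
        # two shifted uniform grids; each category's own equal-count cuts are
        # computed directly and averaged, the documented initialization
        a = np.linspace(0.0, 1.0, 41)
        b = np.linspace(0.5, 1.5, 41)
        cfg = BinningConfig(n_bins=4, min_fill_fraction=0.0001)

        def own_cuts(x):
            x = np.sort(x)
            cuts = [round(j * len(x) / 4) for j in (1, 2, 3)]
            return np.array([(x[c - 1] + x[c]) / 2 for c in cuts])

        expected = (own_cuts(a) + own_cuts(b)) / 2
        t = adaptive_bins(a, b, cfg)
        assert np.allclose(t, expected)

    def test_thresholds_partition_the_range(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 300), rng.normal(0.5, 1.2, 400)
        t = adaptive_bins(a, b, BinningConfig(n_bins=10))
        assert (np.diff(t) >= 0).all()
        assert bin_counts(a, t).sum() == len(a)
        assert bin_counts(b, t).sum() == len(b)

    def test_category_smaller_than_bin_count_is_error(self):
        with pytest.raises(ValueError, match="fewer"):
            adaptive_bins([1.0, 2.0], [1.0, 2.0, 3.0], BinningConfig(n_bins=3))

    def test_refinement_terminates_within_cap(self):
        rng = np.random.default_rng(11)
        a = np.concatenate([rng.uniform(0, 0.1, 500), rng.uniform(0.9, 1.0, 20)])
        b = rng.uniform(0, 1, 520)
        cfg = BinningConfig(n_bins=20, max_iterations=50)
        t = adaptive_bins(a, b, cfg)
        assert len(t) == 19 and (np.diff(t) >= 0).all()

    def test_refinement_grows_smallest_cell_on_skewed_data(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, 400)
        b = np.concatenate([rng.uniform(0, 0.2, 380), rng.uniform(0.2, 1.0, 20)])
        cfg = BinningConfig(n_bins=10)
        t = adaptive_bins(a, b, cfg)
        initial = (  # before refinement: pure averaged quantiles
            adaptive_bins(a, b, BinningConfig(n_bins=10, max_iterations=0))
        )
        smallest_before = min(bin_counts(a, initial).min(), bin_counts(b, initial).min())
        smallest_after = min(bin_counts(a, t).min(), bin_counts(b, t).min())
        assert smallest_after >= smallest_before


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert permutation_test(vals, vals, n_perm=200, rng=0) == 1.0

    def test_separated_groups_match_exhaustive_enumeration(self):
        a, b = [0.0] * 5, [9.0] * 5
        # exhaustive reference over all C(10,5)=252 label assignments
        pooled = a + b
        observed = abs(np.mean(a) - np.mean(b))
        count = sum(
            abs(np.mean(combo) - np.mean([pooled[i] for i in range(10) if i not in idx]))
            >= observed
            for idx, combo in (
                (set(ii), [pooled[i] for i in ii])
                for ii in itertools.combinations(range(10), 5)
            )
        )
        exact_p = count / 252  # = 2/252
        assert exact_p == pytest.approx(2 / 252)
        p = permutation_test(a, b, n_perm=1000, rng=1)
        assert p <= 0.03
        assert abs(p - exact_p) < 3 * math.sqrt(exact_p * (1 - exact_p) / 1000) + 1e-9

    def test_p_values_lie_on_the_permutation_grid(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 25)
            p = permutation_test(a, b, n_perm=100, rng=rng)
            assert abs(p * 100 - round(p * 100)) < 1e-9
            assert 0.0 <= p <= 1.0

    def test_plus_one_estimator(self):
        p = permutation_test([0.0] * 5, [9.0] * 5, n_perm=1000, rng=1, plus_one=True)
        assert p >= 1 / 1001

    def test_seed_determinism(self):
        a, b = list(range(10)), list(range(5, 15))
        assert permutation_test(a, b, rng=42) == permutation_test(a, b, rng=42)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])
        with pytest.raises(ValueError):
            permutation_test([1.0], [1.0], n_perm=0)


class TestBonferroni:
    def test_flags(self):
        assert bonferroni_flags([0.004], n_tests=10) == [True]
        assert bonferroni_flags([0.006], n_tests=10) == [False]
        assert bonferroni_flags([0.04], n_tests=1) == [True]

    def test_default_n_is_list_length(self):
        assert bonferroni_flags([0.004, 0.03]) == [True, False]


class TestChiSquare:
    def test_worked_two_by_two(self):
        res = chi2_homogeneity([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(4 * 25 / 15)  # 6.667 to 3 d.p.
        assert round(res.statistic, 3) == 6.667
        assert res.dof == 1
        assert not res.low_expected_warning

    def test_homogeneous_table_scores_zero(self):
        res = chi2_homogeneity([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.dof == 1

    def test_proportional_columns_with_sparse_row(self):
        res = chi2_homogeneity([[1, 1], [100, 100], [50, 50]])
        assert res.statistic == pytest.approx(0.0)
        assert res.low_expected_warning  # expected count 1 < 5

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = int(rng.integers(2, 6))
            table = rng.integers(1, 60, size=(m, 2))
            ours = chi2_homogeneity(table)
            ref_stat, ref_p, ref_dof, _ = chi2_contingency(table, correction=False)
            assert abs(ours.statistic - ref_stat) < 1e-9
            assert ours.dof == ref_dof
            assert ours.p_value == pytest.approx(ref_p, abs=1e-12)

    def test_row_exclusion_helper(self):
        table = [[10, 20], [20, 10], [1, 2]]
        res = chi2_homogeneity(table, row_names=["a", "b", "sparse"], exclude_rows=["sparse"])
        assert res.dof == 1
        assert res.statistic == pytest.approx(4 * 25 / 15)

    def test_warning_fires_exactly_below_five(self):
        # expected counts equal the table for proportional columns
        assert chi2_homogeneity([[5, 5], [50, 50]]).low_expected_warning is False
        assert chi2_homogeneity([[4, 4], [50, 50]]).low_expected_warning is True

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            chi2_homogeneity([[0, 0], [0, 0]])


class TestBinnedComparison:
    def test_skipped_bins_flagged_on_sparse_category(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, 2000)
        b = np.concatenate([rng.uniform(0, 0.3, 195), rng.uniform(0.9, 1.0, 5)])
        cfg = BinningConfig(n_bins=100, max_iterations=5)
        out = binned_comparison(a, a, b, b, cfg, n_perm=20, rng=0)
        assert any(bin_.skipped for bin_ in out.bins)
        for bin_ in out.bins:
            if bin_.skipped:
                assert math.isnan(bin_.raw_p) and not bin_.significant

    def test_bins_partition_and_count_everything(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 1, 100), rng.uniform(0, 1, 120)
        out = binned_comparison(a, a * 0 + 1, b, b * 0, BinningConfig(n_bins=5), n_perm=50, rng=0)
        assert sum(x.count_a for x in out.bins) == 100
        assert sum(x.count_b for x in out.bins) == 120
        lowers = [x.lower for x in out.bins]
        uppers = [x.upper for x in out.bins]
        assert lowers[1:] == uppers[:-1]  # contiguous
        assert all(x.significant for x in out.bins if not x.skipped)  # 1 vs 0 scores
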