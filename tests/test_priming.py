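"""Priming statistics: quantile bins, rank tests, grids, group comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats

from zgaprime.priming import (bound_site_effect_by_combination, priming_grid,
                              mutant_effect_by_target, quantile_bins,
                              quintile_outcome, tf_enrichment_by_bin,
                              wilcoxon_one_sided)


class TestQuantileBins:
    def test_sizes_differ_by_at_most_one(self, rng):
        for n in (10, 23, 57, 100):
            b = quantile_bins(rng.random(n), 5)
            sizes = np.bincount(b)[1:]
            assert sizes.max() - sizes.min() <= 1

    def test_ten_items_two_per_bin(self, rng):
        b = quantile_bins(rng.random(10), 5)
        assert np.bincount(b)[1:].tolist() == [2, 2, 2, 2, 2]

    def test_monotone_in_value(self, rng):
        x = rng.random(50)
        b = quantile_bins(x, 5)
        order = np.argsort(x)
        assert (np.diff(b[order]) >= 0).all()

    def test_permutation_invariant(self, rng):
        x = rng.random(40)
        ids = np.arange(40)
        perm = rng.permutation(40)
        b1 = quantile_bins(x, 5, ids=ids)
        b2 = quantile_bins(x[perm], 5, ids=ids[perm])
        np.testing.assert_array_equal(b1[perm], b2)

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            quantile_bins([1.0, 2.0], 5)


class TestWilcoxon:
    def test_exact_p_fully_separated(self):
        # b = {4,5,6} vs a = {1,2,3}: only 1 of C(6,3)=20 rank assignments
        # puts b's ranks at the top, so one-sided p = 1/20
        cmp = wilcoxon_one_sided([4, 5, 6], [1, 2, 3], "greater")
        assert cmp.p_value == pytest.approx(1 / 20)

    def test_identical_samples_p_at_least_half(self):
        a = [1.0, 2.0, 3.0]
        assert wilcoxon_one_sided(a, a, "greater").p_value >= 0.5
        assert wilcoxon_one_sided(a, a, "less").p_value >= 0.5

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            cmp = wilcoxon_one_sided([2, 2], [2, 2, 2], "greater")
        assert cmp.p_value == 1.0

    def test_normal_approximation_close_to_exact_at_n8(self, rng):
        for _ in range(20):
            a = rng.normal(0.5, 1, 8)
            b = rng.normal(0, 1, 8)
            exact = wilcoxon_one_sided(a, b, "greater").p_value
            approx = wilcoxon_one_sided(a, b, "greater", exact_max_n=0).p_value
            if 0.01 < exact < 0.99:
                assert approx == pytest.approx(exact, rel=0.25, abs=0.02)

    def test_matches_brute_force_permutation_oracle(self, rng):
        """Exact p equals enumeration over all label permutations of the
        pooled values (independent oracle)."""
        for _ in range(10):
            a = rng.integers(0, 10, 5).astype(float)
            b = rng.integers(0, 10, 4).astype(float)
            got = wilcoxon_one_sided(a, b, "greater").p_value
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            obs = ranks[:5].sum()
            count = total = 0
            for idx in itertools.combinations(range(9), 5):
                total += 1
                if ranks[list(idx)].sum() >= obs - 1e-9:
                    count += 1
            assert got == pytest.approx(count / total)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1.0], "greater")


class TestQuintileOutcome:
    def test_planted_effect_monotone_medians(self, rng):
        n = 2000
        delta = rng.normal(1, 1, n)
        outcome = 1.5 + 1.0 * delta + rng.normal(0, 0.5, n)
        summary, tests = quintile_outcome(delta, outcome)
        assert (np.diff(summary["median_outcome"]) > 0).all()
        assert (tests["p_value"] < 0.01).all()

    def test_ten_items_bins_of_two(self, rng):
        summary, _ = quintile_outcome(rng.random(10), rng.random(10))
        assert summary["n"].tolist() == [2, 2, 2, 2, 2]

    def test_refuses_tiny_input(self, rng):
        with pytest.raises(ValueError):
            quintile_outcome(rng.random(5), rng.random(5))

    def test_null_adjacent_p_uniform(self, rng):
        """With no planted effect, adjacent-bin p-values are approximately
        uniform (KS test over repeated simulations not significant)."""
        pvals = []
        for _ in range(200):
            delta = rng.normal(size=200)
            outcome = rng.normal(size=200)
            _, tests = quintile_outcome(delta, outcome)
            pvals.append(tests["p_value"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPrimingGrid:
    def test_corner_cell_maximal_with_both_effects(self, rng):
        n = 3000
        delta = rng.normal(1, 1, n)
        loss = -rng.exponential(1, n)
        outcome = 2 + delta - loss + rng.normal(0, 0.3, n)
        grid, counts = priming_grid(delta, loss, outcome)
        am = np.unravel_index(np.nanargmax(grid.to_numpy()), grid.shape)
        assert am == (0, 4)   # largest loss row, largest increase column
        assert counts.to_numpy().sum() == n

    def test_null_cells_near_global_median(self, rng):
        n = 5000
        outcome = rng.normal(10, 1, n)
        grid, _ = priming_grid(rng.normal(size=n), rng.normal(size=n), outcome)
        assert np.nanmax(np.abs(grid.to_numpy() - np.median(outcome))) < 0.35

    def test_zscore_variant_normalized_before_aggregation(self, rng):
        n = 500
        sig = rng.normal(100, 20, n)
        grid, counts = priming_grid(rng.normal(size=n), rng.normal(size=n), sig,
                                    statistic="zscore")
        # weighted mean of cell means over counts = grand z mean = 0
        assert abs(np.nansum(grid.to_numpy() * counts.to_numpy()) / n) < 1e-9

    def test_transposing_covariates_transposes_grid(self, rng):
        n = 400
        x, y, o = rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        g1, _ = priming_grid(x, y, o)
        g2, _ = priming_grid(y, x, o)
        np.testing.assert_allclose(g1.to_numpy(), g2.to_numpy().T)


class TestTfEnrichment:
    def test_planted_binding_decreases_across_bins(self, rng):
        n = 1000
        loss = np.concatenate([-rng.exponential(2, 300), rng.normal(0, 0.2, 700)])
        signal = np.where(loss < -1, rng.lognormal(1.5, 0.3, n), rng.lognormal(0, 0.3, n))
        summary, tests = tf_enrichment_by_bin(loss, signal, normalization="genome_mean")
        med = summary["median_signal"].to_numpy()
        assert med[0] > med[-1]
        assert tests.loc[tests.index[-1], "p_value"] < 0.01   # bin1 vs bin5

    def test_null_mostly_non_significant(self, rng):
        hits = 0
        for _ in range(100):
            loss = rng.normal(size=100)
            signal = rng.lognormal(0, 0.3, 100)
            _, tests = tf_enrichment_by_bin(loss, signal, normalization="genome_mean")
            if tests["p_value"].iloc[-1] < 0.01:
                hits += 1
        assert hits <= 10

    def test_constant_signal_genome_mean_all_ones(self, rng):
        summary, _ = tf_enrichment_by_bin(rng.normal(size=50), np.full(50, 7.0),
                                          normalization="genome_mean")
        assert (summary["median_signal"] == 1.0).all()

    def test_missing_input_directs_to_genome_mean(self, rng):
        with pytest.raises(ValueError, match="genome_mean"):
            tf_enrichment_by_bin(rng.normal(size=50), rng.random(50),
                                 normalization="chip_over_input")


class TestGroupComparisons:
    def test_planted_regulated_depletion_detected(self, rng):
        reg = rng.normal(-2, 0.5, 150)
        nonreg = rng.normal(0, 0.5, 150)
        fc = np.concatenate([reg, nonreg])
        flag = np.array([True] * 150 + [False] * 150)
        cmp = mutant_effect_by_target(fc, flag)
        assert cmp.p_value < 0.01 and cmp.statistic < 0

    def test_shuffled_labels_null(self, rng):
        pvals = []
        for _ in range(50):
            fc = rng.normal(0, 1, 200)
            flag = rng.permutation([True] * 100 + [False] * 100)
            pvals.append(mutant_effect_by_target(fc, flag).p_value)
        assert (np.array(pvals) < 0.05).mean() < 0.2

    def test_identical_distributions_t_near_zero(self):
        fc = np.concatenate([np.arange(50.0), np.arange(50.0)])
        flag = np.array([True] * 50 + [False] * 50)
        assert abs(mutant_effect_by_target(fc, flag).statistic) < 1e-9

    def test_small_class_rejected(self, rng):
        with pytest.raises(ValueError):
            mutant_effect_by_target(rng.normal(size=10),
                                    [True] + [False] * 9)


class TestBoundCombinations:
    def test_psn_only_effect_detected(self, rng):
        sets, fc = [], []
        for combo, n in [(frozenset(), 200),
                         (frozenset({"Pou5f1"}), 50),
                         (frozenset({"Sox2"}), 50),
                         (frozenset({"Pou5f1", "Sox2", "Nanog"}), 50)]:
            sets.extend([combo] * n)
            planted = -2.0 if len(combo) == 3 else 0.0
            fc.extend(rng.normal(planted, 0.3, n))
        summary, tests = bound_site_effect_by_combination(np.array(fc), sets)
        s = summary.set_index("combination")
        assert s.loc["PSN", "median_log2fc"] < s.loc["P", "median_log2fc"] - 1
        t = tests.set_index("group")
        assert t.loc["PSN", "p_value"] < 0.01
        assert t.loc["P", "p_value"] > 0.01

    def test_unbound_reference_median_near_zero(self, rng):
        sets = [frozenset()] * 100 + [frozenset({"Nanog"})] * 30
        fc = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(-1, 0.1, 30)])
        summary, _ = bound_site_effect_by_combination(fc, sets)
        med = summary.set_index("combination").loc["unbound", "median_log2fc"]
        assert abs(med) < 0.1

    def test_empty_combinations_skipped(self, rng):
        sets = [frozenset({"Pou5f1"})] * 20 + [frozenset()] * 20
        summary, _ = bound_site_effect_by_combination(rng.normal(size=40), sets)
        assert set(summary["combination"]) == {"unbound", "P"}
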