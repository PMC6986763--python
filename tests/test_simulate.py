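"""Synthetic-data generator: determinism, placement rules, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zgaprime.simulate import (DEFAULT_REPLICATES, SimulationConfig,
                               generate_annotation, generate_chip_and_sequence,
                               generate_control_fragments, generate_expression,
                               generate_fragments)


class TestConfig:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert len(cfg.stages) == 7
        assert cfg.n_replicates_per_stage == DEFAULT_REPLICATES

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(stages=("only",))
        with pytest.raises(ValueError):
            SimulationConfig(cluster_profiles=np.array([[1.0, -1.0]]),
                             stages=("a", "b"),
                             n_replicates_per_stage={"a": 1, "b": 1})


class TestAnnotation:
    def test_counts_match_config(self, small_config, small_truth):
        assert len(small_truth.genes) == small_config.n_genes
        assert len(small_truth.regions) == small_config.n_regions

    def test_deterministic_under_seed(self, small_config):
        t1 = generate_annotation(small_config)
        t2 = generate_annotation(small_config)
        pd.testing.assert_frame_equal(t1.regions, t2.regions)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)

    def test_all_enhancers_distal_from_every_tss(self):
        cfg = SimulationConfig(seed=3, n_genes=20, n_regions=40,
                               fraction_enhancer=1.0)
        truth = generate_annotation(cfg)
        tss = truth.genes["tss"].to_numpy()
        chroms = truth.genes["chrom"].to_numpy()
        for row in truth.regions.itertuples():
            same = tss[chroms == row.chrom]
            # brute-force pairwise distance check
            d = np.where((same >= row.start) & (same < row.end), 0,
                         np.minimum(np.abs(same - row.start),
                                    np.abs(same - (row.end - 1))))
            assert d.min() >= 1000

    def test_promoter_regions_near_tss(self, small_truth):
        prom = small_truth.regions[~small_truth.regions["is_enhancer"]]
        genes = small_truth.genes.set_index("gene_id")
        for row in prom.itertuples():
            tss = genes.loc[row.gene_id, "tss"]
            center = (row.start + row.end) // 2
            assert abs(center - tss) <= 1000

    def test_enhancers_carry_core_and_dev_binding(self, small_truth):
        from zgaprime.simulate import CORE_TFS, DEVELOPMENTAL_TFS
        enh = small_truth.regions[small_truth.regions["is_enhancer"]]
        for bound in enh["bound_by"]:
            tfs = set(bound.split(","))
            assert tfs & set(CORE_TFS)
            assert tfs & set(DEVELOPMENTAL_TFS)

    def test_links_respect_20kb(self, small_truth):
        assert (small_truth.links["distance"].abs() <= 20_000).all()

    def test_too_short_chromosome_raises(self):
        with pytest.raises(ValueError, match="too short"):
            generate_annotation(SimulationConfig(n_genes=200, n_chroms=1,
                                                 chrom_length=1_000_000))


class TestFragments:
    def test_deterministic_under_seed(self, small_config, small_truth):
        f1 = generate_fragments(small_config, small_truth, ("wt", "oblong"))
        f2 = generate_fragments(small_config, small_truth, ("wt", "oblong"))
        for k in f1:
            pd.testing.assert_frame_equal(f1[k], f2[k])

    def test_replicate_structure(self, small_config, small_truth):
        f = generate_fragments(small_config, small_truth, ("wt", "dome"))
        assert len(f) == DEFAULT_REPLICATES["dome"]

    def test_zero_depth_empty(self, small_truth, small_config):
        cfg = small_config.with_(fragment_depth=0)
        f = generate_fragments(cfg, small_truth, ("wt", "oblong"))
        assert all(len(df) == 0 for df in f.values())

    def test_unknown_condition_rejected(self, small_config, small_truth):
        with pytest.raises(ValueError):
            generate_fragments(small_config, small_truth, ("wt", "nosuch"))
        with pytest.raises(ValueError):
            generate_fragments(small_config, small_truth, ("mutant", "MZother"))

    def test_flat_trajectory_stage_means_equal(self):
        """Monte-Carlo: per-stage empirical means of a flat-trajectory
        region agree within 3 SE over >= 50 replicate draws."""
        cfg = SimulationConfig(seed=5, n_genes=12, n_regions=24,
                               chrom_length=1_200_000, n_chroms=1,
                               fragment_depth=20_000, noise_sd=0.0,
                               stages=("a", "b", "c"),
                               n_replicates_per_stage={"a": 1, "b": 1, "c": 1},
                               cluster_profiles=np.array([[2.0, 2.0, 2.0]]))
        truth = generate_annotation(cfg)
        region = truth.regions.iloc[0]
        means = {}
        for stage in cfg.stages:
            counts = []
            for i in range(50):
                f = generate_fragments(cfg.with_(seed=100 + i), truth, ("wt", stage))
                df = next(iter(f.values()))
                sel = (df["chrom"] == region.chrom) & \
                      (df["start"] < region.end) & (df["end"] > region.start)
                counts.append(int(sel.sum()))
            means[stage] = (np.mean(counts), np.std(counts) / np.sqrt(len(counts)))
        vals = [m for m, _ in means.values()]
        ses = [s for _, s in means.values()]
        for i in range(1, len(vals)):
            assert abs(vals[i] - vals[0]) <= 3 * (ses[i] + ses[0])

    def test_null_mutant_indistinguishable(self):
        """mutant_effect = 0: region counts in mutant vs wild-type come
        from the same distribution (rank test non-significant in >= 95%
        of simulations at alpha = 0.01)."""
        cfg = SimulationConfig(seed=9, n_genes=12, n_regions=24, n_chroms=1,
                               chrom_length=1_200_000, fragment_depth=20_000,
                               mutant_effect=0.0)
        truth = generate_annotation(cfg)
        bound = truth.bound_sets().map(lambda b: "Pou5f1" in b).to_numpy()
        regions = truth.regions[bound]
        rejections = 0
        n_sims = 40
        for i in range(n_sims):
            c = cfg.with_(seed=200 + i)
            wt = generate_fragments(c, truth, ("wt", "oblong"))
            mu = generate_fragments(c, truth, ("mutant", "MZpou5f3"))
            def region_counts(samples):
                out = []
                for df in samples.values():
                    for r in regions.itertuples():
                        sel = (df["chrom"] == r.chrom) & \
                              (df["start"] < r.end) & (df["end"] > r.start)
                        out.append(int(sel.sum()))
                return out
            p = stats.mannwhitneyu(region_counts(wt), region_counts(mu)).pvalue
            rejections += p < 0.01
        assert rejections / n_sims <= 0.05

    def test_mutant_depletes_bound_regions(self, small_config, small_truth):
        wt = generate_fragments(small_config, small_truth, ("wt", "oblong"))
        mu = generate_fragments(small_config, small_truth, ("mutant", "MZnanog"))
        bound = small_truth.bound_sets().map(lambda b: "Nanog" in b).to_numpy()
        region = small_truth.regions[bound].iloc[0]

        def mean_count(samples):
            tot = 0
            for df in samples.values():
                sel = (df["chrom"] == region.chrom) & \
                      (df["start"] < region.end) & (df["end"] > region.start)
                tot += int(sel.sum())
            return tot / len(samples)
        assert mean_count(mu) < mean_count(wt) * 0.6

    def test_fragment_lengths_bimodal_around_cutoff(self, small_config, small_truth):
        f = generate_fragments(small_config, small_truth, ("wt", "shield"))
        df = next(iter(f.values()))
        lengths = (df["end"] - df["start"]) - 9  # planted adjusted length
        frac_nfr = (lengths <= 130).mean()
        assert 0.2 < frac_nfr < 0.9
        # both components present
        assert (lengths < 110).any() and (lengths > 160).any()

    def test_control_is_structureless(self, small_config, small_truth):
        ctrl = generate_control_fragments(small_config)
        regions = small_truth.regions
        width_total = (regions["end"] - regions["start"]).sum()
        genome = small_config.n_chroms * small_config.chrom_length
        in_regions = 0
        for r in regions.itertuples():
            sel = (ctrl["chrom"] == r.chrom) & (ctrl["start"] < r.end) & \
                  (ctrl["end"] > r.start)
            in_regions += int(sel.sum())
        frac = in_regions / len(ctrl)
        assert frac < 3 * width_total / genome + 0.02


class TestExpression:
    def test_never_expressed_below_cutoff(self, small_config, small_truth):
        expr = generate_expression(small_config, small_truth)
        silent = small_truth.genes["never_expressed"].to_numpy()
        sums = expr[list(small_config.stages)].sum(axis=1).to_numpy()
        assert (sums[silent] < 0.1).all()

    def test_zero_beta_no_correlation(self):
        cfg = SimulationConfig(seed=21, n_genes=500, n_regions=1000,
                               n_chroms=4, chrom_length=6_000_000,
                               priming_beta=0.0, bound_expression_boost=0.0)
        truth = generate_annotation(cfg)
        generate_expression(cfg, truth)
        g = truth.genes[~truth.genes["never_expressed"]]
        rho = stats.spearmanr(g["delta_access"], g["late_expression"]).statistic
        assert abs(rho) < 0.1

    def test_large_beta_small_noise_rank_correlation_near_one(self):
        cfg = SimulationConfig(seed=22, n_genes=300, n_regions=600,
                               n_chroms=2, chrom_length=7_000_000,
                               priming_beta=10.0, expression_noise_sd=1e-4,
                               bound_expression_boost=0.0,
                               fraction_never_expressed=0.0)
        truth = generate_annotation(cfg)
        generate_expression(cfg, truth)
        g = truth.genes
        rho = stats.spearmanr(g["delta_access"], g["late_expression"]).statistic
        # delta takes only 5 archetype values, so rank ties cap Spearman's
        # rho below 1 (~0.98 for 5 equal groups) even in the noiseless limit
        assert rho > 0.95


class TestChipAndSequence:
    def test_bound_regions_covered_by_their_tfs(self, small_truth, small_dataset):
        chip = small_dataset["chip"]
        for row in small_truth.regions.itertuples():
            bound = set(row.bound_by.split(",")) if row.bound_by else set()
            for tf, peaks in chip.items():
                overlaps = ((peaks["chrom"] == row.chrom) &
                            (peaks["start"] < row.end) &
                            (peaks["end"] > row.start)).any()
                if tf in bound:
                    assert overlaps, f"{tf} should cover {row.region_id}"

    def test_planted_motif_at_recorded_position(self, small_truth, small_dataset):
        from zgaprime.motifs import default_pwms
        pwms = default_pwms()
        seqs = small_dataset["seqs"]
        placements = small_truth.motif_positions
        assert len(placements) > 0
        for row in placements.itertuples():
            cons = pwms[row.motif_id].consensus
            assert seqs[row.region_id][row.offset: row.offset + len(cons)] == cons

    def test_unbound_signal_centered_at_one(self):
        cfg = SimulationConfig(seed=33, n_genes=300, n_regions=600, n_chroms=2,
                               chrom_length=7_000_000, fraction_enhancer=0.1)
        truth = generate_annotation(cfg)
        generate_expression(cfg, truth)
        _, signal, _ = generate_chip_and_sequence(cfg, truth)
        unbound = truth.bound_sets().map(lambda b: "Smad2" not in b).to_numpy()
        med = signal.loc[unbound, "Smad2"].median()
        assert 0.8 <= med <= 1.25
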