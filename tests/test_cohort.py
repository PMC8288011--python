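"""Synthetic cohort generator: determinism, calibration and channel model."""

import numpy as np
import pandas as pd
import pytest

from oxmeth import cohort
from oxmeth.cohort import (
    CnvPlant,
    CohortConfig,
    PlantSpec,
    channel_probs,
    classify_expression,
    make_truth,
    simulate_counts,
    simulate_depth_track,
    simulate_expression,
    simulate_genome,
    simulate_survival,
)
from oxmeth.intervals import merge_intervals


class TestGenome:
    def test_cpg_positions_valid_and_increasing(self, small_genome):
        for chrom, size in small_genome.chrom_sizes.items():
            pos = small_genome.cpg_pos[chrom]
            assert pos.min() >= 0 and pos.max() < size
            assert np.all(np.diff(pos) > 0)

    def test_same_seed_identical(self):
        g1 = simulate_genome(seed=5, n_chrom=1, chrom_len_bp=100_000)
        g2 = simulate_genome(seed=5, n_chrom=1, chrom_len_bp=100_000)
        assert g1.chrom_sizes == g2.chrom_sizes
        for c in g1.cpg_pos:
            assert np.array_equal(g1.cpg_pos[c], g2.cpg_pos[c])
        for cls in g1.catalog:
            pd.testing.assert_frame_equal(g1.catalog[cls], g2.catalog[cls])

    def test_shores_are_1kb_island_flanks(self, small_genome):
        islands = small_genome.catalog["CpG_island"]
        shores = small_genome.catalog["CpG_shore"]
        expected = set()
        for r in islands.itertuples(index=False):
            expected.add((r.chrom, r.start - 1_000, r.start))
            expected.add((r.chrom, r.end, r.end + 1_000))
        got = {(r.chrom, r.start, r.end) for r in shores.itertuples(index=False)}
        assert got == expected

    def test_no_self_overlap_within_class(self, small_genome):
        for cls, df in small_genome.catalog.items():
            merged = merge_intervals(df)
            # merging must not reduce the interval count (no overlaps/abutments
            # collapsed) except for classes built via merge already
            assert (merged["end"] - merged["start"]).sum() == \
                (df["end"] - df["start"]).sum(), cls

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            simulate_genome(n_chrom=0)
        with pytest.raises(ValueError):
            simulate_genome(chrom_len_bp=5_000)


class TestTruth:
    def test_background_means_match_config(self):
        genome = simulate_genome(seed=2, n_chrom=1, chrom_len_bp=1_000_000)
        cfg = CohortConfig(n_per_stage=1, seed=2)
        truth, _ = make_truth(cfg, genome)
        for sample, tr in truth.items():
            stage = sample.rsplit("_", 1)[0]
            assert len(tr) >= 10_000
            assert tr["p_m"].mean() == pytest.approx(cfg.stage_mean_5mC[stage], abs=0.01)
            assert tr["p_h"].mean() == pytest.approx(cfg.stage_mean_5hmC[stage], abs=0.01)
            total = (tr["p_u"] + tr["p_m"] + tr["p_h"]).to_numpy()
            assert np.allclose(total, 1.0, atol=1e-12)

    def test_planted_effect_recovered(self, small_genome):
        cfg = CohortConfig(n_per_stage=1, seed=3)
        spec = PlantSpec(n_cpg=400, effect=0.2, direction="hypo", channel="5mC",
                         stages=("CC",))
        truth, plants = make_truth(cfg, small_genome, [spec])
        tr = truth["CC_1"]
        pl = plants.iloc[0]
        in_plant = (tr["chrom"] == pl.chrom) & (tr["pos"] >= pl.start) & (tr["pos"] < pl.end)
        diff = tr.loc[in_plant, "p_m"].mean() - tr.loc[~in_plant, "p_m"].mean()
        assert diff == pytest.approx(-0.2, abs=0.02)

    def test_effect_clipping_warns(self, small_genome):
        cfg = CohortConfig(n_per_stage=1, seed=4)
        spec = PlantSpec(n_cpg=10, effect=0.9, direction="hyper", channel="5mC",
                         stages=("healthy",))
        with pytest.warns(UserWarning):
            make_truth(cfg, small_genome, [spec])

    def test_bs_channel_never_below_oxbs_in_expectation(self, small_genome):
        cfg = CohortConfig(n_per_stage=1, seed=5)
        truth, _ = make_truth(cfg, small_genome)
        tr = truth["CIN3_1"]
        q_bs, q_ox = channel_probs(tr["p_u"], tr["p_m"], tr["p_h"],
                                   cfg.bs_conv, cfg.ox_conv)
        assert np.all(q_bs.to_numpy() >= q_ox.to_numpy() - 1e-15)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_stage=0)
        bad_m = dict(cohort.STAGE_MEAN_PRESETS["stage_list"]["5mC"], healthy=0.99)
        bad_h = dict(cohort.STAGE_MEAN_PRESETS["stage_list"]["5hmC"], healthy=0.5)
        with pytest.raises(ValueError):
            CohortConfig(stage_mean_5mC=bad_m, stage_mean_5hmC=bad_h)


class TestCounts:
    def test_counts_deterministic(self, small_genome):
        cfg = CohortConfig(n_per_stage=1, seed=6)
        truth, _ = make_truth(cfg, small_genome)
        c1 = simulate_counts(truth, cfg, genome=small_genome)
        c2 = simulate_counts(truth, cfg, genome=small_genome)
        for s in c1:
            pd.testing.assert_frame_equal(c1[s], c2[s])

    def test_spikein_channels_behave(self, small_genome):
        cfg = CohortConfig(n_per_stage=1, seed=7, depth_mean=30.0)
        truth, _ = make_truth(cfg, small_genome)
        counts = simulate_counts(truth, cfg, genome=small_genome)["healthy_1"]
        unmeth = counts[counts["chrom"] == cohort.SPIKE_UNMETH]
        hmc = counts[counts["chrom"] == cohort.SPIKE_HMC]
        # unmethylated control: BS beta ~ 1 - bs_conv
        assert unmeth["bs_meth"].sum() / unmeth["bs_depth"].sum() < 0.01
        # hydroxymethylated control: BS beta ~ 1, oxBS beta ~ 1 - ox_conv
        assert hmc["bs_meth"].sum() / hmc["bs_depth"].sum() > 0.99
        ox_beta = hmc["ox_meth"].sum() / hmc["ox_depth"].sum()
        assert ox_beta == pytest.approx(1 - cfg.ox_conv, abs=0.01)

    def test_zero_depth_rows_retained(self, small_genome):
        cfg = CohortConfig(n_per_stage=1, seed=8, depth_mean=1.0)
        truth, _ = make_truth(cfg, small_genome)
        counts = simulate_counts(truth, cfg)["healthy_1"]
        assert (counts["bs_depth"] == 0).any()
        assert len(counts) == len(truth["healthy_1"])


class TestDepthTrack:
    def test_baseline_poisson_mean(self):
        track, _ = simulate_depth_track({"chr1": 40_000_000}, [], bin_bp=33_000,
                                        baseline_depth=100.0, seed=1)
        assert len(track) >= 1_000
        assert track["depth"].mean() == pytest.approx(100.0, rel=0.03)

    @pytest.mark.parametrize("copy,ratio", [(4.0, 2.0), (1.0, 0.5)])
    def test_planted_ratio(self, copy, ratio):
        plant = CnvPlant("chr1", 20, 10, copy)
        track, truth = simulate_depth_track({"chr1": 3_000_000}, [plant],
                                            baseline_depth=200.0, seed=2)
        inside = track.iloc[20:30]["depth"].mean()
        outside = track.drop(track.index[20:30])["depth"].mean()
        assert inside / outside == pytest.approx(ratio, rel=0.1)
        assert truth.iloc[0]["copy_number"] == copy

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError):
            simulate_depth_track({"chr1": 3_000_000},
                                 [CnvPlant("chr1", 5, 10, 4.0), CnvPlant("chr1", 10, 5, 1.0)])


class TestExpressionSurvival:
    def test_noise_free_expression_perfectly_anticorrelated(self, rng):
        prom = pd.DataFrame({"s1": rng.uniform(0, 1, 50)}, index=[f"g{i}" for i in range(50)])
        expr = simulate_expression(prom, noise_sd=0.0, rng=rng)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(expr["s1"], prom["s1"])
        assert rho == pytest.approx(-1.0)

    def test_expression_classes(self):
        case = pd.Series([4.0, 1.0, 0.2], index=["a", "b", "c"])
        ref = pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"])
        assert list(classify_expression(case, ref)) == ["high", "no", "low"]

    def test_null_hazard_gives_uniform_logrank_p(self, rng):
        # hazard coefficient 0: log-rank p across replicates ~ Uniform(0,1)
        from oxmeth.survival import logrank_test

        ps = []
        for _ in range(60):
            marker = rng.normal(size=80)
            clin = simulate_survival(marker, log_hr=0.0, censor_time=5_000.0, rng=rng)
            hi = clin["marker"] > np.median(marker)
            _, p = logrank_test(clin["time"][hi], clin["event"][hi],
                                clin["time"][~hi], clin["event"][~hi])
            ps.append(p)
        # reject uniformity only on gross miscalibration
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_clinical_table_deterministic(self, rng):
        marker = np.linspace(0, 1, 30)
        a = simulate_survival(marker, rng=np.random.default_rng(9))
        b = simulate_survival(marker, rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)
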