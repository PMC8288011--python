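"""Bin tiling, CNV segmentation, z-scores, correlations and meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from oxmeth.cohort import CnvPlant, simulate_depth_track
from oxmeth.integration import (
    bin_genome,
    boundary_profile,
    cbs_copy_number,
    correlate_tracks,
    distance_correlation,
    m_value,
    normalize_variants,
    peak_meta_profile,
    variant_context_test,
    zscores,
)


class TestBinning:
    def test_tiling_with_terminal_partial_bin(self):
        bins = bin_genome({"chrA": 100_000}, 33_000)
        got = list(zip(bins["start"], bins["end"]))
        assert got == [(0, 33_000), (33_000, 66_000), (66_000, 99_000), (99_000, 100_000)]
        assert bins["partial"].to_list() == [False, False, False, True]

    def test_bin_count_and_conservation(self):
        for size in (1, 33_000, 66_001, 123_456):
            bins = bin_genome({"c": size}, 33_000)
            assert len(bins) == -(-size // 33_000)
            assert (bins["end"] - bins["start"]).sum() == size


class TestZscores:
    def test_formula_exactness(self):
        z = zscores([-1.0], [-2.0], [0.3], [0.1], sd_meth=0.5, sd_cnv=0.1)
        assert z["z_meth"][0] == pytest.approx(2.0, abs=1e-12)
        assert z["z_cnv"][0] == pytest.approx(2.0, abs=1e-12)

    def test_identical_tracks_zero(self, rng):
        m = rng.normal(size=50)
        r = rng.normal(size=50)
        z = zscores(m, m, r, r)
        assert np.allclose(z["z_meth"], 0.0)
        assert np.allclose(z["z_cnv"], 0.0)

    def test_m_value_log2_of_beta(self):
        assert m_value(0.5, eps=0.0) == pytest.approx(-1.0, abs=1e-12)
        assert m_value(0.5) == pytest.approx(-1.0, abs=1e-12)  # eps floors, not shifts
        assert m_value(0.0) == pytest.approx(np.log2(1e-3))

    def test_degenerate_sd_flagged(self):
        with pytest.warns(UserWarning):
            z = zscores([1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [0.0, 0.0])
        assert z["z_meth"].isna().all()


class TestCorrelation:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, _ = correlate_tracks(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_rank_closed_form(self):
        rho, _ = correlate_tracks([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5, abs=1e-12)

    def test_too_few_pairs(self):
        rho, p = correlate_tracks([1, 2], [2, 1])
        assert np.isnan(rho) and np.isnan(p)

    def test_independent_tracks_near_zero(self, rng):
        small = 0
        for _ in range(20):
            rho, _ = correlate_tracks(rng.normal(size=1_000), rng.normal(size=1_000))
            small += abs(rho) < 0.1
        assert small >= 19


class TestDistanceCorrelation:
    def test_scaled_copies(self, rng):
        cnv = rng.normal(size=(5, 40))
        rho, _ = distance_correlation(cnv, 3.0 * cnv)
        assert rho == pytest.approx(1.0)

    def test_two_samples_error(self, rng):
        with pytest.raises(ValueError):
            distance_correlation(rng.normal(size=(2, 10)), rng.normal(size=(2, 10)))

    def test_independent_profiles_centered_on_zero(self, rng):
        rhos = [distance_correlation(rng.normal(size=(6, 30)), rng.normal(size=(6, 30)))[0]
                for _ in range(40)]
        assert abs(np.mean(rhos)) < 0.15


class TestCnvSegmentation:
    def test_identical_tracks_single_neutral_segment(self):
        bins = bin_genome({"chr1": 33_000 * 50}, 33_000)
        depth = np.full(50, 200.0)
        segs = cbs_copy_number(depth, depth, bins)
        assert len(segs) == 1
        assert segs.iloc[0]["call"] == "neutral"
        assert segs.iloc[0]["copy_number"] == pytest.approx(2.0)

    def test_planted_gain_recovered(self, rng):
        bins = bin_genome({"chr1": 33_000 * 100}, 33_000)
        normal = rng.poisson(300, 100).astype(float)
        case = rng.poisson(300, 100).astype(float)
        case[40:50] = rng.poisson(600, 10)
        segs = cbs_copy_number(case, normal, bins)
        gains = segs[segs["call"] == "gain"]
        assert len(gains) == 1
        g = gains.iloc[0]
        covered = min(g["end"], 50 * 33_000) - max(g["start"], 40 * 33_000)
        assert covered >= 8 * 33_000

    def test_copy_2p5_is_neutral(self):
        bins = bin_genome({"chr1": 33_000 * 60}, 33_000)
        normal = np.full(60, 400.0)
        case = np.full(60, 400.0)
        case[20:40] = 500.0  # ratio 1.25 -> copy 2.5 after median norm (~)
        segs = cbs_copy_number(case, normal, bins)
        seg = segs[(segs["start"] <= 20 * 33_000) & (segs["end"] >= 40 * 33_000 - 1)]
        mid = segs[(segs["start"] >= 19 * 33_000) & (segs["end"] <= 41 * 33_000)]
        assert (mid["call"] == "neutral").all()

    def test_recovery_f1_on_generator_output(self):
        # planted gain (copy 4) and loss (copy 1) recovered bin-level F1 >= 0.9
        plants = [CnvPlant("chr1", 30, 10, 4.0), CnvPlant("chr1", 60, 10, 1.0)]
        f1s = []
        for seed in range(5):
            case, _ = simulate_depth_track({"chr1": 33_000 * 120}, plants,
                                           baseline_depth=50.0, seed=seed)
            normal, _ = simulate_depth_track({"chr1": 33_000 * 120}, [],
                                             baseline_depth=50.0, seed=seed + 100)
            bins = case[["chrom", "start", "end", "partial"]]
            segs = cbs_copy_number(case["depth"].astype(float),
                                   normal["depth"].astype(float), bins)
            truth = np.zeros(120, dtype=bool)
            truth[30:40] = truth[60:70] = True
            called = np.zeros(120, dtype=bool)
            for s in segs[segs["call"] != "neutral"].itertuples(index=False):
                called[s.start // 33_000:s.end // 33_000] = True
            tp = (truth & called).sum()
            fp = (~truth & called).sum()
            fn = (truth & ~called).sum()
            f1s.append(2 * tp / (2 * tp + fp + fn))
        assert np.mean(f1s) >= 0.9


class TestVariantContext:
    def test_strand_normalization(self):
        v = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1, 2],
                          "ref": ["G", "C"], "alt": ["T", "A"]})
        out = normalize_variants(v)
        assert list(out["mutation_type"]) == ["C>A", "C>A"]

    def test_known_table_odds_ratio(self):
        # [[8,2],[2,8]]: C>A among hmC+ vs others
        est = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(20),
            "p_m": 0.5, "p_h": [0.2] * 10 + [0.0] * 10,
        })
        alt = ["A"] * 8 + ["T"] * 2 + ["A"] * 2 + ["T"] * 8
        var = pd.DataFrame({"chrom": "chr1", "pos": np.arange(20), "ref": "C", "alt": alt})
        res = variant_context_test(var, est).set_index("mutation_type")
        row = res.loc["C>A"]
        assert row["odds_ratio"] == pytest.approx(16.0)
        assert row["p_fisher"] == pytest.approx(0.023, abs=0.002)

    def test_zero_cell_haldane(self):
        est = pd.DataFrame({"chrom": "chr1", "pos": np.arange(10),
                            "p_m": 0.5, "p_h": [0.2] * 5 + [0.0] * 5})
        var = pd.DataFrame({"chrom": "chr1", "pos": np.arange(10), "ref": "C",
                            "alt": ["A"] * 5 + ["T"] * 5})
        res = variant_context_test(var, est).set_index("mutation_type")
        assert np.isfinite(res.loc["C>A", "odds_ratio"])

    def test_uniform_distribution_or_one(self):
        est = pd.DataFrame({"chrom": "chr1", "pos": np.arange(40),
                            "p_m": 0.5, "p_h": ([0.2] * 10 + [0.0] * 10) * 2})
        alt = (["A"] * 5 + ["G"] * 5) * 4
        var = pd.DataFrame({"chrom": "chr1", "pos": np.arange(40), "ref": "C", "alt": alt})
        res = variant_context_test(var, est)
        assert np.allclose(res[res["mutation_type"] != "C>T"]["odds_ratio"], 1.0)


class TestProfiles:
    def _est(self, levels, positions, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": positions, "p_m": levels})

    def test_uniform_level_gives_flat_profile(self):
        pos = np.arange(0, 100_000, 97)
        est = self._est(np.full(len(pos), 0.7), pos)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [40_000], "end": [45_000]})
        prof = peak_meta_profile(est, peaks, flank_bp=15_000)
        vals = prof["mean_level"].dropna()
        assert np.allclose(vals, 0.7)

    def test_planted_dip_inside_peaks(self):
        pos = np.arange(0, 100_000, 97)
        lv = np.full(len(pos), 0.8)
        lv[(pos >= 40_000) & (pos < 45_000)] = 0.2
        prof = peak_meta_profile(self._est(lv, pos),
                                 pd.DataFrame({"chrom": ["chr1"], "start": [40_000], "end": [45_000]}))
        body = prof[prof["zone"] == "body"]["mean_level"].dropna()
        flank = prof[prof["zone"] != "body"]["mean_level"].dropna()
        assert body.mean() < flank.mean() - 0.3

    def test_zero_peaks_warns_empty(self):
        with pytest.warns(UserWarning):
            prof = peak_meta_profile(self._est([0.5], [10]),
                                     pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(prof) == 0

    def test_minus_strand_profile_is_mirrored(self):
        pos = np.arange(850, 1_150, 10)
        lv = np.linspace(0, 1, len(pos))  # gradient across the window
        est = self._est(lv, pos)
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000], "strand": ["+"], "gene": ["g"]})
        minus = plus.assign(strand="-")
        classes = {"g": "high"}
        a = boundary_profile(est, plus, classes)
        b = boundary_profile(est, minus, classes)
        av = a[a["expr_class"] == "high"]["mean_level"].to_numpy()
        bv = b[b["expr_class"] == "high"]["mean_level"].to_numpy()
        assert np.allclose(av, bv[::-1], equal_nan=True)

    def test_unknown_class_label_rejected(self):
        est = self._est([0.5], [10])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "strand": ["+"], "gene": ["g"]})
        with pytest.raises(ValueError):
            boundary_profile(est, anchors, {"g": "weird"})

    def test_empty_class_all_missing(self):
        est = self._est([0.5], [10])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "strand": ["+"], "gene": ["g"]})
        prof = boundary_profile(est, anchors, {"g": "high"})
        low = prof[prof["expr_class"] == "low"]
        assert low["mean_level"].isna().all()
        assert (low["n_sites"] == 0).all()
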