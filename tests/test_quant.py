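"""Beta values, conversion-rate estimation and the joint BS/oxBS MLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxmeth.quant import (
    ConversionRates,
    beta_value,
    estimate_conversion,
    mlml_estimate,
    mlml_table,
    summarize_genome,
)

from _oracles import grid_mle

PERFECT = ConversionRates(1.0, 1.0)
PAPERISH = ConversionRates(0.9992, 0.9657)


class TestBetaValue:
    @pytest.mark.parametrize("meth,total,expected", [(7, 10, 0.7), (0, 10, 0.0), (10, 10, 1.0)])
    def test_ratio(self, meth, total, expected):
        assert beta_value(meth, total) == pytest.approx(expected)

    def test_zero_depth_scalar_raises(self):
        with pytest.raises(ValueError):
            beta_value(3, 0)

    def test_zero_depth_vector_is_nan(self):
        out = beta_value(np.array([3, 0]), np.array([10, 0]))
        assert out[0] == pytest.approx(0.3)
        assert np.isnan(out[1])

    def test_meth_exceeding_total_is_data_error(self):
        with pytest.raises(ValueError):
            beta_value(11, 10)


class TestConversionEstimate:
    @pytest.mark.parametrize(
        "kind,meth_col,depth_col,meth,depth,expected",
        [
            ("unmethylated_bs", "bs_meth", "bs_depth", 8, 10_000, 0.9992),
            ("hydroxymethylated_ox", "ox_meth", "ox_depth", 343, 10_000, 0.9657),
            ("unmethylated_bs", "bs_meth", "bs_depth", 0, 500, 1.0),
        ],
    )
    def test_pooled_rate(self, kind, meth_col, depth_col, meth, depth, expected):
        df = pd.DataFrame({"bs_meth": [0], "bs_depth": [0], "ox_meth": [0], "ox_depth": [0]})
        df[meth_col] = [meth]
        df[depth_col] = [depth]
        assert estimate_conversion(df, kind) == pytest.approx(expected)

    def test_zero_depth_is_error(self):
        df = pd.DataFrame({"bs_meth": [0], "bs_depth": [0], "ox_meth": [0], "ox_depth": [0]})
        with pytest.raises(ValueError):
            estimate_conversion(df, "unmethylated_bs")


class TestMlml:
    def test_interior_moment_inversion(self):
        est = mlml_estimate(7, 10, 4, 10, PERFECT)
        assert (est.p_u, est.p_m, est.p_h) == pytest.approx((0.3, 0.4, 0.3))
        assert est.boundary == "interior"

    def test_negative_naive_hmc_pools_channels(self):
        # BS 3/10 vs oxBS 6/10: naive p_h < 0, MLE sits on the p_h=0 face
        est = mlml_estimate(3, 10, 6, 10, PERFECT)
        assert est.boundary == "h_zero"
        assert est.p_m == pytest.approx(9 / 20)
        assert est.p_u == pytest.approx(11 / 20)
        assert est.p_h == 0.0

    def test_pure_hydroxymethylation_corner(self):
        est = mlml_estimate(10, 10, 0, 10, PERFECT)
        assert (est.p_u, est.p_m, est.p_h) == pytest.approx((0.0, 0.0, 1.0))

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            mlml_estimate(0, 0, 1, 10)

    def test_matches_grid_search_random_configs(self, rng):
        # spot-check against the exhaustive lattice oracle (full-scale sweep
        # lives in the acceptance suite)
        for _ in range(60):
            bd, od = rng.integers(1, 60, 2)
            bm, om = rng.integers(0, bd + 1), rng.integers(0, od + 1)
            cb, co = rng.uniform(0.95, 1.0), rng.uniform(0.90, 1.0)
            pu, pm, ph = grid_mle(int(bm), int(bd), int(om), int(od), cb, co)
            est = mlml_estimate(int(bm), int(bd), int(om), int(od), ConversionRates(cb, co))
            assert abs(est.p_u - pu) < 2e-3
            assert abs(est.p_m - pm) < 2e-3
            assert abs(est.p_h - ph) < 2e-3

    @given(
        bd=st.integers(1, 100), od=st.integers(1, 100),
        bf=st.floats(0, 1), of=st.floats(0, 1),
        cb=st.floats(0.9, 1.0), co=st.floats(0.85, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_simplex_closure(self, bd, od, bf, of, cb, co):
        bm, om = int(round(bf * bd)), int(round(of * od))
        est = mlml_estimate(bm, bd, om, od, ConversionRates(cb, co))
        assert est.p_u + est.p_m + est.p_h == pytest.approx(1.0, abs=1e-9)
        for p in (est.p_u, est.p_m, est.p_h):
            assert -1e-12 <= p <= 1 + 1e-12

    def test_perfect_conversion_interior_identity(self, rng):
        # with perfect chemistry, interior solutions are exactly
        # p_m = oxBS beta and p_h = BS beta - oxBS beta
        bd = od = 50
        bm, om = 40, 25
        est = mlml_estimate(bm, bd, om, od, PERFECT)
        assert est.boundary == "interior"
        assert est.p_m == pytest.approx(om / od, abs=1e-12)
        assert est.p_h == pytest.approx(bm / bd - om / od, abs=1e-12)

    def test_consistency_mae_shrinks_with_depth(self, rng):
        # estimator is consistent: MAE on the truth decreases with coverage
        # and approaches the binomial-noise floor at depth 200
        n = 2000
        p_m = rng.uniform(0.2, 0.8, n)
        p_h = rng.uniform(0.0, 0.15, n)
        p_u = 1 - p_m - p_h
        cb, co = PAPERISH.bs_conv, PAPERISH.ox_conv
        q_bs = p_m + p_h + p_u * (1 - cb)
        q_ox = p_m + p_h * (1 - co) + p_u * (1 - cb)
        maes = {}
        for depth in (20, 200):
            bm = rng.binomial(depth, q_bs)
            om = rng.binomial(depth, q_ox)
            est = mlml_table(bm, np.full(n, depth), om, np.full(n, depth), PAPERISH)
            maes[depth] = (np.mean(np.abs(est["p_m"] - p_m)),
                           np.mean(np.abs(est["p_h"] - p_h)))
        assert maes[200][0] < maes[20][0] / 2
        assert maes[200][1] < maes[20][1] / 2
        assert maes[200][0] < 0.03 and maes[200][1] < 0.04


class TestSummarize:
    def test_no_hydroxymethylation_flags_empty_denominator(self):
        est = pd.DataFrame({"p_u": [0.5, 0.5], "p_m": [0.5, 0.5], "p_h": [0.0, 0.0],
                            "pass_qc": [True, True]})
        s = summarize_genome(est)
        assert s["mean_5hmC"] == 0.0
        assert np.isnan(s["frac_5hmC_pos_also_5mC"])

    def test_means_are_arithmetic(self):
        est = pd.DataFrame({"p_u": [0.1, 0.1], "p_m": [0.8, 0.6], "p_h": [0.1, 0.3],
                            "pass_qc": [True, True]})
        s = summarize_genome(est)
        assert s["mean_5mC"] == pytest.approx(0.7)
        assert s["mean_5hmC"] == pytest.approx(0.2)
        assert s["mc_over_hmc_ratio"] == pytest.approx(3.5)
        assert s["frac_5hmC_pos_also_5mC"] == 1.0

    def test_empty_input_warns(self):
        est = pd.DataFrame({"p_u": [], "p_m": [], "p_h": [], "pass_qc": []})
        with pytest.warns(UserWarning):
            s = summarize_genome(est)
        assert s["n_sites"] == 0


def test_low_conversion_rate_warns():
    with pytest.warns(UserWarning):
        ConversionRates(0.90, 0.99)
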