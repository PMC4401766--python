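"""Sensitivity-index arithmetic, Latin-Hypercube properties, partial
correlation (two routes + external oracle) and PCA summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliokin.model import PARAM_NAMES
from gliokin.sensitivity import (
    SWEEP_PARAMS,
    factor_ranges,
    initial_condition_sweep,
    lhs_sample,
    local_sweep,
    partial_correlation,
    pca_summary,
    run_lhs_growth,
    sensitivity_index,
    sensitivity_table,
)


class TestSensitivityIndex:
    def test_no_change_gives_zero(self):
        assert sensitivity_index(1000.0, 1000.0, 1000.0, 960.0, 10.0) == 0.0

    def test_direct_arithmetic(self):
        assert sensitivity_index(1100.0, 1000.0, 1000.0, 960.0, 10.0) \
            == pytest.approx(100.0 / 9_600_000.0)

    def test_invalid_denominator(self):
        for bad in [(0.0, 960.0, 10.0), (1.0, 0.0, 10.0), (1.0, 960.0, 0.0)]:
            with pytest.raises(ValueError):
                sensitivity_index(1.0, 2.0, *bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gd_n=st.floats(0, 1e5), gd_o=st.floats(0, 1e5))
    def test_symmetric_in_perturbation_direction(self, gd_n, gd_o):
        a = sensitivity_index(gd_n, gd_o, 1e5, 960.0, 10.0)
        b = sensitivity_index(gd_o, gd_n, 1e5, 960.0, 10.0)
        assert a == b >= 0.0


class TestLocalSweep:
    def test_factor_one_gives_zero_index(self, ln229):
        recs = local_sweep(ln229, "k11", [1.0], horizon=96.0)
        assert recs[0].index == pytest.approx(0.0, abs=1e-10)

    def test_records_satisfy_index_formula(self, ln229):
        recs = local_sweep(ln229, "k10", [0.1, 10.0], horizon=96.0)
        for r in recs:
            assert r.index == pytest.approx(
                abs(r.gd_n - r.gd_o) / (r.normalizer * r.horizon * r.factor))
        # shared normalizer across the sweep, >= every final diameter
        assert len({r.normalizer for r in recs}) == 1
        assert recs[0].normalizer >= max(r.gd_n for r in recs)

    def test_unknown_parameter(self, ln229):
        with pytest.raises(KeyError):
            local_sweep(ln229, "k99", [10.0])

    def test_table_covers_13_constants(self, ln229):
        df = sensitivity_table(ln229, horizon=96.0)
        assert sorted(df["parameter"]) == sorted(SWEEP_PARAMS)
        assert len(df) == 13 and "k12" not in set(df["parameter"])
        assert df["index"].is_monotonic_decreasing
        assert (df["normalizer"] == df["normalizer"].iloc[0]).all()


class TestInitialConditionSweep:
    def test_control_row_matches_control_trajectory(self, ln229):
        df = initial_condition_sweep(ln229, factors=(1.0,),
                                     o2_levels=(21.0,), horizon=96.0)
        ctrl = df[df["varied"] == "control"].iloc[0]
        same = df[(df["varied"] == "igfbp2") & (df["factor"] == 1.0)].iloc[0]
        assert same["final_gd"] == pytest.approx(ctrl["final_gd"], rel=1e-10)

    def test_hypoxia_gives_largest_growth_increase(self, ln229):
        df = initial_condition_sweep(ln229, factors=(0.1, 10.0),
                                     o2_levels=(2.0,), horizon=240.0)
        ctrl = df[df["varied"] == "control"]["final_gd"].iloc[0]
        hyp = df[df["o2_percent"] == 2.0]["final_gd"].iloc[0]
        assert hyp > ctrl
        # robustness to initial HIF1a: smaller effect than hypoxia
        hif_rows = df[df["varied"] == "hif1a"]["final_gd"]
        assert (hif_rows - ctrl).abs().max() < (hyp - ctrl)

    def test_factor_range_enforced(self, ln229):
        with pytest.raises(ValueError):
            initial_condition_sweep(ln229, factors=(20.0,))


class TestLhs:
    def test_two_sample_log_strata(self):
        d = lhs_sample(2, {"k": (0.1, 10.0)}, scale="log", seed=5)
        vals = np.sort(d.samples[:, 0])
        assert 0.1 <= vals[0] < 1.0 <= vals[1] <= 10.0

    def test_latin_property_exact_bin_counts(self):
        d = lhs_sample(500, {"a": (0.1, 10.0), "b": (1.0, 2.0)},
                       scale="log", seed=11)
        # 10 equal-probability bins must hold exactly 50 samples each
        log_edges = np.linspace(np.log10(0.1), np.log10(10.0), 11)
        counts, _ = np.histogram(np.log10(d.samples[:, 0]), bins=log_edges)
        assert list(counts) == [50] * 10

    def test_seed_determinism(self):
        r = {"a": (0.1, 10.0), "b": (0.5, 2.0)}
        d1 = lhs_sample(64, r, seed=3)
        d2 = lhs_sample(64, r, seed=3)
        np.testing.assert_array_equal(d1.samples, d2.samples)
        d3 = lhs_sample(64, r, seed=4)
        assert not np.array_equal(d1.samples, d3.samples)

    def test_degenerate_range_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = lhs_sample(8, {"a": (2.0, 2.0)}, scale="linear", seed=1)
        assert np.all(d.samples == 2.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            lhs_sample(1, {"a": (0.1, 1.0)}, seed=1)
        with pytest.raises(ValueError):
            lhs_sample(4, {"a": (0.0, 1.0)}, scale="log", seed=1)


class TestPartialCorrelation:
    def test_response_copies_one_column(self, rng):
        X = rng.normal(size=(400, 5))
        pc = partial_correlation(X, X[:, 2].copy())
        assert pc.iloc[2] > 0.99
        assert np.all(np.abs(pc.drop(pc.index[2])) < 0.2)

    def test_independent_response_near_zero(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 600
            X = r.normal(size=(n, 6))
            y = r.normal(size=n)
            pc = partial_correlation(X, y)
            assert np.all(np.abs(pc) < 3.0 / np.sqrt(n))

    def test_residual_and_precision_routes_agree(self, rng):
        X = rng.normal(size=(120, 7))
        y = X @ rng.normal(size=7) + rng.normal(size=120)
        a = partial_correlation(X, y, engine="residual")
        b = partial_correlation(X, y, engine="precision")
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(size=(80, 3))
        y = X[:, 0] * 0.5 + rng.normal(size=80)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        pc = partial_correlation(df[["a", "b", "c"]], y)
        for j, name in enumerate(["a", "b", "c"]):
            covar = [c for c in ["a", "b", "c"] if c != name]
            ref = pingouin.partial_corr(df, x=name, y="y", covar=covar)
            assert pc.loc[name] == pytest.approx(float(ref["r"].iloc[0]),
                                                 abs=1e-8)

    def test_dummy_parameter_in_model_sweep(self, ln229):
        # a constant that never enters the equations should show no
        # partial correlation with simulated growth
        ranges = factor_ranges(ln229.params, names=("v1", "k11"))
        ranges["dummy"] = (0.1, 10.0)
        design = lhs_sample(80, ranges, scale="log", seed=2)
        # the sampled "dummy" column is ignored by the model run
        y = run_lhs_growth(ln229, design, horizon=96.0)
        pc = partial_correlation(design, y)
        assert abs(pc.loc["dummy"]) < 3.0 / np.sqrt(80)
        assert pc.loc["k11"] > 0.5

    def test_sample_size_guard(self, rng):
        with pytest.raises(ValueError, match="samples"):
            partial_correlation(rng.normal(size=(6, 5)), np.arange(6.0))


class TestPca:
    def test_single_parameter_single_component(self):
        d = lhs_sample(32, {"a": (0.1, 10.0)}, seed=1)
        s = pca_summary(d)
        assert s.explained_variance_ratio.shape == (1,)
        assert s.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthonormal_loadings_and_unit_fraction_sum(self, rng):
        X = rng.lognormal(size=(100, 6))
        y = rng.normal(size=100)
        s = pca_summary(X, y)
        assert "response" in s.columns
        np.testing.assert_allclose(s.loadings @ s.loadings.T,
                                   np.eye(s.loadings.shape[0]), atol=1e-8)
        assert s.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_model_lhs_pca_components_are_diffuse(self, ln229):
        # 13 log-uniform constants + response: no single direction
        # should dominate (each PC carries roughly 1/14 of variance)
        ranges = factor_ranges(ln229.params, names=SWEEP_PARAMS)
        design = lhs_sample(120, ranges, scale="log", seed=9)
        y = run_lhs_growth(ln229, design, horizon=240.0)
        s = pca_summary(design, y)
        assert s.explained_variance_ratio[0] < 0.35
        assert s.explained_variance_ratio.sum() == pytest.approx(1.0)
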