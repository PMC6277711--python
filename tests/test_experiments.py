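"""Sweep experiments: crossing detector, monotone structure, intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mppsim import (
    compare_worlds,
    feasible_subsidy_interval,
    find_crossing,
    sweep_price_ratio,
    sweep_rd_scale,
    sweep_relative_intensity,
    sweep_royalty,
)

COARSE_RATIOS = np.round(np.arange(0.20, 0.50 + 1e-9, 0.01), 6)
COARSE_ROYALTIES = np.round(np.arange(0.0, 0.50 + 1e-9, 0.02), 6)
COARSE_SUBSIDIES = np.round(np.arange(0.0, 0.20 + 1e-9, 0.002), 6)


class TestFindCrossing:
    def test_linear_root(self):
        grid = np.arange(0.10, 0.60, 0.002)
        assert find_crossing(grid, grid - 0.358) == pytest.approx(0.358, abs=1e-12)

    def test_no_sign_change_returns_none(self):
        grid = np.linspace(0, 1, 11)
        assert find_crossing(grid, grid + 1.0) is None

    def test_exact_zero_returns_grid_point(self):
        assert find_crossing([0.0, 0.5, 1.0], [1.0, 0.0, -1.0]) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            find_crossing([0.0, 1.0], [1.0, 0.0, -1.0])

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            find_crossing([0.0, 0.0, 1.0], [1.0, 0.0, -1.0])

    @given(
        root=st.floats(0.05, 0.95),
        curvature=st.floats(0.2, 3.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_coarse_grid_agrees_with_dense_oracle(self, root, curvature):
        f = lambda x: (root**curvature - np.asarray(x) ** curvature)
        dense = np.linspace(0.0, 1.0, 2001)
        coarse = dense[::10]
        x_dense = find_crossing(dense, f(dense))
        x_coarse = find_crossing(coarse, f(coarse))
        spacing = coarse[1] - coarse[0]
        assert abs(x_coarse - x_dense) <= spacing


@pytest.fixture(scope="module")
def price_sweep(params):
    return sweep_price_ratio(params, COARSE_RATIOS)


@pytest.fixture(scope="module")
def royalty_sweep(params):
    return sweep_royalty(params, COARSE_ROYALTIES)


class TestPriceRatioSweep:
    def test_subsidy_margin_decreasing_in_ratio(self, price_sweep):
        margin = (
            price_sweep.frame["affordable_subsidy"]
            - price_sweep.frame["required_subsidy"]
        ).to_numpy()
        assert np.all(np.diff(margin) < 0.0)

    def test_government_savings_decreasing_in_ratio(self, price_sweep):
        assert np.all(np.diff(price_sweep.frame["affordable_subsidy"].to_numpy()) < 0)

    def test_affordable_exceeds_required_below_crossing(self, price_sweep):
        x = price_sweep.thresholds["price_ratio_crossing"]
        f = price_sweep.frame
        below = f[f["value"] < x]
        assert (below["affordable_subsidy"] > below["required_subsidy"]).all()

    def test_rerun_identical(self, params, price_sweep):
        again = sweep_price_ratio(params, COARSE_RATIOS)
        assert again.frame.equals(price_sweep.frame)
        assert again.thresholds == price_sweep.thresholds


class TestFeasibleSubsidyInterval:
    def test_empty_above_the_price_crossing(self, params):
        # the crossing must be located at the same royalty the scan uses
        sweep = sweep_price_ratio(params, COARSE_RATIOS, royalty_rate=0.05)
        x = sweep.thresholds["price_ratio_crossing"]
        interval = feasible_subsidy_interval(
            params, price_ratio=round(x + 0.05, 3), royalty_rate=0.05,
            s_grid=COARSE_SUBSIDIES,
        )
        assert interval.empty

    def test_width_non_increasing_in_price_ratio(self, params):
        widths = [
            feasible_subsidy_interval(params, x, 0.05, COARSE_SUBSIDIES).width
            for x in (0.15, 0.25, 0.35)
        ]
        assert widths[0] >= widths[1] >= widths[2] > 0.0

    def test_endpoints_sharp_at_grid_resolution(self, params):
        interval = feasible_subsidy_interval(params, 0.30, 0.05, COARSE_SUBSIDIES)
        step = COARSE_SUBSIDIES[1] - COARSE_SUBSIDIES[0]

        def joins(s):
            m = compare_worlds(
                params, price_ratio=0.30, royalty_rate=0.05, subsidy_coef=s
            ).metrics
            return m.joins_orig, m.joins_gov

        assert joins(interval.s_lo) == (True, True)
        assert joins(interval.s_hi) == (True, True)
        assert not joins(interval.s_lo - step)[0]
        assert not joins(interval.s_hi + step)[1]


class TestRoyaltySweep:
    def test_government_expenditure_invariant_to_royalty(self, royalty_sweep):
        d_gov = royalty_sweep.frame["d_gov"].to_numpy()
        assert np.ptp(d_gov) == 0.0

    def test_generic_profit_strictly_decreasing(self, royalty_sweep):
        d_gen = royalty_sweep.frame["d_profit_gen"].to_numpy()
        assert np.all(np.diff(d_gen) < 0.0)

    def test_originator_profit_mildly_increasing(self, royalty_sweep):
        d_orig = royalty_sweep.frame["d_profit_orig"].to_numpy()
        assert np.all(np.diff(d_orig) > 0.0)
        # royalty income is a small share of originator profit changes
        assert np.ptp(d_orig) < abs(np.ptp(royalty_sweep.frame["d_profit_gen"]))


class TestScaleAndIntensitySweeps:
    def test_rd_scale_profit_difference_non_increasing(self, params):
        grid = np.linspace(2e7, 4e8, 8)
        sw = sweep_rd_scale(params, grid)
        assert np.all(np.diff(sw.frame["profit_diff"].to_numpy()) <= 0.0)
        # trajectories scale-invariant -> the pre-subsidy difference is flat
        pre = sw.frame["profit_diff_pre_subsidy"].to_numpy()
        assert np.ptp(pre) <= 1e-9 * abs(pre[0])

    def test_joint_v0_scaling_leaves_patients_unchanged(self, params):
        from mppsim import Scenario, simulate

        base = simulate(Scenario(pooled=True), params).frame
        scaled = simulate(
            Scenario(pooled=True),
            params.replace(v0_in=3 * params.v0_in, v0_out=3 * params.v0_out),
        ).frame
        assert np.allclose(base["cp"], scaled["cp"], rtol=1e-12)

    def test_relative_intensity_profit_difference_non_decreasing(self, params):
        sw = sweep_relative_intensity(params, np.linspace(0.1, 0.9, 9))
        assert np.all(np.diff(sw.frame["profit_diff"].to_numpy()) >= 0.0)

    def test_symmetric_point_reproduces_default_run(self, params):
        sw = sweep_relative_intensity(params, [0.5])
        base = compare_worlds(params).metrics
        assert sw.frame["d_profit_orig"][0] == base.d_profit_orig
        assert sw.frame["d_gov"][0] == base.d_gov
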