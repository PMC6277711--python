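"""Event schedule, single-world trajectories and paired-world comparison."""

import numpy as np
import pytest

from mppsim import (
    ModelParameters,
    Scenario,
    build_schedule,
    compare_worlds,
    incidence_inflow,
    simulate,
)


class TestBuildSchedule:
    def test_pooled_world_events(self):
        sched = build_schedule(Scenario(pooled=True))
        assert sched.time_of("mpp_join") == 0.0
        assert sched.time_of("generic_launch_in_pool") == 2.0
        assert sched.time_of("patent_expiry") == 12.0
        assert sched.time_of("generic_launch_post_expiry") is None

    def test_unpooled_world_events(self):
        sched = build_schedule(Scenario(pooled=False))
        assert sched.time_of("generic_launch_post_expiry") == 14.0
        assert sched.time_of("generic_launch_in_pool") is None

    def test_event_beyond_horizon_dropped(self, caplog):
        s = Scenario(pooled=False, patent_life=9.0, horizon=10.0)
        with caplog.at_level("INFO", logger="mppsim.engine"):
            sched = build_schedule(s)
        assert sched.time_of("generic_launch_post_expiry") is None
        assert any("dropped" in r.message for r in caplog.records)


class TestSimulate:
    def test_record_count_and_time_grid(self, params):
        traj = simulate(Scenario(pooled=True), params)
        assert len(traj.frame) == 97
        t = traj.frame["t"].to_numpy()
        assert np.allclose(np.diff(t), 1.0 / 6.0)

    def test_empty_epidemic(self, params):
        p = params.replace(morbidity=0.0)
        s = Scenario(pooled=True, subsidy_coef=0.05)
        traj = simulate(s, p)
        f = traj.frame
        assert (f[["up", "cp", "rev_orig", "rev_gen"]].to_numpy() == 0.0).all()
        # expenditure is exactly the one-time pooling subsidy
        assert traj.ledger.cum_gov_expenditure == pytest.approx(0.05 * params.v0_in)

    def test_deterministic_rerun_bit_identical(self, params):
        a = simulate(Scenario(pooled=True), params)
        b = simulate(Scenario(pooled=True), params)
        assert a.content_hash() == b.content_hash()

    def test_stocks_nonnegative_and_conserved(self, params):
        for pooled in (True, False):
            traj = simulate(Scenario(pooled=pooled), params)
            f = traj.frame
            stocks = f[["up", "cp", "rejected", "cum_suspended", "cum_dead"]]
            assert (stocks.to_numpy() >= 0.0).all()
            total = stocks.sum(axis=1).to_numpy()
            inflow = incidence_inflow(params, 1.0 / 6.0)
            expected = inflow * np.arange(97)
            assert np.allclose(total, expected, rtol=1e-9)

    def test_population_doubling_doubles_patient_stocks(self, params):
        base = simulate(Scenario(pooled=True), params).frame
        double = simulate(
            Scenario(pooled=True), params.replace(population=2 * params.population)
        ).frame
        for col in ("up", "cp", "rejected"):
            assert np.allclose(
                double[col].to_numpy(), 2.0 * base[col].to_numpy(), rtol=1e-12
            )

    def test_royalty_conservation_along_trajectory(self, params):
        traj = simulate(Scenario(pooled=True, royalty_rate=0.1), params)
        f = traj.frame
        # royalty paid by the generic equals royalty credited to the originator
        expected_orig = (1 - params.psi) * (
            f["rev_orig"] * params.margin + f["royalty"]
        )
        assert np.allclose(
            f["profit_orig"].to_numpy()[1:], expected_orig.to_numpy()[1:], rtol=1e-12
        )
        assert traj.ledger.cum_royalty == pytest.approx(f["royalty"].sum())
        assert traj.ledger.cum_royalty > 0.0

    def test_step_halving_changes_ledgers_below_two_percent(self, params):
        coarse = simulate(Scenario(pooled=True), params).ledger
        fine = simulate(Scenario(pooled=True, dt=1.0 / 12.0), params).ledger
        for field in ("cum_profit_orig", "cum_profit_gen", "cum_gov_expenditure"):
            a, b = getattr(coarse, field), getattr(fine, field)
            assert abs(a - b) <= 0.02 * abs(a)

    def test_amortized_subsidy_totals_match_lump(self, params):
        lump = simulate(Scenario(pooled=True), params).ledger
        amort = simulate(
            Scenario(pooled=True), params.replace(subsidy_timing="amortized")
        ).ledger
        assert amort.cum_subsidy == pytest.approx(lump.cum_subsidy, rel=1e-9)


class TestCompareWorlds:
    def test_worlds_coincide_under_neutral_levers(self, params):
        # same generic timing, generic at the originator's price, no royalty,
        # no subsidy: the two worlds are economically identical
        kwargs = dict(price_ratio=1.0, royalty_rate=0.0, subsidy_coef=0.0)
        s_in = Scenario(pooled=True, t_join=2.0, generic_lag=2.0, **kwargs)
        s_out = Scenario(pooled=False, patent_life=2.0, generic_lag=2.0, **kwargs)
        led_in = simulate(s_in, params).ledger
        led_out = simulate(s_out, params).ledger
        assert led_in.cum_gov_expenditure == pytest.approx(
            led_out.cum_gov_expenditure, rel=1e-12
        )
        assert led_in.cum_profit_orig + led_in.cum_profit_gen == pytest.approx(
            led_out.cum_profit_orig + led_out.cum_profit_gen, rel=1e-12
        )

    def test_join_flags_are_sign_tests(self, params):
        m = compare_worlds(params).metrics
        assert m.joins_orig == (m.d_profit_orig >= 0.0)
        assert m.joins_gov == (m.d_gov >= 0.0)

    def test_decision_metrics_consistency(self, params):
        cmp = compare_worlds(params, subsidy_coef=0.06)
        m = cmp.metrics
        subsidy = cmp.pooled.ledger.cum_subsidy
        assert subsidy == pytest.approx(0.06 * params.v0_in)
        assert m.d_profit_orig == pytest.approx(subsidy - m.required_subsidy, rel=1e-9)
        assert m.d_gov == pytest.approx(m.affordable_subsidy - subsidy, rel=1e-9)
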