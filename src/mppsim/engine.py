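"""Simulation engine: event schedule, single-world stepping, paired worlds.

One world is advanced deterministically over the horizon (default 16 years
at a 2-month step, 97 records).  Within each step the update order is:

1. patent values and relative intensity (closed-form decay at the step's
   start time) and the drug attraction;
2. prices and originator/generic market shares;
3. patient flows (explicit Euler over the step);
4. revenues, profits, royalty, government expenditure (ledgers), using the
   start-of-step in-therapy stock so flows and money see the same prices;
5. scheduled events whose time equals the step's start (the pooling
   subsidy fires once at t_join in pooled worlds).

``compare_worlds`` runs the pooled and unpooled worlds on identical
parameters and returns the cumulative deltas and join decisions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import economics, patients
from .params import ModelParameters, Scenario
from .patent import patent_value, pooling_subsidy, relative_intensity
from .patients import PatientState, drug_attraction, generic_share_split

__all__ = [
    "EventSchedule",
    "Trajectory",
    "PairedComparison",
    "build_schedule",
    "simulate",
    "compare_worlds",
]

logger = logging.getLogger(__name__)

#: Trajectory CSV column order.
TRAJECTORY_COLUMNS = [
    "t", "up", "cp", "rejected", "cum_suspended", "cum_dead",
    "pp", "cp_flow", "attraction", "orig_share", "gen_share",
    "v_in", "v_out", "r_in",
    "p_orig", "p_gen",
    "rev_orig", "rev_gen", "profit_orig", "profit_gen", "royalty",
    "gov_expenditure", "subsidy",
    "cum_profit_orig", "cum_profit_gen", "cum_gov_expenditure",
    "cum_royalty", "cum_subsidy", "cum_tax",
]


@dataclasses.dataclass(frozen=True)
class EventSchedule:
    """Ordered (time, kind) events for one world."""

    events: tuple[tuple[float, str], ...]

    def time_of(self, kind: str) -> Optional[float]:
        for t, k in self.events:
            if k == kind:
                return t
        return None


def build_schedule(scenario: Scenario) -> EventSchedule:
    """Assemble the world's event timeline from the scenario.

    Pooled worlds join the MPP at ``t_join`` and see the licensed generic
    ``generic_lag`` years later; unpooled worlds see the generic
    ``generic_lag`` years after patent expiry.  Events beyond the horizon
    are dropped with a logged notice.
    """
    events: list[tuple[float, str]] = [(scenario.t_launch, "launch")]
    if scenario.pooled:
        events.append((scenario.t_join, "mpp_join"))
        events.append(
            (scenario.t_join + scenario.generic_lag, "generic_launch_in_pool")
        )
    events.append((scenario.patent_life, "patent_expiry"))
    if not scenario.pooled:
        events.append(
            (scenario.patent_life + scenario.generic_lag,
             "generic_launch_post_expiry")
        )
    events.append((scenario.horizon, "horizon_end"))
    kept = []
    for t, kind in sorted(events):
        if t > scenario.horizon:
            logger.info("event %s at t=%.3f y beyond horizon, dropped", kind, t)
            continue
        kept.append((t, kind))
    return EventSchedule(events=tuple(kept))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Per-step records of one world plus its final cumulative ledger.

    ``frame`` has ``n_steps + 1`` rows; row 0 is the initial state at t=0,
    row k>0 holds the stocks after step k together with the flows, prices,
    shares and attraction that applied over that step.
    """

    scenario: Scenario
    params: ModelParameters
    frame: pd.DataFrame
    ledger: economics.EconLedger

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def content_hash(self) -> str:
        """SHA-256 of the trajectory values (determinism check)."""
        return hashlib.sha256(
            self.frame.to_csv(index=False).encode()
        ).hexdigest()


@dataclasses.dataclass(frozen=True)
class PairedComparison:
    """Pooled and unpooled trajectories on identical parameters plus the
    decision metrics derived from them."""

    pooled: Trajectory
    unpooled: Trajectory
    metrics: economics.DecisionMetrics


def simulate(scenario: Scenario, params: ModelParameters) -> Trajectory:
    """Advance one world over the horizon; deterministic.

    A royalty rate exceeding the generic maker's operating margin is
    allowed (the generic then runs at a loss in-pool, which is exactly the
    regime beyond the royalty ceiling) and logged.
    """
    if scenario.royalty_rate >= params.margin_gen:
        logger.info(
            "royalty_rate %.3f >= generic operating margin %.3f: "
            "licensed generic runs at a loss",
            scenario.royalty_rate, params.margin_gen,
        )

    schedule = build_schedule(scenario)
    gen_launch = scenario.generic_launch_time
    if gen_launch > scenario.horizon:
        gen_launch = None  # dropped event: no generic within the horizon

    n = scenario.n_steps
    dt = scenario.dt
    m = params.m_share
    join_step = round(scenario.t_join / dt) if scenario.pooled else None
    subsidy_total = (
        pooling_subsidy(scenario.subsidy_coef, params.v0_in)
        if scenario.pooled
        else 0.0
    )
    if scenario.pooled and params.subsidy_timing == "amortized":
        amort_span = scenario.patent_life - scenario.t_join
        amort_steps = max(1, round(amort_span / dt))
        subsidy_per_step = subsidy_total / amort_steps
    else:
        amort_steps = 0
        subsidy_per_step = 0.0

    state = PatientState()
    ledger = economics.EconLedger()
    rows = np.zeros((n + 1, len(TRAJECTORY_COLUMNS)))
    cols = {name: j for j, name in enumerate(TRAJECTORY_COLUMNS)}

    def write_row(k, t, st, led, **vals):
        row = rows[k]
        row[cols["t"]] = t
        row[cols["up"]] = st.up
        row[cols["cp"]] = st.cp
        row[cols["rejected"]] = st.rejected
        row[cols["cum_suspended"]] = st.cum_suspended
        row[cols["cum_dead"]] = st.cum_dead
        for name, v in vals.items():
            row[cols[name]] = v
        row[cols["cum_profit_orig"]] = led.cum_profit_orig
        row[cols["cum_profit_gen"]] = led.cum_profit_gen
        row[cols["cum_gov_expenditure"]] = led.cum_gov_expenditure
        row[cols["cum_royalty"]] = led.cum_royalty
        row[cols["cum_subsidy"]] = led.cum_subsidy
        row[cols["cum_tax"]] = led.cum_tax

    v_in0 = patent_value(params.v0_in, params.tau, params.d, 0.0)
    v_out0 = patent_value(params.v0_out, params.tau, params.d, 0.0)
    write_row(
        0, 0.0, state, ledger,
        v_in=v_in0, v_out=v_out0, r_in=relative_intensity(v_in0, v_out0),
        p_orig=params.p_orig, p_gen=np.nan,
        orig_share=m, gen_share=0.0, attraction=np.nan,
    )

    cum_inflow = 0.0
    for k in range(n):
        t = k * dt
        # 1. patent state and attraction
        v_in = patent_value(params.v0_in, params.tau, params.d, t)
        v_out = patent_value(params.v0_out, params.tau, params.d, t)
        r_in = relative_intensity(v_in, v_out)
        # 2. prices and shares
        p_orig, p_gen = economics.step_prices(scenario, params, t)
        if gen_launch is None:
            orig_share, gen_share = m, 0.0
        else:
            orig_share, gen_share = generic_share_split(
                t - gen_launch, m, params.gen_share_frac, params.gen_ramp_years
            )
        if m > 0.0 and gen_share > 0.0:
            avg_price = (orig_share * p_orig + gen_share * p_gen) / m
        else:
            avg_price = p_orig
        attraction = drug_attraction(
            r_in, avg_price, params.p_orig, params.gamma_r, params.gamma_p
        )
        delta = 1  # the focal drug class is marketed throughout in both worlds
        # 3. patient flows
        inflow = patients.incidence_inflow(params, dt)
        cp_start = state.cp
        state, flows = patients.step_patient_flow(
            state, inflow, attraction, delta, params, dt
        )
        cum_inflow += inflow
        # 4. money, on the start-of-step in-therapy stock
        in_pool_gen = scenario.pooled and p_gen is not None
        rev_orig, rev_gen = economics.step_revenues(
            cp_start, orig_share, gen_share, m, p_orig, p_gen, dt
        )
        profit_gen, royalty = economics.step_profit_gen(
            rev_gen, scenario.royalty_rate, params, in_pool_gen
        )
        profit_orig = economics.step_profit_orig(
            rev_orig, royalty, params, scenario.pooled
        )
        # 5. events at the step's start time
        subsidy_event = 0.0
        if scenario.pooled:
            if params.subsidy_timing == "lump":
                if k == join_step:
                    subsidy_event = subsidy_total
            elif join_step <= k < join_step + amort_steps:
                subsidy_event = subsidy_per_step
        gov = economics.step_gov_expenditure(
            cp_start, orig_share, gen_share, m, p_orig, p_gen, subsidy_event, dt
        )
        tax = params.psi / (1.0 - params.psi) * max(0.0, profit_orig + profit_gen)
        if params.credit_tax_to_gov:
            gov -= tax
        disc = (
            np.exp(-params.discount_rate * t) if params.discount_rate > 0.0 else 1.0
        )
        ledger = ledger.add(
            profit_orig=profit_orig * disc,
            profit_gen=profit_gen * disc,
            gov=gov * disc,
            royalty=royalty * disc,
            subsidy=subsidy_event * disc,
            tax=tax * disc,
        )
        write_row(
            k + 1, (k + 1) * dt, state, ledger,
            v_in=v_in, v_out=v_out, r_in=r_in,
            p_orig=p_orig, p_gen=p_gen if p_gen is not None else np.nan,
            orig_share=orig_share, gen_share=gen_share, attraction=attraction,
            pp=flows.pp, cp_flow=flows.cp_flow,
            rev_orig=rev_orig, rev_gen=rev_gen,
            profit_orig=profit_orig, profit_gen=profit_gen,
            royalty=royalty, gov_expenditure=gov, subsidy=subsidy_event,
        )
        # invariant: conservation of persons through the bookkeeping
        drift = abs(state.total - cum_inflow)
        if drift > 1e-6 * max(1.0, cum_inflow):
            raise RuntimeError(
                f"patient conservation violated at step {k}: drift {drift!r}"
            )

    frame = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(scenario=scenario, params=params, frame=frame, ledger=ledger)


def compare_worlds(
    params: ModelParameters,
    price_ratio: float = 0.40,
    royalty_rate: float = 0.05,
    subsidy_coef: float = 0.065,
    scenario_kwargs: Optional[dict] = None,
) -> PairedComparison:
    """Run pooled and unpooled worlds on identical parameters and return
    the cumulative deltas at the horizon with the join decisions.

    The required subsidy (originator pre-subsidy shortfall) and affordable
    subsidy (government pre-subsidy savings) are reported alongside the
    with-subsidy decision metrics.
    """
    kwargs = dict(scenario_kwargs or {})
    kwargs.update(
        price_ratio=price_ratio,
        royalty_rate=royalty_rate,
        subsidy_coef=subsidy_coef,
    )
    s_in = Scenario(pooled=True, **kwargs)
    s_out = Scenario(pooled=False, **kwargs)
    traj_in = simulate(s_in, params)
    traj_out = simulate(s_out, params)
    led_in, led_out = traj_in.ledger, traj_out.ledger
    required = led_out.cum_profit_orig - led_in.cum_profit_orig
    affordable = led_out.cum_gov_expenditure - (
        led_in.cum_gov_expenditure - led_in.cum_subsidy
    )
    metrics = economics.DecisionMetrics(
        d_profit_orig=(led_in.cum_profit_orig + led_in.cum_subsidy)
        - led_out.cum_profit_orig,
        d_profit_gen=led_in.cum_profit_gen - led_out.cum_profit_gen,
        d_gov=led_out.cum_gov_expenditure - led_in.cum_gov_expenditure,
        required_subsidy=required,
        affordable_subsidy=affordable,
    )
    return PairedComparison(pooled=traj_in, unpooled=traj_out, metrics=metrics)
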