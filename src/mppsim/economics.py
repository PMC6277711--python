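"""Prices, revenues, costs, royalties, taxes, subsidies and the decision metrics.

Enterprise profit is after-tax operating profit: sales revenue net of
production and marketing cost shares, plus royalty income (originator,
in-pool) or minus royalty paid (licensed generic), times (1 - psi).
Government medical expenditure is the drug purchase bill for all treated
patients on the focal class at prevailing prices, plus the pooling subsidy
in worlds that join the MPP.

Cumulative ledgers over paired worlds yield the decision metrics: the
originator joins when its in-pool cumulative profit (including royalty and
subsidy) is at least its out-of-pool profit; the government joins when its
expenditure in-pool is at most its expenditure out-of-pool.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .params import ModelParameters, Scenario

__all__ = [
    "EconLedger",
    "DecisionMetrics",
    "step_prices",
    "step_revenues",
    "step_profit_orig",
    "step_profit_gen",
    "step_gov_expenditure",
]


@dataclasses.dataclass(frozen=True)
class EconLedger:
    """Cumulative economic quantities (dollars) for one world.

    ``cum_profit_orig`` excludes the pooling subsidy, which is tracked in
    ``cum_subsidy``; the originator's total in-pool take is their sum.
    """

    cum_profit_orig: float = 0.0
    cum_profit_gen: float = 0.0
    cum_gov_expenditure: float = 0.0
    cum_royalty: float = 0.0
    cum_subsidy: float = 0.0
    cum_tax: float = 0.0

    def add(
        self,
        profit_orig: float = 0.0,
        profit_gen: float = 0.0,
        gov: float = 0.0,
        royalty: float = 0.0,
        subsidy: float = 0.0,
        tax: float = 0.0,
    ) -> "EconLedger":
        return EconLedger(
            cum_profit_orig=self.cum_profit_orig + profit_orig,
            cum_profit_gen=self.cum_profit_gen + profit_gen,
            cum_gov_expenditure=self.cum_gov_expenditure + gov,
            cum_royalty=self.cum_royalty + royalty,
            cum_subsidy=self.cum_subsidy + subsidy,
            cum_tax=self.cum_tax + tax,
        )


@dataclasses.dataclass(frozen=True)
class DecisionMetrics:
    """Paired-world deltas at the horizon and the implied join decisions.

    d_profit_orig : in-pool minus out-of-pool originator cumulative profit,
        royalty and subsidy included.
    d_profit_gen : in-pool minus out-of-pool generic cumulative profit.
    d_gov : out-of-pool minus in-pool government expenditure (savings),
        subsidy included.
    required_subsidy : the originator's pre-subsidy profit shortfall from
        joining (out-of-pool minus in-pool profit, royalty included).
    affordable_subsidy : the government's pre-subsidy expenditure savings
        from joining.
    """

    d_profit_orig: float
    d_profit_gen: float
    d_gov: float
    required_subsidy: float
    affordable_subsidy: float

    @property
    def joins_orig(self) -> bool:
        return self.d_profit_orig >= 0.0

    @property
    def joins_gov(self) -> bool:
        return self.d_gov >= 0.0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["joins_orig"] = self.joins_orig
        out["joins_gov"] = self.joins_gov
        return out


def step_prices(
    scenario: Scenario, params: ModelParameters, t: float
) -> tuple[float, Optional[float]]:
    """Prices at time ``t`` ($/patient-year).

    The originator's price is constant in both worlds (under MPP rules the
    original price may be retained).  The generic price is
    ``price_ratio * p_orig`` from the world's generic launch; ``None``
    before.
    """
    p_gen = None
    if t >= scenario.generic_launch_time:
        p_gen = scenario.price_ratio * params.p_orig
    return params.p_orig, p_gen


def step_revenues(
    cp: float,
    orig_share: float,
    gen_share: float,
    m: float,
    p_orig: float,
    p_gen: Optional[float],
    dt: float,
) -> tuple[float, float]:
    """Sales revenues over one step: treated patients on each product times
    its annual price times the step length.

    ``cp * (share / m)`` is the number of treated patients on that product.
    """
    if m <= 0.0:
        return 0.0, 0.0
    rev_orig = cp * (orig_share / m) * p_orig * dt
    rev_gen = cp * (gen_share / m) * (p_gen or 0.0) * dt
    return rev_orig, rev_gen


def step_profit_orig(
    rev_orig: float, royalty_in: float, params: ModelParameters, in_pool: bool
) -> float:
    """Originator after-tax profit for one step.

    (1 - psi) * (rev * (1 - c_prod - c_mkt) + royalty); royalty income only
    accrues in-pool.
    """
    royalty = royalty_in if in_pool else 0.0
    return (1.0 - params.psi) * (rev_orig * params.margin + royalty)


def step_profit_gen(
    rev_gen: float, royalty_rate: float, params: ModelParameters, in_pool: bool
) -> tuple[float, float]:
    """Generic maker's after-tax profit and royalty paid for one step.

    The licensed in-pool generic pays ``royalty_rate`` of its sales revenue
    to the originator; the out-of-pool generic enters after patent expiry
    royalty-free.
    """
    if not (0.0 <= royalty_rate < 1.0):
        raise ValueError(f"royalty_rate must lie in [0, 1), got {royalty_rate!r}")
    royalty_paid = royalty_rate * rev_gen if in_pool else 0.0
    profit = (1.0 - params.psi) * (rev_gen * params.margin_gen - royalty_paid)
    return profit, royalty_paid


def step_gov_expenditure(
    cp: float,
    orig_share: float,
    gen_share: float,
    m: float,
    p_orig: float,
    p_gen: Optional[float],
    subsidy_event: float,
    dt: float,
) -> float:
    """Government medical expenditure for one step: the drug purchase bill
    at prevailing prices for all treated patients on the focal class, plus
    any pooling subsidy paid this step (nonzero only at the join step of
    pooled worlds, or over the amortization window)."""
    if subsidy_event < 0.0:
        raise ValueError(f"subsidy_event must be >= 0, got {subsidy_event!r}")
    rev_orig, rev_gen = step_revenues(cp, orig_share, gen_share, m, p_orig, p_gen, dt)
    return rev_orig + rev_gen + subsidy_event
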