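"""Patent value decay, relative patent intensity and the pooling subsidy.

A drug patent's value starts at the initial R&D investment V0 and is
consumed over time at a rate proportional to its current level,

    dV/dt = -V / (tau + 1/d),

where tau is the patent technology life cycle and d the substitutability of
competing technologies; the solution is exponential decay with time constant
tau + 1/d.  Relative patent intensity r = V_in / (V_in + V_out) drives drug
attraction.  The government's pooling subsidy is the product of a subsidy
coefficient and the originator's market-level initial R&D investment.
"""

from __future__ import annotations

import dataclasses
import math

__all__ = ["PatentState", "patent_value", "relative_intensity", "pooling_subsidy"]


@dataclasses.dataclass(frozen=True)
class PatentState:
    """Current patent values of the in-pool originator and the out-of-pool
    competitor aggregate."""

    v_in: float
    v_out: float

    def __post_init__(self) -> None:
        if self.v_in < 0.0 or self.v_out < 0.0:
            raise ValueError("patent values must be non-negative")

    @property
    def r_in(self) -> float:
        """Relative patent intensity of the in-pool originator."""
        return relative_intensity(self.v_in, self.v_out)


def patent_value(v0: float, tau: float, d: float, t: float) -> float:
    """Patent value at time ``t`` (years) under exponential depreciation.

    Returns ``v0 * exp(-t / (tau + 1/d))``, the closed-form solution of the
    decay equation.  With the default tau=10 y and d=0.05 the time constant
    is 30 years.

    Raises
    ------
    ValueError
        If ``tau`` or ``d`` is not positive, or ``t`` is negative.
    """
    if tau <= 0.0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    if d <= 0.0:
        raise ValueError(f"d must be > 0, got {d!r}")
    if t < 0.0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    return v0 * math.exp(-t / (tau + 1.0 / d))


def relative_intensity(v_in: float, v_out: float) -> float:
    """Relative patent intensity ``v_in / (v_in + v_out)`` in [0, 1].

    Scale-invariant: multiplying both values by the same positive constant
    leaves the result unchanged.

    Raises
    ------
    ValueError
        If either value is negative or both are zero (degenerate state).
    """
    if v_in < 0.0 or v_out < 0.0:
        raise ValueError("patent values must be non-negative")
    total = v_in + v_out
    if total <= 0.0:
        raise ValueError("degenerate patent state: v_in + v_out must be > 0")
    return v_in / total


def pooling_subsidy(subsidy_coef: float, v0_market: float) -> float:
    """Government pooling subsidy: coefficient times the originator's
    market-level initial R&D investment."""
    if subsidy_coef < 0.0:
        raise ValueError(f"subsidy_coef must be >= 0, got {subsidy_coef!r}")
    if v0_market < 0.0:
        raise ValueError(f"v0_market must be >= 0, got {v0_market!r}")
    return subsidy_coef * v0_market
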