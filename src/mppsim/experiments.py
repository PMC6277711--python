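"""Sweep experiments over the policy levers with threshold detection.

Five reusable sweeps mirror the questions a pool organizer asks:

- price ratio: where do the government's pre-subsidy savings stop covering
  the originator's pre-subsidy shortfall (the highest generic price ratio
  at which a subsidy acceptable to both parties exists)?
- subsidy coefficient: over which interval do both the originator and the
  government prefer joining, at a given price ratio and royalty rate?
- royalty rate: above which rate does the licensed generic's cumulative
  profit fall below its out-of-pool (post-expiry entry) baseline?
- R&D scale: how does the originator's profit difference move as the
  initial R&D investments grow jointly at a fixed in/out ratio?
- initial relative intensity: how does the profit difference move with the
  originator's share of total initial R&D?

All sweeps are deterministic; thresholds are located by linear
interpolation between the bracketing grid points of the first sign change.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import compare_worlds
from .params import ModelParameters, Scenario

__all__ = [
    "SweepResult",
    "FeasibleInterval",
    "find_crossing",
    "sweep_price_ratio",
    "feasible_subsidy_interval",
    "sweep_royalty",
    "sweep_rd_scale",
    "sweep_relative_intensity",
    "DEFAULT_PRICE_RATIO_GRID",
    "DEFAULT_SUBSIDY_GRID",
    "DEFAULT_ROYALTY_GRID",
]

# Default grids, fine enough to resolve thresholds at their reported precision.
DEFAULT_PRICE_RATIO_GRID = np.round(np.arange(0.10, 0.60 + 1e-9, 0.002), 6)
DEFAULT_SUBSIDY_GRID = np.round(np.arange(0.0, 0.20 + 1e-9, 0.001), 6)
DEFAULT_ROYALTY_GRID = np.round(np.arange(0.0, 0.60 + 1e-9, 0.002), 6)


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Grid of lever values with paired-world metrics and detected thresholds."""

    lever: str
    grid: np.ndarray
    frame: pd.DataFrame            # one row per grid point
    thresholds: dict[str, Optional[float]]

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


@dataclasses.dataclass(frozen=True)
class FeasibleInterval:
    """Contiguous subsidy-coefficient interval acceptable to both parties;
    empty when no coefficient satisfies both join conditions."""

    price_ratio: float
    royalty_rate: float
    s_lo: Optional[float]
    s_hi: Optional[float]

    @property
    def empty(self) -> bool:
        return self.s_lo is None

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.s_hi - self.s_lo


def find_crossing(grid: Sequence[float], f: Sequence[float]) -> Optional[float]:
    """Lever value at the first sign change of ``f`` along ``grid``.

    Located by linear interpolation between the bracketing grid points;
    an exact zero returns that grid point; ``None`` if ``f`` never changes
    sign.
    """
    grid = np.asarray(grid, dtype=float)
    f = np.asarray(f, dtype=float)
    if grid.shape != f.shape:
        raise ValueError(
            f"grid and f must have the same length, got {grid.size} and {f.size}"
        )
    if grid.size and np.any(np.diff(grid) <= 0.0):
        raise ValueError("grid must be strictly increasing")
    for i in range(f.size):
        if f[i] == 0.0:
            return float(grid[i])
        if i > 0 and (f[i - 1] > 0.0) != (f[i] > 0.0):
            x0, x1, y0, y1 = grid[i - 1], grid[i], f[i - 1], f[i]
            return float(x0 - y0 * (x1 - x0) / (y1 - y0))
    return None


def _metrics_row(params, lever, value, **levers):
    cmp = compare_worlds(params, **levers)
    m = cmp.metrics
    return {
        "lever": lever,
        "value": value,
        "d_profit_orig": m.d_profit_orig,
        "d_profit_gen": m.d_profit_gen,
        "d_gov": m.d_gov,
        "required_subsidy": m.required_subsidy,
        "affordable_subsidy": m.affordable_subsidy,
        "joins_orig": m.joins_orig,
        "joins_gov": m.joins_gov,
    }


def sweep_price_ratio(
    params: ModelParameters,
    grid: Sequence[float] = DEFAULT_PRICE_RATIO_GRID,
    royalty_rate: float = None,
    subsidy_coef: float = None,
) -> SweepResult:
    """Sweep the generic price ratio; detect where the government's
    affordable subsidy stops covering the originator's required subsidy."""
    grid = np.asarray(grid, dtype=float)
    defaults = Scenario(pooled=True)
    royalty_rate = defaults.royalty_rate if royalty_rate is None else royalty_rate
    subsidy_coef = defaults.subsidy_coef if subsidy_coef is None else subsidy_coef
    rows = [
        _metrics_row(
            params, "price_ratio", x,
            price_ratio=float(x), royalty_rate=royalty_rate,
            subsidy_coef=subsidy_coef,
        )
        for x in grid
    ]
    frame = pd.DataFrame(rows)
    margin = frame["affordable_subsidy"] - frame["required_subsidy"]
    crossing = find_crossing(grid, margin.to_numpy())
    return SweepResult(
        lever="price_ratio", grid=grid, frame=frame,
        thresholds={"price_ratio_crossing": crossing},
    )


def feasible_subsidy_interval(
    params: ModelParameters,
    price_ratio: float,
    royalty_rate: float,
    s_grid: Sequence[float] = DEFAULT_SUBSIDY_GRID,
) -> FeasibleInterval:
    """Endpoints of the contiguous subsidy-coefficient region where both the
    originator and the government decide to join.

    Raises
    ------
    RuntimeError
        If the feasible set on the grid is non-contiguous (a non-monotone
        configuration).
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0 or np.any(np.diff(s_grid) <= 0.0) or s_grid[0] < 0.0:
        raise ValueError("s_grid must be non-empty, increasing and >= 0")
    both = np.zeros(s_grid.size, dtype=bool)
    for i, s in enumerate(s_grid):
        cmp = compare_worlds(
            params, price_ratio=price_ratio, royalty_rate=royalty_rate,
            subsidy_coef=float(s),
        )
        both[i] = cmp.metrics.joins_orig and cmp.metrics.joins_gov
    idx = np.flatnonzero(both)
    if idx.size == 0:
        return FeasibleInterval(price_ratio, royalty_rate, None, None)
    if not np.all(np.diff(idx) == 1):
        raise RuntimeError(
            "feasible subsidy set is non-contiguous on the grid "
            f"(indices {idx.tolist()}); non-monotone configuration"
        )
    return FeasibleInterval(
        price_ratio, royalty_rate,
        float(s_grid[idx[0]]), float(s_grid[idx[-1]]),
    )


def sweep_royalty(
    params: ModelParameters,
    grid: Sequence[float] = DEFAULT_ROYALTY_GRID,
    price_ratio: float = None,
    subsidy_coef: float = None,
) -> SweepResult:
    """Sweep the royalty rate; detect the rate above which the in-pool
    generic's cumulative profit falls below its out-of-pool baseline."""
    grid = np.asarray(grid, dtype=float)
    defaults = Scenario(pooled=True)
    price_ratio = defaults.price_ratio if price_ratio is None else price_ratio
    subsidy_coef = defaults.subsidy_coef if subsidy_coef is None else subsidy_coef
    rows = []
    for rho in grid:
        row = _metrics_row(
            params, "royalty_rate", rho,
            price_ratio=price_ratio, royalty_rate=float(rho),
            subsidy_coef=subsidy_coef,
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    crossing = find_crossing(grid, frame["d_profit_gen"].to_numpy())
    return SweepResult(
        lever="royalty_rate", grid=grid, frame=frame,
        thresholds={"royalty_ceiling": crossing},
    )


def sweep_rd_scale(
    params: ModelParameters,
    total_v0_grid: Sequence[float],
    ratio_in_out: float = None,
) -> SweepResult:
    """Scale (v0_in, v0_out) jointly at a fixed in/out ratio.

    Relative intensity — hence the patient trajectories — is invariant to
    the joint scale; the subsidy grows with v0_in, so the with-subsidy
    profit difference (out-of-pool minus in-pool) declines as the scale
    grows while the pre-subsidy difference stays constant.  Both are
    reported (columns ``profit_diff_pre_subsidy`` and ``profit_diff``).
    """
    grid = np.asarray(total_v0_grid, dtype=float)
    if ratio_in_out is None:
        ratio_in_out = params.v0_in / (params.v0_in + params.v0_out)
    rows = []
    for total in grid:
        p = params.replace(
            v0_in=total * ratio_in_out, v0_out=total * (1.0 - ratio_in_out)
        )
        row = _metrics_row(params=p, lever="rd_scale", value=total)
        row["profit_diff_pre_subsidy"] = row["required_subsidy"]
        row["profit_diff"] = -row["d_profit_orig"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    crossing = find_crossing(grid, frame["profit_diff"].to_numpy())
    return SweepResult(
        lever="rd_scale", grid=grid, frame=frame,
        thresholds={"break_even_scale": crossing},
    )


def sweep_relative_intensity(
    params: ModelParameters,
    r0_grid: Sequence[float],
) -> SweepResult:
    """Vary the originator's initial relative patent intensity r0 with its
    own initial R&D cost v0_in held constant (the competitors' v0_out is
    adjusted); report the originator's profit difference at each r0.

    A lower r0 weakens the drug attraction, shrinks the market and hence the
    profit difference from joining, making joining likelier.
    """
    grid = np.asarray(r0_grid, dtype=float)
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise ValueError("r0 grid values must lie strictly in (0, 1)")
    rows = []
    for r0 in grid:
        p = params.replace(v0_out=params.v0_in * (1.0 - r0) / r0)
        row = _metrics_row(params=p, lever="relative_intensity", value=r0)
        row["profit_diff_pre_subsidy"] = row["required_subsidy"]
        row["profit_diff"] = -row["d_profit_orig"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    crossing = find_crossing(grid, frame["profit_diff"].to_numpy())
    return SweepResult(
        lever="relative_intensity", grid=grid, frame=frame,
        thresholds={"break_even_r0": crossing},
    )
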